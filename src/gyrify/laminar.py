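"""Cortical layer thickness from layer band polygons.

Thickness of a layer is its band area divided by the band's tangential
length; the tangential length is measured along the band's mid-arc (the
average of its two long boundaries).  For any parallel-sided band this
equals the true width exactly, and for an annular sector it equals the
radial extent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon

from gyrify._util import UndefinedRatioError, as_points, polyline_length

LAYERS = ("L2/3", "L4", "L5", "L6")


@dataclass(frozen=True)
class LayerBand:
    """One cortical layer's band outline and mid-arc polyline (µm)."""

    layer: str
    polygon: np.ndarray          # (N, 2) outline
    tangential_curve: np.ndarray  # (M, 2) mid-arc

    def __post_init__(self):
        object.__setattr__(self, "polygon", as_points(self.polygon))
        object.__setattr__(self, "tangential_curve", as_points(self.tangential_curve))
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if not Polygon(self.polygon).is_valid:
            raise ValueError(f"layer {self.layer}: band outline is not a simple polygon")

    @property
    def area(self) -> float:
        return float(Polygon(self.polygon).area)

    @property
    def tangential_length(self) -> float:
        return polyline_length(self.tangential_curve)


def layer_thickness(band: LayerBand) -> float:
    """Band area divided by tangential length, in µm."""
    length = band.tangential_length
    if length <= 0:
        raise ValueError(f"layer {band.layer}: tangential length must be positive")
    return band.area / length


def thickness_ratio(ep: float, nonep: float) -> float:
    """EP thickness over nonEP thickness; 1 when the sides are equally thick."""
    if nonep == 0:
        raise UndefinedRatioError("nonEP thickness is zero, ratio undefined")
    return ep / nonep


def upper_lower_ratio(t23: float, t4: float, t5: float, t6: float) -> float:
    """Upper-layer (2/3) thickness over summed lower-layer (4-6) thickness."""
    lower = t4 + t5 + t6
    if lower == 0:
        raise UndefinedRatioError("lower-layer thickness sums to zero, ratio undefined")
    return t23 / lower
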