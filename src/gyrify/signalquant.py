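"""Threshold-based positive-area fractions, band densitometry and
reference-normalised per-cell signal intensities.

Positive area is the fraction of pixels strictly above a threshold inside a
column of interest, normalised by the column's total area.  Band
densitometry computes relative expression as
``(cortex signal / cortex loading control) / (cerebellum signal /
cerebellum loading control)``, which cancels loading differences and any
global exposure factor.  Per-cell in situ intensities are normalised by a
reference intensity (the cerebellar external granule layer of the same
section) before averaging per animal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import Polygon


@dataclass(frozen=True)
class IntensityField:
    """Grayscale raster with physical placement (µm per pixel, µm origin).

    ``values`` is row-major with pixel (0, 0) at ``origin``; pixels outside
    the generating region are NaN.
    """

    values: np.ndarray
    origin: tuple[float, float]
    pixel_size_um: float

    def pixel_centers(self):
        ny, nx = self.values.shape
        xs = self.origin[0] + (np.arange(nx) + 0.5) * self.pixel_size_um
        ys = self.origin[1] + (np.arange(ny) + 0.5) * self.pixel_size_um
        return np.meshgrid(xs, ys)


@dataclass(frozen=True)
class AreaQuant:
    positive_area_um2: float
    total_area_um2: float

    @property
    def fraction(self) -> float:
        return self.positive_area_um2 / self.total_area_um2 if self.total_area_um2 else float("nan")


def positive_area_fraction(field: IntensityField, roi, threshold: float) -> AreaQuant:
    """Fraction of ROI pixels strictly above ``threshold``.

    ``roi`` is a polygon ((N, 2) array or shapely Polygon); a pixel belongs
    to the ROI when its centre lies inside.  Monotone non-increasing in the
    threshold.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    poly = roi if isinstance(roi, Polygon) else Polygon(np.asarray(roi, dtype=float))
    xx, yy = field.pixel_centers()
    inside = shapely.contains_xy(poly, xx.ravel(), yy.ravel()).reshape(xx.shape)
    inside &= np.isfinite(field.values)
    n_total = int(inside.sum())
    if n_total == 0:
        raise ValueError("ROI does not intersect the intensity field")
    n_pos = int((field.values[inside] > threshold).sum())
    px_area = field.pixel_size_um**2
    return AreaQuant(positive_area_um2=n_pos * px_area, total_area_um2=n_total * px_area)


def relative_expression(
    signal_ctx: float, control_ctx: float, signal_cb: float, control_cb: float
) -> float:
    """(cortex signal / cortex control) / (cerebellum signal / cerebellum control).

    With the cerebellar pair set to (1, 1) this reduces to the plain
    loading-corrected cortex ratio used for immunoblot quantification.
    """
    vals = (signal_ctx, control_ctx, signal_cb, control_cb)
    if any(v <= 0 for v in vals):
        raise ValueError(f"band intensities must be positive, got {vals}")
    return (signal_ctx / control_ctx) / (signal_cb / control_cb)


def normalized_cell_intensity(raw, reference: float):
    """Per-cell raw/reference intensities and their per-animal mean.

    Returns ``(normalized_array, mean)``; an empty cell set yields an empty
    array and NaN with a warning.
    """
    if reference <= 0:
        raise ValueError("reference intensity must be positive")
    raw = np.asarray(raw, dtype=float)
    if raw.size and (raw < 0).any():
        raise ValueError("raw intensities must be non-negative")
    norm = raw / reference
    if norm.size == 0:
        warnings.warn("no cells supplied; mean normalised intensity undefined")
        return norm, float("nan")
    return norm, float(norm.mean())
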