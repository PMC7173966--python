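"""Progenitor subtype classification and counting statistics.

Cells carry per-marker boolean calls (or raw intensities plus a threshold)
and a laminar zone label.  Subtypes follow the marker logic used for
germinal-zone counting in gyrencephalic cortex:

* **IP** — Tbr2+ (unconditionally, even if Pax6+ or HOPX+);
* **HOPX+ oRG** — Pax6+ / Tbr2− / HOPX+;
* **HOPX− oRG** — Pax6+ / Tbr2− / HOPX−;
* **other** — everything else (excluded from the progenitor denominator).

"All progenitors" means Pax6+ and/or Tbr2+.  Counts are taken inside
column ROIs (rectangles oriented perpendicular to the ventricular
surface, 100-600 µm wide); column edges are half-open so tiling columns
partition a region exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from gyrify._util import UndefinedRatioError

PROGENITOR_CLASSES = ("HOPX_pos_oRG", "HOPX_neg_oRG", "IP")
ALL_CLASSES = PROGENITOR_CLASSES + ("other",)
COLUMN_WIDTH_RANGE_UM = (100.0, 600.0)


def call_positive(intensity: float, threshold: float):
    """Strictly-greater threshold call; NaN intensity gives a missing call."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if intensity is None or (isinstance(intensity, float) and np.isnan(intensity)):
        return None
    return bool(intensity > threshold)


def otsu_threshold(values) -> float:
    """Otsu's threshold for a 1-D intensity sample (two-class separation)."""
    from skimage.filters import threshold_otsu

    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 2 or np.ptp(values) == 0:
        raise ValueError("need at least two distinct finite intensities for Otsu")
    return float(threshold_otsu(values))


def classify_progenitor(pax6: bool, tbr2: bool, hopx: bool) -> str:
    """Map one cell's Pax6/Tbr2/HOPX calls to its progenitor class."""
    if tbr2:
        return "IP"
    if pax6:
        return "HOPX_pos_oRG" if hopx else "HOPX_neg_oRG"
    return "other"


def _as_calls(col: pd.Series, threshold) -> np.ndarray:
    """Boolean calls from a marker column (booleans/0-1 pass through)."""
    vals = col.to_numpy()
    if vals.dtype == bool:
        return vals
    finite = vals[np.isfinite(vals.astype(float))]
    if np.isin(finite, (0, 1)).all():
        return vals.astype(float) > 0.5
    if threshold is None:
        threshold = otsu_threshold(vals)
    elif threshold == "otsu":
        threshold = otsu_threshold(vals)
    missing = ~np.isfinite(vals.astype(float))
    if missing.any():
        warnings.warn(f"{int(missing.sum())} missing intensities excluded from calls")
    return vals.astype(float) > float(threshold)


def classify_table(
    cells: pd.DataFrame,
    pax6: str = "Pax6",
    tbr2: str = "Tbr2",
    hopx: str = "HOPX_protein",
    thresholds: dict | None = None,
) -> pd.Series:
    """Vectorised classification; returns a 'cell_class' Series aligned to ``cells``.

    ``thresholds`` maps marker column names to a numeric threshold or
    ``"otsu"``; it is only consulted for float intensity columns.
    """
    thresholds = thresholds or {}
    p = _as_calls(cells[pax6], thresholds.get(pax6))
    t = _as_calls(cells[tbr2], thresholds.get(tbr2))
    h = _as_calls(cells[hopx], thresholds.get(hopx))
    out = np.where(t, "IP", np.where(p & h, "HOPX_pos_oRG", np.where(p, "HOPX_neg_oRG", "other")))
    return pd.Series(out, index=cells.index, name="cell_class")


@dataclass(frozen=True)
class ColumnROI:
    """Rectangular counting column.

    ``origin`` is the column's inner (ventricular-side) midpoint, ``axis``
    the unit vector toward the pial surface; the column spans [0, length)
    along the axis and [-width/2, width/2) across it — half-open on the
    high edges so adjacent columns never double-count.
    """

    origin: np.ndarray
    axis: np.ndarray
    length: float
    width: float
    region_label: str = ""
    enforce_width_range: bool = True

    def __post_init__(self):
        o = np.asarray(self.origin, dtype=float)
        a = np.asarray(self.axis, dtype=float)
        n = np.hypot(*a)
        if n == 0:
            raise ValueError("column axis must be a nonzero vector")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "axis", a / n)
        if self.length <= 0 or self.width <= 0:
            raise ValueError("column length and width must be positive")
        lo, hi = COLUMN_WIDTH_RANGE_UM
        if self.enforce_width_range and not (lo <= self.width <= hi):
            raise ValueError(f"column width {self.width} µm outside the {lo}-{hi} µm range")

    def contains(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float)) - self.origin
        normal = np.array([-self.axis[1], self.axis[0]])
        u = pts @ self.axis
        v = pts @ normal
        return (u >= 0) & (u < self.length) & (v >= -self.width / 2) & (v < self.width / 2)

    @property
    def polygon(self) -> np.ndarray:
        normal = np.array([-self.axis[1], self.axis[0]])
        h = self.width / 2
        return np.array(
            [
                self.origin - h * normal,
                self.origin + self.length * self.axis - h * normal,
                self.origin + self.length * self.axis + h * normal,
                self.origin + h * normal,
            ]
        )


def radial_column(
    angle: float,
    r_inner: float,
    r_outer: float,
    width: float,
    region_label: str = "",
    center=(0.0, 0.0),
) -> ColumnROI:
    """Column along the radius at ``angle`` spanning [r_inner, r_outer)."""
    axis = np.array([np.cos(angle), np.sin(angle)])
    origin = np.asarray(center, dtype=float) + r_inner * axis
    return ColumnROI(
        origin=origin, axis=axis, length=r_outer - r_inner, width=width, region_label=region_label
    )


def _predicate_mask(cells: pd.DataFrame, condition) -> np.ndarray:
    """Boolean mask for a marker condition: name, sequence (conjunction) or callable."""
    if condition is None:
        return np.ones(len(cells), dtype=bool)
    if callable(condition):
        return np.asarray(condition(cells), dtype=bool)
    names = [condition] if isinstance(condition, str) else list(condition)
    mask = np.ones(len(cells), dtype=bool)
    for name in names:
        mask &= _as_calls(cells[name], None)
    return mask


def count_in_column(
    cells: pd.DataFrame,
    roi: ColumnROI,
    condition=None,
    class_column: str = "cell_class",
) -> dict[str, int]:
    """Per-class counts of cells inside the column (plus the 'All' total).

    'All' counts Pax6+ and/or Tbr2+ cells, i.e. every classified
    progenitor.  ``condition`` restricts counting to cells satisfying a
    marker predicate.  An ROI containing no cells returns zeros with a
    warning.
    """
    if len(cells) == 0:
        return {cls: 0 for cls in (*ALL_CLASSES, "All")}
    inside = roi.contains(cells[["x_um", "y_um"]].to_numpy())
    if not inside.any():
        warnings.warn(f"column {roi.region_label or '?'} contains no cells")
    inside &= _predicate_mask(cells, condition)
    sub = cells.loc[inside, class_column]
    counts = {cls: int((sub == cls).sum()) for cls in ALL_CLASSES}
    counts["All"] = counts["HOPX_pos_oRG"] + counts["HOPX_neg_oRG"] + counts["IP"]
    return counts


def count_table(
    cells: pd.DataFrame,
    rois: dict[str, ColumnROI],
    conditions: dict[str, object] | None = None,
    class_column: str = "cell_class",
) -> pd.DataFrame:
    """Tidy table of counts keyed by (region, condition, class)."""
    conditions = conditions or {"none": None}
    rows = []
    for region, roi in rois.items():
        for cond_name, cond in conditions.items():
            counts = count_in_column(cells, roi, cond, class_column)
            for cls, n in counts.items():
                rows.append(
                    {"region": region, "condition": cond_name, "cell_class": cls, "count": n}
                )
    return pd.DataFrame(rows)


def cell_number_ratio(count_ep: int, count_nonep: int) -> float:
    """EP-side count over contralateral nonEP-side count of the same section."""
    if count_nonep == 0:
        raise UndefinedRatioError("nonEP count is zero, cell number ratio undefined")
    return count_ep / count_nonep


def region_ratio(
    counts: pd.DataFrame, numerator_region: str, denominator_region: str, cls: str = "All"
) -> float:
    """Count in one region divided by the corresponding count in another.

    1 means equal abundance of ``cls`` in both regions.
    """
    def _get(region):
        sel = counts[(counts["region"] == region) & (counts["cell_class"] == cls)]
        if sel.empty:
            raise KeyError(f"no counts for region {region!r}, class {cls!r}")
        return int(sel["count"].sum())

    num, den = _get(numerator_region), _get(denominator_region)
    if den == 0:
        raise UndefinedRatioError(
            f"zero {cls} count in region {denominator_region!r}, region ratio undefined"
        )
    return num / den


def subtype_proportions(counts: dict[str, int]) -> dict[str, float]:
    """Class proportions among (HOPX+ oRG + HOPX− oRG + IP); they sum to 1."""
    total = sum(counts.get(c, 0) for c in PROGENITOR_CLASSES)
    if total == 0:
        warnings.warn("empty column: subtype proportions undefined")
        return {c: float("nan") for c in PROGENITOR_CLASSES}
    return {c: counts.get(c, 0) / total for c in PROGENITOR_CLASSES}


def colabel_fraction(
    cells: pd.DataFrame,
    base_class: str,
    label_set,
    class_column: str = "cell_class",
) -> float:
    """Fraction of ``base_class`` cells positive for all markers in ``label_set``.

    ``label_set`` is a marker name, a sequence of names (conjunction, e.g.
    EdU ∧ Ki-67) or a callable predicate.
    """
    base = cells[cells[class_column] == base_class]
    if len(base) == 0:
        warnings.warn(f"no {base_class} cells; co-label fraction undefined")
        return float("nan")
    return float(_predicate_mask(base, label_set).mean())
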