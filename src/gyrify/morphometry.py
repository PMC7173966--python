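"""Local fold morphometry on 2-D section contours.

Three window-local metrics characterise folding of a hemisphere in a coronal
section, each compared between the electroporated (EP) and contralateral
non-electroporated (nonEP) side of the same section:

* **local GN** (gyrification number): how many times the pial contour
  detaches from a taut *outer contour* drawn around it — i.e. the number of
  sulci in the window.
* **local SD** (sulcus depth): the perpendicular distance from a sulcus
  bottom to the line joining the tops of the two flanking gyri.
* **local GS** (gyrus size): the area enclosed between the pial surface arc
  spanning a gyrus and the chord joining the bottoms of the two adjacent
  sulci.

The outer contour is constructed by morphological closing of the enclosed
region with a disc (default radius 1 mm), which reproduces a hand-drawn
taut envelope; the convex hull is the infinite-radius limit.  All
coordinates are in µm, areas in µm².
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import LinearRing, Polygon

from gyrify._util import (
    GeometryError,
    UndefinedRatioError,
    as_points,
    circular_runs,
    point_line_distance,
    run_indices,
)

DEFAULT_CLOSING_RADIUS_UM = 1000.0
DEFAULT_GAP_THRESHOLD_UM = 50.0
DEFAULT_MIN_DEPTH_UM = 50.0

#: sections averaged per animal, following the serial-section sampling scheme
SECTIONS_PER_ANIMAL = {"local_gn_ratio": 6, "local_sd_ratio": 3, "local_gs_ratio": 3}


@dataclass(frozen=True)
class SectionContour:
    """Closed pial-surface polyline of one hemisphere, side-labelled.

    ``vertices`` is an (N, 2) array in µm; the ring is implicitly closed
    (the first vertex is not repeated).  Orientation is normalised to
    counter-clockwise on construction.
    """

    vertices: np.ndarray
    side: str = "EP"
    section_id: str = "s0"
    anterior_to_posterior: bool = True

    def __post_init__(self):
        v = as_points(self.vertices)
        if len(v) >= 2 and np.allclose(v[0], v[-1]):
            v = v[:-1]
        if len(v) < 3:
            raise GeometryError("a contour needs at least 3 distinct vertices")
        if np.any(np.all(np.isclose(np.diff(v, axis=0), 0.0), axis=1)):
            raise GeometryError("consecutive duplicate vertices are not allowed")
        ring = LinearRing(v)
        if not ring.is_simple or not ring.is_valid:
            raise GeometryError(f"contour {self.section_id}/{self.side} self-intersects")
        if not ring.is_ccw:
            v = v[::-1].copy()
        if self.side not in ("EP", "nonEP"):
            raise ValueError(f"side must be 'EP' or 'nonEP', got {self.side!r}")
        object.__setattr__(self, "vertices", v)

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def vertex_spacing(self) -> float:
        """Median edge length, used as the resolution scale for tolerances."""
        d = np.hypot(*np.diff(np.vstack([self.vertices, self.vertices[:1]]), axis=0).T)
        return float(np.median(d))


@dataclass(frozen=True)
class OuterContour:
    """Taut envelope around a :class:`SectionContour`.

    ``closing_radius`` records the disc radius used (``inf`` = convex hull).
    """

    vertices: np.ndarray
    closing_radius: float = DEFAULT_CLOSING_RADIUS_UM

    def __post_init__(self):
        object.__setattr__(self, "vertices", as_points(self.vertices))

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def boundary(self) -> LinearRing:
        return LinearRing(self.vertices)


@dataclass(frozen=True)
class FoldLandmarks:
    """Gyrus tops and sulcus bottoms detected along a contour.

    Tops are midpoints of the arcs in contact with the outer contour;
    bottoms are the depth maxima of detached arcs.  ``*_indices`` index
    into the source contour's vertex array, ordered along the contour;
    ``depths`` is the contour-to-outer-contour distance at each bottom.
    """

    gyrus_tops: np.ndarray
    sulcus_bottoms: np.ndarray
    top_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    bottom_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    depths: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_sulci(self) -> int:
        return len(self.sulcus_bottoms)


@dataclass(frozen=True)
class FoldMetrics:
    """Per-section fold metrics for both sides and their EP/nonEP ratios."""

    section_id: str
    local_gn_ep: int
    local_gn_nonep: int
    local_sd_ep: float
    local_sd_nonep: float
    local_gs_ep: float
    local_gs_nonep: float
    local_gn_ratio: float
    local_sd_ratio: float
    local_gs_ratio: float
    closing_radius_um: float
    gap_threshold_um: float
    min_depth_um: float


def compute_outer_contour(
    c: SectionContour, closing_radius: float = DEFAULT_CLOSING_RADIUS_UM
) -> OuterContour:
    """Morphological closing of the section by a disc of ``closing_radius``.

    Closing (dilation by the disc followed by erosion by the same disc)
    bridges every indentation narrower than the disc while leaving convex
    regions untouched, so the result always encloses the input.  An
    infinite radius yields the convex hull.
    """
    poly = c.polygon
    if not poly.is_valid:
        raise GeometryError(f"contour {c.section_id}/{c.side} is not a simple polygon")
    if math.isinf(closing_radius):
        closed = poly.convex_hull
    elif closing_radius <= 0:
        raise ValueError("closing_radius must be positive or infinite")
    else:
        closed = poly.buffer(closing_radius, quad_segs=32).buffer(-closing_radius, quad_segs=32)
        if closed.geom_type == "MultiPolygon":  # numerically split erosion; keep the main part
            closed = max(closed.geoms, key=lambda g: g.area)
    verts = np.asarray(closed.exterior.coords)[:-1]
    return OuterContour(vertices=verts, closing_radius=closing_radius)


def _vertex_gaps(c: SectionContour, o: OuterContour) -> np.ndarray:
    """Distance from each contour vertex to the outer contour's boundary."""
    pts = shapely.points(c.vertices)
    return shapely.distance(pts, o.boundary)


def local_gn(
    c: SectionContour, o: OuterContour, gap_threshold: float = DEFAULT_GAP_THRESHOLD_UM
) -> int:
    """Number of maximal contiguous arcs detached from the outer contour.

    An arc is detached where the contour-to-envelope distance exceeds
    ``gap_threshold``; each detachment corresponds to one sulcus.
    """
    if gap_threshold <= 0:
        raise ValueError("gap_threshold must be positive")
    gaps = _vertex_gaps(c, o)
    return len(circular_runs(gaps > gap_threshold))


def detect_landmarks(
    c: SectionContour,
    o: OuterContour,
    min_depth: float = DEFAULT_MIN_DEPTH_UM,
    contact_tolerance: float | None = None,
) -> FoldLandmarks:
    """Locate gyrus tops and sulcus bottoms from the contour/envelope gap profile.

    A vertex is "in contact" when its distance to the envelope is below
    ``contact_tolerance`` (default: max(vertex spacing, 5 µm)).  Gyrus tops
    are the midpoints of contact runs; sulcus bottoms are the gap maxima of
    detached runs whose maximal depth exceeds ``min_depth``.  Shallow noise
    bumps below ``min_depth`` are not reported.
    """
    if contact_tolerance is None:
        contact_tolerance = max(c.vertex_spacing, 5.0)
    gaps = _vertex_gaps(c, o)
    n = len(gaps)
    contact = gaps <= contact_tolerance

    top_idx = []
    for start, length in circular_runs(contact):
        top_idx.append(int((start + length // 2) % n))
    bottom_idx, depths = [], []
    for start, length in circular_runs(~contact):
        idx = run_indices(start, length, n)
        k = int(np.argmax(gaps[idx]))
        if gaps[idx[k]] >= min_depth:
            bottom_idx.append(int(idx[k]))
            depths.append(float(gaps[idx[k]]))
    order_t = np.argsort(top_idx) if top_idx else []
    order_b = np.argsort(bottom_idx) if bottom_idx else []
    top_idx = np.asarray(top_idx, dtype=int)[order_t] if len(top_idx) else np.empty(0, dtype=int)
    bottom_idx = (
        np.asarray(bottom_idx, dtype=int)[order_b] if len(bottom_idx) else np.empty(0, dtype=int)
    )
    depths = np.asarray(depths)[order_b] if len(depths) else np.empty(0)
    return FoldLandmarks(
        gyrus_tops=c.vertices[top_idx] if len(top_idx) else np.empty((0, 2)),
        sulcus_bottoms=c.vertices[bottom_idx] if len(bottom_idx) else np.empty((0, 2)),
        top_indices=top_idx,
        bottom_indices=bottom_idx,
        depths=depths,
    )


def _flanking_tops(lm: FoldLandmarks, bottom_pos: int, n_vertices: int) -> tuple[int, int]:
    """Indices (into lm.top_indices) of the tops flanking a sulcus bottom."""
    if len(lm.top_indices) < 2:
        raise GeometryError("need at least two gyrus tops to measure sulcus depth")
    rel = (lm.top_indices - bottom_pos) % n_vertices
    after = int(np.argmin(rel))
    before = int(np.argmax(rel))
    return before, after


def local_sd(c: SectionContour, lm: FoldLandmarks, sulcus: int | None = None) -> float:
    """Sulcus depth: perpendicular distance from a sulcus bottom to the
    line joining the two flanking gyrus tops.

    ``sulcus`` selects a bottom by position in ``lm.sulcus_bottoms``; by
    default the deepest sulcus is used (the named reference sulcus is
    identified by eye in practice; the deepest detached arc substitutes
    here).  If the perpendicular foot falls outside the top-to-top segment
    the distance to the infinite line is used, matching a ruler measurement
    along an extended line.
    """
    if lm.n_sulci == 0:
        raise GeometryError("no sulcus bottoms detected")
    if sulcus is None:
        sulcus = int(np.argmax(lm.depths)) if len(lm.depths) else 0
    bottom = lm.sulcus_bottoms[sulcus]
    i, j = _flanking_tops(lm, int(lm.bottom_indices[sulcus]), len(c.vertices))
    return point_line_distance(bottom, lm.gyrus_tops[i], lm.gyrus_tops[j])


def _arc_between(c: SectionContour, i: int, j: int, lm: FoldLandmarks) -> np.ndarray:
    """Pial arc between vertex indices i and j spanning the intervening gyrus.

    Of the two candidate arcs, prefer the one containing at least one gyrus
    top; if both (or neither) qualify, take the shorter — for adjacent
    sulci that is the arc over the gyrus between them.
    """
    n = len(c.vertices)
    fwd = np.arange(i, i + ((j - i) % n) + 1) % n
    bwd = np.arange(j, j + ((i - j) % n) + 1) % n
    tops = set(int(t) for t in lm.top_indices)
    fwd_has = any(int(k) in tops for k in fwd[1:-1])
    bwd_has = any(int(k) in tops for k in bwd[1:-1])
    if fwd_has != bwd_has:
        arc = fwd if fwd_has else bwd
    else:
        arc = fwd if len(fwd) <= len(bwd) else bwd
    return c.vertices[arc]


def local_gs(
    c: SectionContour, lm: FoldLandmarks, pair: tuple[int, int] | None = None
) -> float:
    """Gyrus size: area between the pial arc spanning a gyrus and the chord
    joining the two adjacent sulcus bottoms.

    ``pair`` selects two bottoms by position in ``lm.sulcus_bottoms``; by
    default the two deepest are used.  Coincident bottoms give area 0 with
    a warning.
    """
    if lm.n_sulci < 2:
        warnings.warn("fewer than two sulcus bottoms; gyrus size degenerates to 0")
        return 0.0
    if pair is None:
        order = np.argsort(lm.depths)[::-1]
        pair = (int(order[0]), int(order[1]))
    i, j = (int(lm.bottom_indices[k]) for k in pair)
    if i == j or np.allclose(lm.sulcus_bottoms[pair[0]], lm.sulcus_bottoms[pair[1]]):
        warnings.warn("coincident sulcus bottoms; gyrus size degenerates to 0")
        return 0.0
    arc = _arc_between(c, i, j, lm)
    if len(arc) < 3:
        return 0.0
    return float(Polygon(arc).area)  # closing chord is implicit


def side_ratio(metric_ep: float, metric_nonep: float, section_id: str = "?") -> float:
    """EP-side metric divided by the contralateral nonEP-side metric.

    Equals 1 when the two sides are congruent.
    """
    if metric_nonep == 0:
        raise UndefinedRatioError(
            f"section {section_id}: nonEP metric is zero, ratio undefined"
        )
    return metric_ep / metric_nonep


def fold_metrics(
    ep: SectionContour,
    nonep: SectionContour,
    closing_radius: float = DEFAULT_CLOSING_RADIUS_UM,
    gap_threshold: float = DEFAULT_GAP_THRESHOLD_UM,
    min_depth: float = DEFAULT_MIN_DEPTH_UM,
) -> FoldMetrics:
    """Compute all three fold metrics and their ratios for one section pair."""
    if ep.section_id != nonep.section_id:
        warnings.warn(
            f"pair combines sections {ep.section_id!r} and {nonep.section_id!r}"
        )
    values = {}
    for contour, tag in ((ep, "ep"), (nonep, "nonep")):
        outer = compute_outer_contour(contour, closing_radius)
        lm = detect_landmarks(contour, outer, min_depth=min_depth)
        values[f"gn_{tag}"] = local_gn(contour, outer, gap_threshold)
        values[f"sd_{tag}"] = local_sd(contour, lm) if lm.n_sulci >= 1 and len(lm.top_indices) >= 2 else 0.0
        values[f"gs_{tag}"] = local_gs(contour, lm) if lm.n_sulci >= 2 else 0.0
    sid = ep.section_id
    return FoldMetrics(
        section_id=sid,
        local_gn_ep=values["gn_ep"],
        local_gn_nonep=values["gn_nonep"],
        local_sd_ep=values["sd_ep"],
        local_sd_nonep=values["sd_nonep"],
        local_gs_ep=values["gs_ep"],
        local_gs_nonep=values["gs_nonep"],
        local_gn_ratio=side_ratio(values["gn_ep"], values["gn_nonep"], sid),
        local_sd_ratio=side_ratio(values["sd_ep"], values["sd_nonep"], sid),
        local_gs_ratio=side_ratio(values["gs_ep"], values["gs_nonep"], sid),
        closing_radius_um=closing_radius,
        gap_threshold_um=gap_threshold,
        min_depth_um=min_depth,
    )


def animal_means(per_section, metric: str):
    """Average per-section ratios into a per-animal value.

    ``per_section`` is a sequence of ratio values for one animal, ordered
    by section.  GN ratios are averaged over six sections, SD and GS
    ratios over three, per the serial-section sampling scheme; fewer
    sections than the scheme requests are averaged as-is with a warning.
    """
    want = SECTIONS_PER_ANIMAL.get(metric)
    if want is None:
        raise KeyError(f"unknown metric {metric!r}")
    vals = np.asarray(list(per_section), dtype=float)
    if len(vals) < want:
        warnings.warn(f"{metric}: only {len(vals)} sections available ({want} requested)")
    return float(np.mean(vals[:want] if len(vals) >= want else vals))
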