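"""Synthetic hemisphere sections with known ground truth.

The generator emulates the inputs of the analysis pipeline: paired
hemisphere contours (electroporated / contralateral) with a controllable
number and depth of sulci, concentric laminar zone and cortical layer
geometry, per-zone cell point patterns with subtype densities, a
gyral-accumulation gradient for HOPX-positive oRG cells, per-class
co-labelling probabilities, and pixel fields with a known positive-area
fraction.  Everything is a pure function of the configuration (including
its seed), and closed-form landmark ground truth is returned alongside the
contours so downstream detections can be verified exactly.

Model
-----
A hemisphere outline is a radial curve ``r(θ) = R + noise(θ) − Σ bumps``
around the origin.  Each sulcus is a smooth cosine bump of configurable
depth and width (arc length at radius R), centred on the dorsal aspect;
gyral crests lie midway between adjacent sulci.  Laminar zones (CP, IZ,
OSVZ, ISVZ, VZ from the pial surface inward) are bands obtained by radial
inward offsets of the outline, so they follow the folds.  Cells are placed
by a homogeneous Poisson point process per zone and class, with the
HOPX-positive oRG intensity multiplied by ``gyral_enrichment`` inside the
prospective-gyral angular sectors (exact Poisson thinning elsewhere).

Default parameters reflect the study conditions the package is built
around: baseline (prospective-sulcus) OSVZ composition 6.1 % HOPX+ oRG /
49.4 % HOPX− oRG / 44.4 % IP, gyral enrichment 9.8 for HOPX+ oRG, Ki-67
co-labelling ≈ 0.30 for both oRG subtypes, and EdU co-labelling higher in
HOPX+ (0.222) than HOPX− (0.124) oRG cells.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import shapely
from shapely.geometry import Polygon

from gyrify._util import GeometryError
from gyrify.laminar import LAYERS, LayerBand
from gyrify.morphometry import SectionContour
from gyrify.signalquant import IntensityField

ZONES = ("VZ", "ISVZ", "OSVZ", "IZ", "CP")
CLASSES = ("HOPX_pos_oRG", "HOPX_neg_oRG", "IP", "other")
MARKERS = ("HOPX_protein", "HOPX_mRNA", "Pax6", "Tbr2", "Ki67", "EdU", "CC3", "GFP")
#: markers drawn per cell from colabel_probs (identity markers are set by class)
COLABEL_MARKERS = ("Ki67", "EdU", "CC3", "GFP", "HOPX_mRNA")


def _default_zone_thicknesses():
    # µm, pial surface inward; plausible perinatal ferret germinal-zone scale
    return {"CP": 800.0, "IZ": 500.0, "OSVZ": 400.0, "ISVZ": 150.0, "VZ": 100.0}


def _default_layer_thicknesses():
    return {"L2/3": 300.0, "L4": 150.0, "L5": 200.0, "L6": 150.0}


def _default_densities():
    # cells/mm² per zone and class.  OSVZ baseline composition matches the
    # prospective-sulcus proportions (6.1 / 49.4 / 44.4 %) at 2000
    # progenitors/mm²; other zones are coarse but plausible.
    return {
        "OSVZ": {"HOPX_pos_oRG": 122.0, "HOPX_neg_oRG": 988.0, "IP": 888.0, "other": 100.0},
        "ISVZ": {"HOPX_pos_oRG": 80.0, "HOPX_neg_oRG": 300.0, "IP": 1600.0, "other": 100.0},
        "VZ": {"HOPX_neg_oRG": 1500.0, "IP": 300.0, "other": 100.0},
        "IZ": {"other": 150.0},
        "CP": {"other": 400.0},
    }


def _default_colabel_probs():
    return {
        ("HOPX_pos_oRG", "Ki67"): 0.303,
        ("HOPX_neg_oRG", "Ki67"): 0.323,
        ("IP", "Ki67"): 0.364,
        ("HOPX_pos_oRG", "EdU"): 0.222,
        ("HOPX_neg_oRG", "EdU"): 0.124,
        ("IP", "EdU"): 0.327,
        ("HOPX_pos_oRG", "HOPX_mRNA"): 1.0,
        ("HOPX_neg_oRG", "HOPX_mRNA"): 0.009,
        ("HOPX_pos_oRG", "CC3"): 0.01,
        ("HOPX_neg_oRG", "CC3"): 0.01,
        ("IP", "CC3"): 0.01,
        ("other", "CC3"): 0.01,
    }


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the generator; identical config ⇒ identical output."""

    seed: int = 0
    n_sulci_ep: int = 3
    n_sulci_nonep: int = 3
    sulcus_depth_um: float = 600.0
    sulcus_width_um: float = 800.0
    base_radius_um: float = 4000.0
    noise_amplitude_um: float = 0.0
    n_vertices: int = 1440
    zone_thicknesses_um: dict = field(default_factory=_default_zone_thicknesses)
    layer_thicknesses_um: dict = field(default_factory=_default_layer_thicknesses)
    subtype_densities: dict = field(default_factory=_default_densities)
    gyral_enrichment: float = 9.8
    colabel_probs: dict = field(default_factory=_default_colabel_probs)
    marker_mode: str = "boolean"  # "boolean" | "intensity"
    intensity_separation_sigma: float = 4.0

    def __post_init__(self):
        if self.n_sulci_ep < 0 or self.n_sulci_nonep < 0:
            raise ValueError("sulcus counts must be non-negative")
        for name in ("sulcus_depth_um", "sulcus_width_um", "base_radius_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_amplitude_um < 0:
            raise ValueError("noise_amplitude_um must be non-negative")
        for zone, classes in self.subtype_densities.items():
            if zone not in ZONES:
                raise ValueError(f"unknown zone {zone!r}")
            for cls, d in classes.items():
                if cls not in CLASSES:
                    raise ValueError(f"unknown progenitor class {cls!r}")
                if d < 0:
                    raise ValueError(f"density for {zone}/{cls} must be non-negative")
        for (cls, marker), p in self.colabel_probs.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"colabel probability for ({cls}, {marker}) outside [0, 1]")
        if self.gyral_enrichment < 0:
            raise ValueError("gyral_enrichment must be non-negative")
        if self.marker_mode not in ("boolean", "intensity"):
            raise ValueError("marker_mode must be 'boolean' or 'intensity'")

    def rng(self, *stream) -> np.random.Generator:
        """Independent deterministic stream derived from the seed.

        Stream labels are folded in with a stable CRC so results do not
        depend on the process's string-hash salt.
        """
        tags = [zlib.crc32(str(s).encode()) % (2**31) for s in stream]
        return np.random.default_rng([self.seed % (2**31), *tags])


class GroundTruth(NamedTuple):
    """Closed-form landmark truth emitted with a generated contour."""

    sulcus_angles: np.ndarray      # radians, one per sulcus
    sulcus_bottoms: np.ndarray     # (k, 2) µm
    crest_angles: np.ndarray       # gyrus crest angles (k+1 when k>0)
    gyrus_tops: np.ndarray         # (k+1, 2) µm at nominal radius
    gyral_sectors: np.ndarray      # (m, 2) [lo, hi] angular intervals
    depth_um: float
    width_um: float
    baseline_angle: float          # a reference angle far from every sulcus


class ContourPair(NamedTuple):
    ep: SectionContour
    nonep: SectionContour
    truth_ep: GroundTruth
    truth_nonep: GroundTruth


def _sulcus_layout(cfg: SyntheticConfig, k: int) -> tuple[np.ndarray, float]:
    """Sulcus centre angles (dorsal cluster) and angular bump half-period."""
    w_ang = cfg.sulcus_width_um / cfg.base_radius_um
    if k == 0:
        return np.empty(0), w_ang
    spacing = 1.6 * w_ang
    span = spacing * (k - 1)
    if span + w_ang > 1.6 * math.pi:
        raise GeometryError(
            f"{k} sulci of width {cfg.sulcus_width_um} µm do not fit on a radius-"
            f"{cfg.base_radius_um} µm hemisphere"
        )
    centers = math.pi / 2 + (np.arange(k) - (k - 1) / 2) * spacing
    return centers, w_ang


def _validate_fold_geometry(cfg: SyntheticConfig):
    if cfg.sulcus_depth_um >= 0.8 * cfg.base_radius_um:
        raise GeometryError(
            "sulcus depth too large for the base radius: the folded wall would "
            f"self-intersect (depth {cfg.sulcus_depth_um} µm, radius {cfg.base_radius_um} µm)"
        )
    if cfg.sulcus_depth_um > 2.0 * cfg.sulcus_width_um:
        raise GeometryError(
            "sulcus depth too large for its width: the fold walls would "
            f"self-intersect (depth {cfg.sulcus_depth_um} µm, width {cfg.sulcus_width_um} µm)"
        )


def _radial_profile(cfg: SyntheticConfig, k: int, rng: np.random.Generator):
    """Radius samples r(θ) plus the sulcus layout used."""
    theta = np.linspace(0.0, 2 * math.pi, cfg.n_vertices, endpoint=False)
    centers, w_ang = _sulcus_layout(cfg, k)
    r = np.full_like(theta, cfg.base_radius_um)
    if cfg.noise_amplitude_um > 0:
        modes = np.arange(2, 7)
        amps = rng.normal(size=modes.size)
        phases = rng.uniform(0, 2 * math.pi, size=modes.size)
        noise = (amps[:, None] * np.cos(modes[:, None] * theta + phases[:, None])).sum(axis=0)
        peak = np.abs(noise).max()
        if peak > 0:
            r = r + noise * (cfg.noise_amplitude_um / peak)
    for c in centers:
        u = (theta - c + math.pi) % (2 * math.pi) - math.pi  # wrapped offset
        inside = np.abs(u) < w_ang / 2
        r[inside] -= cfg.sulcus_depth_um * 0.5 * (1 + np.cos(2 * math.pi * u[inside] / w_ang))
    if (r <= 0).any():
        raise GeometryError("fold geometry collapses the contour through the origin")
    return theta, r, centers, w_ang


def _truth(cfg: SyntheticConfig, centers: np.ndarray, w_ang: float) -> GroundTruth:
    R = cfg.base_radius_um
    k = len(centers)
    if k == 0:
        crest = np.empty(0)
        sectors = np.empty((0, 2))
    elif k == 1:
        crest = np.array([centers[0] - 1.6 * w_ang, centers[0] + 1.6 * w_ang])
        sectors = np.column_stack([crest - 0.75 * w_ang, crest + 0.75 * w_ang])
    else:
        spacing = centers[1] - centers[0]
        mids = (centers[:-1] + centers[1:]) / 2
        crest = np.concatenate([[centers[0] - spacing / 2], mids, [centers[-1] + spacing / 2]])
        # sectors reach into the sulcal bump shoulders (surface shift there is
        # negligible) so a 300 µm column at a crest sits fully inside one
        half = (spacing - w_ang / 2) / 2
        sectors = np.column_stack([crest - half, crest + half])
    bottoms = np.column_stack(
        [(R - cfg.sulcus_depth_um) * np.cos(centers), (R - cfg.sulcus_depth_um) * np.sin(centers)]
    )
    tops = np.column_stack([R * np.cos(crest), R * np.sin(crest)])
    return GroundTruth(
        sulcus_angles=centers,
        sulcus_bottoms=bottoms,
        crest_angles=crest,
        gyrus_tops=tops,
        gyral_sectors=sectors,
        depth_um=cfg.sulcus_depth_um,
        width_um=cfg.sulcus_width_um,
        baseline_angle=-math.pi / 2,
    )


def generate_contour_pair(cfg: SyntheticConfig, section_id: str = "s0") -> ContourPair:
    """Paired EP / nonEP hemisphere contours with landmark ground truth.

    Each contour is a simple closed polyline; the EP side carries exactly
    ``n_sulci_ep`` cosine indentations of the configured depth and width on
    the smooth base curve (nonEP likewise).  Raises :class:`GeometryError`
    for fold geometry that would self-intersect.
    """
    _validate_fold_geometry(cfg)
    out = {}
    for side, k in (("EP", cfg.n_sulci_ep), ("nonEP", cfg.n_sulci_nonep)):
        theta, r, centers, w_ang = _radial_profile(cfg, k, cfg.rng("contour", side))
        verts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        out[side] = (
            SectionContour(vertices=verts, side=side, section_id=section_id),
            _truth(cfg, centers, w_ang),
        )
    return ContourPair(out["EP"][0], out["nonEP"][0], out["EP"][1], out["nonEP"][1])


def _radial_band(contour: SectionContour, d_outer: float, d_inner: float) -> Polygon:
    """Band between inward radial offsets d_outer and d_inner of the contour."""
    v = contour.vertices
    r = np.hypot(v[:, 0], v[:, 1])
    if (r - d_inner <= 0).any():
        raise GeometryError("zone thicknesses exceed the contour radius")
    outer = v * ((r - d_outer) / r)[:, None]
    inner = v * ((r - d_inner) / r)[:, None]
    return Polygon(np.vstack([outer, inner[::-1]]))


def zone_offsets(cfg: SyntheticConfig) -> dict[str, tuple[float, float]]:
    """Cumulative (outer, inner) inward offsets per zone, pial surface first."""
    order = ("CP", "IZ", "OSVZ", "ISVZ", "VZ")
    out, depth = {}, 0.0
    for zone in order:
        t = cfg.zone_thicknesses_um[zone]
        out[zone] = (depth, depth + t)
        depth += t
    return out


def generate_zone_bands(cfg: SyntheticConfig, contour: SectionContour) -> dict[str, Polygon]:
    """Laminar zone polygons (VZ…CP) as fold-following bands of the contour."""
    return {
        zone: _radial_band(contour, lo, hi) for zone, (lo, hi) in zone_offsets(cfg).items()
    }


def generate_layer_bands(cfg: SyntheticConfig, contour: SectionContour) -> list[LayerBand]:
    """Cortical layer bands subdividing the cortical-plate depth, pial first."""
    bands, depth = [], 0.0
    v = contour.vertices
    r = np.hypot(v[:, 0], v[:, 1])
    for layer in LAYERS:
        t = cfg.layer_thicknesses_um[layer]
        poly = _radial_band(contour, depth, depth + t)
        mid = v * ((r - depth - t / 2) / r)[:, None]
        mid = np.vstack([mid, mid[:1]])  # closed mid-arc
        bands.append(LayerBand(layer=layer, polygon=np.asarray(poly.exterior.coords)[:-1], tangential_curve=mid))
        depth += t
    return bands


def _sample_in_polygon(poly: Polygon, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform points in a polygon by rejection from its bounding box."""
    if n == 0:
        return np.empty((0, 2))
    minx, miny, maxx, maxy = poly.bounds
    pts = np.empty((0, 2))
    while len(pts) < n:
        m = max(4 * (n - len(pts)), 256)
        cand = rng.uniform([minx, miny], [maxx, maxy], size=(m, 2))
        keep = shapely.contains_xy(poly, cand[:, 0], cand[:, 1])
        pts = np.vstack([pts, cand[keep]])
    return pts[:n]


def _in_sectors(points: np.ndarray, sectors: np.ndarray) -> np.ndarray:
    if len(sectors) == 0:
        return np.zeros(len(points), dtype=bool)
    ang = np.arctan2(points[:, 1], points[:, 0])
    hit = np.zeros(len(points), dtype=bool)
    for lo, hi in sectors:
        # compare on wrapped offsets so sectors may straddle ±π
        mid, half = (lo + hi) / 2, (hi - lo) / 2
        off = (ang - mid + math.pi) % (2 * math.pi) - math.pi
        hit |= np.abs(off) <= half
    return hit


def _identity_markers(cls: str, n: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Class-defining marker calls (Pax6 / Tbr2 / HOPX protein)."""
    z, o = np.zeros(n, dtype=bool), np.ones(n, dtype=bool)
    if cls == "HOPX_pos_oRG":
        return {"Pax6": o, "Tbr2": z, "HOPX_protein": o}
    if cls == "HOPX_neg_oRG":
        return {"Pax6": o, "Tbr2": z, "HOPX_protein": z}
    if cls == "IP":
        # IP cells are Tbr2+; about half retain Pax6
        return {"Pax6": rng.random(n) < 0.5, "Tbr2": o, "HOPX_protein": z}
    return {"Pax6": z, "Tbr2": z, "HOPX_protein": z}


def generate_cell_table(
    cfg: SyntheticConfig,
    zones: dict[str, Polygon],
    truth: GroundTruth | None = None,
) -> "pd.DataFrame":
    """Cell point pattern with marker calls as a tidy table.

    One row per cell with columns ``x_um, y_um, zone, true_class`` and one
    column per marker (boolean calls, or float intensities in intensity
    mode with boolean ground truth kept in ``<marker>_true`` columns).
    Cells are a homogeneous Poisson process per zone and class at the
    configured density; inside the prospective-gyral sectors of ``truth``
    the HOPX-positive oRG intensity is multiplied by ``gyral_enrichment``
    (implemented by exact thinning, so realised densities are Poisson).
    """
    import pandas as pd

    frames = []
    sectors = truth.gyral_sectors if truth is not None else np.empty((0, 2))
    for zone, classes in cfg.subtype_densities.items():
        poly = zones.get(zone)
        if poly is None or poly.area == 0:
            continue
        area_mm2 = poly.area / 1e6
        for cls, dens in classes.items():
            rng = cfg.rng("cells", zone, cls)
            enrich = (
                cfg.gyral_enrichment
                if cls == "HOPX_pos_oRG" and len(sectors) and cfg.gyral_enrichment != 1.0
                else 1.0
            )
            lam = dens * max(enrich, 1.0) * area_mm2
            n = rng.poisson(lam)
            pts = _sample_in_polygon(poly, n, rng)
            if enrich != 1.0 and len(pts):
                gyral = _in_sectors(pts, sectors)
                if enrich > 1.0:  # thin outside gyral sectors down to baseline
                    keep = gyral | (rng.random(len(pts)) < 1.0 / enrich)
                else:  # depletion: thin inside the sectors
                    keep = ~gyral | (rng.random(len(pts)) < enrich)
                pts = pts[keep]
            m = len(pts)
            cols = {"x_um": pts[:, 0], "y_um": pts[:, 1]}
            markers = _identity_markers(cls, m, rng)
            for marker in COLABEL_MARKERS:
                p = cfg.colabel_probs.get((cls, marker), 0.0)
                markers[marker] = rng.random(m) < p
            df = pd.DataFrame(cols)
            df["zone"] = zone
            df["true_class"] = cls
            for marker in MARKERS:
                calls = markers.get(marker, np.zeros(m, dtype=bool))
                if cfg.marker_mode == "intensity":
                    sep = cfg.intensity_separation_sigma
                    sigma = 10.0
                    base = rng.normal(100.0, sigma, size=m)
                    df[marker] = base + np.where(calls, sep * sigma, 0.0)
                    df[f"{marker}_true"] = calls.astype(int)
                else:
                    df[marker] = calls.astype(int)
            frames.append(df)
    if not frames:
        cols = ["x_um", "y_um", "zone", "true_class", *MARKERS]
        return pd.DataFrame(columns=cols)
    return pd.concat(frames, ignore_index=True)


def generate_intensity_field(
    cfg: SyntheticConfig,
    region,
    positive_fraction: float,
    pixel_size_um: float = 5.0,
) -> IntensityField:
    """Raster over ``region`` whose above-threshold area fraction is known.

    Exactly ``round(positive_fraction · n_inside)`` pixels inside the
    region receive values in [150, 250); the rest fall in [10, 90), so any
    threshold in (90, 150] recovers the configured fraction up to
    pixelisation error.  Pixels outside the region are NaN.
    """
    if not (0.0 <= positive_fraction <= 1.0):
        raise ValueError("positive_fraction must lie in [0, 1]")
    poly = region if isinstance(region, Polygon) else Polygon(np.asarray(region, dtype=float))
    if poly.is_empty or poly.area == 0:
        raise ValueError("region is empty")
    minx, miny, maxx, maxy = poly.bounds
    nx = max(int(math.ceil((maxx - minx) / pixel_size_um)), 1)
    ny = max(int(math.ceil((maxy - miny) / pixel_size_um)), 1)
    xs = minx + (np.arange(nx) + 0.5) * pixel_size_um
    ys = miny + (np.arange(ny) + 0.5) * pixel_size_um
    xx, yy = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(poly, xx.ravel(), yy.ravel()).reshape(ny, nx)
    n_in = int(inside.sum())
    if n_in == 0:
        raise ValueError("region is smaller than one pixel at this resolution")
    rng = cfg.rng("field")
    values = np.full((ny, nx), np.nan)
    flat_idx = np.flatnonzero(inside.ravel())
    k = int(round(positive_fraction * n_in))
    pos_idx = rng.permutation(flat_idx)[:k]
    vals = rng.uniform(10.0, 90.0, size=n_in)
    values.ravel()[flat_idx] = vals
    values.ravel()[pos_idx] = rng.uniform(150.0, 250.0, size=k)
    return IntensityField(values=values, origin=(float(minx), float(miny)), pixel_size_um=pixel_size_um)


def miniature_dataset(cfg: SyntheticConfig, n_sections: int = 2):
    """Complete miniature dataset used by the test-suite and the CLI.

    Returns a dict with per-section contour pairs, zone/layer geometry,
    cell tables and one intensity field; sections differ only through
    their seed-derived noise streams.
    """
    sections = {}
    for i in range(n_sections):
        sid = f"s{i + 1}"
        pair = generate_contour_pair(replace(cfg, seed=cfg.seed + i), section_id=sid)
        zones = generate_zone_bands(cfg, pair.ep)
        cells = generate_cell_table(replace(cfg, seed=cfg.seed + i), zones, pair.truth_ep)
        sections[sid] = {
            "pair": pair,
            "zones": zones,
            "layers_ep": generate_layer_bands(cfg, pair.ep),
            "layers_nonep": generate_layer_bands(cfg, pair.nonep),
            "cells": cells,
        }
    field_region = Polygon([(0, 0), (1500, 0), (1500, 1500), (0, 1500)])
    field = generate_intensity_field(cfg, field_region, positive_fraction=0.5)
    return {"sections": sections, "field": field}
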