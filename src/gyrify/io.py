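"""File formats: coordinate-table contours, cell tables, polygon JSON,
raster fields and tidy reports.

Conventions: coordinates are µm stored as floats; CSV is comma-separated,
'.' decimal, UTF-8, with a mandatory header row.  A contour CSV carries a
JSON sidecar (same stem, ``.json``) with side, section id, units and
orientation.  Writing then reading any object is the identity on its
canonical form.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from gyrify.cellquant import ColumnROI
from gyrify.laminar import LayerBand
from gyrify.morphometry import SectionContour
from gyrify.signalquant import IntensityField
from gyrify.synthetic import MARKERS, ZONES

_CONTOUR_COLUMNS = ["x_um", "y_um"]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_contour(contour: SectionContour, path) -> Path:
    path = Path(path)
    pd.DataFrame(contour.vertices, columns=_CONTOUR_COLUMNS).to_csv(path, index=False)
    meta = {
        "side": contour.side,
        "section_id": contour.section_id,
        "anterior_to_posterior": contour.anterior_to_posterior,
        "units": "um",
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def read_contour(path) -> SectionContour:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _CONTOUR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing contour columns {missing}")
    meta = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    return SectionContour(
        vertices=df[_CONTOUR_COLUMNS].to_numpy(),
        side=meta.get("side", "EP"),
        section_id=meta.get("section_id", path.stem),
        anterior_to_posterior=meta.get("anterior_to_posterior", True),
    )


def write_cell_table(cells: pd.DataFrame, path) -> Path:
    path = Path(path)
    cells.to_csv(path, index=False)
    return path


def read_cell_table(path) -> pd.DataFrame:
    """Cell table CSV with schema validation naming the offending row."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("x_um", "y_um", "zone"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    bad = ~df["zone"].isin(ZONES)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"{path}: row {row + 2}: invalid zone {df['zone'].iloc[row]!r} "
            f"(expected one of {ZONES})"
        )
    known = {"x_um", "y_um", "zone", "true_class", "cell_class", *MARKERS}
    known |= {f"{m}_true" for m in MARKERS}
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        import warnings

        warnings.warn(f"{path}: unknown marker columns preserved: {unknown}")
    return df


def write_polygons(polygons: dict, path) -> Path:
    """Named polygons as JSON: {name: [[x, y], ...]}."""
    path = Path(path)
    payload = {
        name: np.asarray(
            poly.exterior.coords if hasattr(poly, "exterior") else poly, dtype=float
        ).tolist()
        for name, poly in polygons.items()
    }
    path.write_text(json.dumps(payload, sort_keys=True))
    return path


def read_polygons(path) -> dict[str, np.ndarray]:
    path = Path(path)
    payload = json.loads(path.read_text())
    out = {}
    for name, coords in payload.items():
        arr = np.asarray(coords, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 3:
            raise ValueError(f"{path}: polygon {name!r} is not a valid coordinate list")
        out[name] = arr
    return out


def write_layer_bands(bands: list[LayerBand], path) -> Path:
    payload = {
        b.layer: {
            "polygon": b.polygon.tolist(),
            "tangential_curve": b.tangential_curve.tolist(),
        }
        for b in bands
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True))
    return Path(path)


def read_layer_bands(path) -> list[LayerBand]:
    payload = json.loads(Path(path).read_text())
    return [
        LayerBand(
            layer=name,
            polygon=np.asarray(entry["polygon"], dtype=float),
            tangential_curve=np.asarray(entry["tangential_curve"], dtype=float),
        )
        for name, entry in payload.items()
    ]


def write_rois(rois: dict[str, ColumnROI], path) -> Path:
    payload = {
        name: {
            "origin": roi.origin.tolist(),
            "axis": roi.axis.tolist(),
            "length": roi.length,
            "width": roi.width,
            "region_label": roi.region_label,
        }
        for name, roi in rois.items()
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True))
    return Path(path)


def read_rois(path) -> dict[str, ColumnROI]:
    payload = json.loads(Path(path).read_text())
    return {
        name: ColumnROI(
            origin=np.asarray(e["origin"]),
            axis=np.asarray(e["axis"]),
            length=float(e["length"]),
            width=float(e["width"]),
            region_label=e.get("region_label", name),
        )
        for name, e in payload.items()
    }


def write_field(field: IntensityField, path) -> Path:
    """Raster to TIFF with a JSON sidecar holding the physical placement."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, field.values.astype(np.float32))
    meta = {"origin": list(field.origin), "pixel_size_um": field.pixel_size_um}
    _sidecar(path).write_text(json.dumps(meta, sort_keys=True))
    return path


def read_field(path) -> IntensityField:
    import tifffile

    path = Path(path)
    values = tifffile.imread(path).astype(float)
    meta = json.loads(_sidecar(path).read_text())
    return IntensityField(
        values=values, origin=tuple(meta["origin"]), pixel_size_um=meta["pixel_size_um"]
    )


def config_hash(params: dict) -> str:
    """Stable short hash of the analysis parameters, embedded in reports."""
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_report(report: pd.DataFrame, path, params: dict | None = None) -> Path:
    """Report as TSV plus a JSON twin embedding the parameter hash."""
    path = Path(path)
    report.to_csv(path, sep="\t", index=False)
    payload = {
        "config_hash": config_hash(params or {}),
        "params": params or {},
        "rows": json.loads(report.to_json(orient="records")),
    }
    path.with_suffix(".report.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path


@dataclasses.dataclass
class RunConfig:
    """Pipeline driver configuration (CLI ``--config``)."""

    seed: int = 0
    closing_radius_um: float = 1000.0
    gap_threshold_um: float = 50.0
    min_depth_um: float = 50.0
    column_width_um: float = 300.0
    threshold: str = "otsu"  # "otsu" | "fixed:<value>"
    out_dir: str = "results"

    def __post_init__(self):
        for name in ("closing_radius_um", "gap_threshold_um", "min_depth_um", "column_width_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.threshold != "otsu" and not self.threshold.startswith("fixed:"):
            raise ValueError("threshold must be 'otsu' or 'fixed:<value>'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def threshold_value(self, intensities=None) -> float | None:
        if self.threshold.startswith("fixed:"):
            return float(self.threshold.split(":", 1)[1])
        if intensities is None:
            return None
        from gyrify.cellquant import otsu_threshold

        return otsu_threshold(intensities)
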