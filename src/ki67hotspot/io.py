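"""On-disk formats: cell TSV, ROI GeoJSON, cohort CSV, params YAML/JSON.

Writers use fixed field order and 4-decimal coordinates (0.1 nm, well
inside the 1 nm round-trip tolerance) so output is byte-stable for a
given input.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import Polygon, shape

from .synthetic import SimulationParams
from .types import CELL_COLUMNS, TumorROI, validate_cells

CELLS_FILENAME = "cells.tsv"
ROIS_FILENAME = "rois.geojson"


def write_cells(cells: pd.DataFrame, path) -> None:
    validate_cells(cells)
    out = cells.loc[:, list(CELL_COLUMNS)].copy()
    out["roi_id"] = out["roi_id"].fillna("")
    out.to_csv(path, sep="\t", index=False, float_format="%.4f",
               lineterminator="\n")


def read_cells(path) -> pd.DataFrame:
    try:
        cells = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "roi_id": str},
                            keep_default_na=False, na_values=[])
    except Exception as exc:  # pragma: no cover - pandas names the line
        raise ValueError(f"malformed cell table {path}: {exc}") from exc
    missing = [c for c in CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise ValueError(f"malformed cell table {path}: missing columns {missing}")
    if len(cells):
        for col in ("x_um", "y_um"):
            try:
                cells[col] = cells[col].astype(float)
            except ValueError as exc:
                raise ValueError(f"malformed cell table {path}, column {col}: {exc}")
    else:
        cells = cells.astype({"x_um": float, "y_um": float})
    cells["roi_id"] = cells["roi_id"].replace("", None)
    return validate_cells(cells)


def write_rois(rois: Sequence[TumorROI], path) -> None:
    features = []
    for roi in rois:
        coords = [[round(float(x), 4), round(float(y), 4)]
                  for x, y in roi.polygon.exterior.coords]
        features.append({
            "type": "Feature",
            "properties": {"roi_id": roi.roi_id, "roi_class": roi.roi_class},
            "geometry": {"type": "Polygon", "coordinates": [coords]},
        })
    doc = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def read_rois(path) -> list[TumorROI]:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed GeoJSON {path}: {exc}") from exc
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"malformed GeoJSON {path}: not a FeatureCollection")
    rois = []
    for i, feat in enumerate(doc.get("features", [])):
        try:
            geom = shape(feat["geometry"])
            props = feat["properties"]
            rois.append(TumorROI(str(props["roi_id"]), Polygon(geom.exterior),
                                 str(props["roi_class"])))
        except (KeyError, TypeError, AttributeError, ValueError) as exc:
            raise ValueError(f"malformed GeoJSON {path}, feature {i}: {exc}") from exc
    return rois


def write_slide(dirpath, cells: pd.DataFrame, rois: Sequence[TumorROI]) -> None:
    """Write a slide bundle (cell TSV + ROI GeoJSON) into a directory."""
    d = Path(dirpath)
    d.mkdir(parents=True, exist_ok=True)
    write_cells(cells, d / CELLS_FILENAME)
    write_rois(rois, d / ROIS_FILENAME)


def read_slide(dirpath) -> tuple[pd.DataFrame, list[TumorROI]]:
    d = Path(dirpath)
    return read_cells(d / CELLS_FILENAME), read_rois(d / ROIS_FILENAME)


COHORT_COLUMNS = (
    "patient_id", "slide_id", "er_percent", "pr_percent", "her2", "grade",
    "mitotic_score", "pT", "pN", "rfs_time", "rfs_event", "os_time",
    "os_event", "intrinsic_subtype", "true_global_ki67", "true_ki67_high",
)


def write_cohort(patients: pd.DataFrame, path) -> None:
    cols = [c for c in COHORT_COLUMNS if c in patients.columns]
    patients.loc[:, cols].to_csv(path, index=False, float_format="%.6f",
                                 lineterminator="\n")


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"patient_id", "rfs_time", "rfs_event", "os_time", "os_event"} \
        - set(df.columns)
    if missing:
        raise ValueError(f"malformed cohort table {path}: missing {sorted(missing)}")
    return df


def load_params(path) -> SimulationParams:
    """Read SimulationParams from a YAML or JSON mapping (1:1 field names)."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"params file {path} must contain a mapping")
    known = {f.name for f in dataclasses.fields(SimulationParams)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown simulation parameters: {sorted(unknown)}")
    for key in ("hotspot_amplitude_range", "hotspot_sigma_range_um",
                "baseline_pos_beta"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return SimulationParams(**data)


def save_params(params: SimulationParams, path) -> None:
    data = dataclasses.asdict(params)
    for k, v in data.items():
        if isinstance(v, tuple):
            data[k] = list(v)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
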