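"""Core domain objects for point-pattern Ki67 analysis.

All coordinates are in micrometres (µm) with the origin at the slide's
top-left corner, x increasing rightward and y downward.  A slide is a
table of nucleus centroids (one row per detected cell) plus a set of
pathologist-style region-of-interest polygons classified as invasive
tumor, in-situ tumor or artifact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon, mapping

#: Scanner pixel pitch recorded as provenance metadata (µm per pixel).
MICRONS_PER_PIXEL = 0.4537

CELL_COLUMNS = ("cell_id", "x_um", "y_um", "cell_class", "ki67_status", "roi_id")
CELL_CLASSES = ("tumor", "immune", "stroma", "other")
KI67_STATUSES = ("positive", "negative", "not_applicable")
ROI_CLASSES = ("invasive", "in_situ", "artifact")

#: Field-of-view drawing radius in µm keyed by magnification.
FOV_RADIUS_UM = {"20x": 520.0, "40x": 260.0}


@dataclass(frozen=True)
class TumorROI:
    """A pathologist-style tumor region of interest.

    Parameters
    ----------
    roi_id : str
        Unique identifier within the slide.
    polygon : shapely.geometry.Polygon
        Simple (non self-intersecting) closed polygon in µm.
    roi_class : {"invasive", "in_situ", "artifact"}
        Region classification; only ``invasive`` regions contribute to
        hot-spot detection.
    """

    roi_id: str
    polygon: Polygon
    roi_class: str

    def __post_init__(self) -> None:
        if self.roi_class not in ROI_CLASSES:
            raise ValueError(f"unknown roi_class {self.roi_class!r}")
        if not isinstance(self.polygon, Polygon):
            raise TypeError("polygon must be a shapely Polygon")
        if not self.polygon.is_valid or self.polygon.area <= 0:
            raise ValueError(f"ROI {self.roi_id!r}: polygon must be simple with area > 0")

    def __geo_interface__(self):  # pragma: no cover - convenience
        return mapping(self.polygon)


@dataclass(frozen=True)
class SlideTruth:
    """Ground truth of a simulated slide, for recovery tests.

    ``true_global_ki67`` is the mean of the positivity field over the
    generated invasive tumor cells, and ``true_hotspot_ki67`` its maximum,
    both in percent, so the hot-spot truth always dominates the global one.
    """

    slide_id: str
    baseline_pos_prob: float
    hotspot_centers: tuple[tuple[float, float], ...]
    hotspot_amplitudes: tuple[float, ...]
    hotspot_sigmas: tuple[float, ...]
    true_global_ki67: float
    true_hotspot_ki67: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.baseline_pos_prob <= 1.0:
            raise ValueError("baseline_pos_prob must lie in [0, 1]")
        for lo, hi, name in (
            (0.0, 100.0, "true_global_ki67"),
            (0.0, 100.0, "true_hotspot_ki67"),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name} must lie in [{lo}, {hi}], got {v}")
        if self.true_hotspot_ki67 < self.true_global_ki67 - 1e-9:
            raise ValueError("true_hotspot_ki67 must be >= true_global_ki67")


@dataclass(frozen=True)
class HotspotConfig:
    """One hot-spot app: the four configurable detection parameters.

    ``min_cells`` is the target tumor-cell count of the hot spot, ``fov``
    the microscope field of view setting the drawing radius (0.52 mm at
    20x, 0.26 mm at 40x), ``basis`` whether the heatmap accumulates
    Ki67-positive cells or the positive ratio, and ``shape`` whether the
    extracted region is a field-of-view circle or follows the heatmap
    contours.
    """

    app_id: str
    min_cells: int
    fov: str
    basis: str
    shape: str

    def __post_init__(self) -> None:
        if self.min_cells not in (200, 400, 600, 800, 1000, 1200):
            raise ValueError(f"unsupported min_cells {self.min_cells}")
        if self.fov not in FOV_RADIUS_UM:
            raise ValueError(f"fov must be one of {tuple(FOV_RADIUS_UM)}")
        if self.basis not in ("positive", "ratio"):
            raise ValueError("basis must be 'positive' or 'ratio'")
        if self.shape not in ("circle", "contour"):
            raise ValueError("shape must be 'circle' or 'contour'")

    @property
    def drawing_radius_um(self) -> float:
        return FOV_RADIUS_UM[self.fov]

    @property
    def drawing_radius_mm(self) -> float:
        return self.drawing_radius_um / 1000.0


@dataclass(frozen=True)
class CircleRegion:
    """Field-of-view circle hot-spot region (closed disc)."""

    center_x: float
    center_y: float
    radius_um: float

    def contains(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x - self.center_x) ** 2 + (y - self.center_y) ** 2 <= self.radius_um**2

    @property
    def area_um2(self) -> float:
        return math.pi * self.radius_um**2

    def to_polygon(self, n_segments: int = 64) -> Polygon:
        theta = np.linspace(0.0, 2.0 * math.pi, n_segments, endpoint=False)
        pts = np.column_stack(
            [
                self.center_x + self.radius_um * np.cos(theta),
                self.center_y + self.radius_um * np.sin(theta),
            ]
        )
        return Polygon(pts)


@dataclass(frozen=True)
class GridRegion:
    """Contour hot-spot region: a union of heatmap bin squares.

    Bins are half-open ``[x, x + bin) x [y, y + bin)`` so every cell maps
    to exactly one bin.
    """

    origin: tuple[float, float]
    bin_size: float
    bins: np.ndarray  # 2-D boolean, (ny, nx)

    def contains(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ix = np.floor((x - self.origin[0]) / self.bin_size).astype(int)
        iy = np.floor((y - self.origin[1]) / self.bin_size).astype(int)
        ny, nx = self.bins.shape
        ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
        out = np.zeros(np.shape(x), dtype=bool)
        out[ok] = self.bins[iy[ok], ix[ok]]
        return out

    @property
    def area_um2(self) -> float:
        return float(self.bins.sum()) * self.bin_size**2

    def to_polygon(self):
        """Merge the member bin squares into a (multi)polygon in µm."""
        x0, y0 = self.origin
        b = self.bin_size
        boxes = [
            shapely.box(x0 + j * b, y0 + i * b, x0 + (j + 1) * b, y0 + (i + 1) * b)
            for i, j in zip(*np.nonzero(self.bins))
        ]
        return shapely.unary_union(boxes)


Region = Union[CircleRegion, GridRegion]


@dataclass(frozen=True)
class HotspotResult:
    """Outcome of running one hot-spot app on one slide."""

    app_id: str
    status: str  # "ok" | "no_valid_hotspot"
    region: Optional[Region] = None
    n_cells: int = 0
    n_positive: int = 0
    ki67_index: float = float("nan")

    def __post_init__(self) -> None:
        if self.status not in ("ok", "no_valid_hotspot"):
            raise ValueError(f"bad status {self.status!r}")
        if not 0 <= self.n_positive <= max(self.n_cells, 0):
            raise ValueError("need 0 <= n_positive <= n_cells")
        if self.status == "ok" and self.n_cells > 0:
            expect = 100.0 * self.n_positive / self.n_cells
            if abs(self.ki67_index - expect) > 1e-9:
                raise ValueError("ki67_index inconsistent with counts")

    def to_dict(self) -> dict:
        d = {
            "app_id": self.app_id,
            "status": self.status,
            "n_cells": int(self.n_cells),
            "n_positive": int(self.n_positive),
            "ki67_index": None if math.isnan(self.ki67_index) else float(self.ki67_index),
        }
        if isinstance(self.region, CircleRegion):
            d["region"] = {
                "type": "circle",
                "center_um": [self.region.center_x, self.region.center_y],
                "radius_um": self.region.radius_um,
            }
        elif isinstance(self.region, GridRegion):
            d["region"] = {
                "type": "grid",
                "origin_um": list(self.region.origin),
                "bin_size_um": self.region.bin_size,
                "bins": [[int(i), int(j)] for i, j in zip(*np.nonzero(self.region.bins))],
                "shape": list(self.region.bins.shape),
            }
        else:
            d["region"] = None
        return d


def validate_cells(cells: pd.DataFrame) -> pd.DataFrame:
    """Check a cell table has the expected columns and vocabulary.

    Returns the (unmodified) frame so the call can be chained.
    """
    missing = [c for c in CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise ValueError(f"cell table missing columns: {missing}")
    bad_class = set(cells["cell_class"].dropna().unique()) - set(CELL_CLASSES)
    if bad_class:
        raise ValueError(f"unknown cell_class values: {sorted(bad_class)}")
    bad_status = set(cells["ki67_status"].dropna().unique()) - set(KI67_STATUSES)
    if bad_status:
        raise ValueError(f"unknown ki67_status values: {sorted(bad_status)}")
    tum = cells[cells["cell_class"] == "tumor"]
    if (tum["ki67_status"] == "not_applicable").any():
        raise ValueError("tumor cells must have a positive/negative Ki67 status")
    return cells
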