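"""Hot-spot extraction from density heatmaps.

The detector family is parameterised by the four app parameters
(min_cells, field of view, basis, shape).  Circle hot spots place a
fixed field-of-view disc at the maximal eligible heatmap bin; contour
hot spots take the connected super-level set of the heatmap around its
maximum at the highest threshold whose region still holds at least the
configured number of tumor cells, so an ``ok`` contour result never
contains fewer cells than requested.

Determinism: argmax ties are broken toward the smallest (row, col) in
row-major order; all steps are pure functions of their inputs.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.base import BaseEstimator

from .heatmap import Heatmap, build_count_heatmap, build_ratio_heatmap
from .registry import get_app
from .types import (
    CircleRegion,
    GridRegion,
    HotspotConfig,
    HotspotResult,
    Region,
    TumorROI,
)

_EIGHT_CONN = np.ones((3, 3), dtype=int)

#: Heatmap bin size as a fraction of the drawing radius (see methods note).
DEFAULT_BIN_FRACTION = 1.0 / 8.0


def restrict_to_invasive(cells: pd.DataFrame, rois: Sequence[TumorROI]) -> pd.DataFrame:
    """Keep only tumor-class cells lying in invasive ROIs.

    Immune/stroma/other cells (e.g. proliferating lymphocytes, which may
    be Ki67-positive) and cells in in-situ or artifact regions are
    removed.  With no invasive ROI at all the result is empty and a
    warning is emitted.
    """
    invasive_ids = {r.roi_id for r in rois if r.roi_class == "invasive"}
    if not invasive_ids:
        warnings.warn("no invasive ROI on slide; hot-spot analysis has no support")
        return cells.iloc[0:0]
    keep = (cells["cell_class"] == "tumor") & cells["roi_id"].isin(invasive_ids)
    return cells[keep]


def score_region(region: Region, cells: pd.DataFrame) -> tuple[int, int, float]:
    """Count tumor cells with centroid inside ``region`` (closed boundary).

    Returns ``(n_cells, n_positive, ki67_index)`` with the index in
    percent; an empty region yields ``nan``.
    """
    inside = region.contains(cells["x_um"].to_numpy(), cells["y_um"].to_numpy())
    n = int(inside.sum())
    npos = int((inside & (cells["ki67_status"].to_numpy() == "positive")).sum())
    index = 100.0 * npos / n if n > 0 else float("nan")
    return n, npos, index


def _argmax_eligible(heatmap: Heatmap) -> Optional[tuple[int, int]]:
    if not heatmap.mask.any():
        return None
    masked = np.where(heatmap.mask, heatmap.values, -np.inf)
    flat = int(np.argmax(masked))  # first max in row-major order -> tie rule
    return np.unravel_index(flat, masked.shape)


def find_circle_hotspot(heatmap: Heatmap, cells: pd.DataFrame,
                        config: HotspotConfig) -> HotspotResult:
    """Place the field-of-view circle at the maximal eligible heatmap bin."""
    seed = _argmax_eligible(heatmap)
    if seed is None:
        return HotspotResult(config.app_id, "no_valid_hotspot")
    i, j = seed
    cx = heatmap.origin[0] + (j + 0.5) * heatmap.bin_size
    cy = heatmap.origin[1] + (i + 0.5) * heatmap.bin_size
    region = CircleRegion(cx, cy, config.drawing_radius_um)
    n, npos, index = score_region(region, cells)
    if n == 0:
        return HotspotResult(config.app_id, "no_valid_hotspot", region=region)
    return HotspotResult(config.app_id, "ok", region, n, npos, index)


def find_contour_hotspot(heatmap: Heatmap, cells: pd.DataFrame,
                         config: HotspotConfig) -> HotspotResult:
    """Extract the contour hot spot around the heatmap maximum.

    Sweeps the finite set of distinct heatmap values in descending
    order; at each level the candidate region is the 8-connected
    component of the super-level set that contains the seed bin, and the
    accepted level is the highest one whose component holds at least
    ``config.min_cells`` tumor cells.  Because the components are nested
    as the level drops, the cell count is monotone and the sweep is
    implemented as an exact binary search over the levels.
    """
    seed = _argmax_eligible(heatmap)
    if seed is None:
        return HotspotResult(config.app_id, "no_valid_hotspot")
    vals = heatmap.values
    iy, ix, ok = heatmap.bin_indices(cells["x_um"].to_numpy(),
                                     cells["y_um"].to_numpy())
    pos = cells["ki67_status"].to_numpy() == "positive"
    iy, ix, pos = iy[ok], ix[ok], pos[ok]

    def component(level: float) -> np.ndarray:
        labels, _ = ndimage.label(vals >= level, structure=_EIGHT_CONN)
        return labels == labels[seed]

    def n_in(comp: np.ndarray) -> int:
        return int(comp[iy, ix].sum())

    levels = np.unique(vals)
    levels = levels[levels <= vals[seed]]  # the seed must stay in the set
    comp_lo = component(levels[0])
    if n_in(comp_lo) < config.min_cells:
        return HotspotResult(config.app_id, "no_valid_hotspot")
    lo, hi = 0, len(levels) - 1
    while lo < hi:  # invariant: levels[lo] feasible
        mid = (lo + hi + 1) // 2
        if n_in(component(levels[mid])) >= config.min_cells:
            lo = mid
        else:
            hi = mid - 1
    comp = component(levels[lo])
    region = GridRegion(heatmap.origin, heatmap.bin_size, comp)
    inside = comp[iy, ix]
    n = int(inside.sum())
    npos = int((inside & pos).sum())
    return HotspotResult(config.app_id, "ok", region, n, npos, 100.0 * npos / n)


class _SlideScorer:
    """Shared heatmap builder for running several apps on one slide.

    Positive- and total-count heatmaps depend only on the field of view
    (radius and grid), so they are computed once per fov and reused by
    every app; the per-app eligibility masks are cheap boolean grids.
    """

    def __init__(self, cells: pd.DataFrame, rois: Sequence[TumorROI],
                 bin_size: Optional[float] = None,
                 enforce_min_cells: bool = True):
        self.cells = restrict_to_invasive(cells, rois) if rois is not None else cells
        self.enforce_min_cells = enforce_min_cells
        self.bin_size = bin_size
        invasive = [r.polygon for r in rois if r.roi_class == "invasive"]
        if invasive:
            xs0, ys0, xs1, ys1 = zip(*(p.bounds for p in invasive))
            self.bounds = (min(xs0), min(ys0), max(xs1), max(ys1))
        else:
            self.bounds = None
        self._cache: dict[str, tuple[Heatmap, Heatmap]] = {}

    def _heatmaps(self, fov: str, radius_um: float) -> tuple[Heatmap, Heatmap]:
        if fov not in self._cache:
            b = self.bin_size if self.bin_size is not None else radius_um * DEFAULT_BIN_FRACTION
            pos_cells = self.cells[self.cells["ki67_status"] == "positive"]
            tot = build_count_heatmap(self.cells, radius_um, b, self.bounds, "count_total")
            pos = build_count_heatmap(pos_cells, radius_um, b, self.bounds, "count_positive")
            self._cache[fov] = (pos, tot)
        return self._cache[fov]

    def run(self, config: HotspotConfig) -> HotspotResult:
        if self.bounds is None or len(self.cells) == 0:
            return HotspotResult(config.app_id, "no_valid_hotspot")
        pos, tot = self._heatmaps(config.fov, config.drawing_radius_um)
        if config.basis == "ratio":
            hm = build_ratio_heatmap(pos, tot, config.min_cells)
        elif config.shape == "circle" and self.enforce_min_cells:
            # circle apps: only bins whose in-radius total reaches the
            # target count are eligible seeds
            hm = pos.with_mask(tot.values >= config.min_cells)
        else:
            hm = pos.with_mask(tot.values > 0)
        if config.shape == "circle":
            return find_circle_hotspot(hm, self.cells, config)
        return find_contour_hotspot(hm, self.cells, config)


def run_app(config: HotspotConfig, cells: pd.DataFrame, rois: Sequence[TumorROI],
            bin_size: Optional[float] = None,
            enforce_min_cells: bool = True) -> HotspotResult:
    """Run one hot-spot app end to end on a slide.

    Restricts to invasive tumor cells, builds the heatmap(s) for the
    app's basis, extracts the region per the app's shape and scores the
    Ki67 index inside it.  Deterministic for fixed inputs.
    """
    return _SlideScorer(cells, rois, bin_size, enforce_min_cells).run(config)


def run_apps(configs: Iterable[HotspotConfig], cells: pd.DataFrame,
             rois: Sequence[TumorROI], bin_size: Optional[float] = None,
             enforce_min_cells: bool = True) -> dict[str, HotspotResult]:
    """Run several apps on one slide, sharing heatmap construction."""
    scorer = _SlideScorer(cells, rois, bin_size, enforce_min_cells)
    return {cfg.app_id: scorer.run(cfg) for cfg in configs}


class HotspotDetector(BaseEstimator):
    """Scikit-learn style wrapper around one hot-spot app.

    Parameters
    ----------
    app : str, default "APP24"
        Registry id of the app configuration to run.
    bin_size : float or None
        Heatmap bin size in µm; ``None`` uses drawing_radius / 8.
    enforce_min_cells : bool, default True
        Whether circle apps mask out seed bins whose in-radius total
        count is below the app's target.

    Attributes
    ----------
    result_ : HotspotResult
    ki67_index_ : float
        Hot-spot Ki67 index in percent (nan when no valid hot spot).
    n_cells_, n_positive_ : int
    status_ : str
    """

    def __init__(self, app: str = "APP24", bin_size: Optional[float] = None,
                 enforce_min_cells: bool = True):
        self.app = app
        self.bin_size = bin_size
        self.enforce_min_cells = enforce_min_cells

    def fit(self, cells: pd.DataFrame, rois: Sequence[TumorROI]):
        config = get_app(self.app)
        self.result_ = run_app(config, cells, rois, self.bin_size,
                               self.enforce_min_cells)
        self.ki67_index_ = self.result_.ki67_index
        self.n_cells_ = self.result_.n_cells
        self.n_positive_ = self.result_.n_positive
        self.status_ = self.result_.status
        return self

    def score(self, cells: pd.DataFrame, rois: Sequence[TumorROI]) -> float:
        """Fit and return the hot-spot Ki67 index (percent)."""
        return self.fit(cells, rois).ki67_index_
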