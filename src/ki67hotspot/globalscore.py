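"""Global (whole-tumor-area) Ki67 scoring with pluggable cell classification.

The global score is the percentage of Ki67-positive nuclei among all
predicted tumor cells within the pathologist-defined tumor area.  The
input is already a nucleus table, so classification is a per-cell
labelling stage: the default ``oracle`` classifier copies the ground
truth (for pipeline tests), and a ``noisy`` classifier corrupts the
tumor/non-tumor call at configurable false-positive / false-negative
rates to probe robustness.  Any callable mapping a cell table to
predicted labels can be registered.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .types import TumorROI

#: Watershed segmentation settings of the upstream nucleus-detection
#: pipeline, recorded as provenance metadata only (the package consumes
#: already-detected nucleus centroids; nothing here executes these).
SEGMENTATION_PROVENANCE = {
    "detection_image": "optical density sum",
    "requested_pixel_size_um": 0.5,
    "background_radius_um": 8.0,
    "median_filter_radius_um": 0.0,
    "sigma_um": 1.5,
    "min_cell_area_um2": 10.0,
    "max_cell_area_um2": 400.0,
    "threshold": 0.1,
    "max_background_intensity": 2.0,
}


def oracle_classifier(cells: pd.DataFrame,
                      rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Copy ground-truth labels into the predicted columns."""
    out = cells.copy()
    out["predicted_class"] = cells["cell_class"].to_numpy()
    out["predicted_ki67_status"] = cells["ki67_status"].to_numpy()
    return out


def make_noisy_classifier(fp: float = 0.0, fn: float = 0.0) -> Callable:
    """Classifier corrupting the tumor call.

    ``fp`` is the rate at which non-tumor cells are mislabelled as tumor,
    ``fn`` the rate at which tumor cells are mislabelled as immune.
    """
    if not (0 <= fp <= 1 and 0 <= fn <= 1):
        raise ValueError("flip rates must lie in [0, 1]")

    def classify(cells: pd.DataFrame, rng: Optional[np.random.Generator] = None
                 ) -> pd.DataFrame:
        if rng is None:
            rng = np.random.default_rng(0)
        out = oracle_classifier(cells)
        is_tumor = out["predicted_class"].to_numpy() == "tumor"
        u = rng.uniform(size=len(out))
        pred = out["predicted_class"].to_numpy(copy=True)
        pred[is_tumor & (u < fn)] = "immune"
        pred[~is_tumor & (u < fp)] = "tumor"
        out["predicted_class"] = pred
        # cells pulled into the tumor pool need a readable Ki67 call
        newly = (pred == "tumor") & (out["predicted_ki67_status"] == "not_applicable")
        out.loc[newly, "predicted_ki67_status"] = "negative"
        return out

    return classify


CLASSIFIERS: dict[str, Callable] = {"oracle": oracle_classifier}


def resolve_classifier(spec) -> tuple[str, Callable]:
    """Resolve a classifier id like ``"oracle"`` or ``"noisy:0.1,0.05"``."""
    if callable(spec):
        return getattr(spec, "__name__", "custom"), spec
    if spec in CLASSIFIERS:
        return spec, CLASSIFIERS[spec]
    if isinstance(spec, str) and spec.startswith("noisy"):
        rates = spec.split(":", 1)[1] if ":" in spec else "0,0"
        fp, fn = (float(v) for v in rates.split(","))
        return spec, make_noisy_classifier(fp, fn)
    raise KeyError(f"unknown classifier {spec!r}")


def classify_cells(cells: pd.DataFrame, classifier="oracle",
                   rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Apply a registered classifier, adding predicted_* columns."""
    cid, fn = resolve_classifier(classifier)
    out = fn(cells, rng)
    out.attrs["classifier_id"] = cid
    return out


@dataclass(frozen=True)
class GlobalScoreResult:
    global_ki67: float
    n_tumor_cells: int
    n_positive: int
    status: str  # "ok" | "no_tumor_cells"
    classifier_id: str


def global_ki67(classified: pd.DataFrame, rois: Sequence[TumorROI],
                roi_classes: tuple[str, ...] = ("invasive",)) -> GlobalScoreResult:
    """Global Ki67 index over the tumor-area ROIs.

    100 x positive / total over predicted-tumor cells inside ROIs of the
    selected classes (invasive only by default).  Predicted-immune cells
    — including Ki67-positive lymphocytes — never enter the denominator.
    """
    wanted = {r.roi_id for r in rois if r.roi_class in roi_classes}
    sel = (classified["predicted_class"] == "tumor") \
        & classified["roi_id"].isin(wanted)
    n = int(sel.sum())
    cid = classified.attrs.get("classifier_id", "unknown")
    if n == 0:
        return GlobalScoreResult(float("nan"), 0, 0, "no_tumor_cells", cid)
    npos = int((classified.loc[sel, "predicted_ki67_status"] == "positive").sum())
    return GlobalScoreResult(100.0 * npos / n, n, npos, "ok", cid)


class GlobalScorer(BaseEstimator):
    """Scikit-learn style wrapper for global Ki67 scoring.

    Parameters
    ----------
    classifier : str or callable, default "oracle"
    roi_classes : tuple of str, default ("invasive",)
        ROI classes forming the tumor area.

    Attributes
    ----------
    global_ki67_ : float (percent)
    n_tumor_cells_, n_positive_ : int
    status_ : str
    """

    def __init__(self, classifier="oracle",
                 roi_classes: tuple[str, ...] = ("invasive",)):
        self.classifier = classifier
        self.roi_classes = roi_classes

    def fit(self, cells: pd.DataFrame, rois: Sequence[TumorROI],
            rng: Optional[np.random.Generator] = None):
        classified = classify_cells(cells, self.classifier, rng)
        res = global_ki67(classified, rois, self.roi_classes)
        self.result_ = res
        self.global_ki67_ = res.global_ki67
        self.n_tumor_cells_ = res.n_tumor_cells
        self.n_positive_ = res.n_positive
        self.status_ = res.status
        return self

    def score(self, cells, rois) -> float:
        """Fit and return the global Ki67 index (percent)."""
        return self.fit(cells, rois).global_ki67_
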