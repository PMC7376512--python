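"""Synthetic digital-pathology slides and cohorts.

The generator emulates the statistical structure the downstream analysis
assumes, at the nucleus-point level (no pixels are rendered):

* tumor nuclei follow a Thomas cluster process (Poisson parents,
  Gaussian offspring) plus a homogeneous background, restricted to an
  irregular invasive-tumor ROI — clustering produces the local density
  heterogeneity that distinguishes count- from ratio-basis hot spots;
* each tumor cell is Ki67-positive with probability
  ``baseline + sum_k amplitude_k * exp(-d_k^2 / 2 sigma_k^2)`` clamped
  to [0, 1], where d_k is the distance to planted hot-spot center k;
* immune and stromal cells are homogeneous Poisson over the whole
  slide, immune cells with a configurable Ki67-positive fraction
  (proliferating lymphocytes are a classic hot-spot confounder);
* optionally an in-situ ROI with elevated positivity, to exercise the
  invasive-only restriction;
* per-patient survival follows an exponential model whose log-hazard
  jumps by a configurable coefficient when the slide's true global Ki67
  is above the cut-off, with independent exponential censoring.

A single master seed fixes every coordinate, label and survival time;
per-slide streams are derived by stable hashing of (seed, slide_id).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import shapely
from scipy.optimize import brentq
from shapely.geometry import Polygon

from .types import SlideTruth, TumorROI, CELL_COLUMNS


@dataclass
class SimulationParams:
    """All knobs of the synthetic cohort, with study-scale defaults.

    Intensities are per mm²; lengths in µm; hazards per year.
    """

    n_patients: int = 139
    slide_width_um: float = 2600.0
    slide_height_um: float = 2600.0
    # Thomas process for tumor nuclei
    parent_intensity_per_mm2: float = 8.0
    offspring_per_parent: float = 450.0
    cluster_sigma_um: float = 140.0
    background_tumor_intensity_per_mm2: float = 1100.0
    # planted proliferation hot spots (placed at tumor-cell cluster
    # centers: proliferative foci are themselves cellular)
    n_hotspots: int = 1
    hotspot_amplitude_range: tuple[float, float] = (0.05, 0.25)
    hotspot_sigma_range_um: tuple[float, float] = (800.0, 1200.0)
    baseline_pos_beta: tuple[float, float] = (1.5, 9.0)
    #: fixed per-slide baseline positivity overriding the Beta draw
    baseline_pos_prob: Optional[float] = None
    # confounders
    immune_intensity_per_mm2: float = 150.0
    immune_ki67_pos_fraction: float = 0.3
    stroma_intensity_per_mm2: float = 100.0
    in_situ_probability: float = 0.3
    in_situ_extra_positivity: float = 0.3
    # outcome linkage
    rfs_baseline_hazard: float = 0.05
    os_baseline_hazard: float = 0.03
    log_hr_high_ki67: float = math.log(3.0)
    censoring_rate: float = 0.3
    ki67_cutoff: float = 20.0
    subtype_label_noise: float = 0.25
    subtype_missing_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("parent_intensity_per_mm2", "offspring_per_parent",
                     "background_tumor_intensity_per_mm2",
                     "immune_intensity_per_mm2", "stroma_intensity_per_mm2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.censoring_rate <= 1.0:
            raise ValueError("censoring_rate must lie in [0, 1]")
        if self.slide_width_um <= 0 or self.slide_height_um <= 0:
            raise ValueError("slide must have positive area")
        if not (math.isfinite(self.log_hr_high_ki67)
                and math.isfinite(self.rfs_baseline_hazard)
                and math.isfinite(self.os_baseline_hazard)):
            raise ValueError("hazard parameters must be finite")
        if self.rfs_baseline_hazard <= 0 or self.os_baseline_hazard <= 0:
            raise ValueError("baseline hazards must be > 0")
        if self.baseline_pos_prob is not None \
                and not 0.0 <= self.baseline_pos_prob <= 1.0:
            raise ValueError("baseline_pos_prob must lie in [0, 1]")


def child_rng(seed: int, slide_id: str) -> np.random.Generator:
    """Deterministic per-slide generator from (master seed, slide id)."""
    digest = hashlib.sha256(slide_id.encode("utf-8")).digest()
    h = int.from_bytes(digest[:8], "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed), h]))


def _poisson_points(rng, intensity_per_mm2: float, x0, y0, x1, y1) -> np.ndarray:
    area_mm2 = (x1 - x0) * (y1 - y0) / 1e6
    n = rng.poisson(intensity_per_mm2 * area_mm2)
    pts = np.column_stack([rng.uniform(x0, x1, n), rng.uniform(y0, y1, n)])
    return pts


def _irregular_polygon(rng, cx, cy, rx, ry, n_vertices=12,
                       jitter=(0.85, 1.05)) -> Polygon:
    # evenly spaced angles with bounded jitter: every edge subtends a
    # small arc, so the radially jittered star polygon stays simple
    step = 2 * math.pi / n_vertices
    theta = (np.arange(n_vertices) * step
             + rng.uniform(-0.3 * step, 0.3 * step, n_vertices))
    scale = rng.uniform(*jitter, n_vertices)
    xs = cx + rx * scale * np.cos(theta)
    ys = cy + ry * scale * np.sin(theta)
    return Polygon(np.column_stack([xs, ys]))


def positivity_field(x, y, baseline: float, centers, amplitudes, sigmas) -> np.ndarray:
    """Ki67-positivity probability at (x, y): clamped sum of Gaussian bumps."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    p = np.full(x.shape, float(baseline))
    for (cx, cy), amp, sig in zip(centers, amplitudes, sigmas):
        d2 = (x - cx) ** 2 + (y - cy) ** 2
        p = p + amp * np.exp(-d2 / (2.0 * sig**2))
    return np.clip(p, 0.0, 1.0)


def _sample_in_polygon(rng, poly: Polygon, n: int, max_tries: int = 60) -> np.ndarray:
    """Rejection-sample n points uniformly inside a polygon."""
    x0, y0, x1, y1 = poly.bounds
    out = []
    need = n
    for _ in range(max_tries):
        if need <= 0:
            break
        cand = np.column_stack([rng.uniform(x0, x1, max(4 * need, 16)),
                                rng.uniform(y0, y1, max(4 * need, 16))])
        keep = shapely.contains_xy(poly, cand[:, 0], cand[:, 1])
        out.append(cand[keep][:need])
        need -= len(out[-1])
    pts = np.concatenate(out) if out else np.empty((0, 2))
    if len(pts) < n:
        raise RuntimeError("polygon sampling failed; degenerate geometry?")
    return pts


def _draw_hotspot_truth(rng, params: SimulationParams, roi: Optional[Polygon],
                        candidate_centers: Optional[np.ndarray] = None):
    """Per-slide baseline / hot-spot parameters (shared by both modes).

    Centers are drawn from ``candidate_centers`` (cluster parents) when
    available, else uniformly in the ROI.
    """
    if params.baseline_pos_prob is not None:
        baseline = float(params.baseline_pos_prob)
    else:
        baseline = float(rng.beta(*params.baseline_pos_beta))
    amplitudes, sigmas, centers = [], [], []
    for _ in range(params.n_hotspots):
        amp = float(rng.uniform(*params.hotspot_amplitude_range))
        # keep baseline + single-bump amplitude within [0, 1]
        amp = min(amp, 1.0 - baseline)
        amplitudes.append(amp)
        sigmas.append(float(rng.uniform(*params.hotspot_sigma_range_um)))
        if candidate_centers is not None and len(candidate_centers):
            k = int(rng.integers(len(candidate_centers)))
            centers.append(tuple(candidate_centers[k]))
        elif roi is not None:
            centers.append(tuple(_sample_in_polygon(rng, roi, 1)[0]))
    return baseline, centers, amplitudes, sigmas


def generate_slide(params: SimulationParams, slide_id: str,
                   rng: Optional[np.random.Generator] = None
                   ) -> tuple[pd.DataFrame, list[TumorROI], SlideTruth]:
    """Generate one synthetic slide: cell table, ROIs and ground truth."""
    if rng is None:
        rng = child_rng(params.seed, slide_id)
    W, H = params.slide_width_um, params.slide_height_um

    invasive = TumorROI(
        "roi_inv_1",
        _irregular_polygon(rng, 0.38 * W, 0.5 * H, 0.33 * W, 0.44 * H),
        "invasive",
    )
    rois = [invasive]
    in_situ = None
    if rng.uniform() < params.in_situ_probability:
        cy = rng.uniform(0.25, 0.75) * H
        in_situ = TumorROI(
            "roi_ins_1",
            _irregular_polygon(rng, 0.87 * W, cy, 0.07 * W, 0.07 * W,
                               n_vertices=10, jitter=(0.9, 1.0)),
            "in_situ",
        )
        rois.append(in_situ)

    # --- tumor nuclei: Thomas cluster process + homogeneous background ---
    bx0, by0, bx1, by1 = invasive.polygon.bounds
    parents = _poisson_points(rng, params.parent_intensity_per_mm2, bx0, by0, bx1, by1)
    in_roi = shapely.contains_xy(invasive.polygon, parents[:, 0], parents[:, 1]) \
        if len(parents) else np.zeros(0, dtype=bool)
    baseline, centers, amplitudes, sigmas = _draw_hotspot_truth(
        rng, params, invasive.polygon, candidate_centers=parents[in_roi])
    offspring = []
    for px, py in parents:
        k = rng.poisson(params.offspring_per_parent)
        offspring.append(np.column_stack([
            rng.normal(px, params.cluster_sigma_um, k),
            rng.normal(py, params.cluster_sigma_um, k),
        ]))
    bg = _poisson_points(rng, params.background_tumor_intensity_per_mm2,
                         bx0, by0, bx1, by1)
    tumor_xy = np.concatenate(offspring + [bg]) if offspring else bg
    inside = shapely.contains_xy(invasive.polygon, tumor_xy[:, 0], tumor_xy[:, 1])
    inside &= ((tumor_xy[:, 0] >= 0) & (tumor_xy[:, 0] <= W)
               & (tumor_xy[:, 1] >= 0) & (tumor_xy[:, 1] <= H))
    tumor_xy = tumor_xy[inside]
    p_tumor = positivity_field(tumor_xy[:, 0], tumor_xy[:, 1], baseline,
                               centers, amplitudes, sigmas)
    tumor_pos = rng.uniform(size=len(tumor_xy)) < p_tumor

    frames = [pd.DataFrame({
        "x_um": tumor_xy[:, 0], "y_um": tumor_xy[:, 1],
        "cell_class": "tumor",
        "ki67_status": np.where(tumor_pos, "positive", "negative"),
        "roi_id": invasive.roi_id,
    })]

    # --- in-situ tumor component with elevated positivity ---
    if in_situ is not None:
        dens = (params.parent_intensity_per_mm2 * params.offspring_per_parent
                + params.background_tumor_intensity_per_mm2)
        ins_xy = _poisson_points(rng, dens, *in_situ.polygon.bounds)
        keep = shapely.contains_xy(in_situ.polygon, ins_xy[:, 0], ins_xy[:, 1])
        ins_xy = ins_xy[keep]
        p_ins = min(baseline + params.in_situ_extra_positivity, 1.0)
        frames.append(pd.DataFrame({
            "x_um": ins_xy[:, 0], "y_um": ins_xy[:, 1],
            "cell_class": "tumor",
            "ki67_status": np.where(rng.uniform(size=len(ins_xy)) < p_ins,
                                    "positive", "negative"),
            "roi_id": in_situ.roi_id,
        }))

    # --- immune and stromal confounders over the whole slide ---
    imm_xy = _poisson_points(rng, params.immune_intensity_per_mm2, 0, 0, W, H)
    str_xy = _poisson_points(rng, params.stroma_intensity_per_mm2, 0, 0, W, H)

    def _roi_of(xy: np.ndarray) -> np.ndarray:
        out = np.full(len(xy), None, dtype=object)
        for roi in rois:
            hit = shapely.contains_xy(roi.polygon, xy[:, 0], xy[:, 1])
            out[hit & (out == None)] = roi.roi_id  # noqa: E711
        return out

    frames.append(pd.DataFrame({
        "x_um": imm_xy[:, 0], "y_um": imm_xy[:, 1],
        "cell_class": "immune",
        "ki67_status": np.where(
            rng.uniform(size=len(imm_xy)) < params.immune_ki67_pos_fraction,
            "positive", "negative"),
        "roi_id": _roi_of(imm_xy),
    }))
    frames.append(pd.DataFrame({
        "x_um": str_xy[:, 0], "y_um": str_xy[:, 1],
        "cell_class": "stroma",
        "ki67_status": "not_applicable",
        "roi_id": _roi_of(str_xy),
    }))

    cells = pd.concat(frames, ignore_index=True)
    cells.insert(0, "cell_id", [f"{slide_id}_c{i:06d}" for i in range(len(cells))])
    cells = cells[list(CELL_COLUMNS)]

    inv_mask = (cells["cell_class"] == "tumor") & (cells["roi_id"] == invasive.roi_id)
    p_inv = positivity_field(cells.loc[inv_mask, "x_um"], cells.loc[inv_mask, "y_um"],
                             baseline, centers, amplitudes, sigmas)
    truth = SlideTruth(
        slide_id=slide_id,
        baseline_pos_prob=baseline,
        hotspot_centers=tuple(centers),
        hotspot_amplitudes=tuple(amplitudes),
        hotspot_sigmas=tuple(sigmas),
        true_global_ki67=float(100.0 * p_inv.mean()) if inv_mask.any() else 0.0,
        true_hotspot_ki67=float(100.0 * p_inv.max()) if inv_mask.any() else 0.0,
    )
    return cells, rois, truth


def _censoring_rate_to_hazard(target: float, hazards: np.ndarray) -> float:
    """Exponential censoring rate c with E[fraction censored] = target.

    For event hazard h and independent censoring Exp(c) the censoring
    probability is c / (h + c); solve the cohort average for c.
    """
    if target <= 0:
        return 0.0
    if target >= 1:
        return math.inf

    def f(c):
        return np.mean(c / (hazards + c)) - target

    hi = float(np.max(hazards)) * target / (1 - target) * 10 + 1.0
    while f(hi) < 0:
        hi *= 10
    return brentq(f, 1e-12, hi)


def _survival_endpoint(rng, hazards: np.ndarray, censoring_rate: float
                       ) -> tuple[np.ndarray, np.ndarray]:
    times = rng.exponential(1.0 / hazards)
    c = _censoring_rate_to_hazard(censoring_rate, hazards)
    if c == 0.0:
        return times, np.ones(len(times), dtype=bool)
    cens = rng.exponential(1.0 / c, len(times))
    event = times <= cens
    return np.minimum(times, cens), event


def generate_cohort(params: SimulationParams, with_slides: bool = True):
    """Generate a synthetic patient cohort.

    Returns ``(patients, slides)`` where ``patients`` is a DataFrame (one
    row per patient, clinicopathological covariates + survival endpoints)
    and ``slides`` maps slide_id -> (cells, rois, truth), or ``None``
    when ``with_slides`` is false (fast covariate-only mode; the true
    Ki67 is then drawn from the same per-slide parameter distribution
    with the Gaussian-bump mass integrated analytically).
    """
    if params.n_patients < 2:
        raise ValueError("need n_patients >= 2")
    # distinct stream from any per-slide stream
    master = np.random.default_rng(np.random.SeedSequence([int(params.seed), 0xC04057]))
    slides = {} if with_slides else None
    records = []
    true_ki67 = np.empty(params.n_patients)
    for i in range(params.n_patients):
        slide_id = f"S{i + 1:04d}"
        if with_slides:
            cells, rois, truth = generate_slide(params, slide_id)
            slides[slide_id] = (cells, rois, truth)
            true_ki67[i] = truth.true_global_ki67
        else:
            rng_i = child_rng(params.seed, slide_id)
            baseline, _, amps, sigmas = _draw_hotspot_truth(rng_i, params, None)
            # mean field over an ROI-sized disc with the bump at a random
            # interior point, by a small fixed-size Monte-Carlo average
            r_roi = 0.38 * math.sqrt(params.slide_width_um
                                     * params.slide_height_um)
            u = rng_i.uniform(size=(256, 2))
            rad = r_roi * np.sqrt(u[:, 0])
            ang = 2 * math.pi * u[:, 1]
            pts = np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
            c = rng_i.uniform(size=2)
            center = (r_roi * math.sqrt(c[0]) * math.cos(2 * math.pi * c[1]),
                      r_roi * math.sqrt(c[0]) * math.sin(2 * math.pi * c[1]))
            p = positivity_field(pts[:, 0], pts[:, 1], baseline,
                                 [center], amps, sigmas)
            true_ki67[i] = 100.0 * float(p.mean())
        records.append({"patient_id": f"P{i + 1:04d}", "slide_id": slide_id})

    high = true_ki67 >= params.ki67_cutoff
    df = pd.DataFrame(records)
    df["true_global_ki67"] = true_ki67
    df["true_ki67_high"] = high

    # ER+/HER2- luminal cohort covariates
    df["er_percent"] = np.round(master.uniform(10, 95, len(df)), 1)
    low_pr = master.uniform(size=len(df)) < 0.26
    df["pr_percent"] = np.round(np.where(low_pr, master.uniform(0, 19.9, len(df)),
                                         master.uniform(20, 95, len(df))), 1)
    df["her2"] = "neg"
    grade_p = np.where(high[:, None], [[0.05, 0.45, 0.50]], [[0.25, 0.60, 0.15]])
    df["grade"] = [int(master.choice([1, 2, 3], p=p)) for p in grade_p]
    mito_p = np.where(high[:, None], [[0.15, 0.40, 0.45]], [[0.60, 0.30, 0.10]])
    df["mitotic_score"] = [int(master.choice([1, 2, 3], p=p)) for p in mito_p]
    df["pT"] = master.choice([1, 2, 3], size=len(df), p=[0.40, 0.55, 0.05])
    df["pN"] = master.choice([0, 1, 2, 3], size=len(df), p=[0.55, 0.32, 0.09, 0.04])

    # intrinsic subtype from true proliferation, with label noise
    subtype = np.where(high, "lumB", "lumA").astype(object)
    flip = master.uniform(size=len(df)) < params.subtype_label_noise
    subtype[flip] = np.where(subtype[flip] == "lumA", "lumB", "lumA")
    missing = master.uniform(size=len(df)) < params.subtype_missing_rate
    subtype[missing] = "none"
    df["intrinsic_subtype"] = subtype

    beta = params.log_hr_high_ki67
    rfs_haz = params.rfs_baseline_hazard * np.exp(beta * high)
    os_haz = params.os_baseline_hazard * np.exp(beta * high)
    df["rfs_time"], df["rfs_event"] = _survival_endpoint(master, rfs_haz,
                                                         params.censoring_rate)
    df["os_time"], df["os_event"] = _survival_endpoint(master, os_haz,
                                                       params.censoring_rate)
    return df, slides
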