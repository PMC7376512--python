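"""Canned simulation experiments.

Each function runs one self-contained study on synthetic data and
returns plain numbers, so the same entry points serve the test-suite
and the reproduction script.  Experiments derive all randomness from an
integer seed.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd

from .detect import find_circle_hotspot, find_contour_hotspot
from .globalscore import classify_cells, global_ki67
from .heatmap import build_count_heatmap, build_ratio_heatmap
from .pipeline import ExperimentConfig, score_cohort
from .reference import brute_force_count_grid, exhaustive_circle, sweep_contour
from .registry import ICC_GROUPS, app_registry, post_qc_apps
from .stats import cox, icc
from .synthetic import SimulationParams, generate_cohort, generate_slide
from .types import CircleRegion, GridRegion, HotspotConfig


def registry_facts() -> dict:
    """Structural facts about the app registry."""
    apps = app_registry()
    factorial = list(itertools.product((200, 1000), ("20x", "40x"),
                                       ("positive", "ratio"),
                                       ("circle", "contour")))
    return {
        "factorial_n_configs": len(factorial),
        "registry_n_apps": len(apps),
        "post_qc_n_apps": len(post_qc_apps()),
        "circle_diameter_20x_mm": 2 * HotspotConfig("APP05", 1000, "20x",
                                                    "ratio", "circle").drawing_radius_mm,
        "circle_diameter_40x_mm": 2 * HotspotConfig("APP08", 200, "40x",
                                                    "ratio", "circle").drawing_radius_mm,
    }


def fuzz_slide(rng: np.random.Generator, max_cells: int = 500,
               extent: float = 1300.0) -> pd.DataFrame:
    """Small random slide: clustered + uniform cells with random positivity."""
    n_clusters = int(rng.integers(1, 4))
    frames = []
    total = 0
    for _ in range(n_clusters):
        k = int(rng.integers(60, 240))
        c = rng.uniform(0.2 * extent, 0.8 * extent, 2)
        sd = rng.uniform(30, 120)
        xy = rng.normal(c, sd, (k, 2))
        frames.append(xy)
        total += k
    n_bg = int(rng.integers(0, max(10, max_cells - total)))
    frames.append(rng.uniform(0, extent, (n_bg, 2)))
    xy = np.clip(np.concatenate(frames), 0, extent)[:max_cells]
    p = rng.uniform(0.05, 0.8)
    pos = rng.uniform(size=len(xy)) < p
    return pd.DataFrame({
        "x_um": xy[:, 0], "y_um": xy[:, 1],
        "ki67_status": np.where(pos, "positive", "negative"),
    })


def _fuzz_config(rng: np.random.Generator) -> HotspotConfig:
    shape = rng.choice(["circle", "contour"])
    basis = rng.choice(["positive", "ratio"])
    fov = rng.choice(["20x", "40x"])
    min_cells = int(rng.choice([200, 400]))
    return HotspotConfig("FUZZ", min_cells, fov, basis, shape)


def _heatmap_pair(cells: pd.DataFrame, cfg: HotspotConfig, extent: float):
    bounds = (0.0, 0.0, extent, extent)
    b = cfg.drawing_radius_um / 8.0
    pos_cells = cells[cells["ki67_status"] == "positive"]
    tot = build_count_heatmap(cells, cfg.drawing_radius_um, b, bounds, "count_total")
    pos = build_count_heatmap(pos_cells, cfg.drawing_radius_um, b, bounds,
                              "count_positive")
    if cfg.basis == "ratio":
        hm = build_ratio_heatmap(pos, tot, cfg.min_cells)
    elif cfg.shape == "circle":
        hm = pos.with_mask(tot.values >= cfg.min_cells)
    else:
        hm = pos.with_mask(tot.values > 0)
    return hm, pos_cells, bounds, b


def oracle_equivalence(n_slides: int = 100, seed: int = 0) -> dict:
    """Compare optimised extraction against exhaustive reference search.

    On fuzzed small slides, circle placement must equal the explicit
    argmax over every bin center and contour extraction must equal the
    full linear threshold sweep, bit-exactly (status, placement, counts).
    """
    rng = np.random.default_rng(seed)
    n_circle = n_contour = 0
    circle_ok = contour_ok = 0
    n_extracted = 0
    for _ in range(n_slides):
        cells = fuzz_slide(rng)
        cfg = _fuzz_config(rng)
        extent = 1300.0
        hm, pos_cells, bounds, b = _heatmap_pair(cells, cfg, extent)
        # reference values from the full distance matrix
        xy = cells[["x_um", "y_um"]].to_numpy()
        xy_pos = pos_cells[["x_um", "y_um"]].to_numpy()
        ref_tot = brute_force_count_grid(xy, cfg.drawing_radius_um, b, bounds)
        ref_pos = brute_force_count_grid(xy_pos, cfg.drawing_radius_um, b, bounds)
        if cfg.basis == "ratio":
            ref_vals = np.divide(ref_pos, ref_tot,
                                 out=np.zeros_like(ref_pos), where=ref_tot > 0)
            ref_mask = ref_tot >= cfg.min_cells
        else:
            ref_vals = ref_pos
            ref_mask = ref_tot >= cfg.min_cells if cfg.shape == "circle" \
                else ref_tot > 0
        if cfg.shape == "circle":
            n_circle += 1
            res = find_circle_hotspot(hm, cells, cfg)
            ref = exhaustive_circle(ref_vals, ref_mask, hm.origin, b,
                                    cfg.drawing_radius_um, cells)
            if ref is None:
                circle_ok += res.status == "no_valid_hotspot"
            else:
                (cx, cy), n, npos = ref
                circle_ok += (res.status == "ok"
                              and isinstance(res.region, CircleRegion)
                              and res.region.center_x == cx
                              and res.region.center_y == cy
                              and res.n_cells == n and res.n_positive == npos)
                n_extracted += 1
        else:
            n_contour += 1
            res = find_contour_hotspot(hm, cells, cfg)
            ref = sweep_contour(ref_vals, ref_mask, hm.origin, b, cells,
                                cfg.min_cells)
            if ref is None:
                contour_ok += res.status == "no_valid_hotspot"
            else:
                comp, n, npos = ref
                contour_ok += (res.status == "ok"
                               and isinstance(res.region, GridRegion)
                               and np.array_equal(res.region.bins, comp)
                               and res.n_cells == n and res.n_positive == npos)
                n_extracted += 1
    return {
        "n_slides": n_slides,
        "n_circle": n_circle, "circle_agreement": circle_ok,
        "n_contour": n_contour, "contour_agreement": contour_ok,
        "n_with_hotspot": n_extracted,
    }


def min_cell_guarantee(n_slides: int = 1000, seed: int = 0) -> dict:
    """Count contour results violating n_cells >= min_cells over fuzz slides."""
    rng = np.random.default_rng(seed)
    n_ok = violations = 0
    for _ in range(n_slides):
        cells = fuzz_slide(rng)
        cfg = _fuzz_config(rng)
        if cfg.shape != "contour":
            cfg = HotspotConfig("FUZZ", cfg.min_cells, cfg.fov, cfg.basis,
                                "contour")
        hm, _, _, _ = _heatmap_pair(cells, cfg, 1300.0)
        res = find_contour_hotspot(hm, cells, cfg)
        if res.status == "ok":
            n_ok += 1
            if res.n_cells < cfg.min_cells:
                violations += 1
    return {"n_slides": n_slides, "n_ok": n_ok, "violations": violations}


def icc_ordering(n_cohorts: int = 20, n_slides: int = 150,
                 seed: int = 0) -> pd.DataFrame:
    """Grouped reproducibility ICCs across replicate synthetic cohorts.

    Scores every slide of each cohort with the 17 grouped apps and
    computes the ICC of the ~200-cell, 400-800-cell and ~1000-cell app
    groups; returns one row per cohort with the three ICCs and whether
    they are ordered low <= mid <= high.
    """
    grouped_apps = tuple(a for members in ICC_GROUPS.values() for a in members)
    rows = []
    for c in range(n_cohorts):
        sim = SimulationParams(n_patients=n_slides,
                               seed=(int(seed) * 1000 + c) % 2**31)
        config = ExperimentConfig(sim=sim, app_ids=grouped_apps,
                                  make_figures=False)
        _, scores, _, _ = score_cohort(config)
        iccs = {}
        for name, members in ICC_GROUPS.items():
            iccs[name] = icc(scores[list(members)]).estimate
        ordered = (iccs["low_~200"] <= iccs["mid_400-800"] + 1e-12
                   <= iccs["high_~1000"] + 2e-12)
        rows.append({"cohort": c, **iccs, "ordered": bool(ordered),
                     "n_slides_complete": len(scores)})
    return pd.DataFrame(rows)


def hr_recovery(n_reps: int = 200, n_patients: int = 500,
                beta: float = math.log(4.0), censoring: float = 0.2,
                seed: int = 0) -> dict:
    """Cox hazard-ratio recovery on covariate-only synthetic cohorts.

    Fits the univariate Cox model of RFS on the true Ki67-high indicator
    in each replicate and summarises the estimate distribution, the 95%
    CI coverage of the true hazard ratio and the alpha=0.05 rejection
    rate.
    """
    true_hr = math.exp(beta)
    hrs, covered, rejected = [], 0, 0
    for rep in range(n_reps):
        sim = SimulationParams(n_patients=n_patients, log_hr_high_ki67=beta,
                               censoring_rate=censoring,
                               seed=(int(seed) * 100_000 + rep) % 2**31)
        patients, _ = generate_cohort(sim, with_slides=False)
        patients = patients.assign(high=patients["true_ki67_high"].astype(float))
        tab = cox(patients, "rfs_time", "rfs_event", ["high"])
        hrs.append(float(tab["hr"].iloc[0]))
        covered += int(tab["ci_low"].iloc[0] <= true_hr <= tab["ci_high"].iloc[0])
        rejected += int(tab["p"].iloc[0] < 0.05)
    return {
        "n_reps": n_reps,
        "true_hr": true_hr,
        "mean_hr": float(np.mean(hrs)),
        "ci_coverage": covered / n_reps,
        "rejection_rate": rejected / n_reps,
    }


def conservation_error(seed: int = 0, k: int = 5) -> float:
    """Max |global - cell-weighted mean of partition sub-indices| over a slide.

    Splits the invasive tumor cells into ``k`` disjoint spatial strips;
    the identity must hold to machine precision.
    """
    sim = SimulationParams(n_patients=2, seed=seed)
    cells, rois, _ = generate_slide(sim, "S_conserve")
    classified = classify_cells(cells, "oracle")
    total = global_ki67(classified, rois)
    inv = {r.roi_id for r in rois if r.roi_class == "invasive"}
    sel = (classified["predicted_class"] == "tumor") & classified["roi_id"].isin(inv)
    sub = classified[sel]
    edges = np.quantile(sub["x_um"], np.linspace(0, 1, k + 1))
    edges[-1] += 1.0
    worst = 0.0
    acc_n, acc_w = 0, 0.0
    for i in range(k):
        part = sub[(sub["x_um"] >= edges[i]) & (sub["x_um"] < edges[i + 1])]
        n = len(part)
        idx = 100.0 * (part["predicted_ki67_status"] == "positive").mean() if n else 0.0
        acc_n += n
        acc_w += n * idx
    weighted = acc_w / acc_n
    return abs(weighted - total.global_ki67)
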