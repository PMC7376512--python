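"""End-to-end in-silico replication of the scoring-comparison study.

One call generates a synthetic cohort, scores every slide with every
configured hot-spot app and with the global method, applies the
exclusion and quality-control rules, and runs the comparison statistics
(grouped ICC, Bland-Altman, McNemar/kappa, surrogate subtyping vs
intrinsic labels, Kaplan-Meier/log-rank, uni- and multivariate Cox for
RFS and OS), writing a reproducible report bundle.
"""

from __future__ import annotations

import dataclasses
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .detect import run_apps
from .globalscore import GlobalScorer
from .qc import qc_realized_counts
from .registry import ICC_GROUPS, app_registry, get_app, post_qc_apps
from .stats import (
    bland_altman,
    concordance,
    cox,
    dichotomize,
    icc,
    km_logrank,
    mcnemar_test,
    plot_bland_altman,
    surrogate_subtype,
)
from .synthetic import SimulationParams, generate_cohort


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class ExperimentConfig:
    """Configuration of a full replication run."""

    sim: SimulationParams = field(default_factory=SimulationParams)
    app_ids: tuple[str, ...] = tuple(c.app_id for c in post_qc_apps())
    icc_groups: dict = field(default_factory=lambda: dict(ICC_GROUPS))
    hotspot_reference_app: str = "APP24"
    ki67_cutoff: float = 20.0
    make_figures: bool = True
    bin_size: Optional[float] = None

    def __post_init__(self) -> None:
        known = {c.app_id for c in app_registry()}
        bad = [a for a in self.app_ids if a not in known]
        if bad:
            raise ValueError(f"unknown app ids {bad}")
        for name, members in self.icc_groups.items():
            bad = [a for a in members if a not in self.app_ids]
            if bad:
                raise ValueError(f"ICC group {name!r} references apps {bad} "
                                 "outside the configured app list")


def exclusion_log(slide_status: pd.DataFrame) -> pd.DataFrame:
    """Per-slide exclusion reasons from the scoring status table.

    ``slide_status`` has one row per (slide_id, app_id) with a ``status``
    column, plus per-slide rows with app_id='__slide__' carrying slide-
    level conditions.  A slide enters the score matrix only if every
    configured app succeeded on it.
    """
    rows = []
    for slide_id, grp in slide_status.groupby("slide_id", sort=True):
        slide_rows = grp[grp["app_id"] == "__slide__"]
        if (slide_rows["status"] == "no_invasive_tumor").any():
            rows.append({"slide_id": slide_id, "reason": "no_invasive_tumor",
                         "detail": ""})
            continue
        failed = grp[(grp["app_id"] != "__slide__")
                     & (grp["status"] != "ok")]["app_id"].tolist()
        if failed:
            rows.append({"slide_id": slide_id, "reason": "no_valid_hotspot",
                         "detail": ",".join(sorted(failed))})
    return pd.DataFrame(rows, columns=["slide_id", "reason", "detail"])


def score_cohort(config: ExperimentConfig, with_progress: bool = False):
    """Generate and score a cohort; returns (patients, scores, status, qc).

    ``scores`` is the wide per-slide matrix (columns = app ids +
    ``global``) containing only slides where every configured app and
    the global scorer succeeded.
    """
    patients, slides = generate_cohort(config.sim, with_slides=True)
    apps = [get_app(a) for a in config.app_ids]
    status_rows, score_rows = [], []
    for slide_id, (cells, rois, truth) in slides.items():
        has_invasive = any(r.roi_class == "invasive" for r in rois)
        n_inv = int(((cells["cell_class"] == "tumor")
                     & cells["roi_id"].isin(
                         [r.roi_id for r in rois if r.roi_class == "invasive"])).sum())
        if not has_invasive or n_inv == 0:
            status_rows.append({"slide_id": slide_id, "app_id": "__slide__",
                                "status": "no_invasive_tumor", "n_cells": 0})
            continue
        results = run_apps(apps, cells, rois, bin_size=config.bin_size)
        gs = GlobalScorer().fit(cells, rois)
        row = {"slide_id": slide_id}
        for app_id, res in results.items():
            status_rows.append({"slide_id": slide_id, "app_id": app_id,
                                "status": res.status, "n_cells": res.n_cells})
            row[app_id] = res.ki67_index if res.status == "ok" else np.nan
        status_rows.append({"slide_id": slide_id, "app_id": "global",
                            "status": gs.status_, "n_cells": gs.n_tumor_cells_})
        row["global"] = gs.global_ki67_ if gs.status_ == "ok" else np.nan
        score_rows.append(row)
    status = pd.DataFrame(status_rows)
    scores = pd.DataFrame(score_rows).set_index("slide_id") if score_rows \
        else pd.DataFrame()
    # strict completeness rule: drop slides failing any configured method
    if len(scores):
        scores = scores.dropna()
    qc_report = qc_realized_counts(
        status[~status["app_id"].isin(["__slide__", "global"])])
    return patients, scores, status, qc_report


def _subtype_block(patients: pd.DataFrame, scores: pd.DataFrame,
                   method: str, cutoff: float) -> dict:
    merged = patients.set_index("slide_id").join(scores[[method]], how="inner")
    k_class = dichotomize(merged[method], cutoff)
    calls = surrogate_subtype(merged["er_percent"], merged["pr_percent"],
                              merged["her2"], k_class)
    keep = merged["intrinsic_subtype"].isin(["lumA", "lumB"])
    rate, kappa, n, table = concordance(calls[keep],
                                        merged.loc[keep, "intrinsic_subtype"])
    return {"method": method, "concordance_rate": rate, "kappa": kappa, "n": n,
            "table": table}


def replicate_study(config: ExperimentConfig, out_dir) -> dict:
    """Run the full comparison experiment and write the report bundle.

    Returns a dict of result tables; writes CSV/JSON (and PNG figures
    when configured) under ``out_dir``.  Rerunning with the same config
    and seed is bit-identical.  Any stage failure removes partial
    outputs and raises :class:`PipelineError` naming the stage.
    """
    out = Path(out_dir)
    created = not out.exists()
    results: dict = {}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except PipelineError:
                raise
            except Exception as exc:
                if created and out.exists():
                    shutil.rmtree(out)
                raise PipelineError(name, exc)
        return wrap

    patients, scores, status, qc_report = stage("score_cohort")(
        lambda: score_cohort(config))
    excl = stage("exclusion_log")(lambda: exclusion_log(status))
    results["exclusions"] = excl
    results["qc"] = qc_report
    results["score_matrix"] = scores
    results["registry"] = pd.DataFrame(
        [dataclasses.asdict(c) for c in app_registry()])

    def _icc_groups():
        rows = []
        for name, members in config.icc_groups.items():
            cols = [m for m in members if m in scores.columns]
            r = icc(scores[cols])
            rows.append({"group": name, "apps": ",".join(cols),
                         "icc": r.estimate, "ci_low": r.ci95[0],
                         "ci_high": r.ci95[1], "n_slides": r.n_subjects})
        return pd.DataFrame(rows)

    results["table_icc_groups"] = stage("icc")(_icc_groups)

    ref = config.hotspot_reference_app

    def _agreement():
        ba = bland_altman(scores[ref], scores["global"])
        hs_cls = dichotomize(scores[ref], config.ki67_cutoff)
        gl_cls = dichotomize(scores["global"], config.ki67_cutoff)
        p_mcnemar, table = mcnemar_test(hs_cls, gl_cls)
        from sklearn.metrics import cohen_kappa_score
        both = pd.DataFrame({"a": hs_cls, "b": gl_cls}).dropna()
        if both["a"].nunique() > 1 or both["b"].nunique() > 1:
            kappa = float(cohen_kappa_score(both["a"], both["b"],
                                            labels=["low", "high"]))
        else:
            kappa = float("nan")  # degenerate: a single class on both sides
        return pd.DataFrame([{
            "comparison": f"{ref}_vs_global", "n": ba.n, "bias": ba.bias,
            "loa_low": ba.loa_low, "loa_high": ba.loa_high, "bias_p": ba.bias_p,
            "slope": ba.slope, "slope_p": ba.slope_p,
            "intercept_p": ba.intercept_p,
            "mcnemar_p": p_mcnemar, "kappa_high_low": kappa,
        }])

    results["table_agreement"] = stage("agreement")(_agreement)

    merged = patients.set_index("slide_id").join(scores, how="inner")

    def _survival():
        uni_rows, km_rows, multi_rows = [], [], []
        for method in (ref, "global"):
            merged[f"{method}_high"] = (
                dichotomize(merged[method], config.ki67_cutoff) == "high"
            ).astype(float)
        merged["pN1"] = (merged["pN"] >= 1).astype(float)
        for g in (2, 3):
            merged[f"grade_{g}"] = (merged["grade"] == g).astype(float)
            merged[f"mitotic_{g}"] = (merged["mitotic_score"] == g).astype(float)
        for endpoint, tcol, ecol in (("rfs", "rfs_time", "rfs_event"),
                                     ("os", "os_time", "os_event")):
            for method in (ref, "global"):
                cls = dichotomize(merged[method], config.ki67_cutoff)
                if cls.nunique() >= 2:
                    _, p = km_logrank(merged[tcol], merged[ecol], cls)
                else:
                    p = float("nan")  # all slides in one Ki67 class
                km_rows.append({"endpoint": endpoint, "method": method,
                                "logrank_p": p})
                uni = cox(merged, tcol, ecol, [f"{method}_high"])
                uni["endpoint"] = endpoint
                uni["method"] = method
                uni_rows.append(uni)
                adj_covs = ["pN1", f"{method}_high"] if endpoint == "rfs" else \
                    ["grade_2", "grade_3", "mitotic_2", "mitotic_3", "pN1",
                     f"{method}_high"]
                adj = cox(merged, tcol, ecol, adj_covs, adjusted=True)
                adj["endpoint"] = endpoint
                adj["method"] = method
                multi_rows.append(adj)
        return (pd.concat(uni_rows, ignore_index=True),
                pd.concat(multi_rows, ignore_index=True),
                pd.DataFrame(km_rows))

    uni, multi, km_tab = stage("survival")(_survival)
    results["table_hr_univariate"] = uni
    results["table_hr_multivariate"] = multi
    results["table_logrank"] = km_tab

    def _subtypes():
        rows = []
        tables = {}
        for method in (ref, "global"):
            blk = _subtype_block(patients, scores, method, config.ki67_cutoff)
            tables[method] = blk.pop("table")
            rows.append(blk)
        results["_subtype_tables"] = tables
        return pd.DataFrame(rows)

    results["table_subtype_concordance"] = stage("subtype")(_subtypes)

    def _write():
        out.mkdir(parents=True, exist_ok=True)
        results["registry"].to_csv(out / "table1_registry.csv", index=False)
        results["table_icc_groups"].to_csv(out / "table_icc_groups.csv", index=False)
        results["table_agreement"].to_csv(out / "table_agreement.csv", index=False)
        uni.to_csv(out / "table_hr_univariate.csv", index=False)
        multi.to_csv(out / "table_hr_multivariate.csv", index=False)
        km_tab.to_csv(out / "table_logrank.csv", index=False)
        results["table_subtype_concordance"].to_csv(
            out / "table_subtype_concordance.csv", index=False)
        excl.to_csv(out / "exclusions.csv", index=False)
        qc_report.to_csv(out / "qc_realized_counts.csv")
        scores.to_csv(out / "score_matrix.csv", float_format="%.6f")
        summary = {
            "version": __version__,
            "seed": config.sim.seed,
            "n_patients": config.sim.n_patients,
            "n_slides_scored": int(len(scores)),
            "n_excluded": int(len(excl)),
            "apps": list(config.app_ids),
            "qc_flagged": sorted(qc_report.index[qc_report["flagged"]]),
        }
        (out / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n")
        if config.make_figures:
            _figures(out, merged, scores, ref, config)
        return None

    stage("write_report")(_write)
    return results


def _figures(out: Path, merged: pd.DataFrame, scores: pd.DataFrame,
             ref: str, config: ExperimentConfig) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from lifelines import KaplanMeierFitter

    plot_bland_altman(scores[ref], scores["global"],
                      out / "bland_altman.png", labels=(ref, "global"))
    fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharey=True)
    for j, method in enumerate((ref, "global")):
        cls = dichotomize(merged[method], config.ki67_cutoff)
        for i, (tcol, ecol, name) in enumerate(
                (("rfs_time", "rfs_event", "RFS"), ("os_time", "os_event", "OS"))):
            ax = axes[i, j]
            for grp in ("low", "high"):
                sel = cls == grp
                if sel.sum() == 0:
                    continue
                KaplanMeierFitter().fit(merged.loc[sel, tcol],
                                        merged.loc[sel, ecol],
                                        label=f"Ki67 {grp}").plot_survival_function(ax=ax)
            ax.set_title(f"{name}, {method}")
            ax.set_xlabel("years")
    fig.tight_layout()
    fig.savefig(out / "km_curves.png", dpi=120)
    plt.close(fig)
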