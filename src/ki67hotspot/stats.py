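"""Cohort-level statistics: agreement, subtyping and survival.

Conventions follow routine clinical-biostatistics practice: ICC is the
two-way random-effects, absolute-agreement, single-measurement ICC(2,1)
on log-transformed scores (ln(Ki67% + 1), so zero scores are admitted);
survival uses Kaplan-Meier / log-rank and Cox proportional hazards with
Efron tie handling; all tests are two-sided at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import pingouin as pg
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from sklearn.metrics import cohen_kappa_score
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

KI67_CUTOFF = 20.0


# ---------------------------------------------------------------- agreement

@dataclass(frozen=True)
class ICCResult:
    estimate: float
    ci95: tuple[float, float]
    n_subjects: int
    n_raters: int


def icc(matrix: pd.DataFrame, log_transform: bool = True) -> ICCResult:
    """ICC(2,1) across scoring methods (columns) on complete rows.

    ``matrix`` holds one row per slide and one column per scoring
    method, values in Ki67 percent.  Rows with any missing score are
    dropped (complete-case).  With ``log_transform`` the ICC is computed
    on ln(score + 1).
    """
    complete = matrix.dropna()
    if complete.shape[0] < 2 or complete.shape[1] < 2:
        raise ValueError("need >= 2 complete rows and >= 2 methods for ICC")
    vals = np.log(complete.astype(float) + 1.0) if log_transform else complete
    long = (vals.reset_index(names="_subject")
            .melt(id_vars="_subject", var_name="_rater", value_name="_score"))
    table = pg.intraclass_corr(long, targets="_subject", raters="_rater",
                               ratings="_score")
    # absolute-agreement single-measurement row; label differs across
    # pingouin versions ("ICC2" vs "ICC(A,1)")
    sel = table["Type"].isin(["ICC2", "ICC(A,1)"])
    row = table.loc[sel].iloc[0]
    ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
    lo, hi = (float(v) for v in row[ci_col])
    return ICCResult(float(row["ICC"]), (lo, hi),
                     complete.shape[0], complete.shape[1])


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    bias_p: float
    slope: float
    slope_p: float
    intercept: float
    intercept_p: float
    n: int
    degenerate: bool


def bland_altman(a, b) -> BlandAltmanResult:
    """Bland-Altman agreement of two paired score vectors (a - b).

    Reports the mean difference (bias, with one-sample t-test against
    zero), the 95% limits of agreement, and a proportional-bias
    regression of the differences on the pair means.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if len(a) < 3:
        raise ValueError("need >= 3 complete pairs")
    diff = a - b
    mean = (a + b) / 2.0
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    from scipy import stats as sps
    if sd == 0:
        bias_p = 1.0 if bias == 0 else 0.0
    else:
        bias_p = float(sps.ttest_1samp(diff, 0.0).pvalue)
    degenerate = bool(np.ptp(mean) == 0)
    if degenerate:
        slope = slope_p = intercept = intercept_p = float("nan")
    else:
        fit = sm.OLS(diff, sm.add_constant(mean)).fit()
        intercept, slope = (float(v) for v in fit.params)
        intercept_p, slope_p = (float(v) for v in fit.pvalues)
    return BlandAltmanResult(bias, bias - 1.96 * sd, bias + 1.96 * sd, bias_p,
                             slope, slope_p, intercept, intercept_p,
                             int(len(a)), degenerate)


def plot_bland_altman(a, b, path, labels=("method A", "method B")) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    res = bland_altman(a, b)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    keep = ~(np.isnan(a) | np.isnan(b))
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((a[keep] + b[keep]) / 2, a[keep] - b[keep], s=12, alpha=0.6)
    for y, style in ((res.bias, "-"), (res.loa_low, "--"), (res.loa_high, "--")):
        ax.axhline(y, color="crimson", linestyle=style, linewidth=1)
    ax.set_xlabel(f"mean of {labels[0]} and {labels[1]} (Ki67 %)")
    ax.set_ylabel(f"{labels[0]} − {labels[1]} (Ki67 %)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ------------------------------------------------------------- dichotomies

def dichotomize(scores, cutoff: float = KI67_CUTOFF) -> pd.Series:
    """Map Ki67 percent to 'high' (>= cutoff) / 'low'; missing stays missing."""
    s = pd.Series(scores, dtype=float)
    out = pd.Series(np.where(s >= cutoff, "high", "low"), index=s.index,
                    dtype=object)
    out[s.isna()] = np.nan
    return out


def surrogate_subtype(er_percent, pr_percent, her2, ki67_class) -> pd.Series:
    """St Gallen 2013 surrogate subtype for ER+/HER2− tumors.

    Luminal A-like requires PR >= 20% and low Ki67; otherwise luminal
    B-like.  ER− or HER2+ tumors (and missing Ki67) are not applicable.
    """
    er = pd.Series(er_percent, dtype=float)
    pr = pd.Series(pr_percent, dtype=float).set_axis(er.index)
    her2 = pd.Series(her2, dtype=object).set_axis(er.index)
    k = pd.Series(ki67_class, dtype=object).set_axis(er.index)
    eligible = (er >= 1.0) & (her2 == "neg") & k.isin(["low", "high"])
    lum_a = (pr >= 20.0) & (k == "low")
    out = pd.Series(np.where(lum_a, "lumA_like", "lumB_like"), index=er.index,
                    dtype=object)
    out[~eligible] = "not_applicable"
    return out


def concordance(surrogate: Sequence[str], intrinsic: Sequence[str]
                ) -> tuple[float, float, int, pd.DataFrame]:
    """Concordance rate (%) and Cohen's kappa of surrogate vs intrinsic calls.

    Surrogate ``lumA_like``/``lumB_like`` are matched against intrinsic
    ``lumA``/``lumB``; pairs with anything else are dropped (complete
    case).  Returns (rate, kappa, n, 2x2 confusion table).
    """
    s = pd.Series(surrogate, dtype=object).map(
        {"lumA_like": "lumA", "lumB_like": "lumB"})
    t = pd.Series(intrinsic, dtype=object)
    keep = s.isin(["lumA", "lumB"]) & t.isin(["lumA", "lumB"])
    s, t = s[keep], t[keep]
    if len(s) == 0:
        raise ValueError("no comparable pairs")
    rate = 100.0 * float((s.to_numpy() == t.to_numpy()).mean())
    kappa = float(cohen_kappa_score(s, t, labels=["lumA", "lumB"])) \
        if s.nunique() > 1 or t.nunique() > 1 else 1.0
    table = pd.crosstab(s, t).reindex(index=["lumA", "lumB"],
                                      columns=["lumA", "lumB"], fill_value=0)
    return rate, kappa, int(len(s)), table


def mcnemar_test(a, b, exact: bool = True) -> tuple[float, pd.DataFrame]:
    """McNemar test for paired dichotomies (exact binomial by default).

    Returns (p-value, 2x2 table with rows = a, columns = b).
    """
    a = pd.Series(a, dtype=object)
    b = pd.Series(b, dtype=object).set_axis(a.index)
    keep = a.notna() & b.notna()
    a, b = a[keep], b[keep]
    cats = sorted(set(a) | set(b))
    if len(cats) > 2:
        raise ValueError("McNemar requires binary categories")
    if len(cats) < 2:
        cats = cats + ["_other"]
    table = pd.crosstab(a, b).reindex(index=cats, columns=cats, fill_value=0)
    res = _sm_mcnemar(table.to_numpy(), exact=exact, correction=True)
    return float(res.pvalue), table


# ---------------------------------------------------------------- survival

def km_logrank(times, events, groups) -> tuple[dict[str, pd.DataFrame], float]:
    """Kaplan-Meier curves per group plus the log-rank p-value.

    Returns a dict group -> DataFrame(timeline, survival) and the
    two-sided log-rank p across groups.
    """
    df = pd.DataFrame({"time": np.asarray(times, dtype=float),
                       "event": np.asarray(events, dtype=bool),
                       "group": np.asarray(groups, dtype=object)})
    df = df.dropna()
    if df["group"].nunique() < 2:
        raise ValueError("need >= 2 groups")
    curves = {}
    for g, sub in df.groupby("group", sort=True):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], label=str(g))
        curves[str(g)] = pd.DataFrame({
            "timeline": kmf.survival_function_.index.to_numpy(),
            "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
        })
    p = float(multivariate_logrank_test(df["time"], df["group"],
                                        df["event"]).p_value)
    return curves, p


def cox(df: pd.DataFrame, duration_col: str, event_col: str,
        covariates: Sequence[str], adjusted: bool = False) -> pd.DataFrame:
    """Cox proportional-hazards HRs with 95% CIs and p-values.

    With ``adjusted`` one model containing all covariates is fitted;
    otherwise each covariate gets its own univariate model.  Covariate
    columns must already be numeric (0/1 indicators for categories).
    Non-convergence (e.g. a stratum with no events giving a monotone
    partial likelihood) is reported per covariate in the ``note`` column
    rather than raised.
    """
    data = df[[duration_col, event_col, *covariates]].dropna().astype(float)
    n_events = int(data[event_col].sum())
    if n_events < len(covariates):
        raise ValueError("need at least as many events as covariates")
    groups = [list(covariates)] if adjusted else [[c] for c in covariates]
    rows = []
    import warnings as _warnings
    for covs in groups:
        try:
            cph = CoxPHFitter()
            with _warnings.catch_warnings():
                # degenerate strata (no events / separation) are reported
                # in the note column instead
                _warnings.simplefilter("ignore")
                cph.fit(data[[duration_col, event_col, *covs]],
                        duration_col=duration_col, event_col=event_col)
            summ = cph.summary
            for c in covs:
                rows.append({
                    "covariate": c,
                    "model": "adjusted" if adjusted else "univariate",
                    "hr": float(summ.loc[c, "exp(coef)"]),
                    "ci_low": float(summ.loc[c, "exp(coef) lower 95%"]),
                    "ci_high": float(summ.loc[c, "exp(coef) upper 95%"]),
                    "p": float(summ.loc[c, "p"]),
                    "n": int(len(data)),
                    "n_events": n_events,
                    "note": "",
                })
        except Exception as exc:  # lifelines ConvergenceError and kin
            for c in covs:
                rows.append({"covariate": c,
                             "model": "adjusted" if adjusted else "univariate",
                             "hr": float("nan"), "ci_low": float("nan"),
                             "ci_high": float("nan"), "p": float("nan"),
                             "n": int(len(data)), "n_events": n_events,
                             "note": f"fit failed: {type(exc).__name__}"})
    return pd.DataFrame(rows)
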