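"""Agreement, subtyping and survival statistics against closed forms."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ki67hotspot.stats import (
    bland_altman,
    concordance,
    cox,
    dichotomize,
    icc,
    km_logrank,
    mcnemar_test,
    surrogate_subtype,
)


class TestICC:
    def test_identical_columns_give_icc_one(self, rng):
        col = rng.uniform(1, 60, 30)
        m = pd.DataFrame({"a": col, "b": col, "c": col})
        res = icc(m)
        assert res.estimate == pytest.approx(1.0, abs=1e-9)

    def test_variance_component_recovery(self):
        """y_ij = subject + noise: ICC must estimate var_s/(var_s+var_e)."""
        rng = np.random.default_rng(2)
        truth = 1.0 / (1.0 + 0.5**2)  # sigma_s=1, sigma_e=0.5
        estimates = []
        for _ in range(60):
            s = rng.normal(0, 1.0, 80)
            y = s[:, None] + rng.normal(0, 0.5, (80, 4))
            m = pd.DataFrame(y, columns=list("abcd"))
            estimates.append(icc(m, log_transform=False).estimate)
        assert np.mean(estimates) == pytest.approx(truth, abs=0.02)

    def test_additive_shift_invariance(self, rng):
        y = rng.normal(10, 2, (25, 3))
        a = icc(pd.DataFrame(y), log_transform=False)
        b = icc(pd.DataFrame(y + 7.5), log_transform=False)
        assert a.estimate == pytest.approx(b.estimate, abs=1e-10)

    def test_two_column_equal_variance_limit_is_pearson(self):
        rng = np.random.default_rng(4)
        s = rng.normal(0, 1, 3000)
        y1 = s + rng.normal(0, 0.6, 3000)
        y2 = s + rng.normal(0, 0.6, 3000)
        m = pd.DataFrame({"a": y1, "b": y2})
        r = sps.pearsonr(y1, y2).statistic
        assert icc(m, log_transform=False).estimate == pytest.approx(r, abs=0.01)

    def test_complete_case_and_minimum_size(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 4.0, np.nan],
                          "b": [1.0, 2.5, 3.0, 8.0]})
        res = icc(m)
        assert res.n_subjects == 3  # the incomplete row is dropped
        with pytest.raises(ValueError):
            icc(m.iloc[:1])


class TestBlandAltman:
    def test_identical_scores_have_zero_bias_and_slope(self, rng):
        a = rng.uniform(5, 50, 30)
        res = bland_altman(a, a.copy())
        assert res.bias == 0.0
        assert res.slope == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset_recovered(self, rng):
        a = rng.uniform(5, 50, 40)
        res = bland_altman(a + 5.0, a)
        assert res.bias == pytest.approx(5.0)
        assert res.slope == pytest.approx(0.0, abs=1e-9)
        assert res.bias_p < 1e-6
        assert res.loa_low == pytest.approx(5.0, abs=1e-6)

    def test_proportional_bias_detected_at_study_size(self):
        rng = np.random.default_rng(6)
        a = rng.uniform(2, 60, 139)
        b = 1.2 * a + rng.normal(0, 1.0, 139)
        res = bland_altman(b, a)
        assert res.slope > 0
        assert res.slope_p < 1e-4

    def test_degenerate_constant_pairs_flagged(self):
        res = bland_altman([5.0] * 6, [5.0] * 6)
        assert res.degenerate
        assert math.isnan(res.slope)

    def test_requires_three_pairs(self):
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0], [1.0, 2.0])


def test_dichotomize_cutoff_is_closed_above():
    out = dichotomize([19.9, 20.0, 20.1, np.nan])
    assert list(out[:3]) == ["low", "high", "high"]
    assert pd.isna(out.iloc[3])


class TestSurrogateSubtype:
    def test_st_gallen_rules(self):
        er = [50, 50, 50, 0, 50]
        pr = [30, 30, 10, 30, 30]
        her2 = ["neg", "neg", "neg", "neg", "pos"]
        ki67 = ["low", "high", "low", "low", "low"]
        out = surrogate_subtype(er, pr, her2, ki67)
        assert list(out) == ["lumA_like", "lumB_like", "lumB_like",
                             "not_applicable", "not_applicable"]

    def test_missing_ki67_not_applicable(self):
        out = surrogate_subtype([50], [30], ["neg"], [np.nan])
        assert list(out) == ["not_applicable"]


class TestConcordance:
    def test_perfect_agreement(self):
        s = ["lumA_like", "lumB_like"] * 10
        t = ["lumA", "lumB"] * 10
        rate, kappa, n, _ = concordance(s, t)
        assert rate == 100.0 and kappa == 1.0 and n == 20

    def test_fixed_table_matches_hand_computed_kappa(self):
        # 2x2 table (40, 20; 15, 25): po=0.65, pe=0.51, kappa=0.14/0.49=2/7
        s = (["lumA_like"] * 60) + (["lumB_like"] * 40)
        t = (["lumA"] * 40 + ["lumB"] * 20) + (["lumA"] * 15 + ["lumB"] * 25)
        rate, kappa, n, table = concordance(s, t)
        assert n == 100
        assert rate == pytest.approx(65.0)
        assert kappa == pytest.approx(2.0 / 7.0, abs=1e-12)
        assert table.loc["lumA", "lumA"] == 40
        assert table.loc["lumB", "lumA"] == 15

    def test_independent_labels_give_near_zero_kappa(self):
        rng = np.random.default_rng(0)
        s = np.where(rng.uniform(size=20000) < 0.5, "lumA_like", "lumB_like")
        t = np.where(rng.uniform(size=20000) < 0.5, "lumA", "lumB")
        _, kappa, _, _ = concordance(s, t)
        assert abs(kappa) < 0.02

    def test_non_luminal_pairs_dropped(self):
        s = ["lumA_like", "not_applicable", "lumB_like"]
        t = ["lumA", "lumA", "none"]
        rate, _, n, _ = concordance(s, t)
        assert n == 1 and rate == 100.0


class TestMcNemar:
    def test_all_concordant_gives_p_one(self):
        p, _ = mcnemar_test(["high", "low"] * 10, ["high", "low"] * 10)
        assert p == 1.0

    def test_one_sided_discordance_closed_form(self):
        # 10 discordant pairs all in one direction: p = 2 * (1/2)^10
        a = ["high"] * 10 + ["low"] * 5
        b = ["low"] * 10 + ["low"] * 5
        p, table = mcnemar_test(a, b)
        assert p == pytest.approx(2 * 0.5**10)
        assert table.loc["high", "low"] == 10

    def test_symmetric_discordance_gives_p_one(self):
        a = ["high"] * 7 + ["low"] * 7
        b = ["low"] * 7 + ["high"] * 7
        p, _ = mcnemar_test(a, b)
        assert p == pytest.approx(1.0)


class TestSurvival:
    def test_product_limit_matches_hand_computation(self):
        # two groups of 3 subjects, no censoring; S drops by 1/3 per event
        times = [1, 3, 5, 2, 4, 6]
        events = [True] * 6
        groups = ["a"] * 3 + ["b"] * 3
        curves, p = km_logrank(times, events, groups)
        for g in ("a", "b"):
            surv = curves[g]["survival"].to_numpy()
            assert np.allclose(surv, [1.0, 2 / 3, 1 / 3, 0.0])
        assert 0.0 <= p <= 1.0

    def test_all_censored_curves_stay_flat(self):
        curves, _ = km_logrank([5, 6, 7, 8], [False] * 4, ["a", "a", "b", "b"])
        for g in ("a", "b"):
            assert (curves[g]["survival"] == 1.0).all()

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            km_logrank([1, 2], [True, True], ["a", "a"])

    def test_cox_two_group_exponential_recovery(self):
        rng = np.random.default_rng(9)
        n = 4000
        high = rng.uniform(size=n) < 0.5
        lam = np.where(high, 0.2, 0.05)
        df = pd.DataFrame({
            "time": rng.exponential(1 / lam),
            "event": True,
            "high": high.astype(float),
        })
        tab = cox(df, "time", "event", ["high"])
        assert tab["hr"].iloc[0] == pytest.approx(4.0, rel=0.1)
        assert tab["ci_low"].iloc[0] < 4.0 < tab["ci_high"].iloc[0]

    def test_adjusted_model_reports_all_covariates_jointly(self):
        rng = np.random.default_rng(10)
        n = 300
        df = pd.DataFrame({
            "time": rng.exponential(10, n),
            "event": rng.uniform(size=n) < 0.7,
            "ki67_high": (rng.uniform(size=n) < 0.5).astype(float),
            "pN1": (rng.uniform(size=n) < 0.4).astype(float),
        })
        tab = cox(df, "time", "event", ["pN1", "ki67_high"], adjusted=True)
        assert list(tab["covariate"]) == ["pN1", "ki67_high"]
        assert (tab["model"] == "adjusted").all()

    def test_more_covariates_than_events_rejected(self):
        df = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": [True, False, False],
                           "a": [0.0, 1.0, 0.0], "b": [1.0, 0.0, 0.0]})
        with pytest.raises(ValueError):
            cox(df, "time", "event", ["a", "b"], adjusted=True)

    def test_monotone_likelihood_reported_not_raised(self):
        # every event in one stratum: separation must yield a note row
        df = pd.DataFrame({
            "time": [1, 2, 3, 4, 5, 6, 7, 8.0],
            "event": [True, True, True, True, False, False, False, False],
            "grp": [1.0, 1.0, 1.0, 1.0, 0.0, 0.0, 0.0, 0.0],
        })
        tab = cox(df, "time", "event", ["grp"])
        assert len(tab) == 1  # reported either way, never raised
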