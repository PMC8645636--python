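"""Kaplan-Meier, (weighted) log-rank, hazard ratio and best-cutoff scan."""

import math

import numpy as np
import pandas as pd
import pytest

from hccnet.survival import (SurvivalCohort, best_cutoff_scan, gbw_test,
                             hazard_ratio, km_estimate, logrank,
                             permutation_corrected_p)
from hccnet.synthetic import CohortGenConfig, generate_survival_cohort


def _naive_weighted_logrank(ta, ea, tb, eb, gbw=False):
    """Independent textbook O/E/V tabulation, deliberately loop-based."""
    ta, ea = np.asarray(ta, float), np.asarray(ea, int)
    tb, eb = np.asarray(tb, float), np.asarray(eb, int)
    times = sorted(set(list(ta[ea == 1]) + list(tb[eb == 1])))
    u = v = 0.0
    for t in times:
        n1 = float((ta >= t).sum())
        n2 = float((tb >= t).sum())
        d1 = float(((ta == t) & (ea == 1)).sum())
        d2 = float(((tb == t) & (eb == 1)).sum())
        n, d = n1 + n2, d1 + d2
        w = n if gbw else 1.0
        u += w * (d1 - d * n1 / n)
        if n > 1:
            v += w * w * d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return (u * u / v) if v > 0 else 0.0


class TestKM:
    def test_two_events(self):
        c = km_estimate([1.0, 2.0], [1, 1])
        assert c.survival == pytest.approx([0.5, 0.0])
        assert c.median == 1.0

    def test_event_then_censor(self):
        c = km_estimate([1.0, 2.0], [1, 0])
        assert c.survival == pytest.approx([0.5])
        assert c.median == 1.0  # S(1) = 0.5 <= 0.5

    def test_hand_worked_six_records(self):
        # events at 1, 3, 5; censored at 2, 4, 6
        c = km_estimate([1, 2, 3, 4, 5, 6], [1, 0, 1, 0, 1, 0])
        assert list(c.times) == [1, 3, 5]
        assert c.survival == pytest.approx([5 / 6, 5 / 6 * 3 / 4, 5 / 6 * 3 / 4 * 1 / 2])
        assert c.median == 5.0

    def test_censored_at_event_time_stays_at_risk(self):
        c = km_estimate([1.0, 1.0], [1, 0])
        assert c.at_risk[0] == 2
        assert c.survival == pytest.approx([0.5])

    def test_median_undefined_when_not_reached(self):
        c = km_estimate([1, 2, 3, 4], [1, 0, 0, 0])
        assert math.isnan(c.median)

    def test_no_censoring_equals_empirical_survivor(self):
        rng = np.random.default_rng(8)
        t = rng.exponential(10, size=60)
        c = km_estimate(t, np.ones(60, int))
        for tt in c.times:
            assert c.at(tt) == pytest.approx((t > tt).mean())

    def test_degenerate_all_zero_no_events(self):
        with pytest.raises(ValueError, match="degenerate"):
            km_estimate([0.0, 0.0], [0, 0])


def _two_arm(seed=1, n=100, hr=0.3, censor=0.2):
    cfg = CohortGenConfig(n_patients=2 * n, true_hr=hr, censor_rate=censor,
                          seed=seed)
    c = generate_survival_cohort(cfg)
    low, high = c.split(4.0)  # bimodal gap midpoint recovers planted arms
    return (low["time"].to_numpy(), low["event"].to_numpy(),
            high["time"].to_numpy(), high["event"].to_numpy())


class TestLogrank:
    def test_identical_groups_null(self):
        t = [1.0, 2.0, 3.0]
        e = [1, 1, 0]
        for fn in (logrank, gbw_test):
            r = fn(t, e, t, e)
            assert r.chi2 == pytest.approx(0.0)
            assert r.p == pytest.approx(1.0)

    def test_label_swap_symmetry(self):
        ta, ea, tb, eb = _two_arm(seed=2)
        r1 = logrank(ta, ea, tb, eb)
        r2 = logrank(tb, eb, ta, ea)
        assert r1.chi2 == pytest.approx(r2.chi2, abs=1e-12)
        assert r1.p == pytest.approx(r2.p, abs=1e-12)
        assert r1.hr == pytest.approx(1 / r2.hr, rel=1e-9)

    @pytest.mark.parametrize("gbw", [False, True])
    def test_matches_naive_tabulation(self, gbw):
        for seed in range(5):
            ta, ea, tb, eb = _two_arm(seed=seed)
            fn = gbw_test if gbw else logrank
            r = fn(ta, ea, tb, eb)
            assert r.chi2 == pytest.approx(
                _naive_weighted_logrank(ta, ea, tb, eb, gbw=gbw), abs=1e-9)

    @pytest.mark.parametrize("gbw", [False, True])
    def test_matches_lifelines(self, gbw):
        from lifelines.statistics import logrank_test
        ta, ea, tb, eb = _two_arm(seed=3)
        kwargs = {"weightings": "wilcoxon"} if gbw else {}
        ref = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb,
                           **kwargs)
        r = (gbw_test if gbw else logrank)(ta, ea, tb, eb)
        assert r.chi2 == pytest.approx(ref.test_statistic, rel=1e-6)
        assert r.p == pytest.approx(ref.p_value, rel=1e-6)

    def test_gbw_equals_logrank_single_event_time(self):
        # one shared event time -> the at-risk weight is a constant factor
        ta, ea = [5.0, 5.0, 5.0], [1, 1, 0]
        tb, eb = [5.0, 5.0], [1, 0]
        a = logrank(ta, ea, tb, eb)
        b = gbw_test(ta, ea, tb, eb)
        assert a.chi2 == pytest.approx(b.chi2, abs=1e-12)

    def test_time_rescaling_invariance(self):
        ta, ea, tb, eb = _two_arm(seed=4)
        r1 = logrank(ta, ea, tb, eb)
        r2 = logrank(ta * 12.0, ea, tb * 12.0, eb)
        assert r1.chi2 == pytest.approx(r2.chi2, abs=1e-9)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            logrank([], [], [1.0], [1])


class TestHazardRatio:
    def test_identical_groups_hr_one(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10, 50)
        e = np.ones(50, int)
        r = hazard_ratio(t, e, t, e)
        assert r.hr == pytest.approx(1.0, abs=1e-6)
        assert r.ci_low < 1.0 < r.ci_high

    def test_swap_reciprocity(self):
        ta, ea, tb, eb = _two_arm(seed=6)
        r1 = hazard_ratio(ta, ea, tb, eb)
        r2 = hazard_ratio(tb, eb, ta, ea)
        assert r1.hr == pytest.approx(1 / r2.hr, rel=1e-9)

    def test_ci_brackets_hr(self):
        ta, ea, tb, eb = _two_arm(seed=7)
        r = hazard_ratio(ta, ea, tb, eb)
        assert r.ci_low <= r.hr <= r.ci_high

    def test_matches_lifelines_cox_without_ties(self):
        # continuous times: Breslow and Efron tie rules coincide
        from lifelines import CoxPHFitter
        ta, ea, tb, eb = _two_arm(seed=8, n=80)
        df = pd.DataFrame({
            "t": np.concatenate([ta, tb]),
            "e": np.concatenate([ea, eb]),
            "z": np.concatenate([np.zeros(len(ta)), np.ones(len(tb))]),
        })
        assert df["t"].nunique() == len(df)  # genuinely tie-free
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        r = hazard_ratio(ta, ea, tb, eb)
        # my Newton iterates to 1e-12; lifelines stops a little earlier
        assert math.log(r.hr) == pytest.approx(cph.params_["z"], abs=1e-5)
        assert r.ci_low == pytest.approx(
            math.exp(cph.confidence_intervals_.iloc[0, 0]), rel=1e-4)

    def test_single_cohort_recovery(self):
        c = generate_survival_cohort(CohortGenConfig(seed=5))
        low, high = c.split(4.0)
        r = hazard_ratio(low["time"], low["event"], high["time"], high["event"])
        assert 0.3 < r.hr < 0.65
        assert r.ci_low <= 0.65

    def test_zero_event_group_flagged_not_crash(self):
        r = hazard_ratio([5.0, 6.0], [1, 1], [7.0, 8.0], [0, 0])
        assert r.degenerate
        assert r.hr == 0.0


class TestCutoffScan:
    def test_planted_gap_recovered(self):
        # hazard differs only across the expression gap [~3, ~7]
        c = generate_survival_cohort(
            CohortGenConfig(n_patients=300, true_hr=0.35, expression_gap=5.0,
                            censor_rate=0.2, seed=13))
        res = best_cutoff_scan(c)
        lo = c.data.loc[c.data["expression"] < 4, "expression"].max()
        hi = c.data.loc[c.data["expression"] >= 4, "expression"].min()
        assert lo < res.best_cutoff <= hi

    def test_candidates_within_quartiles(self):
        c = generate_survival_cohort(CohortGenConfig(seed=3))
        res = best_cutoff_scan(c)
        expr = c.data["expression"].to_numpy()
        q1, q3 = np.quantile(expr, [0.25, 0.75])
        assert np.all(res.candidate_cutoffs >= q1)
        assert np.all(res.candidate_cutoffs <= q3)
        assert res.best_p == np.nanmin(res.p_by_cutoff)

    def test_two_distinct_values(self):
        df = pd.DataFrame({
            "patient": [f"p{i}" for i in range(10)],
            "time": [1, 2, 3, 4, 5, 10, 11, 12, 13, 14],
            "event": [1] * 10,
            "expression": [1.0] * 5 + [2.0] * 5,
        })
        res = best_cutoff_scan(SurvivalCohort(df))
        # both quartile-bounded values enumerated; 1.0 leaves low empty -> skipped
        assert list(res.candidate_cutoffs) == [1.0, 2.0]
        assert res.best_cutoff == 2.0
        assert res.n_skipped == 1

    def test_constant_expression_errors(self):
        df = pd.DataFrame({"patient": list("abcdefgh"),
                           "time": range(1, 9), "event": [1] * 8,
                           "expression": [2.0] * 8})
        with pytest.raises(ValueError, match="constant"):
            best_cutoff_scan(SurvivalCohort(df))

    def test_too_few_patients(self):
        df = pd.DataFrame({"patient": list("abc"), "time": [1, 2, 3],
                           "event": [1, 1, 1], "expression": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="at least 8"):
            best_cutoff_scan(SurvivalCohort(df))

    def test_null_scan_is_anticonservative(self):
        """With no survival-expression association the scanned min-p rejects
        far above the nominal 5% rate: documented behavior of best-cutoff
        selection, not a bug."""
        ps = []
        for seed in range(40):
            c = generate_survival_cohort(
                CohortGenConfig(n_patients=364, true_hr=1.0, expression_gap=0.0,
                                censor_rate=0.3, seed=100 + seed))
            ps.append(best_cutoff_scan(c).best_p)
        ps = np.asarray(ps)
        assert (ps < 0.05).mean() >= 0.15  # >= 3x the nominal rate
        assert np.median(ps) < 0.2

    def test_permutation_correction_tames_null(self):
        c = generate_survival_cohort(
            CohortGenConfig(n_patients=120, true_hr=1.0, expression_gap=0.0,
                            seed=42))
        raw, corrected = permutation_corrected_p(c, n_perm=60, seed=1)
        assert corrected >= raw
        assert corrected > 0.05  # null cohort should not look significant
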