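"""Mean-split dichotomization, inclusion rules and the log-rank screen."""

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test as lifelines_logrank
from scipy import stats

import gliosplice as gs
from gliosplice.screen import (
    EXCLUDE_MISSING,
    EXCLUDE_SMALL,
    _logrank_many,
    group_size_threshold,
)


def manual_logrank(times, events, high):
    """Independent observed-minus-expected tabulation over death times."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    high = np.asarray(high, bool)
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & high).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & high).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = o_minus_e**2 / var
    return chi2, stats.chi2.sf(chi2, df=1)


class TestDichotomize:
    def test_forced_split(self):
        high = gs.dichotomize_by_mean([0.1, 0.2, 0.8, 0.9])
        assert high.tolist() == [False, False, True, True]

    def test_constant_row_all_high(self):
        # tie rule: PSI == mean goes to the high group
        assert gs.dichotomize_by_mean([0.5] * 4).all()

    def test_two_extremes(self):
        assert gs.dichotomize_by_mean([0.0, 1.0]).tolist() == [False, True]

    def test_missing_rejected(self):
        with pytest.raises(ValueError):
            gs.dichotomize_by_mean([0.1, np.nan])


class TestInclusionFilter:
    @pytest.mark.parametrize("n,expected", [(154, 8), (665, 34), (160, 8)])
    def test_threshold_is_ceil(self, n, expected):
        assert group_size_threshold(n) == expected

    def test_cohort_override(self):
        # a cohort-published threshold (e.g. 33 at n=665) can be pinned
        row = np.r_[np.full(33, 0.1), np.full(632, 0.9)]
        ok, _ = gs.inclusion_filter(row, n_total=665, min_per_group=33)
        assert ok
        ok2, why = gs.inclusion_filter(row, n_total=665)  # ceil rule: 34
        assert not ok2 and why == EXCLUDE_SMALL

    def test_missing_excludes(self):
        ok, why = gs.inclusion_filter([0.1, np.nan, 0.9], n_total=3)
        assert not ok and why == EXCLUDE_MISSING

    def test_constant_row_excluded_as_small(self):
        ok, why = gs.inclusion_filter([0.5] * 100, n_total=100)
        assert not ok and why == EXCLUDE_SMALL


class TestLogrank:
    def test_identical_groups_null(self):
        t = [1, 2, 3, 4, 1, 2, 3, 4]
        e = [1, 1, 0, 1, 1, 1, 0, 1]
        g = [0, 0, 0, 0, 1, 1, 1, 1]
        chi2, p = gs.logrank_test(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_manual_tabulation(self):
        t = [1, 2, 3, 4, 5, 6]
        e = [1, 1, 1, 1, 1, 1]
        g = [False, False, False, True, True, True]
        chi2, p = gs.logrank_test(t, e, g)
        chi2_ref, p_ref = manual_logrank(t, e, g)
        assert chi2 == pytest.approx(chi2_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)

    def test_matches_lifelines_with_ties_and_censoring(self):
        rng = np.random.default_rng(5)
        t = np.round(rng.exponential(10, 80), 0) + 1
        e = rng.integers(0, 2, 80)
        g = rng.random(80) < 0.4
        chi2, p = gs.logrank_test(t, e, g)
        ref = lifelines_logrank(t[~g], t[g], event_observed_A=e[~g],
                                event_observed_B=e[g])
        assert chi2 == pytest.approx(float(ref.test_statistic), rel=1e-9)
        assert p == pytest.approx(float(ref.p_value), rel=1e-9)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError, match="non-empty"):
            gs.logrank_test([1, 2], [1, 1], [True, True])

    def test_null_p_uniform_under_permutation(self):
        rng = np.random.default_rng(12)
        n, n_perm = 100, 500
        t = rng.exponential(20, n)
        e = (rng.random(n) < 0.7).astype(float)
        groups = np.stack([rng.permutation(n) < n // 2 for _ in range(n_perm)])
        _, p = _logrank_many(t, e, groups)
        ks = stats.kstest(p, "uniform")
        assert ks.pvalue > 0.01


class TestScreen:
    def test_alpha_boundary(self, strong_cohort):
        psi, clin, *_ = strong_cohort
        res = gs.screen_events(psi, clin, alpha=0.01)
        inc = res[res["included"]]
        assert (inc.loc[inc["p_value"] < 0.01, "prognostic"]).all()
        assert (~inc.loc[inc["p_value"] >= 0.01, "prognostic"]).all()

    def test_group_sizes_sum_to_n(self, strong_cohort):
        psi, clin, *_ = strong_cohort
        res = gs.screen_events(psi, clin)
        inc = res[res["included"]]
        assert ((inc["n_low"] + inc["n_high"]) == psi.n_samples).all()

    def test_order_invariance(self, strong_cohort):
        psi, clin, *_ = strong_cohort
        res = gs.screen_events(psi, clin)
        perm = np.random.default_rng(0).permutation(psi.n_samples)
        psi2 = gs.PsiMatrix(events=psi.events, data=psi.data.iloc[:, perm])
        res2 = gs.screen_events(psi2, clin)
        pd.testing.assert_frame_equal(res, res2)
        rperm = np.random.default_rng(1).permutation(psi.n_events)
        psi3 = gs.PsiMatrix(events=[psi.events[i] for i in rperm],
                            data=psi.data.iloc[rperm])
        res3 = gs.screen_events(psi3, clin)
        pd.testing.assert_frame_equal(res.loc[res3.index], res3)

    def test_all_excluded_is_not_an_error(self, tiny_clinical):
        frame = pd.DataFrame({"s1": [np.nan], "s2": [0.5], "s3": [0.5],
                              "s4": [0.5]}, index=["G1|1|ES"])
        psi = gs.PsiMatrix.from_frame(frame)
        res = gs.screen_events(psi, tiny_clinical)
        assert not res["prognostic"].any()
        assert res["exclusion_reason"].tolist() == [EXCLUDE_MISSING]

    def test_no_overlap_raises(self, tiny_psi):
        clin = gs.ClinicalTable(data=pd.DataFrame(
            {"os_months": [1.0], "os_event": [1]}, index=["other"]))
        with pytest.raises(ValueError, match="overlap"):
            gs.screen_events(tiny_psi, clin)

    def test_planted_effects_detected_with_power(self):
        detected, planted = 0, 0
        for seed in (21, 22, 23):
            cfg = gs.SimulationConfig(
                n_samples=300, n_events=60, k_true=2,
                fraction_informative=0.0, n_prognostic_events=20,
                missing_event_frac=0.0,
                cluster_median_survival=(24.0, 24.0), seed=seed)
            psi, clin, _, truth = gs.simulate_cohort(cfg)
            res = gs.screen_events(psi, clin)
            hits = res.loc[truth.prognostic_events.index, "prognostic"]
            detected += int(hits.sum())
            planted += len(hits)
        assert detected / planted >= 0.8


class TestCategorizeCounts:
    def test_counts_sum_to_total(self, strong_cohort):
        psi, clin, *_ = strong_cohort
        res = gs.screen_events(psi, clin)
        counts = gs.categorize_counts(res)
        assert counts["total"] == counts[list(gs.SPLICE_TYPES)].sum()

    def test_empty_input_all_zero(self):
        empty = pd.DataFrame({"splice_type": [], "prognostic": []})
        counts = gs.categorize_counts(empty)
        assert counts["total"] == 0 and (counts == 0).all()
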