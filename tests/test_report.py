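"""KM summaries, cross-tabs, therapy stratification and PCA."""

import numpy as np
import pandas as pd
import pytest

import gliosplice as gs
from gliosplice.report import format_median_ci, proportion_pct


class TestKmSummary:
    def test_uncensored_median_is_sample_median(self):
        t = list(range(1, 10))
        table, _ = gs.km_summary(t, [1] * 9, ["a"] * 9)
        assert table.loc["a", "median_os"] == 5

    def test_all_censored_not_reached(self):
        table, _ = gs.km_summary([5, 6, 7], [0, 0, 0], ["a"] * 3)
        assert np.isinf(table.loc["a", "median_os"])
        assert format_median_ci(table.loc["a", "median_os"], np.inf, np.inf) \
            == "NA (NA, NA)"

    def test_censored_worked_example(self):
        # deaths at 2 and 4, censoring at 3, 5, 6:
        # S(2) = 4/5 = 0.8; S(4) = 0.8 * 2/3 = 0.5333 — the curve never
        # reaches 0.5, so the product-limit median is not reached
        table, _ = gs.km_summary([2, 3, 4, 5, 6], [1, 0, 1, 0, 0], ["a"] * 5)
        assert np.isinf(table.loc["a", "median_os"])

    def test_censored_median_crosses_half(self):
        # deaths 2, 4, 6 with censoring at 3:
        # S(2)=3/4, S(4)=3/4*2/3=1/2 <= 0.5 -> median 4 by hand tabulation
        table, _ = gs.km_summary([2, 3, 4, 6], [1, 0, 1, 1], ["a"] * 4)
        assert table.loc["a", "median_os"] == 4

    def test_global_logrank_separates_groups(self):
        t = [1, 2, 3, 4, 5, 50, 60, 70, 80, 90]
        lab = ["x"] * 5 + ["y"] * 5
        table, p = gs.km_summary(t, [1] * 10, lab)
        assert p < 0.01
        assert table.loc["x", "median_os"] < table.loc["y", "median_os"]

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            gs.km_summary([], [], [])


class TestCrosstab:
    @pytest.mark.parametrize("count,denom,expected", [
        (49, 53, 92.5), (96, 97, 99.0), (157, 184, 85.3), (38, 48, 79.2),
        (10, 146, 6.8), (189, 203, 93.1), (24, 45, 53.3), (0, 20, 0.0),
    ])
    def test_printed_percentages(self, count, denom, expected):
        assert proportion_pct(count, denom) == expected

    def test_counts_percentages_and_test(self):
        labels = ["c1"] * 53 + ["c2"] * 50
        ann = (["G3"] * 49 + ["G2"] * 4) + (["G3"] * 10 + ["G2"] * 40)
        counts, pct, p, unknowns = gs.crosstab_proportions(labels, ann)
        assert counts.loc["c1", "G3"] == 49
        assert pct.loc["c1", "G3"] == 92.5
        assert p < 0.01
        assert unknowns.empty

    def test_unknowns_excluded_from_denominator(self):
        labels = ["c1"] * 10
        ann = ["yes"] * 4 + ["no"] * 4 + ["unknown"] * 2
        counts, pct, _, unknowns = gs.crosstab_proportions(labels, ann)
        assert counts.loc["c1"].sum() == 8
        assert pct.loc["c1", "yes"] == 50.0
        assert unknowns["c1"] == 2

    def test_fisher_fallback_small_2x2(self):
        labels = ["a"] * 5 + ["b"] * 5
        ann = ["x", "x", "x", "x", "y"] + ["y", "y", "y", "y", "x"]
        counts, _, p, _ = gs.crosstab_proportions(labels, ann)
        from scipy.stats import fisher_exact
        assert p == pytest.approx(float(fisher_exact(counts)[1]))


class TestTherapyStratified:
    def test_identical_arms_p_one(self):
        idx = [f"s{i}" for i in range(8)]
        clin = gs.ClinicalTable(data=pd.DataFrame({
            "os_months": [5, 6, 7, 8] * 2,
            "os_event": [1, 1, 1, 1] * 2,
            "standard_therapy": [1, 1, 1, 1, 0, 0, 0, 0],
        }, index=idx))
        labels = pd.Series(["c1"] * 8, index=idx)
        out = gs.treatment_stratified_survival(clin, labels)
        assert out.loc["c1", "p_value"] == pytest.approx(1.0)

    def test_unknown_therapy_cluster_skipped(self):
        idx = [f"s{i}" for i in range(6)]
        clin = gs.ClinicalTable(data=pd.DataFrame({
            "os_months": [5.0] * 6,
            "os_event": [1] * 6,
            "standard_therapy": [np.nan] * 6,
        }, index=idx))
        labels = pd.Series(["c1"] * 6, index=idx)
        out = gs.treatment_stratified_survival(clin, labels)
        assert np.isnan(out.loc["c1", "p_value"])
        assert "skipped" in out.loc["c1", "note"]

    def test_benefit_confined_to_target_cluster(self):
        hits_target, hits_other = 0, 0
        seeds = (41, 42, 43)
        for seed in seeds:
            cfg = gs.SimulationConfig(
                n_samples=240, n_events=20, k_true=3,
                fraction_informative=0.0, n_prognostic_events=0,
                cluster_median_survival=(20.0, 20.0, 20.0),
                therapy_loghr=(0.0, 0.0, np.log(0.4)),
                missing_event_frac=0.0, seed=seed)
            psi, clin, _, truth = gs.simulate_cohort(cfg)
            labels = pd.Series(truth.labels, index=psi.samples)
            out = gs.treatment_stratified_survival(clin, labels)
            hits_target += out.loc[3, "p_value"] < 0.05
            hits_other += (out.loc[[1, 2], "p_value"] < 0.05).sum()
        assert hits_target >= 2
        assert hits_other <= 2


class TestPca:
    def test_duplicate_samples_identical_coords(self):
        rng = np.random.default_rng(0)
        X = rng.random((5, 6))
        X[:, 3] = X[:, 0]
        coords, var = gs.pca_projection(X)
        assert coords[3] == pytest.approx(coords[0])
        assert var.sum() <= 1.0 + 1e-12

    def test_separated_clusters_split_on_pc1(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.2, 0.02, (10, 20))
        b = rng.normal(0.8, 0.02, (10, 20))
        X = np.hstack([a, b])   # events x samples
        coords, _ = gs.pca_projection(X)
        gap = abs(coords[:20, 0].mean() - coords[20:, 0].mean())
        spread = max(coords[:20, 0].std(), coords[20:, 0].std())
        assert gap > 3 * spread

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(2)
        X = rng.random((4, 12))
        c1, _ = gs.pca_projection(X)
        c2, _ = gs.pca_projection(X)
        assert c1 == pytest.approx(c2)

    def test_input_contracts(self):
        with pytest.raises(ValueError):
            gs.pca_projection(np.random.rand(1, 5))
        bad = np.random.rand(3, 5)
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            gs.pca_projection(bad)


def test_cohort_report_assembles(strong_cohort, strong_labels):
    psi, clin, _, truth = strong_cohort
    sig_rows = psi.data.loc[truth.informative_events].dropna()
    rep = gs.cohort_report(clin, strong_labels, signature_psi=sig_rows)
    assert set(rep.km_table.index) == {1, 2, 3}
    assert 0 <= rep.global_logrank_p <= 1
    assert rep.pca_coords.shape == (psi.n_samples, 2)
    md = rep.to_markdown()
    assert "Overall survival by cluster" in md
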