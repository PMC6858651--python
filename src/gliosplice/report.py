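"""Clinical characterization of splicing clusters.

Kaplan-Meier summaries per cluster (median overall survival with a log-log
confidence interval, "NA" when not reached), a global log-rank comparison,
annotation cross-tabs with one-decimal percentages and a chi-square /
Fisher association test, therapy-stratified survival within clusters, and a
2-D PCA projection of samples on signature-event PSI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import median_survival_times
from scipy import stats
from sklearn.decomposition import PCA

from .io import ClinicalTable, PsiMatrix
from .screen import logrank_test

log = logging.getLogger(__name__)


def km_summary(
    times: Sequence[float],
    events: Sequence[int],
    labels: Sequence,
) -> tuple[pd.DataFrame, float]:
    """Per-group KM median survival with CI, plus the global log-rank p.

    The median is the first time the product-limit estimate drops to <= 0.5;
    groups whose curve never reaches 0.5 report ``NaN`` (printed as "NA").
    The confidence interval comes from lifelines' exponential-Greenwood
    (log-log) survival-curve CI.  Empty groups raise.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    lab = pd.Series(list(labels))
    if lab.empty:
        raise ValueError("no samples given")
    rows = []
    for g in sorted(lab.unique()):
        sel = (lab == g).to_numpy()
        if sel.sum() == 0:
            raise ValueError(f"empty group {g!r}")
        kmf = KaplanMeierFitter().fit(t[sel], e[sel])
        med = float(kmf.median_survival_time_)
        ci = median_survival_times(kmf.confidence_interval_)
        lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
        rows.append((g, int(sel.sum()), med, lo, hi))
    table = pd.DataFrame(rows, columns=["group", "n", "median_os",
                                        "ci_lower", "ci_upper"]).set_index("group")
    if lab.nunique() > 1:
        res = multivariate_logrank_test(t, lab.to_numpy(), e)
        global_p = float(res.p_value)
    else:
        global_p = float("nan")
    return table, global_p


def format_median_ci(median: float, lo: float, hi: float) -> str:
    """Table-style "median (lo, hi)" with NA for unreached values."""
    def f(v: float) -> str:
        return "NA" if not np.isfinite(v) else f"{v:.1f}"
    return f"{f(median)} ({f(lo)}, {f(hi)})"


def crosstab_proportions(
    labels: Sequence, annotation: Sequence
) -> tuple[pd.DataFrame, pd.DataFrame, float, pd.Series]:
    """Cluster x annotation counts, row percentages and an association test.

    "unknown" annotations are excluded from denominators and reported
    separately.  Percentages are 100*count/row-total rounded to one decimal.
    The test is chi-square on the count table, falling back to Fisher's
    exact test for 2x2 tables with any expected cell below 5 (for larger
    sparse tables the chi-square p is reported with a log note).  Returns
    (counts, percentages, p, unknown_counts).
    """
    lab = pd.Series(list(labels), name="cluster")
    ann = pd.Series(list(annotation), name="annotation").astype(str)
    unknown_mask = ann.eq("unknown") | ann.eq("nan")
    unknowns = lab[unknown_mask].value_counts().sort_index()
    counts = pd.crosstab(lab[~unknown_mask], ann[~unknown_mask])
    if counts.size == 0:
        return counts, counts.astype(float), float("nan"), unknowns
    denom = counts.sum(axis=1)
    pct = (100.0 * counts.div(denom, axis=0)).round(1)

    p = float("nan")
    if counts.shape[0] > 1 and counts.shape[1] > 1:
        chi2, p_chi, _, expected = stats.chi2_contingency(counts)
        if (expected < 5).any() and counts.shape == (2, 2):
            _, p = stats.fisher_exact(counts)
        else:
            if (expected < 5).any():
                log.info("expected counts < 5 in a %sx%s table; "
                         "chi-square p reported", *counts.shape)
            p = float(p_chi)
    return counts, pct, p, unknowns


def proportion_pct(count: int, denom: int) -> float:
    """One-decimal percentage exactly as printed in clinical tables."""
    if denom == 0:
        return 0.0
    return round(100.0 * count / denom, 1)


def treatment_stratified_survival(
    clin: ClinicalTable, labels: pd.Series
) -> pd.DataFrame:
    """Within each cluster, log-rank p of standard vs nonstandard therapy.

    Clusters with fewer than 2 usable samples in either arm are skipped with
    a note in the ``note`` column.  Returns a per-cluster table with arm
    sizes and the p-value.
    """
    surv = clin.survival()
    ther = pd.to_numeric(clin.data["standard_therapy"], errors="coerce")
    labels = pd.Series(labels)
    rows = []
    for g in sorted(labels.unique()):
        members = [s for s in labels.index[labels == g]
                   if s in set(surv.index) and not np.isnan(ther.get(s, np.nan))]
        t = surv.loc[members, "os_months"].to_numpy()
        e = surv.loc[members, "os_event"].to_numpy()
        std = ther.loc[members].to_numpy() > 0
        n_std, n_non = int(std.sum()), int((~std).sum())
        if min(n_std, n_non) < 2:
            rows.append((g, n_std, n_non, float("nan"), "skipped: arm too small"))
            continue
        _, p = logrank_test(t, e, std)
        rows.append((g, n_std, n_non, p, ""))
    return pd.DataFrame(rows, columns=["cluster", "n_standard",
                                       "n_nonstandard", "p_value",
                                       "note"]).set_index("cluster")


def pca_projection(
    signature_psi: pd.DataFrame | np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """2-D PCA of samples on signature-event PSI.

    Input is events x samples (rows complete, >= 2 events, >= 3 samples).
    Components follow a deterministic sign convention: the largest-magnitude
    loading of each component is made positive.  Returns (coordinates
    (n_samples, 2), variance_explained (2,)).
    """
    X = (signature_psi.to_numpy(dtype=float)
         if isinstance(signature_psi, pd.DataFrame)
         else np.asarray(signature_psi, dtype=float))
    if X.shape[0] < 2 or X.shape[1] < 3:
        raise ValueError("need >= 2 events and >= 3 samples")
    if np.isnan(X).any():
        raise ValueError("signature PSI must be complete")
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(X.T)
    for c in range(2):
        load = pca.components_[c]
        if load[np.abs(load).argmax()] < 0:
            coords[:, c] *= -1
    return coords, pca.explained_variance_ratio_


@dataclass
class ClusterReport:
    """Assembled per-cluster clinical report."""

    km_table: pd.DataFrame
    global_logrank_p: float
    crosstabs: dict[str, dict]
    therapy_table: pd.DataFrame
    pca_coords: np.ndarray | None
    pca_variance: np.ndarray | None

    def to_markdown(self) -> str:
        lines = ["# Splicing-cluster clinical report", ""]
        km = self.km_table.copy()
        km["median (CI)"] = [
            format_median_ci(r.median_os, r.ci_lower, r.ci_upper)
            for r in km.itertuples()]
        lines += ["## Overall survival by cluster", "",
                  km[["n", "median (CI)"]].to_markdown(),
                  "", f"Global log-rank p = {self.global_logrank_p:.3g}", ""]
        for name, block in self.crosstabs.items():
            lines += [f"## {name}", "", "counts:", block["counts"].to_markdown(),
                      "", "row %:", block["percent"].to_markdown(),
                      "", f"association p = {block['p']:.3g}", ""]
        lines += ["## Therapy-stratified survival", "",
                  self.therapy_table.to_markdown(), ""]
        return "\n".join(lines)


def cohort_report(
    clin: ClinicalTable,
    labels: pd.Series,
    signature_psi: pd.DataFrame | None = None,
    annotations: Sequence[str] = ("grade", "histology", "idh_status",
                                  "codel_1p19q", "mgmt_status"),
) -> ClusterReport:
    """Build the full clinical report for a set of cluster labels."""
    labels = pd.Series(labels)
    surv = clin.survival()
    shared = [s for s in labels.index if s in set(surv.index)]
    t = surv.loc[shared, "os_months"].to_numpy()
    e = surv.loc[shared, "os_event"].to_numpy()
    km_table, global_p = km_summary(t, e, labels.loc[shared])

    crosstabs = {}
    lab_all = labels.loc[[s for s in labels.index if s in set(clin.samples)]]
    for col in annotations:
        if col not in clin.data.columns:
            continue
        counts, pct, p, unknowns = crosstab_proportions(
            lab_all, clin.data.loc[lab_all.index, col])
        # self-consistency: every printed percentage recomputes from counts
        for g in counts.index:
            denom = int(counts.loc[g].sum())
            for a in counts.columns:
                assert pct.loc[g, a] == proportion_pct(int(counts.loc[g, a]), denom)
        crosstabs[col] = {"counts": counts, "percent": pct, "p": p,
                          "unknown": unknowns}

    therapy = treatment_stratified_survival(clin, labels)
    coords = variance = None
    if signature_psi is not None and signature_psi.shape[0] >= 2:
        coords, variance = pca_projection(signature_psi)
    return ClusterReport(km_table=km_table, global_logrank_p=global_p,
                         crosstabs=crosstabs, therapy_table=therapy,
                         pca_coords=coords, pca_variance=variance)
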