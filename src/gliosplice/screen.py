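"""Genome-wide PSI survival screen.

For every splicing event, samples are split into low/high groups at the
event's mean PSI and the two groups are compared with an unstratified,
unweighted (Mantel-Cox) log-rank test.  Events are excluded when any sample
has missing PSI or when either mean-split group is smaller than 5% of the
cohort; events with log-rank p < 0.01 are called prognostic.

The log-rank statistic is computed by a vectorized observed-minus-expected
tabulation shared across all events of a screen, so a cohort-scale screen is
a single pass over the risk sets rather than thousands of independent test
objects.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .events import SPLICE_TYPES
from .io import ClinicalTable, PsiMatrix

log = logging.getLogger(__name__)

EXCLUDE_MISSING = "missing-psi"
EXCLUDE_SMALL = "small-group"


def dichotomize_by_mean(psi_row: np.ndarray) -> np.ndarray:
    """Split at the arithmetic mean; PSI >= mean goes to the high group.

    Returns a boolean vector, True = high.  The input must be free of
    missing values (apply :func:`inclusion_filter` first).
    """
    x = np.asarray(psi_row, dtype=float)
    if np.isnan(x).any():
        raise ValueError("missing PSI; filter events before dichotomizing")
    return x >= x.mean()


def group_size_threshold(n_total: int, min_frac: float = 0.05) -> int:
    """Smallest admissible mean-split group: ceil(min_frac * n_total)."""
    return int(math.ceil(min_frac * n_total))


def inclusion_filter(
    psi_row: np.ndarray,
    n_total: int | None = None,
    min_frac: float = 0.05,
    min_per_group: int | None = None,
) -> tuple[bool, str | None]:
    """Decide whether an event enters the screen.

    Excluded if any PSI is missing, or if either mean-split group is smaller
    than ``min_per_group`` (default ``ceil(min_frac * n_total)``; pass
    ``min_per_group`` explicitly to pin a cohort-specific threshold).
    Returns ``(included, reason)`` with reason in {None, "missing-psi",
    "small-group"}.
    """
    x = np.asarray(psi_row, dtype=float)
    if np.isnan(x).any():
        return False, EXCLUDE_MISSING
    if n_total is None:
        n_total = x.size
    thr = (group_size_threshold(n_total, min_frac)
           if min_per_group is None else int(min_per_group))
    high = dichotomize_by_mean(x)
    n_high = int(high.sum())
    n_low = x.size - n_high
    if min(n_low, n_high) < thr:
        return False, EXCLUDE_SMALL
    return True, None


def _logrank_many(
    times: np.ndarray, deaths: np.ndarray, high: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Mantel-Cox chi-square for many group vectors over one survival table.

    ``high`` is (n_tests, n_samples) boolean.  At each distinct death time
    the risk set is every sample with time >= t (censoring at t stays at
    risk for t).  Returns (chi_square, p_value) arrays; tests with zero
    variance (no information) get chi-square 0 and p 1.
    """
    order = np.argsort(times, kind="stable")
    t_s, d_s = times[order], deaths[order]
    H = high[:, order].astype(float)            # (E, n)
    n = t_s.size

    # boundaries of tied-time blocks
    starts = np.flatnonzero(np.r_[True, t_s[1:] != t_s[:-1]])
    n_at_risk = n - starts                      # per block
    # deaths per block
    d_cum = np.r_[0.0, np.cumsum(d_s)]
    ends = np.r_[starts[1:], n]
    d_block = d_cum[ends] - d_cum[starts]       # (B,)
    # at-risk in high group per block: suffix sums of H
    h_suffix = np.c_[np.cumsum(H[:, ::-1], axis=1)[:, ::-1], np.zeros(len(H))]
    n1 = h_suffix[:, starts]                    # (E, B)
    # deaths in high group per block
    hd_cum = np.c_[np.zeros(len(H)), np.cumsum(H * d_s, axis=1)]
    d1 = hd_cum[:, ends] - hd_cum[:, starts]

    keep = d_block > 0
    d_b, n_b = d_block[keep], n_at_risk[keep].astype(float)
    n1_b, d1_b = n1[:, keep], d1[:, keep]
    frac = n1_b / n_b
    o_minus_e = (d1_b - d_b * frac).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_terms = d_b * frac * (1.0 - frac) * (n_b - d_b) / (n_b - 1.0)
    var = np.nansum(np.where(n_b > 1, var_terms, 0.0), axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(var > 0, o_minus_e**2 / var, 0.0)
    p = np.where(var > 0, stats.chi2.sf(chi2, df=1), 1.0)
    return chi2, p


def logrank_test(
    times: Sequence[float],
    events: Sequence[int],
    groups: Sequence[bool],
) -> tuple[float, float]:
    """Two-group Mantel-Cox log-rank test.

    Returns ``(chi_square, p_value)``; the chi-square has 1 degree of
    freedom and the p-value is its upper tail.  Both groups must be
    non-empty; callers are expected to have applied
    :func:`inclusion_filter` first.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups, dtype=bool)
    if t.size != e.size or t.size != g.size:
        raise ValueError("times, events and groups must have equal length")
    if (t < 0).any():
        raise ValueError("negative survival times")
    if not g.any() or g.all():
        raise ValueError("both groups must be non-empty; filter events first")
    chi2, p = _logrank_many(t, e.astype(float), g[None, :])
    return float(chi2[0]), float(p[0])


def screen_events(
    psi: PsiMatrix,
    clin: ClinicalTable,
    alpha: float = 0.01,
    min_frac: float = 0.05,
    min_per_group: int | None = None,
) -> pd.DataFrame:
    """Run the per-event survival screen.

    Samples are the intersection of the PSI matrix and the clinical table
    restricted to usable survival data; the mean-split cutoff is computed on
    those samples.  Returns one row per event with columns ``splice_type``,
    ``n_low``, ``n_high``, ``chi_square``, ``p_value``, ``included``,
    ``exclusion_reason`` and ``prognostic``; the result is invariant to
    sample and event order.
    """
    surv = clin.survival()
    shared = [s for s in psi.samples if s in set(surv.index)]
    if not shared:
        raise ValueError("no overlapping samples between PSI and clinical data")
    if len(shared) < psi.n_samples:
        log.info("screening on %d/%d overlapping samples",
                 len(shared), psi.n_samples)
    times = surv.loc[shared, "os_months"].to_numpy(dtype=float)
    deaths = surv.loc[shared, "os_event"].to_numpy(dtype=float)
    X = psi.data[shared].to_numpy(dtype=float)
    n = len(shared)

    included = np.empty(psi.n_events, dtype=bool)
    reasons: list[str | None] = []
    for i in range(psi.n_events):
        ok, why = inclusion_filter(X[i], n_total=n, min_frac=min_frac,
                                   min_per_group=min_per_group)
        included[i] = ok
        reasons.append(why)

    n_low = np.zeros(psi.n_events, dtype=int)
    n_high = np.zeros(psi.n_events, dtype=int)
    chi2 = np.full(psi.n_events, np.nan)
    pval = np.full(psi.n_events, np.nan)
    idx = np.flatnonzero(included)
    if idx.size:
        rows = X[idx]
        high = rows >= rows.mean(axis=1, keepdims=True)
        n_high[idx] = high.sum(axis=1)
        n_low[idx] = n - n_high[idx]
        chi2[idx], pval[idx] = _logrank_many(times, deaths, high)

    out = pd.DataFrame({
        "splice_type": psi.splice_types().to_numpy(),
        "n_low": n_low,
        "n_high": n_high,
        "chi_square": chi2,
        "p_value": pval,
        "included": included,
        "exclusion_reason": reasons,
        "prognostic": included & (pval < alpha),
    }, index=pd.Index(psi.event_ids, name="event_id"))
    return out


def categorize_counts(results: pd.DataFrame, which: str = "prognostic") -> pd.Series:
    """Tally events per splice category plus a grand total.

    ``which="prognostic"`` counts prognostic calls; ``"included"`` counts
    screened events; ``"all"`` counts every row.  The returned Series is
    indexed by the 7 categories followed by ``"total"``, and the per-category
    counts always sum to the total.
    """
    if which == "all":
        sel = results
    elif which in ("prognostic", "included"):
        sel = results[results[which].astype(bool)]
    else:
        raise ValueError(f"unknown selector {which!r}")
    counts = sel["splice_type"].value_counts()
    out = pd.Series({t: int(counts.get(t, 0)) for t in SPLICE_TYPES})
    out["total"] = int(out.sum())
    return out
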