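"""Subtype-specific and two-group splicing signatures.

An event is a signature of subtype *s* when its mean PSI in *s* is at least
``fold`` (default 1.30, i.e. "30% higher") times its mean in **every** other
subtype, and every pairwise Mann-Whitney comparison of *s* against the other
subtypes survives Benjamini-Hochberg FDR control.  The fold rule makes
signature sets provably disjoint across subtypes: two positive means cannot
each exceed 1.3x the other.

The two-group variant (IDH mutant vs wild type and the like) selects events
whose group-mean ratio reaches ``fold`` (default 2) after an epsilon
pseudocount stabilizes near-zero means, again under BH-FDR control, and
reports which group is the higher one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import PsiMatrix


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (monotone)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class SignatureSet:
    """Per-event signature calls.

    ``table`` has one row per event: the candidate subtype (the one with the
    highest mean), per-subtype means (``mean_<label>`` columns), the fold of
    the candidate mean against the best other subtype, the largest adjusted
    q over the candidate's pairwise comparisons, and the final assignment
    (``assigned_subtype``; missing = not a signature).
    """

    table: pd.DataFrame
    fold: float
    fdr: float

    def events_for(self, subtype) -> list[str]:
        t = self.table
        return list(t.index[t["assigned_subtype"] == subtype])

    def counts(self) -> pd.Series:
        """Signatures per subtype plus a grand total."""
        assigned = self.table["assigned_subtype"].dropna()
        out = assigned.value_counts().sort_index()
        out.loc["total"] = int(out.sum())
        return out


def _group_values(psi: PsiMatrix, labels: pd.Series) -> tuple[np.ndarray, list, list[np.ndarray]]:
    labels = pd.Series(labels)
    shared = [s for s in psi.samples if s in set(labels.index)]
    if not shared:
        raise ValueError("no overlap between PSI samples and labels")
    lab = labels.loc[shared]
    X = psi.data[shared].to_numpy(dtype=float)
    groups = sorted(pd.unique(lab))
    members = [np.flatnonzero((lab == g).to_numpy()) for g in groups]
    for g, m in zip(groups, members):
        if m.size < 2:
            raise ValueError(f"subtype {g!r} has fewer than 2 samples")
    return X, groups, members


def subtype_specific_events(
    psi: PsiMatrix,
    labels: pd.Series,
    fold: float = 1.30,
    fdr: float = 0.05,
) -> SignatureSet:
    """Call subtype-specific signature events.

    ``labels`` maps sample id -> subtype.  For each event the subtype with
    the highest mean PSI is the only possible signature host; it is tested
    against every other subtype (two-sided Mann-Whitney, normal
    approximation with tie correction) and BH adjustment runs over the full
    event x comparison family in a single pass.
    """
    X, groups, members = _group_values(psi, labels)
    if len(groups) < 2:
        raise ValueError("need at least 2 subtypes")
    k, p_ev = len(groups), X.shape[0]
    means = np.stack([np.nanmean(X[:, m], axis=1) for m in members])  # (k, E)

    cand = means.argmax(axis=0)
    pvals = np.ones((p_ev, k))          # candidate vs each other subtype
    for i in range(p_ev):
        a = X[i, members[cand[i]]]
        a = a[~np.isnan(a)]
        for j in range(k):
            if j == cand[i]:
                continue
            b = X[i, members[j]]
            b = b[~np.isnan(b)]
            if a.size < 2 or b.size < 2 or (np.ptp(np.r_[a, b]) == 0):
                pvals[i, j] = 1.0
            else:
                pvals[i, j] = stats.mannwhitneyu(
                    a, b, alternative="two-sided", method="asymptotic").pvalue
    mask = np.ones((p_ev, k), dtype=bool)
    mask[np.arange(p_ev), cand] = False
    qvals = np.ones_like(pvals)
    qvals[mask] = bh_fdr(pvals[mask])

    cand_mean = means[cand, np.arange(p_ev)]
    other_best = np.where(mask, means.T, -np.inf).max(axis=1)
    with np.errstate(divide="ignore"):
        fold_vs_best = np.where(other_best > 0, cand_mean / other_best, np.inf)
    fold_ok = np.array([
        bool((means[cand[i], i] >= fold * np.delete(means[:, i], cand[i])).all())
        for i in range(p_ev)])
    q_ok = np.array([bool((qvals[i, mask[i]] < fdr).all()) for i in range(p_ev)])
    assigned = np.where(fold_ok & q_ok,
                        np.asarray(groups, dtype=object)[cand], None)

    table = pd.DataFrame(index=pd.Index(psi.event_ids, name="event_id"))
    for gi, g in enumerate(groups):
        table[f"mean_{g}"] = means[gi]
    table["candidate_subtype"] = np.asarray(groups, dtype=object)[cand]
    table["fold_vs_best_other"] = fold_vs_best
    table["max_q"] = np.array([qvals[i, mask[i]].max() for i in range(p_ev)])
    table["assigned_subtype"] = assigned

    result = SignatureSet(table=table, fold=fold, fdr=fdr)
    _assert_disjoint(result)
    return result


def _assert_disjoint(sig: SignatureSet) -> None:
    assigned = sig.table["assigned_subtype"].dropna()
    # one assignment per event row by construction; this guards the invariant
    assert assigned.index.is_unique, "an event was assigned to multiple subtypes"


def two_group_events(
    psi: PsiMatrix,
    group: pd.Series,
    fold: float = 2.0,
    fdr: float = 0.05,
    eps: float = 1e-3,
) -> pd.DataFrame:
    """Two-group (e.g. IDH mutant vs wild-type) related events.

    ``group`` maps sample id -> one of exactly two category values.  An
    event is selected when (max mean + eps) >= fold * (min mean + eps) and
    its BH-adjusted Mann-Whitney q < fdr.  Returns a per-event table with
    group means, ratio, p, q, ``selected`` and ``higher_in`` (the group
    label with the larger mean).  Symmetric in group labelling.
    """
    X, groups, members = _group_values(psi, group)
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    (ga, gb), (ma, mb) = groups, members
    mean_a = np.nanmean(X[:, ma], axis=1)
    mean_b = np.nanmean(X[:, mb], axis=1)
    hi = np.maximum(mean_a, mean_b)
    lo = np.minimum(mean_a, mean_b)
    ratio = (hi + eps) / (lo + eps)

    pvals = np.empty(X.shape[0])
    for i in range(X.shape[0]):
        a = X[i, ma]
        b = X[i, mb]
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        if a.size < 2 or b.size < 2 or np.ptp(np.r_[a, b]) == 0:
            pvals[i] = 1.0
        else:
            pvals[i] = stats.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic").pvalue
    qvals = bh_fdr(pvals)
    selected = (ratio >= fold) & (qvals < fdr)
    return pd.DataFrame({
        f"mean_{ga}": mean_a,
        f"mean_{gb}": mean_b,
        "ratio": ratio,
        "p_value": pvals,
        "q_value": qvals,
        "selected": selected,
        "higher_in": np.where(mean_a >= mean_b, ga, gb),
    }, index=pd.Index(psi.event_ids, name="event_id"))


def rescale_unit(values: np.ndarray | pd.DataFrame) -> np.ndarray | pd.DataFrame:
    """Min-max rescale each event row to [0, 1] for heatmap display.

    Constant rows map to all zeros; missing values stay missing.  Idempotent
    on rows already spanning [0, 1].
    """
    is_frame = isinstance(values, pd.DataFrame)
    X = values.to_numpy(dtype=float) if is_frame else np.asarray(values, dtype=float)
    X = np.array(X, dtype=float, copy=True)
    if X.ndim == 1:
        X = X[None, :]
        squeeze = True
    else:
        squeeze = False
    with np.errstate(invalid="ignore"):
        lo = np.nanmin(X, axis=1, keepdims=True)
        hi = np.nanmax(X, axis=1, keepdims=True)
    span = hi - lo
    out = np.where(span > 0, (X - lo) / np.where(span > 0, span, 1.0), 0.0)
    out[np.isnan(X)] = np.nan
    if squeeze:
        out = out[0]
    if is_frame:
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    return out
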