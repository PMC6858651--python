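"""Monte-Carlo consensus clustering with a simulated null reference.

Samples are clustered repeatedly on random subsamples; the consensus matrix
entry (i, j) is the fraction of co-sampled resamples in which i and j landed
in the same cluster.  Stability at each candidate k is scored by the
proportion of ambiguous clustering (PAC: consensus entries falling strictly
between the unambiguous extremes).  Because PAC drifts with k even on
structureless data, the observed PAC is referenced against Monte-Carlo null
datasets — multivariate-Gaussian draws matching the input's feature
covariance eigenstructure but carrying no cluster structure — yielding a
relative cluster stability index RCSI = ln(mean null PAC / real PAC) and an
add-one empirical p-value per k.  The chosen k maximizes RCSI among
significant k; structureless inputs give a "no structure" verdict.

The inner clusterer is a batched Lloyd k-means (k-means++ seeding, multiple
restarts) that fits all resamples of all datasets simultaneously, which is
what makes the null-reference loop affordable; a PAM (k-medoids) option is
available for non-Euclidean tastes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io import PsiMatrix

log = logging.getLogger(__name__)

DEFAULT_K_RANGE: tuple[int, ...] = tuple(range(2, 9))


# ---------------------------------------------------------------------------
# batched k-means
# ---------------------------------------------------------------------------

def _kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding for a batch of problems.  X: (B, m, f) -> (B, k, f)."""
    B, m, _ = X.shape
    C = np.empty((B, k, X.shape[2]), dtype=X.dtype)
    bi = np.arange(B)
    C[:, 0] = X[bi, rng.integers(0, m, B)]
    d2 = ((X - C[:, 0][:, None, :]) ** 2).sum(-1)  # (B, m)
    for j in range(1, k):
        tot = d2.sum(axis=1, keepdims=True)
        probs = np.where(tot > 0, d2 / np.where(tot > 0, tot, 1.0), 1.0 / m)
        cum = np.cumsum(probs, axis=1)
        idx = np.minimum((cum < rng.random((B, 1))).sum(1), m - 1)
        C[:, j] = X[bi, idx]
        d2 = np.minimum(d2, ((X - C[:, j][:, None, :]) ** 2).sum(-1))
    return C


def _lloyd(X: np.ndarray, C: np.ndarray, max_iter: int) -> tuple[np.ndarray, np.ndarray]:
    """Batched Lloyd iterations.  Returns (labels (B, m), inertia (B,)).

    The returned inertia omits the per-problem constant sum of ||x||^2, which
    cancels when ranking restarts of the same problem.
    """
    B, m, f = X.shape
    k = C.shape[1]
    C = C.copy()
    labels = np.full((B, m), -1, dtype=np.int32)
    active = np.arange(B)
    Xa = X
    eye = np.eye(k, dtype=X.dtype)
    for _ in range(max_iter):
        # squared distances up to the constant ||x||^2 (argmin unaffected)
        d = (C[active] ** 2).sum(-1)[:, None, :] - 2.0 * np.einsum(
            "bmf,bkf->bmk", Xa, C[active], optimize=True)
        new = d.argmin(-1).astype(np.int32)
        changed = (new != labels[active]).any(axis=1)
        labels[active] = new
        if not changed.any():
            break
        upd = active[changed]
        one_hot = eye[labels[upd]]                               # (b, m, k)
        counts = one_hot.sum(1)                                  # (b, k)
        sums = np.einsum("bmk,bmf->bkf", one_hot, X[upd], optimize=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            newC = sums / counts[:, :, None]
        # empty clusters keep their previous centroid
        C[upd] = np.where(counts[:, :, None] > 0, newC, C[upd])
        active = upd
        Xa = X[active]
    d = (C ** 2).sum(-1)[:, None, :] - 2.0 * np.einsum(
        "bmf,bkf->bmk", X, C, optimize=True)
    inertia = np.take_along_axis(
        d, labels[:, :, None].astype(int), axis=2)[..., 0].sum(1, dtype=np.float64)
    return labels, inertia


def kmeans_labels(
    X: np.ndarray,
    k: int,
    rng: np.random.Generator,
    n_init: int = 3,
    max_iter: int = 50,
) -> np.ndarray:
    """Batched k-means labels for a stack of problems.

    ``X`` is (B, m, f) — B independent problems of m points each; returns
    integer labels (B, m).  k-means++ seeding; restarts keep the
    lowest-inertia solution.  Arithmetic runs in float32: at consensus scale
    the co-clustering average washes out any assignment jitter long before
    float32 rounding could matter.
    """
    X = np.asarray(X, dtype=np.float32)
    if X.ndim == 2:
        X = X[None]
    best_labels, best_inertia = None, None
    for _ in range(n_init):
        C0 = _kmeanspp_init(X, k, rng)
        labels, inertia = _lloyd(X, C0, max_iter)
        if best_labels is None:
            best_labels, best_inertia = labels, inertia
        else:
            better = inertia < best_inertia
            best_labels[better] = labels[better]
            best_inertia = np.minimum(best_inertia, inertia)
    return best_labels


def _pam_labels(X: np.ndarray, k: int, rng: np.random.Generator,
                max_iter: int = 30) -> np.ndarray:
    """Simple alternating k-medoids (PAM-style) for one problem (m, f)."""
    m = X.shape[0]
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    medoids = rng.choice(m, size=k, replace=False)
    for _ in range(max_iter):
        labels = D[:, medoids].argmin(1)
        new_medoids = medoids.copy()
        for c in range(k):
            members = np.flatnonzero(labels == c)
            if members.size:
                within = D[np.ix_(members, members)].sum(0)
                new_medoids[c] = members[within.argmin()]
        if (new_medoids == medoids).all():
            break
        medoids = new_medoids
    return D[:, medoids].argmin(1)


# ---------------------------------------------------------------------------
# consensus machinery
# ---------------------------------------------------------------------------

def _resample_indices(n: int, m: int, n_resamples: int,
                      rng: np.random.Generator) -> np.ndarray:
    """(n_resamples, m) sample indices, each row without replacement."""
    return np.argsort(rng.random((n_resamples, n)), axis=1)[:, :m]


def _consensus_from_labels(n: int, idx: np.ndarray, labels: np.ndarray
                           ) -> np.ndarray:
    """Aggregate co-clustering counts into a consensus matrix."""
    pair_count = np.zeros((n, n))
    co_count = np.zeros((n, n))
    for r in range(idx.shape[0]):
        sel = idx[r]
        lab = labels[r]
        pair_count[np.ix_(sel, sel)] += 1.0
        co_count[np.ix_(sel, sel)] += lab[:, None] == lab[None, :]
    off = ~np.eye(n, dtype=bool)
    if (pair_count[off] == 0).any():
        raise ValueError(
            "some sample pairs were never co-sampled; increase n_resamples")
    M = np.divide(co_count, pair_count, out=np.zeros((n, n)),
                  where=pair_count > 0)
    np.fill_diagonal(M, 1.0)
    return (M + M.T) / 2.0


def consensus_matrix(
    data: np.ndarray,
    k: int,
    n_resamples: int = 100,
    item_frac: float = 0.8,
    seed: int | np.random.Generator = 0,
    inner: str = "kmeans",
    n_init: int = 3,
) -> np.ndarray:
    """Consensus matrix of one dataset at one k.

    ``data`` is samples x features with no missing values.  Entry (i, j) is
    the number of resamples clustering i and j together divided by the
    number of resamples containing both; the diagonal is 1.
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    if np.isnan(data).any():
        raise ValueError("missing values not allowed in consensus clustering")
    if k < 2 or k >= n:
        raise ValueError("need 2 <= k < n_samples")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    m = int(np.ceil(item_frac * n))
    idx = _resample_indices(n, m, n_resamples, rng)
    if inner == "kmeans":
        labels = kmeans_labels(data[idx], k, rng, n_init=n_init)
    elif inner == "pam":
        labels = np.stack([_pam_labels(data[idx[r]], k, rng)
                           for r in range(n_resamples)])
    else:
        raise ValueError(f"unknown inner clusterer {inner!r}")
    return _consensus_from_labels(n, idx, labels)


def cdf_and_pac(
    consensus: np.ndarray, window: tuple[float, float] = (0.1, 0.9)
) -> tuple[pd.DataFrame, float]:
    """Empirical CDF of the upper-triangle consensus entries, and PAC.

    PAC = CDF(upper) - CDF(lower): the fraction of entries falling in the
    ambiguous window (lower, upper].  0 = perfectly stable, 1 = maximally
    ambiguous.
    """
    lo, hi = window
    tri = np.asarray(consensus)[np.triu_indices(consensus.shape[0], k=1)]
    xs = np.sort(tri)
    F = np.arange(1, xs.size + 1) / xs.size
    cdf = pd.DataFrame({"consensus": xs, "cdf": F})
    pac = float((tri <= hi).mean() - (tri <= lo).mean())
    return cdf, pac


def simulate_null_references(
    data: np.ndarray,
    n_null: int = 25,
    seed: int | np.random.Generator = 0,
) -> list[np.ndarray]:
    """Structureless reference datasets matching the input's covariance.

    Each null is a multivariate-normal draw whose feature covariance
    eigenstructure equals the input's (sampled through the input's
    principal-component decomposition): correlation structure is preserved,
    cluster structure is destroyed.  Zero-variance features are dropped with
    a warning.
    """
    X = np.asarray(data, dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    var = X.var(axis=0)
    if (var == 0).any():
        warnings.warn(f"dropping {int((var == 0).sum())} zero-variance features "
                      "from null simulation")
        X = X[:, var > 0]
    n = X.shape[0]
    mu = X.mean(axis=0)
    Xc = X - mu
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    scale = s / np.sqrt(n - 1)
    out = []
    for _ in range(n_null):
        Z = rng.standard_normal((n, s.size))
        out.append(mu + (Z * scale) @ Vt)
    return out


def rcsi_and_pvalue(
    real_pac: float, null_pacs: Sequence[float]
) -> tuple[float, float]:
    """Relative cluster stability index and add-one empirical p-value.

    RCSI = ln(mean(null PACs) / real PAC) — positive when the data are more
    stable than the structureless reference.  empirical p =
    (1 + #{null <= real}) / (1 + n_null), never exactly zero.  A real PAC of
    0 yields RCSI = +inf with the p-value computed normally.
    """
    nulls = np.asarray(list(null_pacs), dtype=float)
    if nulls.size == 0:
        raise ValueError("null_pacs must be non-empty")
    p = float((1 + (nulls <= real_pac).sum()) / (1 + nulls.size))
    if real_pac == 0:
        return float("inf"), p
    return float(np.log(nulls.mean() / real_pac)), p


def select_k(stats: pd.DataFrame, p_threshold: float = 0.05
             ) -> int | None:
    """Pick k with maximal RCSI among k with empirical p < threshold.

    ``stats`` must be indexed by k with columns ``rcsi`` and ``empirical_p``.
    Returns None (a "no structure" verdict) when no k is significant; the
    full per-k table remains available to callers who wish to override, e.g.
    preferring a larger significant k for granularity.
    """
    sig = stats[stats["empirical_p"] < p_threshold]
    if sig.empty:
        return None
    return int(sig["rcsi"].idxmax())


def assign_clusters(consensus: np.ndarray, k: int) -> np.ndarray:
    """Final labels: average-linkage hierarchical cut of 1 - consensus.

    Labels are renumbered by decreasing cluster size (largest = 1; ties
    broken by first occurrence).
    """
    C = np.asarray(consensus, dtype=float)
    D = 1.0 - (C + C.T) / 2.0
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    raw = fcluster(Z, t=k, criterion="maxclust")
    sizes = pd.Series(raw).value_counts()
    order = sorted(sizes.index, key=lambda c: (-sizes[c], np.flatnonzero(raw == c)[0]))
    remap = {old: new for new, old in enumerate(order, start=1)}
    return np.asarray([remap[c] for c in raw], dtype=int)


# ---------------------------------------------------------------------------
# end-to-end driver
# ---------------------------------------------------------------------------

@dataclass
class ConsensusResult:
    """Everything the consensus run produced."""

    k_range: tuple[int, ...]
    consensus: dict[int, np.ndarray]
    cdf: dict[int, pd.DataFrame]
    pac: dict[int, float]
    null_pac_mean: dict[int, float]
    rcsi: dict[int, float]
    empirical_p: dict[int, float]
    chosen_k: int | None
    labels: np.ndarray | None
    samples: list[str] | None = None

    def per_k_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "pac": self.pac,
            "null_pac_mean": self.null_pac_mean,
            "rcsi": self.rcsi,
            "empirical_p": self.empirical_p,
        }).rename_axis("k")

    def labels_series(self) -> pd.Series:
        if self.labels is None:
            raise ValueError("no structure was found; no labels assigned")
        idx = self.samples or range(1, len(self.labels) + 1)
        return pd.Series(self.labels, index=idx, name="cluster")


def prepare_features(psi: PsiMatrix, event_ids: Sequence[str]) -> np.ndarray:
    """Samples x features matrix of per-event standardized PSI.

    Each selected event's PSI row is z-scored across samples (constant rows
    are centred only).  Missing PSI is not allowed here — the screen's
    no-missing inclusion rule guarantees completeness of prognostic events.
    """
    sub = psi.data.loc[list(event_ids)]
    X = sub.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("selected events contain missing PSI")
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return ((X - mu) / sd).T


def run_consensus(
    data: np.ndarray,
    k_range: Iterable[int] = DEFAULT_K_RANGE,
    n_resamples: int = 100,
    item_frac: float = 0.8,
    n_null: int = 25,
    seed: int = 0,
    inner: str = "kmeans",
    n_init: int = 3,
    p_threshold: float = 0.05,
    samples: Sequence[str] | None = None,
) -> ConsensusResult:
    """Full Monte-Carlo consensus run over a k range.

    Computes the real consensus matrix, CDF and PAC per k; simulates
    ``n_null`` covariance-matched reference datasets and scores their PAC
    through the identical consensus procedure; derives RCSI and the
    empirical p per k; selects k and assigns final labels (None when no k is
    significant).
    """
    data = np.asarray(data, dtype=float)
    ks = tuple(k_range)
    n = data.shape[0]
    rng = np.random.default_rng(seed)
    nulls = simulate_null_references(data, n_null=n_null, seed=rng)
    datasets = [data] + nulls          # reals first
    m = int(np.ceil(item_frac * n))

    consensus: dict[int, np.ndarray] = {}
    cdf: dict[int, pd.DataFrame] = {}
    pac: dict[int, float] = {}
    null_mean: dict[int, float] = {}
    rcsi: dict[int, float] = {}
    emp_p: dict[int, float] = {}
    for k in ks:
        idx = np.stack([_resample_indices(n, m, n_resamples, rng)
                        for _ in datasets])              # (D, R, m)
        if inner == "kmeans":
            stacked = np.stack(datasets)                  # (D, n, f)
            flat_idx = idx.reshape(-1, m)                 # (D*R, m)
            ds_of = np.repeat(np.arange(len(datasets)), n_resamples)
            X = stacked[ds_of[:, None], flat_idx]         # (D*R, m, f)
            labels = kmeans_labels(X, k, rng, n_init=n_init)
            labels = labels.reshape(len(datasets), n_resamples, m)
        else:
            labels = np.stack([
                np.stack([_pam_labels(datasets[d][idx[d, r]], k, rng)
                          for r in range(n_resamples)])
                for d in range(len(datasets))])
        null_pacs = []
        for d in range(len(datasets)):
            M = _consensus_from_labels(n, idx[d], labels[d])
            _, p_ac = cdf_and_pac(M)
            if d == 0:
                consensus[k] = M
                cdf[k], pac[k] = cdf_and_pac(M)
            else:
                null_pacs.append(p_ac)
        rcsi[k], emp_p[k] = rcsi_and_pvalue(pac[k], null_pacs)
        null_mean[k] = float(np.mean(null_pacs))
        log.info("k=%d PAC=%.3f nullPAC=%.3f RCSI=%.3f p=%.3f",
                 k, pac[k], null_mean[k], rcsi[k], emp_p[k])

    table = pd.DataFrame({"rcsi": rcsi, "empirical_p": emp_p})
    chosen = select_k(table, p_threshold=p_threshold)
    labels_final = assign_clusters(consensus[chosen], chosen) if chosen else None
    return ConsensusResult(
        k_range=ks, consensus=consensus, cdf=cdf, pac=pac,
        null_pac_mean=null_mean, rcsi=rcsi, empirical_p=emp_p,
        chosen_k=chosen, labels=labels_final,
        samples=list(samples) if samples is not None else None)
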