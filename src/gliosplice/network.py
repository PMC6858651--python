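"""Splicing-factor -> splicing-event regulatory network.

Each candidate edge is the Spearman correlation between a splicing factor's
expression and an event's PSI across shared samples; edges with |rho| above
the threshold (default 0.45) and p below 0.05 enter a signed bipartite
graph.  Factor nodes additionally carry a prognostic direction (favorable /
unfavorable) derived from a mean-split log-rank analysis of the factor's
own expression, with the direction read off the restricted-mean survival of
the two expression groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.utils import restricted_mean_survival_time
from scipy import stats

from .io import ClinicalTable, ExpressionMatrix, PsiMatrix
from .screen import dichotomize_by_mean, logrank_test

log = logging.getLogger(__name__)

FAVORABLE = "favorable"
UNFAVORABLE = "unfavorable"
UNDETERMINED = "undetermined"


def default_splicing_factors() -> list[str]:
    """The shipped 22-factor panel of recognized prognostic splicing factors."""
    text = resources.files("gliosplice.data").joinpath(
        "splicing_factors.txt").read_text()
    return [line.strip() for line in text.splitlines()
            if line.strip() and not line.startswith("#")]


def prognostic_direction(
    expression_row: pd.Series | np.ndarray,
    clin: ClinicalTable,
) -> tuple[str, float]:
    """Prognostic direction of one factor's expression.

    Expression is mean-split into low/high groups; the two Kaplan-Meier
    curves are compared by log-rank, and the direction is *unfavorable* when
    the high-expression group has the smaller restricted-mean survival
    (horizon = largest observed time), else *favorable*.  Constant
    expression yields ("undetermined", nan).  Returns (direction, p).
    """
    x = pd.Series(expression_row)
    surv = clin.survival()
    shared = [s for s in x.index if s in set(surv.index)]
    if len(shared) < 10:
        raise ValueError("need >= 10 samples with expression and survival")
    vals = x.loc[shared].to_numpy(dtype=float)
    if np.ptp(vals) == 0:
        return UNDETERMINED, float("nan")
    high = dichotomize_by_mean(vals)
    if not high.any() or high.all():
        return UNDETERMINED, float("nan")
    t = surv.loc[shared, "os_months"].to_numpy()
    e = surv.loc[shared, "os_event"].to_numpy()
    _, p = logrank_test(t, e, high)
    horizon = float(t.max())
    rmst = []
    for grp in (high, ~high):
        kmf = KaplanMeierFitter().fit(t[grp], e[grp])
        rmst.append(float(restricted_mean_survival_time(kmf, t=horizon)))
    direction = UNFAVORABLE if rmst[0] < rmst[1] else FAVORABLE
    return direction, float(p)


def sf_event_correlations(
    expr: ExpressionMatrix,
    psi: PsiMatrix,
    factors: Sequence[str] | None = None,
    events: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Spearman rho and p for every (factor, event) pair over shared samples.

    Samples with missing PSI are dropped pairwise.  Factors absent from the
    expression matrix are skipped and returned in the second element rather
    than raising.  Returns (candidates, skipped_factors) where candidates
    has columns ``factor``, ``event_id``, ``rho``, ``p_value``, ``n``.
    """
    factors = list(factors) if factors is not None else expr.genes
    events = list(events) if events is not None else psi.event_ids
    shared = [s for s in expr.samples if s in set(psi.samples)]
    if len(shared) < 10:
        raise ValueError("need >= 10 shared samples")
    skipped = [f for f in factors if f not in set(expr.genes)]
    if skipped:
        log.warning("skipping %d factors absent from expression: %s",
                    len(skipped), ", ".join(skipped))
    kept = [f for f in factors if f not in set(skipped)]
    E = expr.data.loc[kept, shared].to_numpy(dtype=float)
    P = psi.data.loc[events, shared].to_numpy(dtype=float)
    rows = []
    for fi, f in enumerate(kept):
        for ei, ev in enumerate(events):
            ok = ~np.isnan(P[ei]) & ~np.isnan(E[fi])
            n = int(ok.sum())
            if n < 3:
                rho, p = float("nan"), float("nan")
            else:
                rho, p = stats.spearmanr(E[fi, ok], P[ei, ok])
            rows.append((f, ev, float(rho), float(p), n))
    return (pd.DataFrame(rows, columns=["factor", "event_id", "rho",
                                        "p_value", "n"]),
            skipped)


@dataclass
class CorrelationNetwork:
    """Signed bipartite factor-event network."""

    graph: nx.Graph
    edges: pd.DataFrame          # factor, event_id, rho, p_value, sign
    rho_threshold: float
    p_max: float

    @property
    def factors(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True)
                if d.get("kind") == "factor"]

    @property
    def events(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True)
                if d.get("kind") == "event"]

    def to_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, str(path))

    def to_edge_table(self, path: str | Path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)


def build_network(
    candidates: pd.DataFrame,
    rho_threshold: float = 0.45,
    p_max: float = 0.05,
    factor_directions: dict[str, str] | None = None,
) -> CorrelationNetwork:
    """Threshold candidate correlations into a signed bipartite network.

    Keeps edges with |rho| > rho_threshold and p < p_max (the absolute-value
    reading, so strong negative regulators are retained as negative edges).
    ``factor_directions`` optionally annotates factor nodes with their
    prognostic direction.  The edge set is exactly the filtered candidate
    set; kept/dropped counts are logged.
    """
    cand = candidates.dropna(subset=["rho", "p_value"])
    keep = cand[(cand["rho"].abs() > rho_threshold) & (cand["p_value"] < p_max)]
    log.info("network: keeping %d of %d candidate edges", len(keep), len(candidates))
    edges = keep.assign(sign=np.sign(keep["rho"]).astype(int)).reset_index(drop=True)

    g = nx.Graph()
    for f in edges["factor"].unique():
        direction = (factor_directions or {}).get(f, UNDETERMINED)
        g.add_node(f, kind="factor", direction=direction, bipartite=0)
    for ev in edges["event_id"].unique():
        g.add_node(ev, kind="event", bipartite=1)
    for row in edges.itertuples(index=False):
        g.add_edge(row.factor, row.event_id, rho=float(row.rho),
                   p_value=float(row.p_value), sign=int(row.sign))
    return CorrelationNetwork(graph=g, edges=edges,
                              rho_threshold=rho_threshold, p_max=p_max)
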