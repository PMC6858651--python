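"""Synthetic glioma-like PSI cohorts with known ground truth.

The generator emulates the statistical structure of a TCGA-SpliceSeq-style
glioma cohort: an events x samples PSI matrix whose events fall into the
seven splice categories, cluster-structured "informative" events that define
splicing subtypes, exponential overall survival tied to subtype and to the
PSI of planted prognostic events, independent censoring, event-concentrated
missingness, and splicing-factor expression monotonically linked to the mean
PSI of each factor's target events.

Defaults mirror the pan-glioma study conditions: 665 samples in 7 subtypes
with the published subtype sizes (153, 54, 173, 94, 20, 74, 97) and
per-subtype median overall survival in months; the event panel is scaled to
2,000 events so that a full screen+cluster run is a desk-scale computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .events import SPLICE_TYPES, SpliceEvent
from .io import ClinicalTable, ExpressionMatrix, PsiMatrix

# Pan-glioma study conditions used when k_true == 7 and the field is left None.
_STUDY_PROPORTIONS = (153, 54, 173, 94, 20, 74, 97)
_STUDY_MEDIANS = (13.5, 20.2, 94.5, 88.7, 60.0, 148.2, 172.2)  # months; NA->60
_STUDY_IDH_MUTANT = (0.06, 0.09, 0.97, 0.90, 0.90, 0.93, 0.99)


class ConfigError(ValueError):
    """Inconsistent simulation configuration."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Per-cluster tuples left as ``None`` resolve to the 7-subtype study
    conditions when ``k_true == 7``, otherwise to neutral automatic values
    (equal proportions, log-spaced survival medians, an IDH-mutant
    probability ramp).
    """

    n_samples: int = 665
    n_events: int = 2000
    k_true: int = 7
    cluster_proportions: tuple[float, ...] | None = None
    #: fraction of events whose mean PSI differs across clusters
    fraction_informative: float = 0.15
    #: added to the base mean in the elevated cluster of an informative event
    mean_gap: float = 0.3
    #: beta-distribution concentration (a+b); larger = tighter PSI
    concentration: float = 30.0
    base_mean_range: tuple[float, float] = (0.2, 0.5)
    uninformative_mean_range: tuple[float, float] = (0.1, 0.9)
    #: fraction of events that carry any missing cells at all
    missing_event_frac: float = 0.5
    #: per-cell missing probability within those events
    missing_rate: float = 0.05
    cluster_median_survival: tuple[float, ...] | None = None
    n_prognostic_events: int = 100
    #: total log hazard ratio per unit PSI carried by the planted risk axis;
    #: with the default coupling this puts the mean-split group hazard ratio
    #: of a single prognostic event near 2
    prognostic_loghr: float = 6.0
    #: how strongly prognostic events' PSI tracks the shared latent risk
    #: axis (0 = independent events, which would dilute any marginal effect
    #: across a large panel; real prognostic events co-vary)
    prognostic_coupling: float = 0.5
    censoring_rate: float = 0.4
    therapy_rate: float = 0.5
    #: per-cluster log hazard ratio of standard therapy (0 = no benefit)
    therapy_loghr: tuple[float, ...] | None = None
    idh_mutant_prob: tuple[float, ...] | None = None
    n_splicing_factors: int = 22
    targets_per_factor: int = 5
    factor_scale: float = 3.0
    factor_noise_sd: float = 0.2
    seed: int = 0

    def resolved(self) -> "SimulationConfig":
        """Return a copy with every per-cluster field made concrete."""
        k = self.k_true
        cfg = SimulationConfig(**asdict(self))
        if cfg.cluster_proportions is None:
            if k == 7:
                tot = sum(_STUDY_PROPORTIONS)
                cfg.cluster_proportions = tuple(n / tot for n in _STUDY_PROPORTIONS)
            else:
                cfg.cluster_proportions = tuple(1.0 / k for _ in range(k))
        if cfg.cluster_median_survival is None:
            cfg.cluster_median_survival = (
                _STUDY_MEDIANS if k == 7
                else tuple(np.geomspace(12.0, 120.0, k)))
        if cfg.therapy_loghr is None:
            cfg.therapy_loghr = tuple(0.0 for _ in range(k))
        if cfg.idh_mutant_prob is None:
            cfg.idh_mutant_prob = (
                _STUDY_IDH_MUTANT if k == 7
                else tuple(np.linspace(0.1, 0.9, k)))
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.k_true < 1 or self.k_true > self.n_samples:
            raise ConfigError("k_true must be in [1, n_samples]")
        for name in ("cluster_proportions", "cluster_median_survival",
                     "therapy_loghr", "idh_mutant_prob"):
            val = getattr(self, name)
            if val is not None and len(val) != self.k_true:
                raise ConfigError(f"{name} must have k_true={self.k_true} entries")
        if self.cluster_proportions is not None:
            if abs(sum(self.cluster_proportions) - 1.0) > 1e-8:
                raise ConfigError("cluster_proportions must sum to 1")
        for name in ("fraction_informative", "missing_rate",
                     "missing_event_frac", "censoring_rate", "therapy_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        lo, hi = self.base_mean_range
        if not (0 < lo <= hi < 1):
            raise ConfigError("base_mean_range must lie inside (0, 1)")
        n_inf = int(round(self.fraction_informative * self.n_events))
        if self.n_prognostic_events > self.n_events - n_inf:
            raise ConfigError(
                "n_prognostic_events exceeds the uninformative event pool")


@dataclass
class GroundTruth:
    """What the generator planted, for downstream validation."""

    labels: np.ndarray                     # true cluster per sample (1-based)
    informative_events: list[str]
    prognostic_events: pd.DataFrame        # index event_id, column 'sign'
    factor_map: pd.DataFrame               # index factor, columns targets/sign
    event_cluster_means: pd.DataFrame      # k_true x n_events mean PSI


def _make_events(n: int) -> list[SpliceEvent]:
    return [
        SpliceEvent(symbol=f"GENE{i:05d}", as_id=10000 + i,
                    splice_type=SPLICE_TYPES[i % len(SPLICE_TYPES)],
                    exon_label=f"exon{i % 40 + 2}")
        for i in range(n)
    ]


def simulate_cohort(
    config: SimulationConfig, seed: int | None = None
) -> tuple[PsiMatrix, ClinicalTable, ExpressionMatrix, GroundTruth]:
    """Draw one synthetic cohort.

    The same (config, seed) pair always yields byte-identical tables.  If
    ``seed`` is None the config's own seed is used.
    """
    cfg = config.resolved()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n, p, k = cfg.n_samples, cfg.n_events, cfg.k_true

    # -- cluster assignment -------------------------------------------------
    counts = np.floor(np.asarray(cfg.cluster_proportions) * n).astype(int)
    counts[: n - counts.sum()] += 1  # distribute the remainder
    labels = np.repeat(np.arange(1, k + 1), counts)

    # -- per-event per-cluster mean profiles --------------------------------
    n_inf = int(round(cfg.fraction_informative * p))
    means = np.empty((k, p))
    lo, hi = cfg.uninformative_mean_range
    means[:] = rng.uniform(lo, hi, size=p)[None, :]
    blo, bhi = cfg.base_mean_range
    base = rng.uniform(blo, bhi, size=n_inf)
    elevated = np.minimum(base + cfg.mean_gap, 0.95)
    for j in range(n_inf):
        means[:, j] = base[j]
        means[j % k, j] = elevated[j]

    # -- PSI draws ----------------------------------------------------------
    m_per_sample = means[labels - 1, :]            # n x p
    a = m_per_sample * cfg.concentration
    b = (1.0 - m_per_sample) * cfg.concentration
    psi = rng.beta(a, b)                           # n x p

    # -- prognostic events ride a shared latent risk axis -------------------
    n_prog = cfg.n_prognostic_events
    prog_idx = np.arange(n_inf, n_inf + n_prog)
    signs = np.where(np.arange(n_prog) % 2 == 0, 1.0, -1.0)
    if n_prog:
        risk = rng.beta(2, 2, n)  # latent per-sample risk, cluster-independent
        m_prog = np.clip(
            means[0, prog_idx][None, :]
            + cfg.prognostic_coupling * (risk[:, None] - 0.5) * signs[None, :],
            0.02, 0.98)
        psi[:, prog_idx] = rng.beta(m_prog * cfg.concentration,
                                    (1.0 - m_prog) * cfg.concentration)

    # -- survival -----------------------------------------------------------
    base_hazard = math.log(2) / np.asarray(cfg.cluster_median_survival)
    coefs = signs * cfg.prognostic_loghr / max(n_prog, 1)
    # centre PSI on the event's population mean so cluster medians stay put
    centred = psi[:, prog_idx] - means[0, prog_idx][None, :]
    therapy = (rng.random(n) < cfg.therapy_rate).astype(int)
    loghr = centred @ coefs + np.asarray(cfg.therapy_loghr)[labels - 1] * therapy
    hazard = base_hazard[labels - 1] * np.exp(loghr)
    t_death = rng.exponential(1.0 / hazard)
    if cfg.censoring_rate > 0:
        # censoring hazard proportional to each sample's own death hazard
        # gives P(censored) == censoring_rate exactly, per sample
        c_rate = hazard * cfg.censoring_rate / (1.0 - cfg.censoring_rate)
        t_cens = rng.exponential(1.0 / c_rate)
    else:
        t_cens = np.full(n, np.inf)
    os_months = np.minimum(t_death, t_cens)
    os_event = (t_death <= t_cens).astype(int)

    # -- missingness (event-concentrated, as in real PSI tables) ------------
    psi_released = psi.copy()
    gappy = rng.random(p) < cfg.missing_event_frac
    mask = (rng.random((n, p)) < cfg.missing_rate) & gappy[None, :]
    psi_released[mask] = np.nan

    # -- splicing-factor expression -----------------------------------------
    n_f = cfg.n_splicing_factors
    factor_names = [f"SF{i + 1:02d}" for i in range(n_f)]
    # targets of one factor share an elevated cluster so the factor's link to
    # their mean PSI carries through to each individual target
    strata = [[j for j in range(n_inf) if j % k == s] for s in range(k)]
    f_targets, f_signs, expr_rows = [], [], []
    for i in range(n_f):
        if n_inf:
            pool = strata[i % k] or list(range(n_inf))
            start = (i // k) * cfg.targets_per_factor
            t = [pool[(start + j) % len(pool)]
                 for j in range(cfg.targets_per_factor)]
        else:
            t = [(i * cfg.targets_per_factor + j) % p
                 for j in range(cfg.targets_per_factor)]
        sign = 1.0 if i % 2 == 0 else -1.0
        mean_psi = psi[:, t].mean(axis=1)
        z = 1.0 + sign * cfg.factor_scale * (mean_psi - 0.5)
        expr_rows.append(np.exp(z + rng.normal(0, cfg.factor_noise_sd, n)))
        f_targets.append(t)
        f_signs.append(sign)

    # -- assemble tables ----------------------------------------------------
    events = _make_events(p)
    event_ids = [e.event_id for e in events]
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    psi_mat = PsiMatrix(events=events,
                        data=pd.DataFrame(psi_released.T, index=event_ids,
                                          columns=sample_ids))

    idh_p = np.asarray(cfg.idh_mutant_prob)[labels - 1]
    idh = np.where(rng.random(n) < idh_p, "mutant", "wildtype")
    grade = np.where(labels == 1, "G4",
                     np.where(rng.random(n) < 0.5, "G2", "G3"))
    histology = np.where(labels == 1, "glioblastoma",
                         np.where(rng.random(n) < 0.5, "astrocytoma",
                                  "oligodendroglioma"))
    clin = ClinicalTable(data=pd.DataFrame({
        "os_months": np.round(os_months, 4),
        "os_event": os_event,
        "age": np.round(rng.normal(50, 12, n).clip(18, 90), 1),
        "karnofsky": rng.choice([100, 90, 80, 70, 60], size=n),
        "grade": grade,
        "histology": histology,
        "idh_status": idh,
        "codel_1p19q": np.where(rng.random(n) < 0.25, "codel", "non-codel"),
        "mgmt_status": np.where(rng.random(n) < 0.5, "methylated",
                                "unmethylated"),
        "tert_status": "unknown",
        "atrx_status": "unknown",
        "chr7gain_chr10loss": "unknown",
        "chr19_20_gain": "unknown",
        "standard_therapy": therapy,
    }, index=pd.Index(sample_ids, name="sample_id")))

    expr = ExpressionMatrix(data=pd.DataFrame(
        np.asarray(expr_rows), index=factor_names, columns=sample_ids))

    truth = GroundTruth(
        labels=labels,
        informative_events=[event_ids[j] for j in range(n_inf)],
        prognostic_events=pd.DataFrame(
            {"sign": np.sign(coefs).astype(int)},
            index=pd.Index([event_ids[j] for j in prog_idx], name="event_id")),
        factor_map=pd.DataFrame(
            {"targets": [";".join(event_ids[j] for j in t) for t in f_targets],
             "sign": [int(s) for s in f_signs]},
            index=pd.Index(factor_names, name="factor")),
        event_cluster_means=pd.DataFrame(
            means, index=[f"cluster{c}" for c in range(1, k + 1)],
            columns=event_ids),
    )
    return psi_mat, clin, expr, truth
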