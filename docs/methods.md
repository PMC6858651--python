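# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions taken where the underlying procedures
are conventionally underspecified.

## Survival screen

Per event, samples are split at the event's arithmetic mean PSI; ties
(PSI == mean) go to the **high** group, a deterministic convention that also
makes a constant event a single-group (hence excluded) case. Exclusion
rules: any missing PSI, or either mean-split group smaller than
⌈`min_frac`·n⌉ with `min_frac` = 0.05. Published cohort thresholds that
differ from the ceiling rule (e.g. a printed 33 where ⌈0.05·665⌉ = 34) can
be pinned exactly via `min_per_group`. The test is the unstratified,
unweighted Mantel–Cox log-rank with the 1-df χ² approximation; no exact
small-sample variant is offered, which is why the group-size floor exists.
Samples lacking survival time or status are dropped from the screen (with a
logged count) but retained for non-survival analyses; the mean cutoff is
computed on the post-alignment samples.

The screen computes all events' statistics in one vectorized
observed-minus-expected tabulation over the shared risk sets. `lifelines`
is used for Kaplan–Meier estimation and restricted-mean survival elsewhere
in the package and serves as an independent cross-check of the log-rank
implementation in the tests. No multiple-testing correction is applied at
the screening stage — prognostic means raw *p* < 0.01 by design; the FDR
machinery enters at the signature stage.

## Consensus clustering

For each k in 2…8, `n_resamples` = 100 subsamples of `item_frac` = 0.8 of
the samples are clustered and co-clustering frequencies aggregated into the
consensus matrix M (entry = co-clustered count / co-sampled count, unit
diagonal; a pair never co-sampled raises an error advising more resamples).
Features are the prognostic events' PSI rows, z-scored per event; missing
values are disallowed (guaranteed upstream by the screen's no-missing rule).

Ambiguity is PAC = CDF(0.9) − CDF(0.1) over the upper-triangle entries,
i.e. the mass in the window (0.1, 0.9]: 0 for a perfectly binary consensus,
1 when every entry is 0.5. Because PAC drifts with k even without
structure, `n_null` = 25 reference datasets are simulated through the
input's principal-component decomposition — multivariate-Gaussian draws
whose feature covariance equals the sample covariance (zero-variance
features dropped with a warning) — and pushed through the *identical*
consensus procedure. Per k this yields RCSI = ln(mean null PAC / real PAC)
and an add-one empirical p-value (1 + #{null PAC ≤ real PAC})/(1 + n_null),
never exactly zero. A real PAC of 0 reports RCSI = +∞ with the p-value
computed normally. `select_k` returns the k with maximal RCSI among k with
empirical *p* < 0.05, or a "no structure" verdict (None) when nothing is
significant; the full per-k table is always returned so callers can prefer
a finer significant k for granularity — deliberately so, since strongly
hierarchical cohorts (e.g. grade-dominated gliomas) can be perfectly stable
at a coarse split while the finer split is the scientifically interesting
one.

Final labels cut an average-linkage hierarchy of 1 − M at the chosen k and
are renumbered by decreasing cluster size (ties by first occurrence).

**Inner clusterer.** Lloyd k-means with k-means++ seeding, 3 restarts,
max 50 iterations, implemented as a batched solver that fits all resamples
of the real and all null datasets simultaneously in float32. The batching
is what makes the null-reference framework affordable: a full run touches
tens of thousands of ~120 × 20 clustering problems, a regime where
per-call overhead of a general-purpose implementation dominates the
arithmetic (the batched path is cross-checked against scikit-learn's KMeans
in the tests). Three k-means++ restarts rather than a larger count: the
consensus average over 100 resamples already integrates over initialization
noise, and restarts multiply the cost of the entire null loop; empty
clusters retain their previous centroid. A PAM (k-medoids) inner option is
available where Euclidean centroids are inappropriate.

## Signatures

Subtype rule: the subtype with the highest mean PSI for an event is the
only candidate; it is a signature host iff its mean is ≥ `fold` = 1.30
times the mean of **every** other subtype and every candidate-vs-other
Mann–Whitney comparison (two-sided, normal approximation with tie
correction) passes BH-FDR < 0.05. "30 % higher" is read as *relative*
(mean_s ≥ 1.3·mean_t), not as an absolute PSI difference of 0.3; `fold` is
a parameter, so the alternative reading is one argument away. BH adjustment
runs over the full event × comparison family in a single pass — the most
conservative of the common choices, since the per-event families are not
independent. Disjointness of signature sets across subtypes follows from
the fold rule (two positive means cannot each exceed 1.3× the other) and is
asserted on every run.

Two-group rule: selected iff (max mean + ε) ≥ `fold`·(min mean + ε) with
`fold` = 2 and ε = 1e-3, plus BH-FDR < 0.05 over the per-event tests. The
ε pseudocount makes near-zero means well-defined instead of silently
infinite. The fold-on-means reading keeps the two-group rule stylistically
consistent with the subtype rule; the selection is symmetric in group
labelling, with the reported direction flipping.

`rescale_unit` maps each event row through (x − min)/(max − min) for
heatmap display; constant rows map to 0 (a declared convention), missing
stays missing, and rows already spanning [0, 1] are fixed points.

## Splicing-factor network

Candidate edges are Spearman ρ and two-sided *p* per (factor, event) over
shared samples, dropping missing PSI pairwise; factors absent from the
expression matrix are reported as skipped, not fatal. Edges keep
|ρ| > 0.45 and *p* < 0.05 — the absolute-value reading, so strong negative
regulators are retained as negative edges; *p* is raw (the factor × event
family is small relative to the screen) and a stricter `p_max` is a
parameter. Factor prognostic direction is computed from the data at hand —
mean-split of the factor's expression, log-rank *p*, and direction
*unfavorable* iff the high-expression arm has the smaller restricted-mean
survival at a horizon of the largest observed time (more robust than
comparing medians, which may not be reached); constant expression yields an
explicit *undetermined*. The default factor panel ships as a replaceable
text file of 22 recognized prognostic splicing factors.

## Cohort report

KM medians are the first time the product-limit curve drops to ≤ 0.5,
with "NA" when never reached; the CI uses lifelines' exponential-Greenwood
(log-log) survival-band inversion, chosen because it behaves near 0/1
survival. Cross-tab percentages are 100·count/denominator rounded to one
decimal (matching clinical-table formatting, so reports diff cleanly
against published tables); "unknown" annotations leave the denominator and
are tallied separately, and a self-consistency assertion recomputes every
printed percentage from its counts on report emission. Association testing
is χ² with a Fisher-exact fallback for 2×2 tables with any expected cell
below 5; larger sparse tables keep the χ² *p* with a logged note (no exact
test for r×c tables is attempted). Therapy stratification runs a two-arm
log-rank within each cluster, skipping clusters with fewer than two usable
samples per arm. PCA is centered, two components, with the deterministic
sign convention that each component's largest-magnitude loading is
positive. "Standard therapy" is consumed as a precomputed 0/1 column;
deriving it from raw drug/radiation records is out of scope.

## Synthetic cohorts

The generator emulates the *structure* of a TCGA-SpliceSeq-style glioma
cohort, not its marginal distributions:

- **PSI**: per event and cluster, Beta(mμ, m(1−μ)) draws with concentration
  m (default 30; within-cluster s.d. ≈ 0.08 at μ = 0.5). Informative
  events (default 15 %) have one elevated cluster at base + `mean_gap`
  (default +0.3, capped at 0.95); uninformative events share a single mean
  U(0.1, 0.9) across clusters, which makes "no planted structure" literally
  true by construction.
- **Subtypes**: default 7 clusters with the pan-glioma study sizes
  (153, 54, 173, 94, 20, 74, 97 of 665) and per-cluster median overall
  survival in months (13.5, 20.2, 94.5, 88.7, 60, 148.2, 172.2); other k
  resolve to equal proportions and log-spaced medians. The default event
  panel is 2,000 — a deliberately desk-scale stand-in for the ~10^5-event
  genome-wide panel, chosen so a full screen+cluster run completes in
  minutes; nothing in the pipeline depends on the panel size.
- **Survival**: exponential per sample with log-hazard = cluster baseline
  (ln 2 / median) + Σ coef·(PSI − population mean) + therapy term — the
  simplest model satisfying the proportional-hazards structure a log-rank
  screen assumes. Planted prognostic events *co-vary along a shared latent
  risk axis* (Beta(2,2) per sample, coupling 0.5) and the per-event
  coefficients are the total `prognostic_loghr` (default 6 per unit PSI)
  divided by the panel size. This matters: a panel of *independent* strong
  effects acts as unobserved frailty that dilutes every marginal
  association — measured power collapses from ~1.0 to ~0.25 at 20
  independent events — whereas correlated prognostic events (the realistic
  case: risk-linked splicing programs move together) leave each event's
  mean-split hazard ratio near 2. Censoring is exponential with per-sample
  rate hazard·c/(1−c), giving exactly the configured censoring probability
  c (default 0.4) per sample regardless of covariates.
- **Regulation**: each factor's expression is exp(1 + sign·3·(mean target
  PSI − 0.5) + N(0, σ)) with σ = 0.2; the targets of one factor share an
  elevated cluster so the factor's link to their *mean* carries through to
  each individual target with a known sign (targets drawn from different
  clusters would anti-correlate and wash the signal out).
- **Annotations**: IDH status is drawn per cluster from study-like mutant
  probabilities; grade/histology follow a coarse cluster mapping; therapy
  is Bernoulli(0.5) with optional per-cluster log-hazard effects.
- **Missingness** is event-concentrated (a fraction of events carries all
  the gaps), mirroring real PSI tables where whole events are poorly
  quantified — important because the screen's no-missing rule would
  otherwise exclude nearly everything at cohort scale.

What passing tests on these cohorts do **not** show: robustness to
non-proportional hazards, to informative censoring, to batch effects or
covariate-driven missingness, or to the heavy-tailed, zero-inflated PSI
marginals of real SpliceSeq output. The generator is a correctness
instrument, not a realism benchmark.

## Problem sizes in tests and the acceptance script

Property checks run at desk scale as the package's own choice of study
conditions: screening calibration on 300 × 2,000 null cohorts (5 seeds),
cluster-number recovery on 150-sample/20-feature planted-k = 3 cohorts
(20 seeds, 100 resamples, 25 nulls), null-clustering control on 60 × 15
Gaussian noise (40 seeds), therapy localization on 240-sample cohorts
(20 seeds). The acceptance script's demonstration cohort is 240 samples ×
500 events with 3 subtypes, 20 risk-axis events and a therapy benefit
(hazard ratio 0.4) planted only in cluster 3. On that cohort the default
k-selection rule picks k = 2 with PAC = 0 — the coarse split is genuinely
perfectly stable because the screen over-represents the survival-extreme
subtypes — while the consensus matrix at the planted k = 3 reproduces the
true partition exactly (ARI = 1.0); the script reports both, exercising the
documented granularity override.

## Known limitations

- The χ² log-rank approximation is anticonservative for very small groups;
  the 5 % group floor is the guard, not an exact test.
- Empirical p-values are bounded below by 1/(n_null + 1) = 1/26 at the
  default reference count; finer significance claims need more nulls.
- Fisher's exact fallback exists only for 2×2 tables.
- The network is signed correlation, not causal inference; no multiple-
  testing correction is applied to edges by default (flag available).
- `select_k` ties on RCSI = +∞ (multiple k with PAC exactly 0) resolve to
  the smallest such k; inspect the per-k table when data are hierarchical.
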