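"""Clinical characterization of splicing clusters.

Kaplan-Meier medians with confidence intervals per cluster, a global
log-rank comparison, annotation cross-tabs with printed-style percentages,
therapy-stratified survival and a PCA projection on signature events.
"""

import numpy as np
import pandas as pd

import gliosplice as gs

cfg = gs.SimulationConfig(
    n_samples=240, n_events=100, k_true=3,
    fraction_informative=0.3, mean_gap=0.4, concentration=50.0,
    cluster_median_survival=(14.0, 40.0, 90.0),
    therapy_loghr=(0.0, 0.0, float(np.log(0.4))),  # benefit only in cluster 3
    idh_mutant_prob=(0.05, 0.5, 0.95),
    n_prognostic_events=0, missing_event_frac=0.0, seed=17,
)
psi, clin, _, truth = gs.simulate_cohort(cfg)
labels = pd.Series(truth.labels, index=psi.samples)

rep = gs.cohort_report(clin, labels,
                       signature_psi=psi.data.loc[truth.informative_events])

print("median overall survival (months) by cluster:")
from gliosplice.report import format_median_ci
for g, row in rep.km_table.iterrows():
    print(f"  cluster {g} (n={row['n']}): "
          f"{format_median_ci(row['median_os'], row['ci_lower'], row['ci_upper'])}")
print(f"global log-rank p = {rep.global_logrank_p:.2e}")

idh = rep.crosstabs["idh_status"]
print("\nIDH status by cluster (row %):")
print(idh["percent"].to_string())
print(f"association p = {idh['p']:.2e}")

print("\ntherapy-stratified log-rank p per cluster "
      "(benefit was planted only in cluster 3):")
print(rep.therapy_table[["n_standard", "n_nonstandard", "p_value"]]
      .round(4).to_string())

print(f"\nPCA of samples on signature PSI: PC1 {rep.pca_variance[0]:.0%}, "
      f"PC2 {rep.pca_variance[1]:.0%} of variance; subtypes separate on PC1.")
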