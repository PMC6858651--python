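"""Monte-Carlo consensus clustering with PAC/RCSI model selection.

Samples are clustered on prognostic-event PSI over 100 random subsamples
per k; stability (PAC) is referenced against covariance-matched Gaussian
null datasets, giving an RCSI and an empirical p per k.
"""

import pandas as pd
from sklearn.metrics import adjusted_rand_score

import gliosplice as gs

cfg = gs.SimulationConfig(
    n_samples=150, n_events=100, k_true=3,
    fraction_informative=0.3, mean_gap=0.4, concentration=50.0,
    n_prognostic_events=0, missing_event_frac=0.0, seed=5,
)
psi, _, _, truth = gs.simulate_cohort(cfg)

X = gs.prepare_features(psi, truth.informative_events)
res = gs.run_consensus(X, k_range=range(2, 9), n_resamples=100, n_null=25,
                       seed=11, samples=psi.samples)

print(res.per_k_table().round(3).to_string())
print(f"\nchosen k = {res.chosen_k} (maximal RCSI among empirically "
      "significant k; PAC 0 means perfectly unambiguous co-clustering)")
ari = adjusted_rand_score(truth.labels, res.labels)
print(f"adjusted Rand index vs planted subtypes: {ari:.2f}")
print(f"cluster sizes: {pd.Series(res.labels).value_counts().to_dict()}")
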