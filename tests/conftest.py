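import numpy as np
import pandas as pd
import pytest

import gliosplice as gs


@pytest.fixture(scope="session")
def strong_cohort():
    """Well-separated 3-subtype cohort with planted prognosis and regulators."""
    cfg = gs.SimulationConfig(
        n_samples=150, n_events=120, k_true=3,
        fraction_informative=0.25, mean_gap=0.4, concentration=50.0,
        n_prognostic_events=20, missing_event_frac=0.3,
        factor_noise_sd=0.2, seed=7,
    )
    return gs.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def strong_labels(strong_cohort):
    psi, _, _, truth = strong_cohort
    return pd.Series(truth.labels, index=psi.samples)


@pytest.fixture()
def tiny_psi():
    """3 events x 4 samples, fully observed."""
    frame = pd.DataFrame(
        [[0.10, 0.20, 0.80, 0.90],
         [0.50, 0.50, 0.50, 0.50],
         [0.00, 1.00, 0.25, 0.75]],
        index=["KIF4A|10001|AT|exon32", "GENE1|1|ES", "GENE2|2|RI|exon3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return gs.PsiMatrix.from_frame(frame)


@pytest.fixture()
def tiny_clinical():
    data = pd.DataFrame({
        "os_months": [12.0, 30.0, 8.0, 50.0],
        "os_event": [1, 0, 1, 0],
        "idh_status": ["mutant", "wildtype", "wildtype", "mutant"],
        "standard_therapy": [1, 0, 1, 0],
    }, index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"))
    return gs.ClinicalTable(data=data)
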