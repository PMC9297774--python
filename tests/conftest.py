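import numpy as np
import pandas as pd
import pytest

from survddg import CohortSpec, InformativeGene, simulate_cohort


@pytest.fixture
def ten_patient_cohort():
    """Worked 10-patient cohort: times 1..10, alternating events, groups 5/5."""
    time = np.arange(1.0, 11.0)
    event = np.array([1, 0, 1, 0, 1, 0, 1, 0, 1, 0])
    groups = np.array([1, 1, 1, 1, 1, 2, 2, 2, 2, 2])
    return time, event, groups


@pytest.fixture
def untied_cohort():
    """30 patients, distinct times, mixed events and groups (oracle fixture)."""
    rng = np.random.default_rng(42)
    time = np.sort(rng.exponential(1.0, 30)) + np.arange(30) * 1e-3
    event = (rng.uniform(size=30) < 0.7).astype(int)
    groups = np.where(rng.uniform(size=30) < 0.5, 1, 2)
    groups[:2] = [1, 2]  # both groups guaranteed nonempty
    return time, event, groups


@pytest.fixture
def informative_cohort():
    """600-patient cohort with one median-cutoff gene at log-HR 1."""
    spec = CohortSpec(
        n_patients=600, n_genes=2,
        informative_genes=(InformativeGene(0, 0.5, 1.0),), seed=11,
    )
    X, clin, truth = simulate_cohort(spec)
    return X, clin, truth


@pytest.fixture
def signature_cohorts():
    """Train/test cohort pair sharing 3 informative genes out of 5."""
    genes = (
        InformativeGene(0, 0.5, 1.0),
        InformativeGene(1, 0.4, 0.8),
        InformativeGene(2, 0.6, -0.8, "suppressor-like"),
    )
    train = simulate_cohort(CohortSpec(400, 5, genes, seed=3))
    test = simulate_cohort(CohortSpec(400, 5, genes, seed=10003))
    return train, test
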