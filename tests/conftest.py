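import numpy as np
import pytest

from cogniscreen.pipeline import PipelineConfig, tables_from_cohort
from cogniscreen.synthetic_cohort import CohortSpec, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def toy_table():
    """A small, quickly computed feature table for classifier/MRMR tests.

    Built directly from Gaussian blocks (no signal extraction) with the
    modality namespacing the assembly stage produces.
    """
    import pandas as pd

    from cogniscreen.features_assembly import FeatureTable

    rng = np.random.default_rng(99)
    n = 60
    y = np.array([1] * (n // 2) + [-1] * (n // 2))
    g = y * 1.0 + rng.standard_normal(n)  # shared latent, d' = 2/sqrt(2)
    data = {}
    for i in range(3):
        data[f"clinical.c{i}"] = 0.5 * g + rng.standard_normal(n)
    for i in range(5):
        data[f"ntb.s{i}"] = 0.7 * g + rng.standard_normal(n)
    for i in range(4):
        data[f"eeg.f{i}"] = 0.6 * g + rng.standard_normal(n)
    for i in range(2):
        data[f"et.f{i}"] = 0.6 * g + rng.standard_normal(n)
    df = pd.DataFrame(data, index=[f"S{i:03d}" for i in range(n)])
    labels = pd.Series(y, index=df.index)
    return FeatureTable(data=df, labels=labels)


@pytest.fixture(scope="session")
def small_cohort():
    """A tiny fully simulated cohort shared across integration tests."""
    spec = CohortSpec(
        n_nc=8, n_mci=8, eeg_duration_s=13.0, et_duration_s=30.0, seed=42
    )
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def small_cohort_table(small_cohort):
    return tables_from_cohort(small_cohort)
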