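import numpy as np
import pandas as pd
import pytest

from pkdpeptidome.cohort import CohortConfig, generate_cohort, generate_matrix


@pytest.fixture(scope="session")
def small_config():
    return CohortConfig(
        n_cases=15, n_controls=25, n_peptides=300, n_standards=10,
        n_severity_peptides=20, seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_matrix(small_config):
    return generate_matrix(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_matrix(values, labels=None, sample_prefix="s"):
    """Small IntensityMatrix from a 2-D array."""
    from pkdpeptidome.core import IntensityMatrix

    values = np.asarray(values, dtype=float)
    idx = [f"{sample_prefix}{i}" for i in range(values.shape[0])]
    cols = list(range(1, values.shape[1] + 1))
    lab = pd.Series(labels, index=idx) if labels is not None else None
    return IntensityMatrix(pd.DataFrame(values, index=idx, columns=cols), labels=lab)
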