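import numpy as np
import pandas as pd
import pytest

from frailtykit import (SimulationConfig, code_matrix, compute_fi_vector,
                        default_data_dictionary, generate_default_cohort)


@pytest.fixture(scope="session")
def dictionary():
    return default_data_dictionary()


@pytest.fixture(scope="session")
def default_cohort(dictionary):
    """Default-configuration cohort, n=30,000, with missingness applied."""
    return generate_default_cohort(seed=1, dictionary=dictionary)


@pytest.fixture(scope="session")
def default_matrix(default_cohort, dictionary):
    return code_matrix(default_cohort, dictionary)


@pytest.fixture(scope="session")
def small_cohort(dictionary):
    """A 3,000-participant cohort for cheaper model-level tests."""
    return generate_default_cohort(seed=7, n=3000, dictionary=dictionary)


def toy_deficit_matrix():
    """A small hand-checkable deficit matrix with missingness."""
    return pd.DataFrame(
        {"a": [1.0, 0.0, np.nan, 1.0],
         "b": [0.5, 0.0, np.nan, np.nan],
         "c": [0.0, 1.0, np.nan, 0.0],
         "d": [1.0, 0.5, np.nan, 0.0],
         "e": [0.0, 0.0, np.nan, 1.0]},
        index=[f"P{i}" for i in range(4)],
    )
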