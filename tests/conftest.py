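import numpy as np
import pandas as pd
import pytest

from lipidscreen.lipids import DEFAULT_IS_TABLE, default_database
from lipidscreen.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_db():
    return default_database(40)


@pytest.fixture(scope="session")
def is_table(small_db):
    return {
        cls: (small_db.internal_standard(cls).name, DEFAULT_IS_TABLE[cls][1])
        for cls in small_db.classes
        if small_db.internal_standard(cls) is not None
    }


@pytest.fixture(scope="session")
def small_cohort():
    cfg = CohortConfig(n_cases=40, n_controls=40, n_lipids=40, seed=11)
    matrix, samples = generate_cohort(cfg)
    return cfg, matrix, samples


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
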