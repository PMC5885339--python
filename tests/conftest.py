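import numpy as np
import pandas as pd
import pytest

from fracrisk import CohortTable, default_params, generate_cohort


def toy_table(x: np.ndarray, labels, columns=None) -> CohortTable:
    """Build a CohortTable from a raw feature matrix (algorithm-level toys
    bypass the clinical 20-column schema)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] == 1 and len(labels) > 1:
        x = x.T
    cols = columns or [f"f{i}" for i in range(x.shape[1])]
    return CohortTable(pd.DataFrame(x, columns=cols), np.asarray(labels))


@pytest.fixture
def small_cohort() -> CohortTable:
    """Seeded 400-patient synthetic cohort with the canonical schema."""
    params = default_params(seed=11)
    params.n_patients = 400
    return generate_cohort(params)


@pytest.fixture
def balanced_toy() -> CohortTable:
    """Linearly separable balanced 40-record toy in 2 features."""
    rng = np.random.default_rng(0)
    neg = rng.normal(-2.0, 0.4, size=(20, 2))
    pos = rng.normal(2.0, 0.4, size=(20, 2))
    return toy_table(np.vstack([neg, pos]), [0] * 20 + [1] * 20)
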