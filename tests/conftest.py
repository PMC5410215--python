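import numpy as np
import pandas as pd
import pytest

from tnbc_subtyper import ExpressionMatrix, SimConfig, generate_cohort


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """Deterministic 10x6 matrix with two batches."""
    rng = np.random.default_rng(42)
    values = pd.DataFrame(
        rng.normal(8.0, 1.0, (10, 6)),
        index=[f"P{i:02d}_at" for i in range(10)],
        columns=[f"s{j}" for j in range(6)],
    )
    batch = pd.Series(["A"] * 3 + ["B"] * 3, index=values.columns)
    return ExpressionMatrix(values, batch)


@pytest.fixture(scope="session")
def tnbc_cohort():
    """150-sample all-TNBC cohort with 5 planted subtypes (shared, read-only)."""
    config = SimConfig(
        n_datasets=1, samples_per_dataset=150, tnbc_only=True,
        batch_shift_sd=0.0, seed=7,
    )
    return generate_cohort(config)


@pytest.fixture(scope="session")
def mixed_cohort():
    """Default multi-dataset cohort with receptor-positive samples included."""
    return generate_cohort(SimConfig(seed=3))
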