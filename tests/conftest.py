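import numpy as np
import pandas as pd
import pytest

from pcatx.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 120+100 sample, 150-gene cohort with 10 planted genes (delta = 1 SD)."""
    planted = {f"G{i:05d}": 1.0 for i in range(1, 11)}
    spec = CohortSpec(
        n_group1=120, n_group0=100, n_genes=150, planted_effects=planted, seed=42
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def outcome_and_cov(small_cohort):
    from pcatx.association import covariates_from_clinical

    clinical = small_cohort.clinical
    outcome = pd.Series(
        (clinical["group"] == "AAM").astype(float).to_numpy(),
        index=clinical["sample_id"].to_numpy(),
    )
    return outcome, covariates_from_clinical(clinical)


@pytest.fixture
def toy_expr():
    """4-gene x 5-sample deterministic matrix."""
    rng = np.random.default_rng(7)
    return pd.DataFrame(
        rng.normal(size=(4, 5)),
        index=[f"g{i}" for i in range(4)],
        columns=[f"s{i}" for i in range(5)],
    )
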