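import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from covnet import CohortSpec, generate_cohort
from covnet.preprocess import CovariateTable

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """Two-group cohort with one planted block and mild missingness."""
    spec = CohortSpec(
        n_per_group=(120, 100),
        n_features=12,
        n_covariates=6,
        n_blocks=2,
        block_size=4,
        within_block_rho=0.7,
        missing_rate=0.08,
        seed=11,
    )
    conc, cov, truth = generate_cohort(spec)
    return spec, conc, cov, truth


@pytest.fixture()
def mixed_covariates():
    """Small covariate table with both variable types and missing cells."""
    rng = np.random.default_rng(5)
    n = 40
    data = pd.DataFrame(
        {
            "age": rng.uniform(80, 100, n),
            "glucose": np.exp(rng.normal(1.0, 0.3, n)),
            "diabetes": rng.integers(0, 2, n).astype(float),
            "smoker": rng.integers(0, 2, n).astype(float),
        },
        index=[f"s{i:02d}" for i in range(n)],
    )
    data.loc[data.index[:4], "glucose"] = np.nan
    data.loc[data.index[10:12], "diabetes"] = np.nan
    types = pd.Series(
        {
            "age": "continuous",
            "glucose": "continuous",
            "diabetes": "dichotomous",
            "smoker": "dichotomous",
        }
    )
    return CovariateTable(data, types)
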