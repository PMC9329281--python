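import numpy as np
import pytest

from heartage import GeneratorConfig, generate_cohort, split_by_sex
from heartage.association import default_catalogue


@pytest.fixture(scope="session")
def small_bundle():
    """A small two-sex cohort with 20 intercorrelated features."""
    cfg = GeneratorConfig(
        n_women=120, n_men=110, n_features=20, latent_rank=3, seed=42
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_catalogue():
    """A 40-variable exposure catalogue over three categories."""
    return default_catalogue(
        {"Abdominal MRI": 5, "Blood biomarkers": 20, "Physical measures": 15}
    )


@pytest.fixture(scope="session")
def female_stratum(small_bundle):
    return split_by_sex(small_bundle.cohort)["female"]


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
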