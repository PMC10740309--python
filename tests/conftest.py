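import numpy as np
import pytest

from dimorph.effects import BootstrapConfig
from dimorph.synthetic import generate_cohort, generate_null_cohort, study_spec
from dimorph.tiv import build_datasets


@pytest.fixture(scope="session")
def fast_cfg() -> BootstrapConfig:
    """Reduced bootstrap repetitions for quick unit tests."""
    return BootstrapConfig(
        n_boot_deciles=200, n_boot_overlap=100, n_boot_u3=100, n_boot_moments=200, seed=123
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_cohort():
    """Study-condition cohort at desk scale (60 subjects per sex)."""
    return generate_cohort(study_spec(n_per_sex=60, seed=5))


@pytest.fixture(scope="session")
def null_cohort():
    return generate_null_cohort(n_per_sex=40, seed=2)


@pytest.fixture(scope="session")
def small_datasets(small_cohort):
    return build_datasets(small_cohort)
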