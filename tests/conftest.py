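import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lncfeather import synthetic_data as sd
from lncfeather import transcript_discovery as td

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def clean_fixture():
    """Noise-free synthetic fixture shared across the suite."""
    return sd.generate_fixture(sd.SyntheticConfig(seed=1, fpkm_noise_cv=0.0))


@pytest.fixture(scope="session")
def clustering_fixture():
    """Noise-free fixture without explicit DE plants (clean cluster geometry)."""
    return sd.generate_fixture(
        sd.SyntheticConfig(seed=3, fpkm_noise_cv=0.0, de_fraction=0.0)
    )


@pytest.fixture(scope="session")
def discovery_result(clean_fixture):
    fx = clean_fixture
    retained, expr, report = td.run_discovery(
        fx.isotigs, fx.genome.annotation, fx.expression, fx.genome.catalog
    )
    return retained, expr, report


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
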