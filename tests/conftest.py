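import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from seropanel.pipeline import analyze_cohort
from seropanel.positivity import fit_cutoffs
from seropanel.simulate import crc_like_config, generate

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def crc_cohort():
    """The bundled CRC-like synthetic cohort at study size (94 HD / 90 cancer)."""
    return generate(crc_like_config(seed=0))


@pytest.fixture(scope="session")
def crc_models(crc_cohort):
    return fit_cutoffs(crc_cohort)


@pytest.fixture(scope="session")
def crc_results(crc_cohort):
    """Full in-memory analysis of the bundled cohort (computed once)."""
    return analyze_cohort(crc_cohort, candidate="FIRdexon2")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
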