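import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from peritomorph import SectionParams, generate_section

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: Reduced-scale infant-parameter section used by several suites: small
#: enough to keep the full suite fast, large enough for ~30 vessels.
SMALL_AREA = 0.15  # mm²


@pytest.fixture(scope="session")
def infant_params():
    return SectionParams(analyzed_area=SMALL_AREA, seed=20160219)


@pytest.fixture(scope="session")
def infant_sample(infant_params):
    """One full synthetic infant sample: all four channels plus truth."""
    sections, truth = generate_section(infant_params)
    return sections, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160219)
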