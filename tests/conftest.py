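import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import saccadapt as sa
from saccadapt.model import NoiseSpec
from saccadapt.synth import SubjectSpec

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(params=["CTS_in", "CTS_out", "CVE_in", "CVE_out"])
def any_condition(request):
    return sa.condition(request.param)


@pytest.fixture(scope="session")
def noiseless_session():
    """One clean CTS_in session: no motor/report noise, default filter violations."""
    spec = SubjectSpec(
        condition=sa.condition("CTS_in"), noise=NoiseSpec(0.0, 0.0), seed=7
    )
    return spec, sa.simulate_subject(spec)
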