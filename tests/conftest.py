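import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def kappa_germline():
    from baddisplay.references import synthetic_kappa_germline

    return synthetic_kappa_germline()


@pytest.fixture(scope="session")
def heavy_germline():
    from baddisplay.references import synthetic_heavy_germline

    return synthetic_heavy_germline()
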