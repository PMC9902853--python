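import pytest
from hypothesis import HealthCheck, settings

from tauflow.kinetics import SRTMParams, make_basis, srtm_model_tac
from tauflow.simulate import default_schedule, reference_tac

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def schedule():
    return default_schedule()


@pytest.fixture(scope="session")
def ref(schedule):
    """Noiseless reference-region TAC on the default 130-min schedule."""
    return reference_tac(schedule=schedule)


@pytest.fixture(scope="session")
def basis(ref):
    return make_basis(ref)


@pytest.fixture(scope="session")
def canonical_params():
    return SRTMParams(R1=0.85, k2=0.0425, BPND=0.6)


@pytest.fixture(scope="session")
def canonical_target(ref, canonical_params):
    return srtm_model_tac(canonical_params, ref)
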