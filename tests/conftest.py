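import pytest

from phenoparasite import ModelParameters, PhenologyTraits, SeasonBoundaryState


@pytest.fixture(scope="session")
def params_tau3() -> ModelParameters:
    """Standard parameter set with a long latency period (one infection
    generation per season)."""
    return ModelParameters(tau=3.0)


@pytest.fixture(scope="session")
def params_tau15() -> ModelParameters:
    """Standard parameter set with a short latency period (multiple
    infection generations per season)."""
    return ModelParameters(tau=1.5)


@pytest.fixture(scope="session")
def base_traits() -> PhenologyTraits:
    """The reference phenology: emergence starts at 0 over a pulse of 0.5."""
    return PhenologyTraits(t0=0.0, tl=0.5)


@pytest.fixture(scope="session")
def no_parasites() -> SeasonBoundaryState:
    return SeasonBoundaryState(s_hat=1e4, v_hat=0.0)
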