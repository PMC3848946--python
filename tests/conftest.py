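import pytest

from thetagamma import ModelParams


@pytest.fixture
def excitable_params() -> ModelParams:
    """Excitable reference set: IE=-0.5, lam=1, strong inhibition."""
    return ModelParams(IE=-0.5, lam=1.0, gIE=6.0, epsI=0.1, epsTheta=0.01, omega=4.0)


@pytest.fixture
def oscillator_params() -> ModelParams:
    """Oscillator reference set: IE=0.5, lam=0.8, strong inhibition."""
    return ModelParams(IE=0.5, lam=0.8, gIE=6.0, epsI=0.1, epsTheta=0.01, omega=4.0)
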