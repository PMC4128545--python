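import pytest

from phagecommons import ModelParameters, SimulationSpec, StateVector


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    """Baseline rate constants (the packaged defaults)."""
    return ModelParameters()


@pytest.fixture(scope="session")
def equal_burst_params(params) -> ModelParameters:
    return params.with_bursts("equal")


def fast_spec(params, **overrides) -> SimulationSpec:
    """A coarse-step two-phage spec for quick dynamical tests."""
    defaults = dict(
        params=params,
        initial_state=StateVector(B=2.5e8, R=2.5e8, P_G=1e4, P_W=1e4),
        t_end=1500.0,
        dt=0.01,
    )
    defaults.update(overrides)
    return SimulationSpec(**defaults)
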