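import numpy as np
import pytest

from prebotc_memristor.model_core import ModelParams
from prebotc_memristor.simulate import SimConfig, Trajectory, integrate_full


@pytest.fixture(scope="session")
def p_default() -> ModelParams:
    return ModelParams()


@pytest.fixture(scope="session")
def fig2_traj() -> Trajectory:
    """Reference no-stimulus bursting run (Iextz=0, k1=0), transient removed."""
    return integrate_full(SimConfig(params=ModelParams(Iextz=0.0, k1=0.0)))


@pytest.fixture(scope="session")
def fig3b_traj() -> Trajectory:
    """Low-current bursting run (Iextz=5, k1=0.1)."""
    return integrate_full(SimConfig(params=ModelParams(Iextz=5.0, k1=0.1)))


@pytest.fixture(scope="session")
def fig3f_traj() -> Trajectory:
    """High-current run with depolarized quiescence (Iextz=50, k1=0.1)."""
    return integrate_full(SimConfig(params=ModelParams(Iextz=50.0, k1=0.1)))


def synthetic_trajectory(t, V, p=None, **extra) -> Trajectory:
    """Build a Trajectory from arrays (for detector tests)."""
    states = {"V": np.asarray(V, float)}
    states.update({k: np.asarray(v, float) for k, v in extra.items()})
    return Trajectory(np.asarray(t, float), states, p or ModelParams(), {})
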