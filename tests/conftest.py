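import numpy as np
import pytest

from colicomp import CommunityParams, State
from colicomp.synth import gen_competition_scenarios


@pytest.fixture(scope="session")
def generic_params() -> CommunityParams:
    """An asymmetric, fully general parameter set for oracle checks."""
    return CommunityParams(
        beta_A=1.2, beta_B=0.9, delta=0.1,
        kill_AonB=0.7, kill_BonA=0.4,
        induce_AonB=3.0, induce_BonA=5.0,
        s=0.05, d=0.8, epsilon=0.2,
    )


@pytest.fixture(scope="session")
def generic_state() -> State:
    return State(u_A=0.3, u_B=0.2, c_A=0.1, c_B=0.25)


@pytest.fixture(scope="session")
def scenarios():
    return gen_competition_scenarios()


@pytest.fixture(scope="session")
def spatial_asym_params() -> CommunityParams:
    """Strain A clearly more potent; mild mutual induction; plate-like diffusion."""
    return CommunityParams(
        beta_A=1.0, beta_B=1.0, delta=0.1, s=0.05, d=1.0,
        kill_AonB=2.0, kill_BonA=1.0, induce_AonB=2.0, induce_BonA=2.0,
        D_u=0.1, D_c=1.0,
    )


@pytest.fixture(scope="session")
def spatial_sym_params() -> CommunityParams:
    return CommunityParams(
        beta_A=1.0, beta_B=1.0, delta=0.1, s=0.05, d=1.0,
        kill_AonB=1.5, kill_BonA=1.5, induce_AonB=2.0, induce_BonA=2.0,
        D_u=0.1, D_c=1.0,
    )


def rk4_reference(params, y0: np.ndarray, horizon: float, dt: float) -> np.ndarray:
    """Fixed-step classical Runge-Kutta reference integration.

    Independent of the package's adaptive integrator; used as the fine-step
    oracle for trajectory accuracy checks.
    """
    from colicomp import rhs_homogeneous

    n = int(round(horizon / dt))
    y = y0.astype(float).copy()
    for _ in range(n):
        k1 = rhs_homogeneous(y, params)
        k2 = rhs_homogeneous(y + 0.5 * dt * k1, params)
        k3 = rhs_homogeneous(y + 0.5 * dt * k2, params)
        k4 = rhs_homogeneous(y + dt * k3, params)
        y = y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return y
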