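import numpy as np
import pytest

from contpsych import BPParams, SpringFit, WalkConfig, gen_session_walk, simulate_session


@pytest.fixture(scope="session")
def default_params() -> BPParams:
    return BPParams()


@pytest.fixture(scope="session")
def noiseless_params() -> BPParams:
    return BPParams(sigma_omega2=0.0, sigma_psi2=0.0, sigma_phi2=0.0, sigma_lambda2=0.0)


@pytest.fixture(scope="session")
def rightward_cfg() -> WalkConfig:
    return WalkConfig(seed=13)


@pytest.fixture(scope="session")
def symmetric_cfg() -> WalkConfig:
    return WalkConfig(range_lo=-90.0, range_hi=90.0, duration=250.0, seed=13)


def true_spring(params: BPParams, dt: float = 0.05) -> SpringFit:
    """SpringFit holding the generative action parameters (no fit noise)."""
    return SpringFit(
        b=params.b,
        c=params.c,
        delta_t=params.delta_t,
        delta_t_hat=params.delta_t,
        sigma_omega2_hat=params.sigma_omega2,
        n_steps=0,
        rss=0.0,
        dt=dt,
    )


@pytest.fixture(scope="session")
def default_session(default_params, rightward_cfg):
    """One simulated default session, shared across read-only tests."""
    walk = gen_session_walk(rightward_cfg)
    return simulate_session(walk, default_params, seed=77)
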