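"""Independent oracles used by the tests.

These deliberately avoid the package's own filtering code paths: the grid
posterior is brute-force sequential Bayes on a discretized state space.
"""

from __future__ import annotations

import numpy as np


def grid_posterior_means(
    obs: np.ndarray,
    process_var: float,
    obs_var: float,
    prior_mean: float,
    prior_var: float,
    span: float = 60.0,
    n_grid: int = 12001,
) -> np.ndarray:
    """Sequential Bayes posterior means for a Gaussian random-walk state.

    The state performs a random walk with step variance ``process_var`` and
    is observed with Gaussian noise ``obs_var``.  The posterior is tracked
    on a dense grid: predict = convolve with the step kernel, update =
    multiply by the likelihood.  Returns the posterior mean after each
    observation.
    """
    center = float(np.mean(obs))
    grid = np.linspace(center - span, center + span, n_grid)
    h = grid[1] - grid[0]
    post = np.exp(-0.5 * (grid - prior_mean) ** 2 / prior_var)
    post /= post.sum()

    if process_var > 0:
        half = int(np.ceil(6.0 * np.sqrt(process_var) / h))
        kx = np.arange(-half, half + 1) * h
        kernel = np.exp(-0.5 * kx**2 / process_var)
        kernel /= kernel.sum()
    else:
        kernel = None

    means = np.empty(obs.size)
    for t, X in enumerate(obs):
        if t > 0 and kernel is not None:
            post = np.convolve(post, kernel, mode="same")
        like = np.exp(-0.5 * (grid - X) ** 2 / obs_var)
        post = post * like
        s = post.sum()
        if s <= 0:
            raise RuntimeError("grid posterior underflow; widen the span")
        post /= s
        means[t] = float(np.dot(grid, post))
    return means


def steady_state_prior_variance(process_var: float, obs_var: float) -> float:
    """Fixed point of the Kalman prior-variance recursion S = P + Q."""
    q, r = process_var, obs_var
    return 0.5 * (q + np.sqrt(q * q + 4.0 * q * r))
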