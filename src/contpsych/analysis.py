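"""Inverse analysis: from raw (x, y) to the ideal series (x*, y*).

The analysis mirrors the generative model of :mod:`contpsych.agent`:

* ``x*`` is the constant-gain filter estimate of the background direction
  run on the raw x data -- the experimenter's model of the participant's
  internal background estimate.
* ``y_hat`` is the constant-gain filter estimate of the target direction,
  with the observed per-step increments standing in for the intended
  actions.  The gain is small when the motor noise is small relative to the
  sensory noise, so the unintended component of the increments is strongly
  attenuated.
* The intended (spring-driven) component of the actions is inverted to
  recover the perceived-deviation series that must have driven them,
  and ``y* = y_hat - y_tilde`` corrects the target estimate for deviations
  of perceived target direction from the goal.

The decomposed lags are reported alongside: the group delay of the sensory
filter, the reaction plus rise time of the action system, and whatever
residual lag remains between x* and y* (zero when the model fully accounts
for the dynamics).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from .agent import BPParams, SessionRecord, gain_or_default
from .errors import ConfigError
from .series import AngleSeries
from .training import SpringFit, _step_response


#: default prior on how fast the perceived deviation may change, deg per step
PERCEPT_STEP_SD = 1.0


def smooth_series(values: np.ndarray, dt: float, cutoff_hz: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth low-pass (no added group delay)."""
    nyq = 0.5 / dt
    wn = min(cutoff_hz / nyq, 0.99)
    b_coef, a_coef = butter(4, wn)
    return filtfilt(b_coef, a_coef, values)


def _spring_smoother(
    dy: np.ndarray,
    b: float,
    c: float,
    dt: float,
    motor_var: float,
    percept_step_sd: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Kalman (RTS) smoother for the damped-spring action system.

    Observations are the per-step position increments
    ``dy_t = dt * v_t + lambda_t`` with white motor noise ``lambda``.  The
    state is ``[v_t, e_t]`` where ``e`` is the error driving the spring:
    ``v_t = (1 - dt*c) v_{t-1} + dt*b*e_t`` and ``e`` follows a random walk
    with step SD ``percept_step_sd`` (a smoothness prior on the percept).
    Returns the smoothed ``(v, e)`` series -- the minimum-variance linear
    reconstruction of the intended velocity and its driving error.
    """
    n = dy.size
    a_v = 1.0 - dt * c
    g = dt * b
    F = np.array([[a_v, g], [0.0, 1.0]])
    q = percept_step_sd**2
    Q = q * np.array([[g * g, g], [g, 1.0]])
    H = np.array([dt, 0.0])
    R = max(motor_var, 1e-12)

    x_pred = np.zeros((n, 2))
    P_pred = np.zeros((n, 2, 2))
    x_filt = np.zeros((n, 2))
    P_filt = np.zeros((n, 2, 2))

    x = np.zeros(2)
    # diffuse-ish prior on the initial velocity and error
    P = np.diag([100.0, 400.0])
    for t in range(n):
        if t > 0:
            x = F @ x
            P = F @ P @ F.T + Q
        x_pred[t] = x
        P_pred[t] = P
        S = H @ P @ H + R
        K = (P @ H) / S
        x = x + K * (dy[t] - H @ x)
        P = P - np.outer(K, H @ P)
        x_filt[t] = x
        P_filt[t] = P

    x_s = x_filt.copy()
    for t in range(n - 2, -1, -1):
        C = P_filt[t] @ F.T @ np.linalg.inv(P_pred[t + 1])
        x_s[t] = x_filt[t] + C @ (x_s[t + 1] - x_pred[t + 1])
    return x_s[:, 0], x_s[:, 1]


@dataclass
class FinalSeries:
    """Analysis outputs: ideal series, recovered percepts and lags."""

    x_star: AngleSeries
    y_star: AngleSeries
    y_tilde_hat: AngleSeries
    lag_sense: float  # group delay of the x estimation filter, s
    lag_action: float  # reaction lag + spring rise time, s
    lag_residual: float  # remaining x*-y* cross-correlation lag, s
    k_x: float
    k_y: float


def constant_gain_filter(
    obs: np.ndarray, k: float, action: np.ndarray | None = None
) -> np.ndarray:
    """Scalar constant-gain filter ``est_t = (1-k)(est_{t-1} + a_t) + k obs_t``.

    ``action[t]`` is the known state change between t-1 and t (zero if not
    given).  The filter is initialized at the first observation.
    """
    if not 0.0 <= k <= 1.0:
        raise ConfigError(f"gain must lie in [0, 1], got {k}")
    obs = np.asarray(obs, dtype=float)
    est = np.empty_like(obs)
    est[0] = obs[0]
    if action is None:
        for t in range(1, obs.size):
            est[t] = (1.0 - k) * est[t - 1] + k * obs[t]
    else:
        for t in range(1, obs.size):
            est[t] = (1.0 - k) * (est[t - 1] + action[t]) + k * obs[t]
    return est


def estimate_states(
    session: SessionRecord, params: BPParams
) -> tuple[AngleSeries, AngleSeries, float, float]:
    """Filter the raw series into state estimates (x_hat, y_hat).

    ``k_x`` weighs new x data against the no-change prediction using the
    world step variance and x sensory noise; ``k_y`` weighs new y data
    against the action-updated prediction using the motor and y sensory
    noise, as the participant's own filter would.
    """
    p = params
    k_x = gain_or_default(p.sigma_mu2, p.sigma_omega2, 1.0)
    k_y = gain_or_default(p.sigma_lambda2, p.sigma_psi2, 0.0)
    x_hat = constant_gain_filter(session.x.values, k_x)
    dy = np.concatenate(([0.0], np.diff(session.y.values)))
    y_hat = constant_gain_filter(session.y.values, k_y, action=dy)
    xs = session.x.with_values(x_hat, filter_gain=k_x)
    ys = session.y.with_values(y_hat, filter_gain=k_y)
    return xs, ys, k_x, k_y


def invert_action(
    y_hat: AngleSeries,
    fit: SpringFit,
    goal: float = 0.0,
    motor_var: float = 0.22,
    percept_step_sd: float = PERCEPT_STEP_SD,
) -> tuple[AngleSeries, AngleSeries]:
    """Recover the perceived-deviation series that drove the actions.

    Naive double differencing of the target series amplifies the white
    motor noise by 1/(b*dt**2); instead the spring difference equation is
    inverted by a Kalman smoother over its own state space
    (:func:`_spring_smoother`): the minimum-variance linear estimate of the
    driving error given the motor-noise variance and a random-walk
    smoothness prior on the percept.  The recovered error is shifted
    forward by the fitted reaction lag so the percept series is
    time-aligned with the perception it estimates.

    Returns ``(y_tilde_hat, intended_a)``: the recovered percept series and
    the intended per-step actions ``dt * v_hat``, both on the input grid.
    """
    if fit.b <= 0:
        raise ConfigError(f"spring constant must be > 0, got {fit.b}")
    dt = y_hat.dt
    n = y_hat.n
    dy = np.concatenate(([0.0], np.diff(y_hat.values)))
    v_hat, e_hat = _spring_smoother(dy, fit.b, fit.c, dt, motor_var, percept_step_sd)
    y_tilde_applied = goal - e_hat

    # the error applied at step t was perceived at t - lag: shift left
    lag_steps = fit.delta_t / dt
    idx = np.arange(n) + lag_steps
    y_tilde = np.interp(idx, np.arange(n), y_tilde_applied)
    return (
        y_hat.with_values(y_tilde, lag_steps=lag_steps),
        y_hat.with_values(dt * v_hat),
    )


def spring_rise_time(fit: SpringFit, fraction: float = 0.5, horizon: float = 20.0) -> float:
    """Time for the closed-loop spring (no lag) to reach ``fraction`` of a step."""
    n = int(round(horizon / fit.dt))
    u = _step_response(fit.b, fit.c, 0.0, 1.0, n, fit.dt)
    idx = np.nonzero(u >= fraction)[0]
    return float(idx[0] * fit.dt) if idx.size else float(horizon)


def residual_lag(
    x_star: AngleSeries, y_star: AngleSeries, max_lag: float = 5.0
) -> float:
    """Cross-correlation argmax lag (s) between sin(x*) and sin(y*).

    Positive values mean y* still lags x* after the sensory and action lags
    have been compensated; a well-specified analysis leaves ~0.
    """
    dt = x_star.dt
    a = np.sin(np.radians(x_star.values))
    b = np.sin(np.radians(y_star.values))
    a = a - a.mean()
    b = b - b.mean()
    if np.std(a) < 1e-9 or np.std(b) < 1e-9:
        return 0.0  # a constant series carries no lag information
    m = min(int(round(max_lag / dt)), a.size - 1)
    lags = np.arange(-m, m + 1)
    cc = np.array([np.dot(a[: a.size - k], b[k:]) if k >= 0 else np.dot(a[-k:], b[: b.size + k])
                   for k in lags])
    # normalize by overlap length so long overlaps aren't favored
    cc = cc / (a.size - np.abs(lags))
    return float(lags[int(np.argmax(cc))] * dt)


def finalize(
    session: SessionRecord,
    params: BPParams,
    fit: SpringFit,
    discard: float = 10.0,
    percept_step_sd: float = PERCEPT_STEP_SD,
) -> FinalSeries:
    """Run the full inverse pipeline and report the ideal series and lags.

    The participant's internal target estimate is replicated by running the
    constant-gain filter on the raw y data with the *recovered intended*
    actions as the prediction input (so the unintended motor noise enters
    only through the small observation gain, as it does for the
    participant); ``y* = y_hat - y_tilde`` then corrects that estimate for
    the recovered deviations of perceived target direction from the goal.
    """
    x_hat, y_hat_raw, k_x, k_y = estimate_states(session, params)
    y_tilde, intended_a = invert_action(
        y_hat_raw, fit, goal=params.goal,
        motor_var=params.sigma_lambda2, percept_step_sd=percept_step_sd,
    )
    y_hat_vals = constant_gain_filter(session.y.values, k_y, action=intended_a.values)
    y_star_vals = y_hat_vals - y_tilde.values

    x_star = x_hat.discard_initial(discard)
    y_star = session.y.with_values(y_star_vals).discard_initial(discard)
    y_tilde_f = y_tilde.discard_initial(discard)

    lag_sense = x_hat.dt * (1.0 - k_x) / k_x if k_x > 0 else float("inf")
    lag_action = fit.delta_t + spring_rise_time(fit)
    lag_res = residual_lag(x_star, y_star)
    return FinalSeries(
        x_star=x_star,
        y_star=y_star,
        y_tilde_hat=y_tilde_f,
        lag_sense=lag_sense,
        lag_action=lag_action,
        lag_residual=lag_res,
        k_x=k_x,
        k_y=k_y,
    )
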