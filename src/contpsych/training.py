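"""Estimate a participant's action system from a blob-step training session.

The training stimulus is a blob whose direction jumps a fixed number of
degrees clockwise or anticlockwise at a fixed period; the participant steers
the target toward it.  The per-step responses are aligned on the jumps,
rectified so every driving step is positive, and averaged; the damped-spring
action model is then fit to the average response by least squares.  The
endpoint variance (target minus blob at the end of each step epoch)
estimates the shared sensory noise variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .agent import BPParams, delayed_value, simulate_training
from .errors import ConfigError, FitFailureError, InsufficientDataError, UnidentifiableError
from .series import AngleSeries

#: fraction of the step size the response must travel before it counts as
#: having departed from baseline (threshold lag estimator)
DEPARTURE_FRACTION = 0.05


@dataclass
class SpringFit:
    """Fitted action-system parameters and training-derived estimates.

    ``b`` (s**-2) and ``c`` (s**-1) are the spring and damping constants,
    ``delta_t`` the response lag from the spring fit (free parameter) and
    ``delta_t_hat`` the model-free threshold estimate of the same lag
    (time at which the average response first departs 5% of the step size
    from baseline).  ``sigma_omega2_hat`` is the endpoint-variance estimate
    of the sensory noise, shared across channels by the training assumption.
    """

    b: float
    c: float
    delta_t: float
    delta_t_hat: float
    sigma_omega2_hat: float
    n_steps: int
    rss: float
    dt: float

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ConfigError(f"fitted spring constant must be > 0, got {self.b}")
        if self.delta_t_hat < 0 or self.sigma_omega2_hat < 0:
            raise ConfigError("lag and variance estimates must be >= 0")


def _jump_indices(blob: AngleSeries) -> np.ndarray:
    """Indices i at which blob[i] != blob[i-1] (first sample of a new epoch)."""
    return np.nonzero(np.diff(blob.values) != 0.0)[0] + 1


def extract_step_responses(
    blob: AngleSeries, target: AngleSeries, step_period: float,
    min_time: float | None = None,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Aligned, rectified per-step response segments.

    For every blob jump (optionally restricted to jumps at or after
    ``min_time`` seconds, so a warm-up window can be excluded without losing
    the step on its boundary), the following ``step_period`` seconds of
    target data are re-zeroed to the pre-step target value and sign-flipped
    so that the driving step is positive.  Returns ``(segments, steps)``
    where ``steps`` holds the rectified (positive) driving step sizes.
    Segments that would run past the end of the session are dropped.
    """
    if not blob.same_grid(target):
        raise ConfigError("blob and target series must share the sampling grid")
    n_per = int(round(step_period / blob.dt))
    jumps = _jump_indices(blob)
    times = blob.times
    segments: list[np.ndarray] = []
    steps: list[float] = []
    for j in jumps:
        if min_time is not None and times[j] < min_time - 1e-9:
            continue
        if j + n_per > target.n:
            break
        jump = blob.values[j] - blob.values[j - 1]
        sign = 1.0 if jump >= 0 else -1.0
        seg = sign * (target.values[j : j + n_per] - target.values[j - 1])
        segments.append(seg)
        steps.append(sign * jump)
    if len(segments) < 2:
        raise InsufficientDataError(
            f"found {len(segments)} usable blob steps; need at least 2"
        )
    return segments, np.asarray(steps)


def average_response(segments: list[np.ndarray]) -> np.ndarray:
    """Element-wise mean of the rectified step-response segments."""
    return np.mean(np.asarray(segments), axis=0)


def threshold_lag(avg_response: np.ndarray, step_size: float, dt: float) -> float:
    """Model-free lag: time to first departure of 5% of the step size."""
    idx = np.nonzero(np.abs(avg_response) >= DEPARTURE_FRACTION * abs(step_size))[0]
    return float(idx[0] * dt) if idx.size else float(avg_response.size * dt)


def _step_response(b: float, c: float, delta_t: float, step: float, n: int, dt: float) -> np.ndarray:
    """From-rest response of the lagged closed-loop spring to one step."""
    u = np.zeros(n)
    err = np.empty(n)
    lag_steps = delta_t / dt
    v = 0.0
    for t in range(n - 1):
        err[t] = step - u[t]
        e_lag = delayed_value(err[:t + 1], t, lag_steps)
        v = v + dt * (b * e_lag - c * v)
        u[t + 1] = u[t] + dt * v
    return u


#: coarse (b, c) grid used to seed the least-squares refinement; the
#: objective is multimodal for lightly damped springs, so local descent
#: alone is not reliable
_B_GRID = (0.05, 0.1, 0.2, 0.375, 0.7, 1.3)
_C_GRID = (0.005, 0.02, 0.08, 0.3, 0.9, 2.0)


def _seeded_starts(residual, fit_lag: bool, max_lag: float, n_keep: int = 3):
    """Rank coarse grid points by residual norm; return the best as starts."""
    lags = (0.0, min(0.4, max_lag)) if fit_lag else (None,)
    scored = []
    for b in _B_GRID:
        for c in _C_GRID:
            for lag in lags:
                theta = (b, c) if lag is None else (b, c, lag)
                try:
                    cost = float(np.sum(residual(theta) ** 2))
                except Exception:
                    continue
                if np.isfinite(cost):
                    scored.append((cost, theta))
    scored.sort(key=lambda t: t[0])
    return [theta for _, theta in scored[:n_keep]]


def _multistart_lsq(residual, x0s, bounds):
    best = None
    for x0 in x0s:
        try:
            res = least_squares(residual, x0, bounds=bounds, method="trf")
        except Exception:  # singular jacobian etc.; try the next start
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitFailureError("spring fit failed from every starting point")
    return best


def fit_spring(
    avg_response: np.ndarray,
    step_size: float,
    dt: float,
    fit_lag: bool = True,
    max_lag: float = 2.0,
) -> SpringFit:
    """Least-squares fit of the damped-spring difference equation to an
    average step response.

    The model is the from-rest response of the lagged closed-loop spring to
    a single step of ``step_size`` degrees.  ``b``, ``c`` (and the lag, if
    ``fit_lag``) are free parameters; multiple starting points guard
    against local minima.
    """
    avg_response = np.asarray(avg_response, dtype=float)
    n = avg_response.size
    if n < 10:
        raise InsufficientDataError(f"average response has {n} samples; need >= 10")
    if step_size == 0 or np.allclose(avg_response, avg_response[0]):
        raise UnidentifiableError(
            "no excitation: step size is zero or the response never moves"
        )

    if fit_lag:
        def residual(theta):
            b, c, lag = theta
            return _step_response(b, c, lag, step_size, n, dt) - avg_response

        bounds = ([1e-4, 0.0, 0.0], [20.0, 20.0, max_lag])
    else:
        def residual(theta):
            b, c = theta
            return _step_response(b, c, 0.0, step_size, n, dt) - avg_response

        bounds = ([1e-4, 0.0], [20.0, 20.0])

    best = _multistart_lsq(residual, _seeded_starts(residual, fit_lag, max_lag), bounds)
    b, c = best.x[0], best.x[1]
    lag = best.x[2] if fit_lag else 0.0
    rss = float(2.0 * best.cost)
    return SpringFit(
        b=float(b),
        c=float(c),
        delta_t=float(lag),
        delta_t_hat=threshold_lag(avg_response, step_size, dt),
        sigma_omega2_hat=0.0,
        n_steps=0,
        rss=rss,
        dt=dt,
    )


def estimate_endpoint_variance(blob: AngleSeries, target: AngleSeries) -> float:
    """Sample variance of (target - blob) at the final sample of each epoch.

    This is the training estimate of the shared sensory noise variance
    (n - 1 denominator).
    """
    if not blob.same_grid(target):
        raise ConfigError("blob and target series must share the sampling grid")
    jumps = _jump_indices(blob)
    if jumps.size < 2:
        raise InsufficientDataError("need at least 2 blob steps to estimate endpoint variance")
    ends = np.concatenate([jumps - 1, [blob.n - 1]])
    diffs = target.values[ends] - blob.values[ends]
    return float(np.var(diffs, ddof=1))


def _session_average(blob: AngleSeries, target: AngleSeries, step_period: float, discard: float):
    """Extract post-warm-up responses, rectify and average.

    Jumps inside the first ``discard`` seconds are excluded; the step on
    the discard boundary itself still counts (its pre-step baseline is the
    last warm-up sample).
    """
    segments, steps = extract_step_responses(
        blob, target, step_period, min_time=blob.t0 + discard
    )
    return average_response(segments), float(np.mean(steps)), len(segments)


def fit_training_session(
    blob: AngleSeries,
    target: AngleSeries,
    step_period: float = 5.0,
    discard: float = 10.0,
    replay: bool = True,
    fit_lag: bool = True,
    max_lag: float = 2.0,
) -> SpringFit:
    """Full training analysis: average step response -> spring parameters.

    With ``replay=True`` the model prediction for a candidate (b, c, lag)
    is obtained by running the deterministic (noise-free) closed loop over
    the *whole* blob sequence and passing it through the same
    extract/rectify/average pipeline as the data.  This accounts for the
    spring state carried over from one step epoch into the next, which the
    single from-rest step model ignores; with ``replay=False`` the simpler
    from-rest model of :func:`fit_spring` is used.
    """
    avg, step, n_steps = _session_average(blob, target, step_period, discard)
    n = avg.size
    dt = blob.dt

    if replay:
        quiet = BPParams(
            sigma_phi2=0.0, sigma_psi2=0.0, sigma_lambda2=0.0, b=1.0, c=0.0, delta_t=0.0
        )
        y0 = float(target.values[0])

        def model_average(b, c, lag):
            p = quiet.replace(b=b, c=c, delta_t=lag)
            sim = simulate_training(blob, p, seed=0, y0=y0)
            m_avg, _, _ = _session_average(blob, sim.y, step_period, discard)
            return m_avg

        if np.allclose(avg, avg[0]):
            raise UnidentifiableError("no excitation in the averaged training response")

        if fit_lag:
            def residual(theta):
                return model_average(theta[0], theta[1], theta[2]) - avg

            bounds = ([1e-4, 0.0, 0.0], [20.0, 20.0, max_lag])
        else:
            def residual(theta):
                return model_average(theta[0], theta[1], 0.0) - avg

            bounds = ([1e-4, 0.0], [20.0, 20.0])

        best = _multistart_lsq(residual, _seeded_starts(residual, fit_lag, max_lag), bounds)
        fit = SpringFit(
            b=float(best.x[0]),
            c=float(best.x[1]),
            delta_t=float(best.x[2]) if fit_lag else 0.0,
            delta_t_hat=threshold_lag(avg, step, dt),
            sigma_omega2_hat=0.0,
            n_steps=n_steps,
            rss=float(2.0 * best.cost),
            dt=dt,
        )
    else:
        fit = fit_spring(avg, step, dt, fit_lag=fit_lag, max_lag=max_lag)
        fit.n_steps = n_steps

    fit.sigma_omega2_hat = estimate_endpoint_variance(
        blob.discard_initial(discard), target.discard_initial(discard)
    )
    return fit
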