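"""Generative model of a Bayesian participant in a continuous-correction task.

The participant is modelled in three stages, iterated once per stimulus
update:

Sensation
    Constant-gain Bayesian filtering of noisy sensory copies of the
    independent (background, ``x``) and dependent (target, ``y``) direction
    angles.  Because the model assumes the internal and external noise
    variances are constant throughout a session, the filter gain is fixed at
    the steady-state value of the scalar random-walk Kalman recursion
    (:func:`steady_state_gain`).  The expectation for ``x`` is "no change"
    (the world steps have zero mean); the expectation for ``y`` is the
    previous estimate updated by the participant's own intended action.

Perception
    The two estimates interact: the perceived direction of the target
    acquires a motion component opposite to the background (induced motion).
    In horizontal-component (sine) space::

        sin(y_perceived) = sin(y_hat) - beta * sin(x_hat) + d

    where ``beta`` is the induced-motion strength and ``d`` a constant
    offset.  An optional linear-accumulation adaptation term reduces the
    sensed horizontal component of the target by ``q`` times the running sum
    of exposure (see :mod:`contpsych.adaptation`).

Action
    A lagged, damped spring drives the dependent variable toward the goal:
    the action velocity integrates a restoring force ``b`` times the
    perceived error and a damping force ``c`` times the velocity (explicit
    Euler at ``dt``); the error is read from a delay line ``delta_t``
    seconds in the past.  Gaussian motor noise is added to the realized
    position step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateModelError, StabilityError
from .series import AngleSeries

#: velocity bound (deg/s) beyond which the action system is declared divergent
V_GUARD = 1e6


@dataclass
class BPParams:
    """All generative-model parameters of the Bayesian participant.

    Variances are in deg**2 per update step; ``b`` (spring constant,
    s**-2), ``c`` (damping, s**-1) and ``delta_t`` (reaction lag, s) define
    the action system; ``beta`` (unitless) and ``d`` (unitless, horizontal
    component) define the induced-motion perception stage; ``q`` is the
    per-step adaptation rate and ``speed`` the global motion speed in deg/s.

    The default damping keeps the closed loop formed by the spring and the
    reaction lag stable (which requires roughly ``c > b * delta_t``) with a
    2x margin, and yields the moderately underdamped, overshooting step
    responses participants produce; per-participant values of ``b`` and
    ``c`` are normally estimated from a training session.
    """

    sigma_mu2: float = 2.25  # world step variance of the background walk
    sigma_omega2: float = 1.6  # sensory noise on x
    sigma_psi2: float = 1.6  # sensory noise on y
    sigma_phi2: float = 1.6  # sensory noise on the training blob
    sigma_lambda2: float = 0.22  # action (motor) noise
    b: float = 0.375
    c: float = 0.3
    delta_t: float = 0.4
    beta: float = 0.71
    d: float = 0.0
    q: float = 0.0
    goal: float = 0.0  # degrees clockwise from vertical
    speed: float = 6.0  # deg/s

    def __post_init__(self) -> None:
        for name in ("sigma_mu2", "sigma_omega2", "sigma_psi2", "sigma_phi2", "sigma_lambda2"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.b <= 0:
            raise ConfigError(f"spring constant b must be > 0, got {self.b}")
        if self.c < 0:
            raise ConfigError(f"damping constant c must be >= 0, got {self.c}")
        if self.delta_t < 0:
            raise ConfigError(f"reaction lag delta_t must be >= 0, got {self.delta_t}")
        if self.q < 0:
            raise ConfigError(f"adaptation rate q must be >= 0, got {self.q}")
        if self.speed <= 0:
            raise ConfigError(f"speed must be > 0, got {self.speed}")

    @classmethod
    def with_sensory_noise(cls, variance: float, **kwargs) -> "BPParams":
        """Constructor for the training assumption that the sensory noise is
        shared across channels (x, y and the blob)."""
        return cls(
            sigma_omega2=variance, sigma_psi2=variance, sigma_phi2=variance, **kwargs
        )

    def replace(self, **kwargs) -> "BPParams":
        return replace(self, **kwargs)


@dataclass
class AgentState:
    """Internal state of the agent at one step (exposed for truth records)."""

    x_hat: float = 0.0
    y_hat: float = 0.0
    y_tilde: float = 0.0
    v: float = 0.0
    adapt_sum: float = 0.0


@dataclass
class SessionRecord:
    """A raw session: aligned (x, y) series plus optional simulation truth."""

    x: AngleSeries
    y: AngleSeries
    truth: pd.DataFrame | None = None
    params: BPParams | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.x.same_grid(self.y):
            raise ConfigError("x and y series must share t0, dt and length")

    @property
    def dt(self) -> float:
        return self.x.dt


def steady_state_gain(process_var: float, obs_var: float) -> float:
    """Fixed-point gain of the scalar constant-gain filter for a random walk.

    For a state performing a Gaussian random walk with step variance
    ``process_var`` observed with noise variance ``obs_var``, the Kalman
    variance recursion ``P <- (1 - k)(P + Q)``, ``k = (P + Q)/(P + Q + R)``
    has the fixed point::

        k = (-r + sqrt(r**2 + 4 r)) / 2,   r = process_var / obs_var

    The gain is strictly increasing in ``r``: a fast-moving world or precise
    senses push ``k`` toward 1 (trust the data), a slow world or noisy
    senses push it toward 0 (trust the prediction).
    """
    if process_var < 0 or obs_var < 0:
        raise ConfigError("variances must be >= 0")
    if process_var == 0 and obs_var == 0:
        raise DegenerateModelError(
            "both process and observation variance are zero; the gain is undefined"
        )
    if obs_var == 0:
        return 1.0
    if process_var == 0:
        return 0.0
    r = process_var / obs_var
    return 0.5 * (-r + math.sqrt(r * r + 4.0 * r))


def gain_or_default(process_var: float, obs_var: float, default: float) -> float:
    """Steady-state gain, with a stated convention for the degenerate case.

    When both variances are zero every gain yields exact estimates; the
    caller supplies the convention (1 = trust the data, 0 = trust the
    prediction) instead of failing.
    """
    if process_var == 0 and obs_var == 0:
        return default
    return steady_state_gain(process_var, obs_var)


def sense_step(
    x_hat_prev: float,
    y_hat_prev: float,
    X: float,
    Y: float,
    intended_a: float,
    k_x: float,
    k_y: float,
) -> tuple[float, float]:
    """One constant-gain update of the two world-state estimates.

    ``X`` and ``Y`` are the current (noisy) sensory data.  The x expectation
    is the previous estimate (zero-mean world steps); the y expectation is
    the previous estimate advanced by the known intended action.
    """
    if not (0.0 <= k_x <= 1.0 and 0.0 <= k_y <= 1.0):
        raise ConfigError(f"gains must lie in [0, 1], got k_x={k_x}, k_y={k_y}")
    x_hat = (1.0 - k_x) * x_hat_prev + k_x * X
    y_hat = (1.0 - k_y) * (y_hat_prev + intended_a) + k_y * Y
    return x_hat, y_hat


def perceive(
    x_hat: float,
    y_hat: float,
    beta: float,
    d: float,
    adapt_offset: float = 0.0,
) -> tuple[float, bool]:
    """Perceived target deviation from vertical, degrees.

    Combines the two estimates in horizontal-component space (unit-speed
    vectors): ``h = sin(y_hat) - adapt_offset - beta*sin(x_hat) + d`` and
    returns ``asin(h)`` in degrees.  ``adapt_offset`` is the accumulated
    adaptation correction already expressed as a unit-speed horizontal
    component.  ``h`` is clipped to [-1, 1]; the second return value flags
    whether clipping occurred.
    """
    h = (
        math.sin(math.radians(y_hat))
        - adapt_offset
        - beta * math.sin(math.radians(x_hat))
        + d
    )
    clipped = not -1.0 <= h <= 1.0
    if clipped:
        h = max(-1.0, min(1.0, h))
    return math.degrees(math.asin(h)), clipped


def act_step(
    v: float, error: float, b: float, c: float, dt: float
) -> tuple[float, float]:
    """One explicit-Euler step of the unit-mass damped spring.

    ``v <- v + dt * (b * error - c * v)``; the intended position step is
    ``dt * v``.  Returns ``(v_new, intended_a)``.  Divergent velocities
    raise :class:`StabilityError`.
    """
    if dt <= 0:
        raise ConfigError(f"dt must be > 0, got {dt}")
    v_new = v + dt * (b * error - c * v)
    if not np.isfinite(v_new) or abs(v_new) > V_GUARD:
        raise StabilityError(
            f"action system diverged (|v| > {V_GUARD:g} deg/s) for b={b}, c={c}, dt={dt}"
        )
    return v_new, dt * v_new


def delayed_value(history: np.ndarray, t: int, lag_steps: float, fill: float = 0.0) -> float:
    """Value of ``history`` at fractional index ``t - lag_steps``.

    Fractional lags are linearly interpolated; indices before the start of
    the session return ``fill`` (no perceived error before stimulus onset).
    """
    idx = t - lag_steps
    if idx <= 0:
        return fill if idx < 0 else float(history[0])
    lo = int(math.floor(idx))
    frac = idx - lo
    if frac == 0.0 or lo + 1 >= history.size:
        return float(history[lo])
    return float((1.0 - frac) * history[lo] + frac * history[lo + 1])


def simulate_session(
    walk: AngleSeries, params: BPParams, seed: int, y0: float | None = None
) -> SessionRecord:
    """Simulate a full continuous-correction session.

    The world x follows ``walk``; per step the agent senses noisy copies of
    x and y, filters them with the steady-state gains, perceives the target
    deviation (with optional adaptation), and acts through the lagged damped
    spring; motor noise corrupts the realized step.  The full internal truth
    (sensed values, estimates, percepts, intended actions) is stored for
    validation of the inverse analysis.
    """
    p = params
    n = walk.n
    dt = walk.dt
    rng = np.random.default_rng(seed)
    k_x = gain_or_default(p.sigma_mu2, p.sigma_omega2, 1.0)
    k_y = gain_or_default(p.sigma_lambda2, p.sigma_psi2, 0.0)
    lag_steps = p.delta_t / dt

    omega = rng.normal(0.0, math.sqrt(p.sigma_omega2), size=n)
    psi = rng.normal(0.0, math.sqrt(p.sigma_psi2), size=n)
    lam = rng.normal(0.0, math.sqrt(p.sigma_lambda2), size=n)

    x = walk.values
    y = np.empty(n)
    y[0] = p.goal if y0 is None else y0

    X = np.empty(n)
    Y = np.empty(n)
    xh = np.empty(n)
    yh = np.empty(n)
    yt = np.empty(n)
    a = np.empty(n)

    v = 0.0
    a_prev = 0.0
    adapt_sum = 0.0
    n_clipped = 0

    for t in range(n):
        X[t] = x[t] + omega[t]
        Y[t] = y[t] + psi[t]
        if t == 0:
            xh[t] = X[t]
            yh[t] = Y[t]
        else:
            xh[t], yh[t] = sense_step(xh[t - 1], yh[t - 1], X[t], Y[t], a_prev, k_x, k_y)
        adapt_offset = p.q * adapt_sum / p.speed
        yt[t], clipped = perceive(xh[t], yh[t], p.beta, p.d, adapt_offset)
        n_clipped += clipped
        error = p.goal - delayed_value(yt, t, lag_steps, fill=p.goal)
        v, a[t] = act_step(v, error, p.b, p.c, dt)
        if t + 1 < n:
            y[t + 1] = y[t] + a[t] + lam[t]
        # exposure accumulates over completed steps: the percept at step t
        # sees the sum of horizontal components for all steps before t
        adapt_sum += p.speed * math.sin(math.radians(y[t]))
        a_prev = a[t]

    truth = pd.DataFrame(
        {"X": X, "Y": Y, "x_hat": xh, "y_hat": yh, "y_tilde": yt, "a": a}
    )
    y_series = AngleSeries(
        dt=dt,
        values=y,
        t0=walk.t0,
        meta={"seed": seed, "k_x": k_x, "k_y": k_y, "n_clipped": n_clipped},
    )
    return SessionRecord(x=walk, y=y_series, truth=truth, params=p, seed=seed)


def simulate_training(
    blob: AngleSeries, params: BPParams, seed: int, y0: float | None = None
) -> SessionRecord:
    """Simulate a training session: the agent steers the target toward a
    stepping blob.

    The perceived error is the sensed blob angle minus the sensed target
    angle (sensory noise ``sigma_phi2`` and ``sigma_psi2`` respectively),
    read through the same ``delta_t`` delay line as the main session, and
    drives the same damped spring; motor noise corrupts the realized step.
    There is no coherent background during training, so the perception
    stage reduces to this direct comparison.
    """
    p = params
    n = blob.n
    dt = blob.dt
    rng = np.random.default_rng(seed)
    lag_steps = p.delta_t / dt

    phi = rng.normal(0.0, math.sqrt(p.sigma_phi2), size=n)
    psi = rng.normal(0.0, math.sqrt(p.sigma_psi2), size=n)
    lam = rng.normal(0.0, math.sqrt(p.sigma_lambda2), size=n)

    blob_vals = blob.values
    y = np.empty(n)
    y[0] = blob_vals[0] if y0 is None else y0
    err = np.empty(n)
    a = np.empty(n)
    v = 0.0

    for t in range(n):
        err[t] = (blob_vals[t] + phi[t]) - (y[t] + psi[t])
        e_lagged = delayed_value(err, t, lag_steps)
        v, a[t] = act_step(v, e_lagged, p.b, p.c, dt)
        if t + 1 < n:
            y[t + 1] = y[t] + a[t] + lam[t]

    truth = pd.DataFrame({"error": err, "a": a})
    y_series = AngleSeries(dt=dt, values=y, t0=blob.t0, meta={"seed": seed})
    return SessionRecord(x=blob, y=y_series, truth=truth, params=p, seed=seed)
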