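"""Linear-accumulation motion adaptation: model, removal and rate fitting.

Prolonged exposure to motion with a persistent horizontal component lowers
sensitivity to that component, and the participant compensates by steering
the target further in the adapted direction.  The model is deliberately
simple: the loss of sensed horizontal speed at step t equals a constant
``q`` times the running sum of the horizontal components over all previous
steps.  De-adaptation subtracts that term; the rate ``q`` is found by a
bounded 1-D search that drives the regression of de-adapted target
components on background components through a chosen intercept (the origin,
unless the participant carries a genuine constant bias).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import linregress

from .errors import ConfigError, UnidentifiableError
from .series import AngleSeries


@dataclass
class AdaptationFit:
    """Estimated adaptation rate and the intercept it achieves."""

    q: float  # per-step rate (>= 0)
    target_intercept: float  # requested intercept, degrees
    achieved_intercept: float  # intercept at the optimum, degrees
    n_iter: int

    def __post_init__(self) -> None:
        if self.q < 0:
            raise ConfigError(f"adaptation rate must be >= 0, got {self.q}")


def horizontal(series: AngleSeries, speed: float) -> np.ndarray:
    """Horizontal motion components, deg/s: speed * sin(angle)."""
    return speed * np.sin(np.radians(series.values))


def de_adapt(y: AngleSeries, q: float, speed: float = 6.0) -> AngleSeries:
    """Remove the modelled adaptation from a dependent-variable series.

    Each horizontal component ``h_t`` is corrected to
    ``h_t - q * sum(h_tau for tau < t)`` (accumulation is per update step)
    and mapped back to an angle.  Corrected components beyond ``+/-speed``
    are clipped before the arcsine; the clip count is recorded in the
    output metadata.
    """
    if q < 0:
        raise ConfigError(f"adaptation rate must be >= 0, got {q}")
    h = horizontal(y, speed)
    running = np.concatenate(([0.0], np.cumsum(h)[:-1]))
    h_corr = h - q * running
    n_clipped = int(np.sum(np.abs(h_corr) > speed))
    h_corr = np.clip(h_corr, -speed, speed)
    values = np.degrees(np.arcsin(h_corr / speed))
    return y.with_values(values, deadapt_q=q, n_clipped=n_clipped)


def re_adapt(y: AngleSeries, q: float, speed: float = 6.0) -> AngleSeries:
    """Inverse of :func:`de_adapt` (absent clipping): add the accumulated
    term back, reconstructing the adapted series step by step."""
    if q < 0:
        raise ConfigError(f"adaptation rate must be >= 0, got {q}")
    h_corr = horizontal(y, speed)
    h = np.empty_like(h_corr)
    running = 0.0
    for t in range(h.size):
        h[t] = h_corr[t] + q * running
        running += h[t]
    h = np.clip(h, -speed, speed)
    return y.with_values(np.degrees(np.arcsin(h / speed)))


def _intercept(x_h: np.ndarray, y_h: np.ndarray) -> float:
    return float(linregress(x_h, y_h).intercept)


def optimize_q(
    x: AngleSeries,
    y: AngleSeries,
    target_intercept: float = 0.0,
    speed: float = 6.0,
    bounds: tuple[float, float] = (0.0, 1e-2),
) -> AdaptationFit:
    """Estimate the adaptation rate from an (x, y) session.

    Minimizes ``(intercept(q) - target)**2`` over ``q`` in ``bounds``,
    where ``intercept(q)`` is the y-intercept of the least-squares
    regression of de-adapted target horizontal components on background
    horizontal components and the target is ``speed * sin(target_intercept)``
    (a nonzero value accommodates a genuine constant perceptual bias).
    """
    if not x.same_grid(y):
        raise ConfigError("x and y series must share the sampling grid")
    if np.std(y.values) < 1e-12 or np.std(x.values) < 1e-12:
        raise UnidentifiableError("constant series carry no information about q")
    x_h = horizontal(x, speed)
    target_h = speed * np.sin(np.radians(target_intercept))

    def objective(q: float) -> float:
        y_h = horizontal(de_adapt(y, q, speed), speed)
        return (_intercept(x_h, y_h) - target_h) ** 2

    # At large q the correction clips and the objective is no longer
    # unimodal; bracket the optimum with a coarse log-spaced scan first,
    # then refine by bounded Brent inside the winning decade.
    lo, hi = bounds
    grid = np.concatenate(([lo], np.geomspace(max(lo, 1e-8), hi, 40)))
    scores = [objective(q) for q in grid]
    i = int(np.argmin(scores))
    b_lo = grid[max(i - 1, 0)]
    b_hi = grid[min(i + 1, grid.size - 1)]
    if b_hi <= b_lo:
        b_hi = b_lo + 1e-8
    res = minimize_scalar(
        objective, bounds=(b_lo, b_hi), method="bounded", options={"xatol": 1e-10}
    )
    q_opt = float(max(res.x, 0.0))
    if objective(q_opt) > scores[i]:
        q_opt = float(grid[i])
    achieved_h = _intercept(x_h, horizontal(de_adapt(y, q_opt, speed), speed))
    achieved = float(np.degrees(np.arcsin(np.clip(achieved_h / speed, -1.0, 1.0))))
    return AdaptationFit(
        q=q_opt,
        target_intercept=target_intercept,
        achieved_intercept=achieved,
        n_iter=int(res.nfev),
    )
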