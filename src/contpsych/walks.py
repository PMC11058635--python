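"""Computer-driven stimulus trajectories.

Two generators are provided:

* :func:`gen_random_walk` / :func:`gen_session_walk` -- the Gaussian-step
  direction random walk that drives the independent variable during an
  experimental session, with reflecting boundaries at the configured range
  plus buffer and a coverage-selection loop that keeps drawing candidate
  walks until one visits every analysis bin.
* :func:`gen_blob_walk` -- the training-session blob trajectory: a
  piecewise-constant walk that jumps a fixed number of degrees clockwise or
  anticlockwise with equal probability at a fixed period.

Reflection (mirroring a step at the boundary) is used for boundary handling
so that the walk respects its range without biasing small-step statistics in
the interior.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .errors import ConfigError, CoverageError
from .series import AngleSeries


@dataclass
class WalkConfig:
    """Configuration of a session random walk.

    Parameters
    ----------
    sigma_mu : float
        Standard deviation of the Gaussian direction step, degrees per
        update (sigma_mu**2 is the step variance of the walk).
    duration, dt : float
        Session length and update interval, seconds.
    range_lo, range_hi : float
        Target coverage span, degrees clockwise from vertical.
    buffer : float
        Extra margin on either side of the range; the walk reflects at
        ``range_lo - buffer`` and ``range_hi + buffer``.
    discard : float
        Initial seconds excluded from analysis (and from coverage checks).
    n_bins : int
        Number of equal-width bins over [range_lo, range_hi] that a session
        walk must visit to count as covering the direction space.
    seed : int
        Seed of the walk's random generator.
    start : float or None
        Starting angle; defaults to the middle of the range.
    """

    sigma_mu: float = 1.5
    duration: float = 130.0
    dt: float = 0.05
    range_lo: float = 0.0
    range_hi: float = 90.0
    buffer: float = 10.0
    discard: float = 10.0
    n_bins: int = 9
    seed: int = 0
    start: float | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.duration <= 0:
            raise ConfigError(f"duration and dt must be positive (got {self.duration}, {self.dt})")
        if self.sigma_mu < 0:
            raise ConfigError(f"sigma_mu must be >= 0, got {self.sigma_mu}")
        if not self.duration > self.discard >= 0:
            raise ConfigError(f"need duration > discard >= 0 (got {self.duration}, {self.discard})")
        if not self.range_lo < self.range_hi:
            raise ConfigError(f"need range_lo < range_hi (got {self.range_lo}, {self.range_hi})")
        if self.n_bins < 1:
            raise ConfigError(f"n_bins must be >= 1, got {self.n_bins}")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    def start_value(self) -> float:
        return 0.5 * (self.range_lo + self.range_hi) if self.start is None else self.start


def _reflect(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold positions into [lo, hi] by mirror reflection at the limits."""
    if not np.isfinite(lo) or not np.isfinite(hi):
        return values
    width = hi - lo
    v = np.mod(values - lo, 2.0 * width)
    return lo + np.where(v > width, 2.0 * width - v, v)


def gen_random_walk(cfg: WalkConfig, seed: int | None = None) -> AngleSeries:
    """Draw one Gaussian-step random walk with reflecting boundaries.

    Increments are i.i.d. N(0, sigma_mu**2); at the limits
    ``range_lo - buffer`` and ``range_hi + buffer`` the step is mirrored so
    the walk stays range-respecting.
    """
    use_seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(use_seed)
    n = cfg.n_steps
    lo, hi = cfg.range_lo - cfg.buffer, cfg.range_hi + cfg.buffer
    steps = rng.normal(0.0, cfg.sigma_mu, size=n - 1) if n > 1 else np.empty(0)
    raw = cfg.start_value() + np.concatenate(([0.0], np.cumsum(steps)))
    # cumulative-sum then fold: reflection of the path is equivalent to
    # reflecting each crossing step because folding is an involution on steps
    values = _reflect(raw, lo, hi)
    return AngleSeries(
        dt=cfg.dt, values=values, t0=0.0, meta={"seed": use_seed, "config": asdict(cfg)}
    )


def coverage_bins(series: AngleSeries, cfg: WalkConfig) -> np.ndarray:
    """Per-bin post-discard sample counts over [range_lo, range_hi]."""
    seg = series.discard_initial(cfg.discard)
    edges = np.linspace(cfg.range_lo, cfg.range_hi, cfg.n_bins + 1)
    counts, _ = np.histogram(seg.values, bins=edges)
    return counts


def gen_session_walk(cfg: WalkConfig, max_tries: int = 100) -> AngleSeries:
    """Return the first candidate walk that covers the direction space.

    Candidate walks are drawn with seeds ``cfg.seed, cfg.seed + 1, ...`` and
    the first whose post-discard segment puts at least one sample into every
    one of the ``cfg.n_bins`` equal-width bins spanning
    [range_lo, range_hi] is returned.  The number of candidates tried is
    recorded in the output metadata.
    """
    if max_tries < 1:
        raise ConfigError(f"max_tries must be >= 1, got {max_tries}")
    counts = np.empty(0)
    for attempt in range(max_tries):
        walk = gen_random_walk(cfg, seed=cfg.seed + attempt)
        counts = coverage_bins(walk, cfg)
        if np.all(counts > 0):
            walk.meta["n_tried"] = attempt + 1
            return walk
    empty = np.nonzero(counts == 0)[0]
    edges = np.linspace(cfg.range_lo, cfg.range_hi, cfg.n_bins + 1)
    missing = ", ".join(f"[{edges[i]:.1f}, {edges[i + 1]:.1f})" for i in empty)
    raise CoverageError(
        f"no covering walk within {max_tries} tries; last candidate missed bins {missing}"
    )


def gen_blob_walk(
    step_deg: float = 10.0,
    step_period: float = 5.0,
    duration: float = 130.0,
    dt: float = 0.05,
    seed: int = 0,
    start: float = 0.0,
) -> AngleSeries:
    """Training-session blob trajectory: +/-step_deg jumps at a fixed period.

    The series is piecewise constant; at each ``step_period`` boundary the
    angle jumps ``step_deg`` clockwise or anticlockwise with probability 1/2.
    """
    if dt <= 0 or duration <= 0:
        raise ConfigError(f"duration and dt must be positive (got {duration}, {dt})")
    per = step_period / dt
    if abs(per - round(per)) > 1e-9:
        raise ConfigError(
            f"step_period ({step_period} s) must be an integer multiple of dt ({dt} s)"
        )
    per = int(round(per))
    n = int(round(duration / dt))
    n_epochs = int(np.ceil(n / per))
    rng = np.random.default_rng(seed)
    jumps = step_deg * rng.choice([-1.0, 1.0], size=n_epochs)
    jumps[0] = 0.0  # first epoch sits at the start value
    levels = start + np.cumsum(jumps)
    values = np.repeat(levels, per)[:n]
    return AngleSeries(
        dt=dt,
        values=values,
        t0=0.0,
        meta={
            "seed": seed,
            "step_deg": step_deg,
            "step_period": step_period,
            "n_epochs": n_epochs,
        },
    )
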