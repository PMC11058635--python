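"""Binning, the induced-motion model fit and fit-quality statistics.

The induced-motion model is linear in horizontal-component (sine) space:
``sin(y) = beta * sin(x) - d``, i.e. the target direction that nulls the
percept acquires ``beta`` times the background's horizontal component, minus
any constant offset ``d`` the participant carries.  The fit is ordinary
least squares in that space (closed form); the fitted curve
``y(x) = asin(beta * sin(x) - d)`` is mapped back to angle space for the
binned mean-square distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .errors import ConfigError, DataError, UnidentifiableError
from .series import AngleSeries

#: number of free parameters charged to the AIC: beta, d and the error variance
AIC_K = 3


@dataclass
class BinSummary:
    """Per-bin statistics of y over equal-width bins of x."""

    edges: np.ndarray
    centers: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    counts: np.ndarray

    @property
    def mean_sd(self) -> float:
        """Mean per-bin standard deviation over bins with >= 2 samples."""
        ok = self.counts >= 2
        return float(np.mean(self.sds[ok])) if np.any(ok) else float("nan")


@dataclass
class ModelFit:
    """Fitted induced-motion model and its quality statistics."""

    beta: float
    d: float  # horizontal-component offset; curve is asin(beta*sin(x) - d)
    r2: float
    aic: float
    msd: float  # mean square distance between bin means and the curve, deg**2
    rss: float  # residual sum of squares in horizontal-component space
    n: int

    def curve(self, x_deg: np.ndarray) -> np.ndarray:
        """Model curve in angle space, degrees."""
        h = np.clip(self.beta * np.sin(np.radians(x_deg)) - self.d, -1.0, 1.0)
        return np.degrees(np.arcsin(h))


def bin_series(
    x: AngleSeries,
    y: AngleSeries,
    n_bins: int = 9,
    lo: float | None = None,
    hi: float | None = None,
) -> BinSummary:
    """Bin y by x into equal-width bins over [lo, hi].

    Empty bins carry NaN mean/sd and count 0; single-sample bins carry a
    NaN sd.  Samples outside [lo, hi] are assigned to the nearest edge bin
    so the counts always sum to the number of samples.
    """
    if n_bins < 1:
        raise ConfigError(f"n_bins must be >= 1, got {n_bins}")
    if not x.same_grid(y):
        raise ConfigError("x and y series must share the sampling grid")
    xv, yv = x.values, y.values
    lo = float(np.min(xv)) if lo is None else lo
    hi = float(np.max(xv)) if hi is None else hi
    if not lo < hi:
        raise ConfigError(f"need lo < hi, got {lo}, {hi}")
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(xv, edges) - 1, 0, n_bins - 1)
    means = np.full(n_bins, np.nan)
    sds = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = yv[idx == b]
        counts[b] = sel.size
        if sel.size:
            means[b] = sel.mean()
        if sel.size >= 2:
            sds[b] = sel.std(ddof=1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return BinSummary(edges=edges, centers=centers, means=means, sds=sds, counts=counts)


def fit_model(
    x: AngleSeries,
    y: AngleSeries,
    n_bins: int = 9,
    lo: float | None = None,
    hi: float | None = None,
) -> ModelFit:
    """Least-squares fit of the induced-motion model to an (x, y) pair.

    Regresses sin(y) on sin(x); the slope is ``beta`` and minus the
    intercept is ``d``.  Reports R**2 on the raw pairs, the AIC
    ``n * ln(RSS/n) + 2K`` with K = 3, and the mean-square distance between
    the per-bin means and the model curve in angle space.
    """
    if not x.same_grid(y):
        raise ConfigError("x and y series must share the sampling grid")
    n = x.n
    if n < 3:
        raise DataError(f"need at least 3 samples to fit the model, got {n}")
    sx = np.sin(np.radians(x.values))
    sy = np.sin(np.radians(y.values))
    if np.std(sx) < 1e-12:
        raise UnidentifiableError("x has zero variance; beta is unidentifiable")
    ols = sm.OLS(sy, sm.add_constant(sx)).fit()
    intercept, beta = ols.params
    rss = float(np.sum(ols.resid**2))
    aic = n * np.log(max(rss, 1e-300) / n) + 2 * AIC_K
    fit = ModelFit(
        beta=float(beta),
        d=float(-intercept),
        r2=float(ols.rsquared),
        aic=float(aic),
        msd=float("nan"),
        rss=rss,
        n=n,
    )
    bins = bin_series(x, y, n_bins=n_bins, lo=lo, hi=hi)
    ok = ~np.isnan(bins.means)
    if np.any(ok):
        resid = bins.means[ok] - fit.curve(bins.centers[ok])
        fit.msd = float(np.mean(resid**2))
    return fit


@dataclass
class FitComparison:
    """Raw-vs-processed fit comparison (positive deltas favor processed)."""

    d_r2: float
    d_aic: float
    d_msd: float
    d_bin_sd: float | None
    significant: bool  # AIC improvement of >= 2


def compare_fits(
    raw: ModelFit,
    processed: ModelFit,
    raw_bins: BinSummary | None = None,
    processed_bins: BinSummary | None = None,
) -> FitComparison:
    """Compare model fits on raw and processed data of equal length.

    An AIC drop of at least 2 under processing is flagged as a significant
    improvement; a rise is a non-improvement.
    """
    if raw.n != processed.n:
        raise DataError(f"fits compare different sample counts ({raw.n} vs {processed.n})")
    d_bin_sd = None
    if raw_bins is not None and processed_bins is not None:
        d_bin_sd = raw_bins.mean_sd - processed_bins.mean_sd
    d_aic = raw.aic - processed.aic
    return FitComparison(
        d_r2=processed.r2 - raw.r2,
        d_aic=d_aic,
        d_msd=raw.msd - processed.msd,
        d_bin_sd=d_bin_sd,
        significant=bool(d_aic >= 2.0),
    )
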