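import numpy as np
import pytest

from contpsych import bin_series, compare_fits, fit_model
from contpsych.errors import ConfigError, DataError, UnidentifiableError
from contpsych.series import AngleSeries
from contpsych.stats import AIC_K


def series(values, dt=0.05):
    return AngleSeries(dt=dt, values=np.asarray(values, dtype=float))


def curve_data(beta, d=0.0, n=2000, lo=0.0, hi=90.0, noise=0.0, seed=0):
    """(x, y) lying on the induced-motion curve sin(y) = beta*sin(x) - d."""
    rng = np.random.default_rng(seed)
    x = np.linspace(lo, hi, n)
    h = np.clip(beta * np.sin(np.radians(x)) - d, -1.0, 1.0)
    y = np.degrees(np.arcsin(h))
    if noise:
        y = y + rng.normal(0.0, noise, n)
    return series(x), series(y)


class TestBinSeries:
    def test_single_occupied_bin_holds_overall_mean(self):
        x = series(np.full(50, 5.0))
        y = series(np.arange(50.0))
        bins = bin_series(x, y, n_bins=9, lo=0.0, hi=90.0)
        assert bins.counts[0] == 50
        assert bins.means[0] == pytest.approx(y.values.mean())
        assert np.all(bins.counts[1:] == 0)
        assert np.all(np.isnan(bins.means[1:]))

    def test_identity_relation_puts_means_at_centers(self):
        x = series(np.linspace(0.0, 90.0, 9000))
        bins = bin_series(x, x, n_bins=9, lo=0.0, hi=90.0)
        # mean y per bin equals the bin's mean x, within half the bin spread
        assert np.max(np.abs(bins.means - bins.centers)) < 5.0 / 2.0
        assert bins.counts.sum() == 9000

    def test_uniform_samples_fill_bins_evenly(self):
        rng = np.random.default_rng(2)
        x = series(rng.uniform(0.0, 90.0, 9000))
        bins = bin_series(x, x, n_bins=9, lo=0.0, hi=90.0)
        # multinomial: SE of a count is sqrt(n p (1-p)) ~ 29.8
        se = np.sqrt(9000 * (1 / 9) * (8 / 9))
        assert np.all(np.abs(bins.counts - 1000) < 5 * se)

    def test_sds_use_sample_denominator(self):
        x = series([5.0, 5.0])
        y = series([1.0, -1.0])
        bins = bin_series(x, y, n_bins=1, lo=0.0, hi=10.0)
        assert bins.sds[0] == pytest.approx(np.sqrt(2.0))

    def test_invalid_bin_count_rejected(self):
        x = series(np.zeros(5))
        with pytest.raises(ConfigError):
            bin_series(x, x, n_bins=0, lo=0.0, hi=1.0)


class TestFitModel:
    def test_exact_curve_is_fit_perfectly(self):
        x, y = curve_data(beta=0.5, d=0.0)
        fit = fit_model(x, y, lo=0.0, hi=90.0)
        assert fit.beta == pytest.approx(0.5, abs=1e-12)
        assert fit.d == pytest.approx(0.0, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        # bin means of a curved relation differ from the curve at bin
        # centers by its within-bin curvature; ~1e-3 deg^2 here, not zero
        assert fit.msd == pytest.approx(0.0, abs=1e-2)

    def test_no_interaction_data_yields_zero_slope(self):
        rng = np.random.default_rng(7)
        x = series(rng.uniform(0.0, 90.0, 3000))
        y = series(rng.normal(0.0, 1.0, 3000))  # independent of x, near goal
        fit = fit_model(x, y, lo=0.0, hi=90.0)
        assert fit.beta == pytest.approx(0.0, abs=0.01)

    def test_offset_is_recovered_with_its_sign(self):
        # participant nulls sin(y) = beta sin(x) - d; a positive intercept
        # (clockwise settings at vertical background) means negative d
        x, y = curve_data(beta=0.6, d=-np.sin(np.radians(9.0)))
        fit = fit_model(x, y, lo=0.0, hi=90.0)
        assert fit.d == pytest.approx(-np.sin(np.radians(9.0)), abs=1e-9)
        assert fit.curve(np.zeros(1))[0] == pytest.approx(9.0, abs=1e-9)

    def test_degenerate_background_rejected(self):
        x = series(np.full(100, 30.0))
        y = series(np.zeros(100))
        with pytest.raises(UnidentifiableError):
            fit_model(x, y, lo=0.0, hi=90.0)

    def test_fit_is_invariant_to_sample_order(self):
        x, y = curve_data(beta=0.7, noise=2.0, seed=3)
        rng = np.random.default_rng(0)
        perm = rng.permutation(x.n)
        fit1 = fit_model(x, y, lo=0.0, hi=90.0)
        fit2 = fit_model(
            series(x.values[perm]), series(y.values[perm]), lo=0.0, hi=90.0
        )
        assert fit1.beta == pytest.approx(fit2.beta, abs=1e-12)
        assert fit1.aic == pytest.approx(fit2.aic, abs=1e-9)

    def test_aic_convention_on_nested_pure_noise_fits(self):
        # for y independent of x, adding the slope parameter changes the
        # AIC by approximately 2 - chi2(1); the mean over seeds is ~1
        rng = np.random.default_rng(11)
        n = 400
        deltas = []
        for _ in range(200):
            sx = rng.uniform(-0.5, 0.5, n)
            sy = rng.normal(0.0, 0.1, n)
            rss_full = np.sum((sy - np.polyval(np.polyfit(sx, sy, 1), sx)) ** 2)
            rss_null = np.sum((sy - sy.mean()) ** 2)
            aic_full = n * np.log(rss_full / n) + 2 * AIC_K
            aic_null = n * np.log(rss_null / n) + 2 * (AIC_K - 1)
            deltas.append(aic_full - aic_null)
        assert np.mean(deltas) == pytest.approx(1.0, abs=0.35)


class TestCompareFits:
    def test_identical_fits_give_zero_deltas(self):
        x, y = curve_data(beta=0.5, noise=1.0, seed=1)
        fit = fit_model(x, y, lo=0.0, hi=90.0)
        comp = compare_fits(fit, fit)
        assert comp.d_r2 == 0.0 and comp.d_aic == 0.0 and comp.d_msd == 0.0
        assert not comp.significant

    def test_aic_improvement_of_two_is_significant(self):
        x, y = curve_data(beta=0.5, noise=3.0, seed=2)
        raw = fit_model(x, y, lo=0.0, hi=90.0)
        x2, y2 = curve_data(beta=0.5, noise=0.5, seed=2)
        proc = fit_model(x2, y2, lo=0.0, hi=90.0)
        comp = compare_fits(raw, proc)
        assert comp.d_aic > 2.0 and comp.significant

    def test_worse_processed_fit_is_flagged_as_non_improvement(self):
        x, y = curve_data(beta=0.5, noise=0.5, seed=2)
        raw = fit_model(x, y, lo=0.0, hi=90.0)
        x2, y2 = curve_data(beta=0.5, noise=3.0, seed=2)
        proc = fit_model(x2, y2, lo=0.0, hi=90.0)
        assert not compare_fits(raw, proc).significant

    def test_mismatched_sample_counts_rejected(self):
        x, y = curve_data(beta=0.5, n=100)
        x2, y2 = curve_data(beta=0.5, n=200)
        with pytest.raises(DataError):
            compare_fits(fit_model(x, y), fit_model(x2, y2))
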