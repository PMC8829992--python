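"""Synthetic perinatal-mortality stage: generator, excess-model fit, readouts."""

import math

import numpy as np
import pytest
from scipy.special import ndtr

import logndose as ld
from logndose import EpiModelSpec, EpiRecord, EpiTruth


class TestGenerator:
    def test_null_series_matches_baseline(self):
        truth = EpiTruth(amplitude=0.0)
        records = ld.generate_epi_series(truth=truth, seed=5)
        assert len(records) == 60
        for r in records[:5] + records[-5:]:
            expected = 50_000 * (truth.baseline_per_1000 / 1000.0) * math.exp(
                truth.trend_per_month * r.period
            )
            assert abs(r.deaths - expected) < 5.0 * math.sqrt(expected)

    def test_poisson_total_conservation(self):
        records = ld.generate_epi_series(seed=6)
        truth = EpiTruth()
        t = np.arange(60)
        curve = ld.default_burden_curve(67)
        lam = np.where(curve[:60] > 0, ndtr((np.log(np.maximum(curve[:60], 1e-12)) - truth.mu) / truth.sigma), 0.0)
        expected = 50_000 * (truth.baseline_per_1000 / 1000.0) * np.exp(truth.trend_per_month * t) * (
            1.0 + truth.amplitude * lam
        )
        total = sum(r.deaths for r in records)
        assert abs(total - expected.sum()) < 4.0 * math.sqrt(expected.sum())

    def test_burden_below_median_effect_is_near_null(self):
        # with the default truth the excess is < 1% of baseline whenever the
        # burden stays far below exp(mu) ~ 53 Bq/kg
        lam = ndtr((math.log(5.0) - 3.97) / 0.30)
        assert 1.2 * lam < 0.01
        records = ld.generate_epi_series(burden_curve=np.full(80, 5.0), seed=7)
        null = ld.generate_epi_series(truth=EpiTruth(amplitude=0.0), seed=7)
        total, null_total = sum(r.deaths for r in records), sum(r.deaths for r in null)
        assert abs(total - null_total) < 5.0 * math.sqrt(null_total)

    def test_reproducible_and_seed_sensitive(self):
        a = ld.generate_epi_series(seed=8)
        assert a == ld.generate_epi_series(seed=8)
        assert a != ld.generate_epi_series(seed=9)

    def test_burden_curve_shape(self):
        curve = ld.default_burden_curve(70)
        assert curve[0] == 0.0
        assert curve.max() == pytest.approx(38.0)
        assert curve.max() < 40.0
        assert np.argmax(curve) == 12
        assert curve[-1] < 2.0  # decayed long after the accident

    def test_short_burden_curve_rejected(self):
        with pytest.raises(ValueError):
            ld.generate_epi_series(burden_curve=np.ones(30), n_months=60, seed=0)

    def test_record_invariants(self):
        with pytest.raises(ValueError):
            EpiRecord(period=0, births=10, deaths=11, burden=0.0)
        with pytest.raises(ValueError):
            EpiRecord(period=0, births=10, deaths=1, burden=-1.0)


class TestFit:
    def test_single_series_recovery(self):
        records = ld.generate_epi_series(seed=12)
        fit = ld.fit_epi_model(records)
        assert fit.converged
        assert fit.p_cesium < 0.05
        assert abs(fit.mu - 3.97) <= 3.0 * fit.standard_errors["mu"]
        assert fit.reduced_df - fit.df == 3

    def test_null_amplitude_within_error(self):
        records = ld.generate_epi_series(truth=EpiTruth(amplitude=0.0), seed=13)
        fit = ld.fit_epi_model(records)
        assert abs(fit.amplitude) <= 2.0 * fit.standard_errors["amplitude"] + 0.05

    def test_zero_burden_unidentifiable(self):
        records = ld.generate_epi_series(
            truth=EpiTruth(amplitude=0.0), burden_curve=np.zeros(80), seed=14
        )
        with pytest.raises(ValueError):
            ld.fit_epi_model(records)

    def test_compute_se_flag_only_affects_ses(self):
        records = ld.generate_epi_series(seed=15)
        full = ld.fit_epi_model(records)
        fast = ld.fit_epi_model(records, compute_se=False)
        assert fast.mu == pytest.approx(full.mu)
        assert fast.p_cesium == pytest.approx(full.p_cesium)
        assert math.isnan(fast.standard_errors["mu"])

    def test_misspecified_lag_fits_worse_on_average(self):
        # fitting with the wrong exposure lag should not beat the true lag
        true_dev, wrong_dev = [], []
        for child in np.random.SeedSequence(55).spawn(15):
            records = ld.generate_epi_series(seed=child, n_months=60)
            good = ld.fit_epi_model(records, compute_se=False)
            bad = ld.fit_epi_model(records, EpiModelSpec(lag=11), compute_se=False)
            # different lags keep different numbers of periods, so compare
            # deviance per degree of freedom
            true_dev.append(good.deviance / good.df)
            wrong_dev.append(bad.deviance / bad.df)
        assert np.mean(true_dev) < np.mean(wrong_dev)


class TestRateRatios:
    def test_noise_free_input_reproduces_excess_curve(self):
        records = ld.generate_epi_series(seed=16)
        fit = ld.fit_epi_model(records, compute_se=False)
        # rebuild records whose rates sit exactly on the fitted full model
        spec = EpiModelSpec(lag=fit.lag)
        b0 = fit.baseline_coefficients["intercept"]
        b1 = fit.baseline_coefficients["trend"]
        exact = []
        for r in records:
            lagged = records[r.period - spec.lag].burden if r.period >= spec.lag else 0.0
            lam = ndtr((math.log(lagged) - fit.mu) / fit.sigma) if lagged > 0 else 0.0
            rate = math.exp(b0 + b1 * r.period) * (1.0 + fit.amplitude * lam)
            exact.append(
                EpiRecord(period=r.period, births=r.births, deaths=rate * r.births, burden=r.burden)
            )
        points = ld.rate_ratio_curve(exact, fit)
        for p in points:
            lam = ndtr((math.log(p.burden) - fit.mu) / fit.sigma) if p.burden > 0 else 0.0
            assert p.ratio == pytest.approx(1.0 + fit.amplitude * lam, abs=1e-10)

    def test_null_ratios_scatter_around_one(self):
        records = ld.generate_epi_series(truth=EpiTruth(amplitude=0.0), seed=17)
        fit = ld.fit_epi_model(records, compute_se=False)
        points = ld.rate_ratio_curve(records, fit)
        within = [abs(p.ratio - 1.0) <= 2.0 * p.sd for p in points if not p.flagged]
        assert np.mean(within) > 0.80

    def test_high_burden_ratios_exceed_low_burden_ratios(self):
        records = ld.generate_epi_series(seed=18)
        fit = ld.fit_epi_model(records, compute_se=False)
        points = ld.rate_ratio_curve(records, fit)
        cut = math.exp(3.97)
        high = [p.ratio for p in points if p.burden > 30.0]
        low = [p.ratio for p in points if p.burden < cut / 2.0]
        assert np.mean(high) > np.mean(low)

    def test_sd_scales_inverse_sqrt_deaths(self):
        # quadrupling deaths (and births) exactly halves the relative error
        records = ld.generate_epi_series(seed=19)
        fit = ld.fit_epi_model(records, compute_se=False)
        big = [
            EpiRecord(period=r.period, births=4 * r.births, deaths=4 * r.deaths, burden=r.burden)
            for r in records
        ]
        big_fit = ld.fit_epi_model(big, compute_se=False)
        small_rel = np.array([p.sd / p.ratio for p in ld.rate_ratio_curve(records, fit) if not p.flagged])
        big_rel = np.array([p.sd / p.ratio for p in ld.rate_ratio_curve(big, big_fit) if not p.flagged])
        np.testing.assert_allclose(big_rel, small_rel / 2.0, rtol=1e-12)


class TestPracticalThreshold:
    def _fit_like(self, amplitude, mu, sigma):
        return ld.EpiFitResult(
            baseline_coefficients={"intercept": -5.1, "trend": 0.0},
            amplitude=amplitude,
            mu=mu,
            sigma=sigma,
            standard_errors={},
            deviance=50.0,
            df=48,
            p_cesium=0.001,
            converged=True,
            n_iterations=3,
            lag=7,
            reduced_coefficients={"intercept": -5.1, "trend": 0.0},
            reduced_deviance=80.0,
            reduced_df=51,
        )

    def test_closed_form_value(self):
        fit = self._fit_like(1.0, 3.97, 0.30)
        assert ld.practical_threshold(fit, 0.05) == pytest.approx(
            math.exp(3.97 - 1.6449 * 0.30), rel=1e-4
        )
        assert ld.practical_threshold(fit, 0.05) == pytest.approx(32.3, rel=0.01)

    def test_monotone_in_epsilon_and_zero_limit(self):
        fit = self._fit_like(1.0, 3.97, 0.30)
        eps = [1e-6, 1e-3, 0.01, 0.05, 0.2]
        thresholds = [ld.practical_threshold(fit, e) for e in eps]
        assert all(b > a for a, b in zip(thresholds, thresholds[1:]))
        # no true threshold exists: the read-off point vanishes as eps -> 0
        assert ld.practical_threshold(fit, 1e-30) < 2.0

    def test_larger_sigma_lowers_threshold(self):
        lo = ld.practical_threshold(self._fit_like(1.0, 3.97, 0.30), 0.05)
        hi = ld.practical_threshold(self._fit_like(1.0, 3.97, 0.60), 0.05)
        assert hi < lo

    def test_unreachable_excess_is_infinite(self):
        assert ld.practical_threshold(self._fit_like(0.03, 3.97, 0.3), 0.05) == math.inf

    def test_zero_amplitude_signalled(self):
        with pytest.raises(ValueError):
            ld.practical_threshold(self._fit_like(0.0, 3.97, 0.3), 0.05)
        with pytest.raises(ValueError):
            ld.practical_threshold(self._fit_like(1.0, 3.97, 0.3), -0.1)
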