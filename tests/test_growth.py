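"""Exponential PLA fits, windowed RGR, Richards curve and its MCMC fit."""

import math

import numpy as np
import pytest
from scipy.special import expit

from clgrow.growth import (
    RichardsParams,
    cumulative_interception,
    fit_exponential_pla,
    fit_richards_mcmc,
    rgr_window,
    richards_eval,
)
from clgrow.synth import pla_trajectory_params, simulate_pla


class TestRgrWindow:
    @pytest.mark.parametrize(
        ("p1", "p2", "d1", "d2", "expected"),
        [
            (100.0, 110.0, 5.0, 6.0, math.log(1.1)),
            (80.0, 80.0, 3.0, 4.5, 0.0),
            (100.0, 200.0, 0.0, 2.0, math.log(2.0) / 2.0),
        ],
    )
    def test_values(self, p1, p2, d1, d2, expected):
        assert rgr_window(p1, p2, d1, d2) == pytest.approx(expected, abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            rgr_window(-1.0, 10.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            rgr_window(10.0, 10.0, 2.0, 2.0)


class TestRichardsCurve:
    def test_midpoint_of_logistic_case(self):
        p = RichardsParams(16.9, 0.5, 13.0, 1.0)
        assert richards_eval(p, 13.0) == pytest.approx(16.9 / 2.0, rel=1e-12)

    def test_saturates_at_asymptote(self):
        p = RichardsParams(16.9, 0.5, 13.0, 2.0)
        assert richards_eval(p, 13.0 + 1e3) == pytest.approx(16.9, rel=1e-9)

    def test_v1_equals_independent_logistic(self):
        """At v = 1 the Richards curve is the logistic; check against an
        independent expit-based implementation on a dense grid."""
        p = RichardsParams(12.0, 0.4, 9.0, 1.0)
        t = np.linspace(0.0, 25.0, 100)
        oracle = 12.0 * expit(0.4 * (t - 9.0))
        np.testing.assert_allclose(richards_eval(p, t), oracle, rtol=1e-12)

    def test_strictly_increasing_and_bounded(self):
        p = RichardsParams(16.9, 0.5, 13.0, 2.7)
        t = np.linspace(-5.0, 40.0, 200)
        y = richards_eval(p, t)
        assert np.all(np.diff(y) > 0)
        assert np.all((y > 0) & (y < 16.9))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            RichardsParams(-1.0, 0.5, 13.0, 2.0)
        with pytest.raises(ValueError):
            RichardsParams(16.9, 0.5, 13.0, 0.0)


class TestExponentialFit:
    def test_noiseless_exact_recovery(self):
        dat = np.tile(np.arange(2.0, 14.0), 8)
        series = {
            "18h": (dat, 10.0 * np.exp(0.20 * dat)),
            "CL": (dat, 10.0 * np.exp(0.25 * dat)),
        }
        fit = fit_exponential_pla(series)
        assert fit.converged
        assert fit.pla_initial == pytest.approx(10.0, rel=1e-6)
        assert fit.rgr["18h"] == pytest.approx(0.20, rel=1e-6)
        assert fit.rgr["CL"] == pytest.approx(0.25, rel=1e-6)

    def test_lognormal_noise_recovery_within_3_se(self, rng):
        dat = np.tile(np.arange(2.0, 14.0), 8)  # 12 days x 8 plants
        series = {}
        for lab, r in (("18h", 0.20), ("CL", 0.25)):
            noise = np.exp(rng.normal(0.0, 0.05, dat.size))
            series[lab] = (dat, 10.0 * np.exp(r * dat) * noise)
        fit = fit_exponential_pla(series)
        for lab, r in (("18h", 0.20), ("CL", 0.25)):
            assert abs(fit.rgr[lab] - r) <= 3.0 * fit.rgr_se[lab]

    def test_flat_series_gives_zero_rgr(self):
        dat = np.arange(2.0, 14.0)
        fit = fit_exponential_pla({"18h": (dat, np.full(dat.size, 42.0))})
        assert fit.rgr["18h"] == pytest.approx(0.0, abs=1e-8)
        assert fit.pla_initial == pytest.approx(42.0, rel=1e-8)

    def test_too_few_points_in_window_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential_pla({"18h": (np.array([3.0, 5.0]), np.array([1.0, 2.0]))})

    def test_zero_noise_generator_round_trip(self, zero_noise_config):
        """Generator -> fit is an exact fixed point at zero noise."""
        table, truth = simulate_pla(zero_noise_config)
        params = pla_trajectory_params(zero_noise_config)
        for cv in ("Danstar", "Jagger"):
            sub = table[table.cultivar == cv]
            series = {
                tr: (sub[sub.treatment == tr].dat.to_numpy(),
                     sub[sub.treatment == tr].pla_cm2.to_numpy())
                for tr in ("18h", "CL")
            }
            fit = fit_exponential_pla(series)
            assert fit.pla_initial == pytest.approx(
                zero_noise_config.pla_initial, rel=1e-6)
            for tr in ("18h", "CL"):
                assert fit.rgr[tr] == pytest.approx(params[(tr, cv)][1], rel=1e-6)


class TestCumulativeInterception:
    def test_constant_series(self):
        dat = np.arange(1.0, 20.0)
        assert cumulative_interception(dat, np.full(19, 16.9)) == pytest.approx(
            16.9 * 18.0, rel=1e-12)

    def test_zero_series(self):
        dat = np.arange(1.0, 20.0)
        assert cumulative_interception(dat, np.zeros(19)) == 0.0

    def test_linear_ramp_is_triangle_area(self):
        dat = np.arange(1.0, 20.0)
        ramp = 16.9 * (dat - 1.0) / 18.0
        assert cumulative_interception(dat, ramp) == pytest.approx(152.1, abs=1e-9)

    def test_range_not_covered_rejected(self):
        with pytest.raises(ValueError):
            cumulative_interception(np.arange(3.0, 10.0), np.ones(7))

    def test_bounded_by_supplied_dli_times_width(self):
        dat = np.arange(1.0, 20.0)
        y = np.clip(16.9 * expit(0.5 * (dat - 13.0)), 0, 16.9)
        assert cumulative_interception(dat, y) <= 16.9 * 18.0


class TestRichardsMCMC:
    def test_priors_only_run_reproduces_prior_means(self):
        """With the likelihood switched off the posterior is the prior."""
        dat = np.arange(1.0, 20.0)
        post = fit_richards_mcmc(dat, np.ones(19), seed=3, likelihood_weight=0.0)
        m = post.posterior_mean()
        assert m["dli_int_max"] == pytest.approx(16.9, abs=3 * 0.25 / math.sqrt(300))
        assert m["rgr_dli_int"] == pytest.approx(0.5, abs=0.05)
        assert m["t_m"] == pytest.approx(13.0, abs=1.0)
        # v ~ N(2, 1) confined to v > 0 by the log-scale sampling
        assert m["v"] == pytest.approx(2.06, abs=0.2)

    def test_degenerate_data_flagged_but_runs(self):
        dat = np.arange(1.0, 20.0)
        post = fit_richards_mcmc(dat, np.full(19, 5.0), seed=1,
                                 chains=2, iterations=600, warmup=200)
        assert any("degenerate" in w for w in post.warnings)
        assert post.draws.shape == (2, 400, 5)

    def test_draw_count_contract_and_determinism(self):
        dat = np.arange(1.0, 20.0)
        y = richards_eval(RichardsParams(16.9, 0.5, 13.0, 2.0), dat)
        a = fit_richards_mcmc(dat, y, seed=9, chains=2, iterations=500, warmup=100)
        b = fit_richards_mcmc(dat, y, seed=9, chains=2, iterations=500, warmup=100)
        assert a.draws.shape == (2, 400, 5)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_posterior_contracts_with_data_size(self):
        """Posterior SD of the asymptote shrinks when n grows 19 -> 190."""
        truth = RichardsParams(16.9, 0.5, 13.0, 2.0, 0.3)
        rng = np.random.default_rng(5)
        small_t = np.arange(1.0, 20.0)
        big_t = np.repeat(small_t, 10)
        small = richards_eval(truth, small_t) + rng.normal(0, 0.3, small_t.size)
        big = richards_eval(truth, big_t) + rng.normal(0, 0.3, big_t.size)
        post_small = fit_richards_mcmc(small_t, small, seed=21)
        post_big = fit_richards_mcmc(big_t, big, seed=21)
        sd_small = post_small.flat()[:, 0].std()
        sd_big = post_big.flat()[:, 0].std()
        assert sd_big < sd_small

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_richards_mcmc(np.arange(3.0), np.ones(3))
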