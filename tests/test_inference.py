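import math

import numpy as np
import pytest

from empen.astro import ColonySite
from empen.inference import (
    CountSeries,
    MCMCConfig,
    fit_full,
    fit_satellite,
    geometric_error,
    log_likelihood,
    log_prior,
    mean_geometric_error,
    predictive_band,
    summarize,
)
from empen.metrics import r_squared
from empen.phenology import occupancy, build_event_schedule
from empen.synthetic import GeneratorSpec, generate_counts, pg_like_params

PG_SITE = ColonySite("PG-like", -(66 + 40 / 60), 140 + 1 / 60)


class TestLogPrior:
    def test_valid_params_constant(self, pg_params):
        assert log_prior(pg_params) == 0.0

    def test_absence_duration_out_of_box(self, pg_params):
        assert log_prior(pg_params.replace(b=120.0)) == -np.inf

    def test_ordering_violation(self, pg_params):
        assert log_prior(pg_params.replace(s_min=pg_params.s_max + 1)) == -np.inf


class TestLogLikelihood:
    def make_data(self, pg_params, factor=1.0):
        days = np.arange(70.0, 340.0, 7.0)
        model = occupancy(build_event_schedule(pg_params), days).adults
        return CountSeries(days=days, counts=model * factor, kind="adults_only")

    def test_exact_match_is_maximum(self, pg_params):
        data = self.make_data(pg_params)
        ll0 = log_likelihood(pg_params, data, 0.1)
        for factor in (1.1, 0.9):
            assert log_likelihood(pg_params, self.make_data(pg_params, factor), 0.1) < ll0

    def test_doubling_obs_shifts_by_closed_form(self, pg_params):
        sigma = 0.2
        data1 = self.make_data(pg_params)
        data2 = self.make_data(pg_params, 2.0)
        n = len(data1)
        expected_drop = n * (math.log(2.0) ** 2) / (2.0 * sigma**2)
        got = log_likelihood(pg_params, data1, sigma) - log_likelihood(pg_params, data2, sigma)
        assert got == pytest.approx(expected_drop, rel=1e-3)

    def test_flat_for_huge_sigma(self, pg_params):
        data = self.make_data(pg_params)
        lls = [
            log_likelihood(pg_params.replace(bp=bp), data, 1e6) for bp in (3000.0, 9000.0)
        ]
        assert lls[0] == pytest.approx(lls[1], abs=1e-4)

    def test_zero_model_handled_by_floor(self, pg_params):
        data = CountSeries(days=np.array([61.0]), counts=np.array([50.0]))
        assert np.isfinite(log_likelihood(pg_params, data, 0.5))


class TestGeometricError:
    @pytest.mark.parametrize(
        "pred, obs, expected",
        [(1.25, 1.0, 25.0), (1.0, 1.0, 0.0), (0.5, 1.0, 100.0)],
    )
    def test_worked_examples(self, pred, obs, expected):
        assert geometric_error(pred, obs) == pytest.approx(expected)

    def test_symmetry_and_zero_iff_equal(self):
        rng = np.random.default_rng(3)
        a, b = rng.uniform(0.1, 10, 50), rng.uniform(0.1, 10, 50)
        assert np.allclose(geometric_error(a, b), geometric_error(b, a))
        assert np.all(geometric_error(a, a) == 0.0)
        assert np.all(geometric_error(a, b)[a != b] > 0)

    def test_aggregate_on_log_scale(self):
        pred, obs = np.array([2.0, 0.5]), np.array([1.0, 1.0])
        assert mean_geometric_error(pred, obs) == pytest.approx(100.0)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            geometric_error(0.0, 1.0)


class TestFitFull:
    def test_recovers_bp_hr_from_weekly_noisy_counts(self):
        spec = GeneratorSpec(seed=1, count_noise_sd_log=0.10)
        sc = generate_counts(spec)
        post = fit_full(
            sc.adults_series(),
            config=MCMCConfig(n_walkers=44, n_burn=1500, n_steps=250, n_start=1500),
            seed=10,
        )
        assert abs(post.means["bp"] / spec.phenology.bp - 1) < 0.10
        assert abs(post.means["hr"] / spec.phenology.hr - 1) < 0.10
        # the creche trip-duration ridge leaves F with a wide but honest
        # posterior: truth must sit inside the central 90 % interval
        lo, hi = post.samples["f"].quantile([0.05, 0.95])
        assert lo <= spec.phenology.f <= hi
        # chick curve is predicted without chick data
        band = predictive_band(post, sc.truth["day"].to_numpy(), which="chicks")
        assert r_squared(band["mean"], sc.truth["chicks"].to_numpy()) > 0.6

    def test_posterior_samples_respect_prior(self):
        spec = GeneratorSpec(seed=2)
        post = fit_full(
            generate_counts(spec).adults_series(),
            config=MCMCConfig(n_walkers=32, n_burn=300, n_steps=80, n_start=400),
            seed=3,
        )
        s = post.samples
        assert (s["f"] <= s["hr"] + 1e-12).all()
        assert (s["db"] >= s["dt0"] - 1e-12).all()
        assert s["bp"].between(2000, 15000).all()

    def test_truncated_late_season_is_weakly_identified(self):
        """Post-September adult counts alone cannot pin the full model: the
        arrival parameters stay close to their priors and BP is left with a
        large posterior spread — the motivation for the constrained
        satellite mode."""
        spec = GeneratorSpec(seed=4, count_noise_sd_log=0.10)
        days = np.arange(245.0, 420.0, 7.0)  # post-September only
        sc = generate_counts(spec, days=days)
        post = fit_full(
            sc.adults_series(),
            config=MCMCConfig(n_walkers=32, n_burn=800, n_steps=200, n_start=800),
            seed=5,
        )
        prior_sd_dt0 = (14 - 4) / np.sqrt(12.0)
        prior_sd_t0 = (150 - 50) / np.sqrt(12.0)
        assert post.sds["dt0"] > 0.2 * prior_sd_dt0
        assert post.sds["t0"] > 0.3 * prior_sd_t0
        assert post.sds["bp"] > 500.0  # far looser than a full-season fit

    def test_refuses_too_few_points(self, pg_params):
        data = CountSeries(days=np.array([100.0, 110.0]), counts=np.array([10.0, 20.0]))
        with pytest.raises(ValueError):
            fit_full(data)


class TestFitSatellite:
    def make_sparse(self, seed, noise=0.10, n_points=6):
        spec = GeneratorSpec(seed=seed, count_noise_sd_log=noise)
        days = np.linspace(280.0, 350.0, n_points)
        return spec, generate_counts(spec, days=days).total_series()

    def test_recovery_at_paper_sparsity(self, quick_mcmc):
        spec, data = self.make_sparse(seed=1)
        post = fit_satellite(data, site=PG_SITE, fixed=pg_like_params(), config=quick_mcmc, seed=7)
        assert abs(post.means["bp"] / spec.phenology.bp - 1) < 0.15
        assert abs(post.means["f"] - spec.phenology.f) < 0.15

    def test_noiseless_recovery(self, quick_mcmc):
        spec, data = self.make_sparse(seed=2, noise=0.0)
        post = fit_satellite(data, site=PG_SITE, fixed=pg_like_params(), config=quick_mcmc, seed=8)
        assert abs(post.means["bp"] / spec.phenology.bp - 1) < 0.03
        assert abs(post.means["f"] - spec.phenology.f) < 0.05

    def test_anchored_return_date(self, quick_mcmc):
        _, data = self.make_sparse(seed=3)
        post = fit_satellite(data, site=PG_SITE, fixed=pg_like_params(), config=quick_mcmc, seed=9)
        d = pg_like_params()
        # female return = t0 + m + b must equal first sunrise (Jun 29 +/- 1 d) + 27.4
        ret = post.diagnostics["anchored_t0"] + d.m + d.b
        assert ret == pytest.approx(180 + 27.4, abs=1.5)

    def test_seed_stability(self, quick_mcmc):
        _, data = self.make_sparse(seed=5)
        fits = [
            fit_satellite(data, site=PG_SITE, fixed=pg_like_params(), config=quick_mcmc, seed=s)
            for s in (11, 12)
        ]
        diff = abs(fits[0].means["bp"] - fits[1].means["bp"])
        combined = np.hypot(fits[0].sds["bp"], fits[1].sds["bp"])
        assert diff < 2.0 * combined

    def test_refuses_fewer_than_three_points(self, quick_mcmc):
        data = CountSeries(days=np.array([300.0, 310.0]), counts=np.array([4000.0, 3500.0]), kind="total")
        with pytest.raises(ValueError, match="at least 3"):
            fit_satellite(data, site=PG_SITE, fixed=pg_like_params(), config=quick_mcmc, seed=1, year=2018)


class TestSummarize:
    def test_calibrated_coverage_near_68pct(self):
        spec = GeneratorSpec(seed=6, count_noise_sd_log=0.10)
        sc = generate_counts(spec)
        data = sc.adults_series()
        post = fit_full(
            data,
            config=MCMCConfig(n_walkers=44, n_burn=1200, n_steps=200, n_start=1000),
            seed=13,
        )
        report = summarize(post, data=data)
        assert 0.5 <= report["coverage_1sd"] <= 0.9

    def test_roundtrip_from_exported_samples(self, quick_mcmc):
        spec = GeneratorSpec(seed=8)
        data = generate_counts(spec).adults_series()
        post = fit_full(data, config=quick_mcmc, seed=14)
        report = summarize(post)
        recomputed = post.samples.mean()
        for name in post.param_names:
            assert report["parameters"].loc[name, "mean"] == pytest.approx(recomputed[name])

    def test_degenerate_posterior(self, quick_mcmc):
        spec = GeneratorSpec(seed=9)
        data = generate_counts(spec).adults_series()
        post = fit_full(data, config=quick_mcmc, seed=15)
        post.samples.iloc[:, :] = post.samples.iloc[0].to_numpy()[None, :]
        report = summarize(post)
        assert (report["parameters"]["sd"].abs() < 1e-9).all()
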