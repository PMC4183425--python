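"""Limiting distributions, scaling/collapse, rank order, log-normal fit."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from synkesten import DistributionSpec, KestenParams, mu_class_spec
from synkesten.population import (
    SizeSample,
    collapse_test,
    delta_vs_initial,
    ks_critical_value,
    limiting_sample,
    lognormal_comparison,
    perturbation_experiment,
    rank_order_analysis,
    tail_exponent,
    zscore,
)

from conftest import deterministic_ensemble


class TestLimitingSample:
    def test_degenerate_process_collapses_to_the_fixed_point(self):
        params = KestenParams(
            DistributionSpec.degenerate(0.9), DistributionSpec.degenerate(0.2)
        )
        sample = limiting_sample(params, 50, 200, seed=0)
        np.testing.assert_allclose(sample.values, 2.0, rtol=1e-9)

    def test_sample_mean_matches_stationary_mean(self, baseline_params):
        sample = limiting_sample(baseline_params, 4000, 1500, seed=3)
        se = sample.values.std(ddof=1) / np.sqrt(sample.n)
        assert abs(sample.values.mean() - 1.0) < 3 * se

    def test_cv_increases_toward_the_instability_boundary(self):
        # three eps settings with <ln eps> rising toward 0 give increasingly
        # broad limiting distributions
        eta = DistributionSpec.gaussian(0.05, 0.01)
        cvs = []
        for mean_eps in (0.90, 0.96, 0.99):
            params = KestenParams(
                DistributionSpec.gaussian(mean_eps, 0.05), eta
            )
            s = limiting_sample(params, 4000, 2500, seed=7)
            cvs.append(s.values.std() / s.values.mean())
        assert cvs[0] < cvs[1] < cvs[2]

    def test_unstable_regime_rejected(self):
        params = KestenParams(
            DistributionSpec.gaussian(1.05, 0.02), DistributionSpec.degenerate(0.01)
        )
        with pytest.raises(ValueError):
            limiting_sample(params, 10, 100, seed=0)


class TestTailExponent:
    def test_recovers_pareto_generator_truth(self):
        rng = np.random.default_rng(0)
        sample = SizeSample((1.0 / rng.uniform(size=50_000)) ** (1.0 / 3.0))
        fit = tail_exponent(sample, 0.1)
        assert fit.exponent == pytest.approx(3.0, abs=0.15)
        assert fit.r_squared > 0.99

    def test_exponential_tail_flagged_by_low_r_squared(self):
        rng = np.random.default_rng(1)
        expo = SizeSample(rng.exponential(size=50_000) + 1e-9)
        pareto = SizeSample((1.0 / rng.uniform(size=50_000)) ** (1.0 / 3.0))
        assert (
            tail_exponent(expo, 0.2).r_squared
            < tail_exponent(pareto, 0.2).r_squared
        )

    def test_kesten_tail_is_heavy_with_exponent_below_mu(self):
        # the asymptotic exponent is mu, approached from below at finite
        # sample depth (slow tail convergence)
        spec = mu_class_spec("gaussian", 6.0, sd=0.1)
        params = KestenParams(spec, DistributionSpec.gaussian(0.03, 0.01))
        sample = limiting_sample(params, 30_000, 1500, seed=5)
        fit = tail_exponent(sample, 0.05)
        assert fit.r_squared > 0.99
        assert 3.0 < fit.exponent < 6.5

    def test_too_few_tail_points_raises(self):
        sample = SizeSample(np.linspace(0.1, 1.0, 500))
        with pytest.raises(ValueError):
            tail_exponent(sample, 0.1)


class TestZscore:
    def test_output_is_standardized(self):
        rng = np.random.default_rng(2)
        z = zscore(rng.lognormal(size=1000))
        assert abs(z.mean()) < 1e-12
        assert z.std() == pytest.approx(1.0, abs=1e-12)

    @settings(derandomize=True, max_examples=25)
    @given(
        a=st.floats(0.1, 10.0),
        b=st.floats(-5.0, 5.0),
    )
    def test_affine_invariance(self, a, b):
        x = np.linspace(0.5, 4.0, 37)
        np.testing.assert_allclose(zscore(a * x + b), zscore(x), atol=1e-9)

    def test_population_sd_convention(self):
        np.testing.assert_allclose(
            zscore(np.array([1.0, 3.0])), [-1.0, 1.0]
        )  # sd with the n-denominator is 1 for [1, 3]

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            zscore(np.full(5, 2.0))


class TestCollapse:
    def test_self_comparison_is_zero(self):
        s = SizeSample(np.linspace(0.2, 3.0, 100))
        out = collapse_test(s, s)
        assert out["ks_raw"] == 0.0
        assert out["ks_z"] == 0.0

    def test_pure_rescaling_collapses_under_zscore(self):
        rng = np.random.default_rng(3)
        vals = rng.lognormal(size=2000)
        a, b = SizeSample(vals), SizeSample(1.5 * vals)
        out = collapse_test(a, b)
        assert out["ks_raw"] > 0.1
        # up to one rank flip from floating-point rounding of the z-scores
        assert out["ks_z"] <= 1.0 / a.n

    def test_ks_invariant_under_common_monotone_transform(self):
        rng = np.random.default_rng(4)
        x, y = rng.lognormal(size=500), rng.lognormal(0.3, 1.0, size=500)
        base = collapse_test(SizeSample(x), SizeSample(y))["ks_raw"]
        trans = collapse_test(SizeSample(np.exp(x)), SizeSample(np.exp(y)))["ks_raw"]
        assert trans == pytest.approx(base, abs=1e-12)

    def test_eta_rescaling_moves_the_mean_not_the_shape(self):
        # scaling the additive factor rescales the limiting distribution
        # proportionally while the z-scored shape is preserved
        eps = DistributionSpec.gaussian(0.97, 0.05)
        s1 = limiting_sample(
            KestenParams(eps, DistributionSpec.gaussian(0.03, 0.01)),
            8000, 1500, seed=11,
        )
        s2 = limiting_sample(
            KestenParams(eps, DistributionSpec.gaussian(0.06, 0.02)),
            8000, 1500, seed=12,
        )
        assert s2.values.mean() / s1.values.mean() == pytest.approx(2.0, abs=0.15)
        out = collapse_test(s1, s2)
        assert out["ks_z"] < ks_critical_value(s1.n, s2.n)


class TestDeltaVsInitial:
    def test_additive_random_walk_has_no_size_dependence(self):
        rng = np.random.default_rng(5)
        n, t = 2000, 49
        sizes = np.empty((n, t))
        sizes[:, 0] = rng.uniform(0.5, 2.0, n)
        for k in range(1, t):
            sizes[:, k] = sizes[:, k - 1] + rng.normal(0, 0.01, n)
        ens = deterministic_ensemble(1.0, 0.0, np.ones(n), t - 1)
        ens.sizes = np.abs(sizes)
        table, fit = delta_vs_initial(ens, 24.0)
        x = ens.sizes[:, 0]
        dx = ens.sizes[:, -1] - x
        resid = dx - fit["slope"] * x - fit["intercept"]
        se = resid.std() / (x.std() * np.sqrt(n))
        assert abs(fit["slope"]) < 3 * se

    def test_multiplicative_transform_gives_exact_line_through_origin(self):
        init = np.linspace(0.2, 3.0, 30)
        ens = deterministic_ensemble(1.0, 0.0, init, 48)
        ens.sizes = np.outer(init, np.linspace(1.0, 1.14, 49))
        table, fit = delta_vs_initial(ens, 24.0)
        assert fit["slope"] == pytest.approx(0.14, abs=1e-10)
        assert fit["intercept"] == pytest.approx(0.0, abs=1e-10)

    def test_stationary_kesten_line_crosses_at_the_population_mean(
        self, baseline_params, stationary_init
    ):
        crossings, slopes = [], []
        for s in range(8):
            from synkesten import simulate_ensemble

            ens = simulate_ensemble(baseline_params, stationary_init, 48, seed=70 + s)
            _, fit = delta_vs_initial(ens, 24.0)
            slopes.append(fit["slope"])
            crossings.append(fit["zero_crossing"])
        assert all(s < 0 for s in slopes)
        se = np.std(crossings, ddof=1) / np.sqrt(len(crossings))
        assert abs(np.mean(crossings) - 1.0) < 3 * se

    def test_off_grid_interval_rejected(self):
        ens = deterministic_ensemble(0.9, 0.1, np.linspace(0.5, 2, 10), 10)
        with pytest.raises(ValueError):
            delta_vs_initial(ens, 0.75)


class TestRankOrder:
    def test_monotone_transform_preserves_rank(self):
        rng = np.random.default_rng(6)
        x = rng.lognormal(size=300)
        out = rank_order_analysis(SizeSample(x), SizeSample(x**2 + 1.0))
        assert out["rank_rho"] == pytest.approx(1.0)

    def test_independent_permutation_destroys_rank(self):
        rng = np.random.default_rng(7)
        x = rng.lognormal(size=2000)
        out = rank_order_analysis(
            SizeSample(x), SizeSample(rng.permutation(x))
        )
        assert abs(out["rank_rho"]) < 2.0 / np.sqrt(x.size)

    def test_kesten_evolution_partially_shuffles_rank(
        self, baseline_params, stationary_init
    ):
        from synkesten import simulate_ensemble

        for s in range(10):
            ens = simulate_ensemble(baseline_params, stationary_init, 48, seed=500 + s)
            ok = ens.alive[:, 0] & ens.alive[:, -1]
            out = rank_order_analysis(
                SizeSample(ens.sizes[ok, 0]), SizeSample(ens.sizes[ok, -1])
            )
            assert 0.0 < out["rank_rho"] < 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rank_order_analysis(
                SizeSample(np.ones(3) + np.arange(3)),
                SizeSample(np.ones(4) + np.arange(4)),
            )


class TestPerturbation:
    def test_null_perturbation_changes_nothing_systematic(self, baseline_params):
        init = np.ones(800)
        ratios = []
        for s in range(6):
            _, rep = perturbation_experiment(
                init, baseline_params, baseline_params, 24, 24, seed=900 + s
            )
            ratios.append(rep.mean_ratio)
        se = np.std(ratios, ddof=1) / np.sqrt(len(ratios))
        assert abs(np.mean(ratios) - 1.0) < 3 * se

    def test_eps_switch_rescales_like_the_mean_recursion(self):
        # 0.992 -> 0.995 with <eta> fixed at 0.008: the deterministic
        # recursion m <- 0.995 m + 0.008 gives the expected mean ratio
        pb = KestenParams(
            DistributionSpec.gaussian(0.992, 0.05),
            DistributionSpec.gaussian(0.008, 0.03),
        )
        pa = KestenParams(
            DistributionSpec.gaussian(0.995, 0.05),
            DistributionSpec.gaussian(0.008, 0.03),
        )
        m = 1.0
        for _ in range(48):
            m = 0.995 * m + 0.008
        init = limiting_sample(pb, 1000, 1500, seed=5).values
        init /= init.mean()
        ratios, ks_zs, rhos = [], [], []
        for s in range(8):
            _, rep = perturbation_experiment(init, pb, pa, 48, 48, seed=200 + s)
            ratios.append(rep.mean_ratio)
            ks_zs.append(rep.ks_z < rep.ks_critical)
            rhos.append(rep.rank_rho)
        se = np.std(ratios, ddof=1) / np.sqrt(len(ratios))
        assert abs(np.mean(ratios) - m) < 3 * se
        assert sum(ks_zs) >= len(ks_zs) - 1  # shape preserved
        assert all(r < 1.0 for r in rhos)  # rank order not preserved


class TestLognormalComparison:
    def test_lognormal_sample_prefers_its_own_fit(self):
        rng = np.random.default_rng(8)
        sample = SizeSample(rng.lognormal(0.0, 0.5, size=5000))
        mismatched = SizeSample(rng.lognormal(0.8, 0.2, size=5000))
        out = lognormal_comparison(sample, mismatched)
        assert out["cdf_error_lognormal"] < out["cdf_error_kesten"]

    def test_identical_reference_has_zero_error(self):
        vals = np.linspace(0.1, 2.0, 500)
        out = lognormal_comparison(SizeSample(vals), SizeSample(vals))
        assert out["cdf_error_kesten"] == 0.0

    def test_kesten_reference_wins_in_the_low_tail(self, baseline_params):
        wins = 0
        for s in range(7):
            sample = limiting_sample(baseline_params, 4000, 1500, seed=40 + s)
            ref = limiting_sample(baseline_params, 4000, 1500, seed=140 + s)
            out = lognormal_comparison(sample, ref)
            wins += (
                out["low_tail_errors"]["kesten"] < out["low_tail_errors"]["lognormal"]
            )
        assert wins >= 4  # majority of seeds
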