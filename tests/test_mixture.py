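import math

import numpy as np
import pytest
from scipy import stats

from pintervals import (
    ConjugateNormalPrior,
    EffectSizeTable,
    Family,
    TabulatedEffectPrior,
    TestSpec,
    classical_p_interval,
    conjugate_prediction_interval,
    delta_from_or,
    discretize_prior,
    mixture_prediction_interval,
    posterior_weights,
    predictive_cdf,
    predictive_quantile,
    p_to_stat,
    tabulated_prior_from_or_table,
)

NORMAL = TestSpec(Family.NORMAL)


class TestDiscretizePrior:
    @pytest.mark.parametrize("s0_sq", [1e-6, 1e-3, 0.25, 1.0, 49.0])
    def test_default_grid_has_76_components(self, s0_sq):
        assert discretize_prior(0.0, s0_sq).B == 76

    def test_unit_step_with_one_sigma_tails_gives_two_components(self):
        prior = discretize_prior(
            0.0, 1.0, step_fraction=1.0, tail_quantile=stats.norm.cdf(-1.0)
        )
        assert prior.B == 2

    @pytest.mark.parametrize("s0_sq", [1e-4, 0.5, 9.0])
    def test_probabilities_sum_to_one(self, s0_sq):
        prior = discretize_prior(0.0, s0_sq)
        assert prior.probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_variance_gives_point_mass(self):
        prior = discretize_prior(0.3, 0.0)
        assert prior.B == 1
        assert prior.values[0] == pytest.approx(0.3)

    def test_grid_masses_match_prior_cdf_differences(self):
        prior = discretize_prior(0.0, 1.0)
        # middle bins: mass should equal Phi increments of width sigma0/8
        mids = prior.values
        width = mids[1] - mids[0]
        expect = stats.norm.cdf(mids[30] + width / 2) - stats.norm.cdf(
            mids[30] - width / 2
        )
        # masses renormalized over the truncated range (factor ~1 - 2e-6)
        assert prior.probs[30] == pytest.approx(expect, rel=1e-5)

    def test_rejects_bad_tail_quantile(self):
        with pytest.raises(ValueError):
            discretize_prior(0.0, 1.0, tail_quantile=0.5)


def ncf_pdf_series(x, df1, df2, nc, k_max=300):
    """Independent oracle: noncentral F density as a Poisson mixture of
    scaled central F densities."""
    total = 0.0
    for k in range(k_max):
        w = stats.poisson.pmf(k, nc / 2.0)
        if w < 1e-18 and k > nc:
            break
        scale = df1 / (df1 + 2 * k)
        total += w * stats.f.pdf(x * scale, df1 + 2 * k, df2) * scale
    return total


class TestPosteriorWeights:
    def test_single_component_is_certain(self):
        prior = TabulatedEffectPrior(np.array([0.4]), np.array([1.0]))
        post = posterior_weights(prior, 2.7, NORMAL)
        assert post.post_probs == pytest.approx([1.0])

    def test_symmetric_observation_splits_evenly(self):
        prior = TabulatedEffectPrior(
            np.array([0.0, 2.0]), np.array([0.5, 0.5])
        )
        post = posterior_weights(prior, 1.0, NORMAL)
        assert post.post_probs == pytest.approx([0.5, 0.5], abs=1e-12)

    def test_zero_prior_probability_stays_zero(self):
        prior = TabulatedEffectPrior(
            np.array([-1.0, 0.0, 1.0]), np.array([0.0, 0.5, 0.5])
        )
        post = posterior_weights(prior, 0.4, NORMAL)
        assert post.post_probs[0] == 0.0

    def test_f_family_weights_match_density_series_oracle(self):
        # two-sample F test, n1 = n2 = 50: df1 = 1, df2 = 98
        spec = TestSpec(Family.F, df1=1, df2=98)
        prior = TabulatedEffectPrior(
            np.array([0.0, 2.25]), np.array([0.5, 0.5]), scale="delta_squared"
        )
        post = posterior_weights(prior, 4.0, spec)
        d0 = stats.f.pdf(4.0, 1, 98)
        d1 = ncf_pdf_series(4.0, 1, 98, 2.25)
        assert post.post_probs == pytest.approx(
            [d0 / (d0 + d1), d1 / (d0 + d1)], abs=1e-6
        )

    def test_log_space_normalization_survives_extreme_tail(self):
        prior = discretize_prior(0.0, 0.25)
        post = posterior_weights(prior, 19.0, NORMAL)  # density ~1e-80
        assert post.post_probs.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.isfinite(post.post_probs))

    def test_rescaled_prior_probabilities_leave_posterior_unchanged(self):
        values = np.array([-0.5, 0.0, 0.8])
        base = TabulatedEffectPrior(values, np.array([0.2, 0.5, 0.3]))
        # same ratios expressed through a different renormalization path
        other = TabulatedEffectPrior(values, np.array([0.04, 0.1, 0.06]) / 0.2)
        p1 = posterior_weights(base, 1.3, NORMAL).post_probs
        p2 = posterior_weights(other, 1.3, NORMAL).post_probs
        assert p1 == pytest.approx(p2, abs=1e-12)


class TestPredictiveCdf:
    def test_single_null_component_reduces_to_central_cdf(self):
        prior = TabulatedEffectPrior(np.array([0.0]), np.array([1.0]))
        post = posterior_weights(prior, 0.3, NORMAL)
        xs = np.linspace(-3, 3, 7)
        assert predictive_cdf(post, xs, NORMAL) == pytest.approx(
            stats.norm.cdf(xs)
        )

    def test_symmetric_two_component_midpoint(self):
        prior = TabulatedEffectPrior(np.array([0.0, 2.0]), np.array([0.5, 0.5]))
        post = posterior_weights(prior, 1.0, NORMAL)
        assert predictive_cdf(post, 1.0, NORMAL) == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "spec",
        [
            NORMAL,
            TestSpec(Family.STUDENT_T, df2=20),
            TestSpec(Family.CHI_SQUARE, df1=1),
            TestSpec(Family.F, df1=1, df2=40),
        ],
        ids=lambda s: s.family.value,
    )
    def test_proper_cdf_for_every_family(self, spec):
        prior = discretize_prior(0.0, 0.5)
        t_obt = 2.0
        post = posterior_weights(prior, t_obt, spec)
        lo = spec.support_lower if spec.support_lower > -math.inf else -30.0
        xs = np.linspace(lo, 150.0, 200)
        cdf = predictive_cdf(post, xs, spec)
        assert np.all(np.diff(cdf) >= -1e-12)
        assert cdf[0] == pytest.approx(0.0, abs=1e-8)
        assert cdf[-1] == pytest.approx(1.0, abs=1e-6)


class TestPredictiveQuantile:
    def test_central_normal_quantile(self):
        prior = TabulatedEffectPrior(np.array([0.0]), np.array([1.0]))
        post = posterior_weights(prior, 0.0, NORMAL)
        assert predictive_quantile(post, 0.9, NORMAL) == pytest.approx(
            1.281552, abs=1e-6
        )

    def test_round_trip_to_cdf_tolerance(self):
        prior = discretize_prior(0.0, 1.0)
        post = posterior_weights(prior, 1.7, NORMAL)
        for q in np.arange(0.01, 1.0, 0.07):
            x = predictive_quantile(post, q, NORMAL)
            assert abs(predictive_cdf(post, x, NORMAL) - q) <= 1e-10


class TestMixturePredictionInterval:
    def test_point_null_prior_gives_standard_normal_band(self):
        prior = TabulatedEffectPrior(np.array([0.0]), np.array([1.0]))
        iv = mixture_prediction_interval(t_obt=2.0, prior=prior, level=0.80)
        assert iv.stat_lower == pytest.approx(-1.281552, abs=1e-6)
        assert iv.stat_upper == pytest.approx(1.281552, abs=1e-6)

    @pytest.mark.parametrize("sigma0_sq", [0.25, 0.5, 1.0, 3.0])
    @pytest.mark.parametrize("p_obt", [0.01, 0.1, 0.446, 0.9])
    def test_default_grid_matches_conjugate_closed_form(self, sigma0_sq, p_obt):
        z = p_to_stat(p_obt)
        prior = discretize_prior(0.0, sigma0_sq)
        miv = mixture_prediction_interval(t_obt=z, prior=prior, level=0.8)
        civ = conjugate_prediction_interval(
            z, ConjugateNormalPrior(sigma0_sq=sigma0_sq), 0.8
        )
        assert miv.stat_lower == pytest.approx(civ.stat_lower, abs=1e-3)
        assert miv.stat_upper == pytest.approx(civ.stat_upper, abs=1e-3)

    def test_error_shrinks_as_grid_refines(self):
        z, sigma0_sq = p_to_stat(0.02), 0.5
        civ = conjugate_prediction_interval(
            z, ConjugateNormalPrior(sigma0_sq=sigma0_sq), 0.8
        )

        def err(step):
            prior = discretize_prior(0.0, sigma0_sq, step_fraction=step)
            miv = mixture_prediction_interval(t_obt=z, prior=prior, level=0.8)
            return max(
                abs(miv.stat_lower - civ.stat_lower),
                abs(miv.stat_upper - civ.stat_upper),
            )

        errors = [err(s) for s in (1 / 2, 1 / 4, 1 / 8, 1 / 16)]
        assert errors[-1] <= errors[0]
        assert errors[-1] < 5e-4

    def test_flat_prior_limit_recovers_classical_interval(self):
        # a very diffuse prior needs a grid fine relative to the unit
        # sampling noise, hence the small step fraction here
        p_obt = 0.05
        prior = discretize_prior(0.0, 1e6, step_fraction=5e-4)
        miv = mixture_prediction_interval(p_obt=p_obt, prior=prior, level=0.8)
        civ = classical_p_interval(p_obt, 0.8)
        assert miv.p_lower == pytest.approx(civ.p_lower, abs=1e-2)
        assert miv.p_upper == pytest.approx(civ.p_upper, abs=1e-2)


class TestTabulatedPriorFromOrTable:
    def test_single_row_covering_all_tests(self):
        table = EffectSizeTable(rows=((1.005, 1000),), total_tests=1000)
        prior = tabulated_prior_from_or_table(table, 100.0)
        assert prior.B == 1
        assert prior.probs == pytest.approx([1.0])

    def test_symmetric_rows_give_symmetric_grid(self):
        table = EffectSizeTable(
            rows=((1.3, 500), (1 / 1.3, 500)), total_tests=1000
        )
        prior = tabulated_prior_from_or_table(table, 100.0)
        assert prior.values[0] == pytest.approx(-prior.values[-1])
        assert prior.probs == pytest.approx([0.5, 0.5])

    def test_three_row_toy_table_weights_and_deltas(self):
        table = EffectSizeTable(
            rows=((1.005, 990), (1.2, 8), (1.5, 2)), total_tests=1000
        )
        prior = tabulated_prior_from_or_table(table, 100.0)
        # rows cover all mass, so no null component is added
        assert prior.B == 3
        assert prior.probs == pytest.approx([0.990, 0.008, 0.002])
        expected = sorted(
            delta_from_or(o, pooled_approximation=True)
            for o in (1.005, 1.2, 1.5)
        )
        assert prior.values == pytest.approx(expected)

    def test_residual_mass_split_between_null_or_and_inverse(self):
        table = EffectSizeTable(rows=((1.5, 100),), total_tests=1000)
        prior = tabulated_prior_from_or_table(table, 100.0)
        assert prior.B == 3
        assert prior.probs == pytest.approx([0.45, 0.45, 0.1])

    def test_overfull_table_rejected(self):
        with pytest.raises(ValueError):
            EffectSizeTable(rows=((1.2, 2000),), total_tests=1000)

    def test_delta_scale_prior_folds_for_chi_square(self):
        table = EffectSizeTable(
            rows=((1.3, 500), (1 / 1.3, 500)), total_tests=1000
        )
        prior = tabulated_prior_from_or_table(table, 100.0)
        spec = TestSpec(Family.CHI_SQUARE, df1=1, effective_n=100.0)
        post = posterior_weights(prior, 1.0, spec)
        # +/- delta fold to a single delta^2 component
        assert post.post_probs == pytest.approx([1.0])
        assert post.gammas[0] == pytest.approx(
            100.0 * delta_from_or(1.3, pooled_approximation=True) ** 2
        )
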