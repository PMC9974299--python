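import numpy as np
import pytest
from scipy.stats import norm, weibull_min

import mcprobit as m
from mcprobit.prior_posterior import (
    calc_posterior,
    default_grid,
    fit_weibull_mixture_prior,
    kl_divergence,
    kl_divergence_masses,
    ordinalize_continuous,
    point_and_interval,
    prior_density,
    sample_prior,
)


class TestWeibullMixturePrior:
    def test_single_component_recovery(self):
        rng = np.random.default_rng(1)
        x = weibull_min.rvs(2.0, scale=10.0, size=5000, random_state=rng)
        prior = fit_weibull_mixture_prior(x, n_components=1, seed=0)
        (_, shape, scale), = prior.components
        assert shape == pytest.approx(2.0, rel=0.05)
        assert scale == pytest.approx(10.0, rel=0.05)

    def test_two_separated_components_weights_recovered(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([
            weibull_min.rvs(3.0, scale=2.0, size=3000, random_state=rng),
            weibull_min.rvs(4.0, scale=15.0, size=7000, random_state=rng),
        ])
        prior = fit_weibull_mixture_prior(x, n_components=2, seed=0)
        weights = sorted(c[0] for c in prior.components)
        assert weights[0] == pytest.approx(0.3, abs=0.05)
        assert weights[1] == pytest.approx(0.7, abs=0.05)

    def test_em_loglik_trace_nondecreasing(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([
            weibull_min.rvs(1.5, scale=3.0, size=1000, random_state=rng),
            weibull_min.rvs(5.0, scale=12.0, size=1000, random_state=rng),
        ])
        _, trace = fit_weibull_mixture_prior(x, n_components=2, seed=0, full_output=True)
        assert np.all(np.diff(trace) >= -1e-7 * (1 + np.abs(trace[:-1])))

    def test_bic_selection_returns_valid_prior(self):
        rng = np.random.default_rng(4)
        x = weibull_min.rvs(2.0, scale=8.0, size=800, random_state=rng)
        prior = fit_weibull_mixture_prior(x, seed=0, max_components=2)
        assert abs(sum(c[0] for c in prior.components) - 1.0) < 1e-12


class TestPriorDensity:
    def test_uniform_density_value(self):
        prior = m.PriorSpec(kind="uniform", x_min=0.0, x_max=10.0)
        grid = prior_density(prior, np.linspace(0, 10, 513))
        assert np.allclose(grid.f, 0.1, atol=1e-12)

    def test_mixture_integrates_to_one_on_wide_grid(self):
        prior = m.PriorSpec(
            kind="weibull_mixture",
            components=((0.4, 2.0, 3.0), (0.6, 3.0, 12.0)),
        )
        grid = prior_density(prior, np.linspace(1e-3, 60, 2049))
        assert grid.integral() == pytest.approx(1.0, abs=1e-4)

    def test_offset_support(self):
        prior = m.PriorSpec(kind="weibull_mixture", x0=0.5, components=((1.0, 2.0, 5.0),))
        x = np.linspace(0.0, 20.0, 201)
        from mcprobit.prior_posterior import prior_pdf

        f = prior_pdf(prior, x)
        assert np.all(f[x <= 0.5] == 0.0)
        assert f[x > 1.0].max() > 0

    def test_grid_outside_support_rejected(self):
        prior = m.PriorSpec(kind="uniform", x_min=5.0, x_max=6.0)
        with pytest.raises(m.ValidationError):
            prior_density(prior, np.linspace(10, 20, 11))

    def test_sampling_matches_density_mean(self):
        prior = m.PriorSpec(kind="weibull_mixture", components=((1.0, 2.0, 10.0),))
        draws = sample_prior(prior, 20000, np.random.default_rng(0))
        assert draws.mean() == pytest.approx(10.0 * 0.8862, rel=0.02)  # scale*Gamma(1.5)


@pytest.fixture(scope="module")
def single_continuous_model():
    spec = m.VariableSpec("w", "continuous", noise_spec="const", group="g")
    theta_u = m.ThetaUnivariate(mean=(1.0, 1.0, 1e-12), noise=(1.0,))  # mean ~= x
    theta = m.ThetaMultivariate((theta_u,), (), ("g",))
    return spec, theta


class TestPosterior:
    def test_all_missing_returns_prior(self, single_continuous_model):
        spec, theta = single_continuous_model
        prior = m.PriorSpec(kind="uniform", x_min=0.1, x_max=10.0)
        x_calc = np.linspace(0.1, 10, 257)
        post = calc_posterior([0.0], [False], theta, (spec,), prior, x_calc)
        assert np.allclose(post.f, prior_density(prior, x_calc).f)

    def test_posterior_mode_at_matching_x(self, single_continuous_model):
        spec, theta = single_continuous_model
        prior = m.PriorSpec(kind="uniform", x_min=0.1, x_max=10.0)
        x_calc = np.linspace(0.1, 10, 991)
        post = calc_posterior([5.0], [True], theta, (spec,), prior, x_calc)
        assert x_calc[np.argmax(post.f)] == pytest.approx(5.0, abs=0.02)

    def test_posterior_equals_normalized_likelihood_under_flat_prior(self, single_continuous_model):
        # Bayes consistency: uniform prior, single homoscedastic continuous
        # variable with mean ~ x -> posterior is the normalized N(w, 1) curve
        spec, theta = single_continuous_model
        prior = m.PriorSpec(kind="uniform", x_min=0.1, x_max=10.0)
        x_calc = np.linspace(0.1, 10, 513)
        post = calc_posterior([5.0], [True], theta, (spec,), prior, x_calc)
        lik = norm.pdf(x_calc, loc=5.0, scale=1.0)
        lik /= np.trapezoid(lik, x_calc)
        assert np.max(np.abs(post.f - lik)) < 1e-10

    def test_grid_refinement_stability(self, single_continuous_model):
        spec, theta = single_continuous_model
        prior = m.PriorSpec(kind="uniform", x_min=0.1, x_max=10.0)
        means = []
        for n in (513, 1025):
            post = calc_posterior([4.0], [True], theta, (spec,), prior,
                                  np.linspace(0.1, 10, n))
            means.append(point_and_interval(post)[0])
        assert abs(means[0] - means[1]) < 1e-3

    def test_posterior_integrates_to_one(self, paper_fixture):
        specs, theta, x_prior, _ = m.paper_like_design()
        prior = m.PriorSpec(kind="uniform", x_min=0.05, x_max=22.0)
        x_calc = np.linspace(0.05, 22.0, 513)
        row = 0
        post = calc_posterior(
            paper_fixture.Y[row], paper_fixture.mask[row], theta, specs, prior, x_calc
        )
        assert post.integral() == pytest.approx(1.0, abs=1e-8)


class TestPointAndInterval:
    def test_symmetric_triangle_mean(self):
        x = np.linspace(0, 10, 1001)
        f = np.maximum(0.0, 1 - np.abs(x - 5) / 2)
        g = m.DensityGrid(x, f).normalize()
        mean, lo, hi = point_and_interval(g)
        assert mean == pytest.approx(5.0, abs=1e-9)

    def test_uniform_equal_tailed_interval(self):
        x = np.linspace(0, 10, 513)
        g = m.DensityGrid(x, np.full_like(x, 0.1))
        mean, lo, hi = point_and_interval(g)
        assert (lo, hi) == pytest.approx((0.25, 9.75), abs=1e-12)

    def test_narrow_gaussian_interval_width(self):
        sigma = 0.05
        x = np.linspace(2.0, 4.0, 4001)
        g = m.DensityGrid(x, norm.pdf(x, 3.0, sigma)).normalize()
        mean, lo, hi = point_and_interval(g)
        assert mean == pytest.approx(3.0, abs=1e-6)
        assert hi - lo == pytest.approx(2 * norm.ppf(0.975) * sigma, rel=1e-3)


class TestKL:
    def test_self_divergence_zero(self):
        x = np.linspace(0, 10, 101)
        P = m.DensityGrid(x, norm.pdf(x, 5, 1)).normalize()
        assert kl_divergence(P, P) == 0.0

    def test_two_point_example_one_bit(self):
        assert kl_divergence_masses([1.0, 0.0], [0.5, 0.5]) == pytest.approx(1.0)

    def test_hand_computed_two_point_value(self):
        expected = 0.75 * np.log2(1.5) + 0.25 * np.log2(0.5)
        assert kl_divergence_masses([0.75, 0.25], [0.5, 0.5]) == pytest.approx(expected)
        assert expected == pytest.approx(0.18872, abs=1e-5)

    def test_prior_mass_missing_gives_infinity(self):
        with pytest.warns(UserWarning):
            assert kl_divergence_masses([0.5, 0.5], [1.0, 0.0]) == np.inf

    def test_narrower_noise_gives_larger_kl(self):
        # overconfidence mechanism: a tighter likelihood concentrates the
        # posterior more, hence larger divergence from the same prior
        prior = m.PriorSpec(kind="uniform", x_min=0.1, x_max=10.0)
        x_calc = np.linspace(0.1, 10, 513)
        q = prior_density(prior, x_calc)
        kls = []
        for sd in (1.0, 0.3):
            spec = m.VariableSpec("w", "continuous", noise_spec="const", group="g")
            theta_u = m.ThetaUnivariate(mean=(1.0, 1.0, 1e-9), noise=(sd,))
            theta = m.ThetaMultivariate((theta_u,), (), ("g",))
            post = calc_posterior([5.0], [True], theta, (spec,), prior, x_calc)
            kls.append(kl_divergence(post, q))
        assert kls[1] > kls[0]


class TestOrdinalize:
    @pytest.mark.parametrize(
        "w, expected",
        [(-5.0, 0), (0.5, 0), (1.0, 0), (1.5, 1), (2.0, 1), (2.5, 2), (10.0, 3)],
    )
    def test_right_closed_binning(self, w, expected):
        assert ordinalize_continuous(w, [1.0, 2.0, 3.0]) == expected

    def test_three_cutpoints_give_four_stages(self):
        stages = ordinalize_continuous(np.linspace(-5, 10, 100), [1.0, 2.0, 3.0])
        assert set(stages.tolist()) == {0, 1, 2, 3}


def test_default_grid_spans_prior_quantiles():
    prior = m.PriorSpec(kind="uniform", x_min=0.0, x_max=10.0)
    grid = default_grid(prior, n=513)
    assert grid.size == 513
    assert grid[0] == pytest.approx(0.005, abs=1e-9)
    assert grid[-1] == pytest.approx(9.995, abs=1e-9)
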