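import itertools

import numpy as np
import pytest

import mcprobit as m
from mcprobit._mvn import mvn_rectangle_probability
from mcprobit.multivariate import (
    build_covariance,
    correlation_from_groups,
    correlation_matrix,
    loglik_mixed_dataset,
    loglik_mixed_single,
    marginalize_missing,
)
from mcprobit.response_models import loglik_univariate


class TestGroupedCorrelations:
    def test_four_group_structure_has_eight_terms(self):
        grouping = ("ef", "oss", "dental", "dental", "long", "long")
        from mcprobit.multivariate import z_layout

        _, slots = z_layout(grouping)
        assert len(slots) == 8
        assert sum(1 for s in slots if s[0] == "within") == 2
        assert sum(1 for s in slots if s[0] == "between") == 6

    def test_zero_z_gives_zero_correlations(self):
        grouping = ("a", "a", "b")
        z = np.zeros(2)
        for i, l in itertools.combinations(range(3), 2):
            assert correlation_from_groups(i, l, grouping, z) == 0.0

    def test_symmetry_in_variable_pair(self):
        grouping = ("a", "b", "a")
        z = np.array([0.5, 0.2])  # within a, between (a, b)
        for i, l in itertools.combinations(range(3), 2):
            assert correlation_from_groups(i, l, grouping, z) == correlation_from_groups(
                l, i, grouping, z
            )

    def test_singleton_within_group_term_is_structural_error(self):
        from mcprobit.multivariate import within_group_correlation

        with pytest.raises(m.ValidationError, match="fewer than two members"):
            within_group_correlation("a", ("a", "b"), np.array([0.1]))

    def test_correlation_matrix_is_symmetric_unit_diagonal(self):
        grouping = ("a", "a", "b", "c")
        z = np.array([0.5, 0.3, -0.2, 0.1])
        R = correlation_matrix(grouping, z)
        assert np.allclose(R, R.T)
        assert np.allclose(np.diag(R), 1.0)
        assert R[0, 1] == 0.5  # within-group term


class TestBuildCovariance:
    def test_zero_z_is_diagonal_of_squared_sds(self, four_variable_dataset):
        data, theta = four_variable_dataset
        cov = build_covariance(2.0, data.specs, theta.thetas, np.zeros(4), theta.grouping)
        assert np.allclose(cov.sigma, np.diag(cov.sd**2))

    def test_off_diagonal_scales_with_sds(self):
        specs = (
            m.VariableSpec("w1", "continuous", noise_spec="const", group="a"),
            m.VariableSpec("w2", "continuous", noise_spec="const", group="b"),
        )
        thetas = (
            m.ThetaUnivariate(mean=(1.0, 1.0, 1.0), noise=(1.0,)),
            m.ThetaUnivariate(mean=(1.0, 1.0, 1.0), noise=(2.0,)),
        )
        cov = build_covariance(1.0, specs, thetas, np.array([0.5]), ("a", "b"))
        assert cov.sigma[0, 1] == pytest.approx(1.0)  # 0.5 * 1 * 2

    def test_heteroscedastic_diagonal_grows_with_x_correlation_fixed(self):
        specs = (
            m.VariableSpec("w1", "continuous", noise_spec="lin_pos_int", group="a"),
            m.VariableSpec("w2", "continuous", noise_spec="lin_pos_int", group="b"),
        )
        thetas = (
            m.ThetaUnivariate(mean=(1.0, 1.0, 1.0), noise=(1.0, 0.5)),
            m.ThetaUnivariate(mean=(1.0, 1.0, 1.0), noise=(2.0, 0.5)),
        )
        c1 = build_covariance(1.0, specs, thetas, np.array([0.5]), ("a", "b"))
        c2 = build_covariance(5.0, specs, thetas, np.array([0.5]), ("a", "b"))
        assert np.all(np.diag(c2.sigma) > np.diag(c1.sigma))
        rho1 = c1.sigma[0, 1] / np.prod(c1.sd)
        rho2 = c2.sigma[0, 1] / np.prod(c2.sd)
        assert rho1 == pytest.approx(rho2) == pytest.approx(0.5)


class TestMixedLikelihood:
    def test_conditional_independence_equals_stacked_univariate(self, four_variable_dataset):
        data, theta = four_variable_dataset
        theta_ci = m.ThetaMultivariate(theta.thetas, np.zeros(4), theta.grouping)
        ll_mv = loglik_mixed_dataset(data, theta_ci)
        ll_uni = sum(
            loglik_univariate(*data.observed(s.name)[::-1], theta.thetas[j], s)
            for j, s in enumerate(data.specs)
        )
        assert ll_mv == pytest.approx(ll_uni, abs=1e-8)

    def test_single_continuous_component_reduces_to_univariate(self, four_variable_dataset):
        data, theta = four_variable_dataset
        mask = np.array([False, False, True, False])
        y = np.array([0.0, 0.0, 25.0, 0.0])
        ll = loglik_mixed_single(y, mask, 2.0, theta, data.specs)
        expected = loglik_univariate(25.0, 2.0, theta.thetas[2], data.specs[2])
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_correlated_rectangle_matches_quadrature_oracle(self, four_variable_dataset):
        # two ordinal variables, within-group correlation 0.5, no continuous
        data, theta = four_variable_dataset
        mask = np.array([True, True, False, False])
        y = np.array([1.0, 2.0, 0.0, 0.0])
        x = 2.0
        ll = loglik_mixed_single(y, mask, x, theta, data.specs)
        # oracle: standardized box of the two ordinal components
        from mcprobit.response_models import mean_response, noise_sd
        from mcprobit.synthetic_data import oracle_rectangle_probability

        R = correlation_matrix(theta.grouping, np.asarray(theta.z))[:2, :2]
        lo, hi = [], []
        for j in (0, 1):
            g = float(mean_response(x, theta.thetas[j], data.specs[j]))
            sd = float(noise_sd(x, data.specs[j].noise_spec, theta.thetas[j].noise))
            t = np.concatenate(([-np.inf], theta.thetas[j].tau, [np.inf]))
            v = int(y[j])
            lo.append((t[v] - g) / sd)
            hi.append((t[v + 1] - g) / sd)
        p_oracle = oracle_rectangle_probability(lo, hi, cov=R)
        assert np.exp(ll) == pytest.approx(p_oracle, abs=1e-6)

    def test_all_missing_contributes_zero(self, four_variable_dataset):
        data, theta = four_variable_dataset
        assert loglik_mixed_single(np.zeros(4), np.zeros(4, bool), 2.0, theta, data.specs) == 0.0

    def test_marginalization_index_sets(self, four_variable_dataset):
        data, _ = four_variable_dataset
        cont, ordn = marginalize_missing([True, False, True, True], data.specs)
        assert cont.tolist() == [2, 3]
        assert ordn.tolist() == [0]

    def test_dropping_variable_equals_reduced_model(self, four_variable_dataset):
        from tests_helpers import reduced_theta

        data, theta = four_variable_dataset
        row = 0
        for drop in range(4):
            mask = data.mask[row].copy()
            mask[drop] = False
            ll_masked = loglik_mixed_single(data.Y[row], mask, data.x[row], theta, data.specs)
            keep = [j for j in range(4) if j != drop]
            theta_red = reduced_theta(theta, keep)
            ll_red = loglik_mixed_single(
                data.Y[row, keep], mask[keep], data.x[row], theta_red,
                [data.specs[j] for j in keep],
            )
            assert ll_masked == pytest.approx(ll_red, abs=1e-8)

    def test_widening_ordinal_rectangle_never_decreases_likelihood(self, four_variable_dataset):
        data, theta = four_variable_dataset
        # widen stage v to the union of stages v and v+1 by comparing
        # P(v) + P(v+1) >= P(v): rectangle monotonicity at the probability level
        mask = np.array([True, True, False, False])
        x = 1.5
        for v in range(3):
            p_narrow = np.exp(
                loglik_mixed_single(np.array([1.0, v, 0, 0]), mask, x, theta, data.specs)
            )
            p_wide = p_narrow + np.exp(
                loglik_mixed_single(np.array([1.0, v + 1, 0, 0]), mask, x, theta, data.specs)
            )
            assert p_wide >= p_narrow

    def test_dataset_additivity_and_permutation_invariance(self, four_variable_dataset):
        data, theta = four_variable_dataset
        ll = loglik_mixed_dataset(data, theta)
        doubled = m.MixedDataset(
            np.concatenate([data.x, data.x]),
            np.vstack([data.Y, data.Y]),
            np.vstack([data.mask, data.mask]),
            data.specs,
        )
        assert loglik_mixed_dataset(doubled, theta) == pytest.approx(2 * ll, rel=1e-14)
        rng = np.random.default_rng(0)
        perm = rng.permutation(data.n)
        assert loglik_mixed_dataset(data.subset_rows(perm), theta) == ll

    def test_single_row_dataset_reduces_to_single(self, four_variable_dataset):
        data, theta = four_variable_dataset
        one = data.subset_rows(np.array([5]))
        assert loglik_mixed_dataset(one, theta) == pytest.approx(
            loglik_mixed_single(data.Y[5], data.mask[5], data.x[5], theta, data.specs),
            rel=1e-12,
        )


class TestRectangleIntegrator:
    def test_full_space_box_is_one(self):
        cov = np.array([[1, 0.4, 0.2], [0.4, 1, 0.5], [0.2, 0.5, 1]])
        p = mvn_rectangle_probability([-np.inf] * 3, [np.inf] * 3, cov=cov)
        assert p == pytest.approx(1.0, abs=1e-10)

    def test_one_dimensional_interval(self):
        from scipy.stats import norm

        p = mvn_rectangle_probability([-1.0], [1.0])
        assert p == pytest.approx(norm.cdf(1) - norm.cdf(-1), abs=1e-12)

    def test_independence_factorizes(self):
        from scipy.stats import norm

        p = mvn_rectangle_probability([-1.0, 0.0], [1.0, 2.0], cov=np.diag([1.0, 4.0]))
        expected = (norm.cdf(1) - norm.cdf(-1)) * (norm.cdf(1) - norm.cdf(0))
        assert p == pytest.approx(expected, abs=1e-12)

    def test_deterministic_given_seed(self):
        cov = np.array([[1, 0.6], [0.6, 1]])
        args = ([-1, -0.5], [0.5, 2.0])
        assert mvn_rectangle_probability(*args, cov=cov, seed=7) == mvn_rectangle_probability(
            *args, cov=cov, seed=7
        )

    def test_agrees_with_scipy(self):
        from scipy.stats import multivariate_normal

        cov = np.array([[2.0, 0.7, 0.3], [0.7, 1.5, -0.4], [0.3, -0.4, 1.0]])
        lo = np.array([-1.0, -2.0, -0.5])
        hi = np.array([1.5, 0.5, 2.0])
        ours = mvn_rectangle_probability(lo, hi, cov=cov, tol=1e-8)
        ref = multivariate_normal.cdf(hi, mean=np.zeros(3), cov=cov, lower_limit=lo,
                                      abseps=1e-10, releps=1e-10)
        assert ours == pytest.approx(ref, abs=1e-6)
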