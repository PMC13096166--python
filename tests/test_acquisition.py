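import numpy as np
import pytest

from phbo import (
    AcquisitionConfig,
    CategoricalPolicy,
    CategoricalVariable,
    ContinuousVariable,
    FittedSurrogate,
    HybridPoint,
    HybridSpace,
    ObservationSet,
    exact_expected_acquisition,
    mc_expected_acquisition,
    optimize_acquisition,
    reinforce_grad_theta,
    reinforce_grad_theta_cv,
    ucb,
)
from phbo.acquisition import (
    _as_alpha_value_grad,
    enumeration_grad_theta,
    grad_x_expected,
)

from conftest import default_hyp, make_surrogate


class TestUCB:
    def test_zero_beta_is_posterior_mean(self, small_space):
        surr = make_surrogate(small_space, n=8, seed=0)
        rng = np.random.default_rng(1)
        p = small_space.random_point(rng)
        mean, _ = surr.posterior(p)
        assert ucb(surr, p, 0.0) == pytest.approx(mean)

    def test_monotone_in_beta(self, small_space):
        surr = make_surrogate(small_space, n=8, seed=0)
        p = small_space.random_point(np.random.default_rng(2))
        assert ucb(surr, p, 4.0) >= ucb(surr, p, 1.0)
        with pytest.raises(ValueError):
            ucb(surr, p, -1.0)

    def test_equals_observation_at_noiseless_training_point(self, small_space):
        rng = np.random.default_rng(3)
        p = small_space.random_point(rng)
        obs = ObservationSet()
        obs.add(p, 0.9)
        obs.add(small_space.random_point(rng), 0.1)
        surr = FittedSurrogate.from_observations(
            obs, small_space, default_hyp(small_space, noise_variance=1e-10)
        )
        assert ucb(surr, p, 4.0) == pytest.approx(0.9, abs=1e-3)


class TestPolicy:
    def test_probabilities_normalize(self):
        pol = CategoricalPolicy([np.array([0.0, 3.0, -2.0]), np.array([1.0, 1.0])])
        for p in pol.probs():
            assert p.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(p > 0)

    def test_point_mass_concentrates(self):
        pol = CategoricalPolicy.point_mass([1], [3], clip=10)
        p = pol.probs()[0]
        assert p[1] > 1 - 1e-8

    def test_frozen_uniforms_give_deterministic_draws(self):
        pol = CategoricalPolicy([np.array([0.5, -0.5, 0.1])])
        uni = np.random.default_rng(0).uniform(size=(64, 1))
        a = pol.sample_indices(64, uniforms=uni)
        b = pol.sample_indices(64, uniforms=uni)
        assert np.array_equal(a, b)


def table_alpha(values):
    """Acquisition stub: per-combination lookup table over level indices."""
    values = np.asarray(values, dtype=float)

    def alpha(U, C):
        if C.shape[1] == 0:
            return np.zeros(len(U))
        idx = tuple(C[:, j] for j in range(C.shape[1]))
        return values[idx]

    return alpha


class TestExpectedAcquisition:
    def test_point_mass_reduces_to_alpha(self, tiny_space):
        surr = make_surrogate(tiny_space, n=6, seed=4)
        pol = CategoricalPolicy.point_mass([2], [3])
        u = np.array([0.3])
        expected = exact_expected_acquisition(surr, u, pol, ucb_beta=4.0)
        point = tiny_space.denormalize(u, [2])
        assert expected == pytest.approx(ucb(surr, point, 4.0), abs=1e-7)
        # Monte Carlo agrees exactly for any sample size under a point mass
        assert mc_expected_acquisition(surr, u, pol, n_mc=5, seed=0, ucb_beta=4.0) == pytest.approx(expected, abs=1e-7)

    def test_uniform_two_levels_averages(self):
        alpha = table_alpha([1.0, 3.0])
        pol = CategoricalPolicy([np.zeros(2)])
        assert exact_expected_acquisition(alpha, np.zeros(0), pol) == pytest.approx(2.0)

    def test_two_by_two_hand_enumeration(self):
        vals = np.array([[1.0, 2.0], [5.0, 7.0]])
        alpha = table_alpha(vals)
        pol = CategoricalPolicy([np.log([0.3, 0.7]), np.log([0.9, 0.1])])
        hand = sum(
            pa * pb * vals[i, j]
            for i, pa in enumerate([0.3, 0.7])
            for j, pb in enumerate([0.9, 0.1])
        )
        assert exact_expected_acquisition(alpha, np.zeros(0), pol) == pytest.approx(hand, rel=1e-12)

    def test_mc_is_seed_deterministic(self, tiny_space):
        surr = make_surrogate(tiny_space, n=6, seed=5)
        pol = CategoricalPolicy([np.array([0.2, -0.1, 0.4])])
        u = np.array([0.6])
        v1 = mc_expected_acquisition(surr, u, pol, n_mc=256, seed=42)
        v2 = mc_expected_acquisition(surr, u, pol, n_mc=256, seed=42)
        assert v1 == v2

    def test_mc_standard_error_scales_with_sample_size(self):
        rng = np.random.default_rng(6)
        alpha = table_alpha(rng.uniform(size=(3, 4)))
        pol = CategoricalPolicy([rng.normal(size=3), rng.normal(size=4)])
        reps = 200

        def se(n_mc, base):
            vals = [
                mc_expected_acquisition(alpha, np.zeros(0), pol, n_mc=n_mc, seed=base + i)
                for i in range(reps)
            ]
            return np.std(vals)

        ratio = se(128, 10_000) / se(8192, 50_000)
        assert 4.0 < ratio < 16.0  # ideal sqrt(8192/128) = 8


class TestGradients:
    def test_constant_alpha_has_zero_gradients(self):
        alpha = table_alpha(np.full((3, 2), 2.5))
        pol = CategoricalPolicy([np.array([0.3, -0.2, 0.0]), np.zeros(2)])
        exact = enumeration_grad_theta(alpha, np.zeros(0), pol)
        for g in exact:
            assert np.allclose(g, 0.0, atol=1e-12)
        # score-function estimator is exactly zero with a perfect baseline
        g_cv = reinforce_grad_theta_cv(alpha, np.zeros(0), pol, n_mc=64, baseline=2.5, seed=0)
        for g in g_cv:
            assert np.allclose(g, 0.0, atol=1e-12)

    def test_degenerate_policy_gradients_vanish(self, tiny_space):
        surr = make_surrogate(tiny_space, n=6, seed=7)
        pol = CategoricalPolicy.point_mass([1], [3], clip=12)
        g = reinforce_grad_theta(surr, np.array([0.5]), pol, n_mc=128, seed=1)
        assert np.max(np.abs(g[0])) < 1e-3

    def test_continuous_gradient_matches_analytic_route(self, small_space):
        surr = make_surrogate(small_space, n=10, seed=8)
        rng = np.random.default_rng(9)
        pol = CategoricalPolicy([rng.normal(size=3), rng.normal(size=2)])
        u = rng.uniform(0.2, 0.8, size=2)
        g_fd = grad_x_expected(surr, u, pol, ucb_beta=4.0)
        # independent analytic route: probability-weighted posterior grads
        from phbo.space import enumerate_combination_indices

        combos = enumerate_combination_indices([3, 2])
        w = pol.combination_probs(combos)
        vg = _as_alpha_value_grad(surr, 4.0, 1e-5)
        _, grads = vg(np.broadcast_to(u, (len(combos), 2)).copy(), combos)
        assert np.allclose(g_fd, w @ grads, atol=1e-4)

    def test_degenerate_policy_continuous_gradient(self, tiny_space):
        surr = make_surrogate(tiny_space, n=6, seed=10)
        pol = CategoricalPolicy.point_mass([0], [3], clip=14)
        u = np.array([0.4])
        g = grad_x_expected(surr, u, pol, ucb_beta=0.0)
        h = 1e-5
        up = surr.posterior_arrays(np.array([[0.4 + h]]), np.array([[0]]))[0][0]
        um = surr.posterior_arrays(np.array([[0.4 - h]]), np.array([[0]]))[0][0]
        assert g[0] == pytest.approx((up - um) / (2 * h), rel=1e-3, abs=1e-6)

    def test_reinforce_matches_enumeration_in_expectation(self):
        rng = np.random.default_rng(11)
        alpha = table_alpha(rng.uniform(1, 2, size=(3, 2)))
        pol = CategoricalPolicy([rng.normal(size=3), rng.normal(size=2)])
        exact = np.concatenate(enumeration_grad_theta(alpha, np.zeros(0), pol))
        est = np.concatenate(
            reinforce_grad_theta(alpha, np.zeros(0), pol, n_mc=200_000, seed=12)
        )
        assert np.allclose(est, exact, atol=0.01)

    def test_zero_baseline_reduces_to_plain_estimator(self):
        rng = np.random.default_rng(13)
        alpha = table_alpha(rng.uniform(size=(4,)))
        pol = CategoricalPolicy([rng.normal(size=4)])
        g1 = reinforce_grad_theta(alpha, np.zeros(0), pol, n_mc=64, seed=3)
        g2 = reinforce_grad_theta_cv(alpha, np.zeros(0), pol, n_mc=64, baseline=0.0, seed=3)
        assert np.array_equal(g1[0], g2[0])

    def test_control_variate_reduces_variance_for_offset_alpha(self):
        rng = np.random.default_rng(14)
        alpha = table_alpha(10.0 + rng.uniform(size=(3, 3)))
        pol = CategoricalPolicy([rng.normal(size=3), rng.normal(size=3)])
        baseline = 10.5
        plain, cv = [], []
        for i in range(400):
            plain.append(np.concatenate(reinforce_grad_theta(alpha, np.zeros(0), pol, n_mc=16, seed=1000 + i)))
            cv.append(np.concatenate(reinforce_grad_theta_cv(alpha, np.zeros(0), pol, n_mc=16, baseline=baseline, seed=1000 + i)))
        var_plain = np.var(np.array(plain), axis=0).sum()
        var_cv = np.var(np.array(cv), axis=0).sum()
        assert var_cv < var_plain


class TestOptimizeAcquisition:
    def test_single_level_space_reduces_to_continuous(self):
        space = HybridSpace(
            categoricals=(CategoricalVariable("c", ("only",)),),
            continuous=(ContinuousVariable("x", 0.0, 1.0),),
        )
        surr = make_surrogate(space, n=6, seed=15)
        cfg = AcquisitionConfig(n_restarts=4, maxiter=40)
        point, value = optimize_acquisition(surr, space, cfg, np.random.default_rng(16))
        assert point.z == {"c": "only"}
        assert 0.0 <= point.x["x"] <= 1.0
        # value equals alpha at the returned point
        assert value == pytest.approx(ucb(surr, point, cfg.ucb_beta), abs=1e-8)

    def test_feasibility_and_determinism(self, small_space):
        surr = make_surrogate(small_space, n=10, seed=17)
        cfg = AcquisitionConfig(n_restarts=3, maxiter=25)
        p1, v1 = optimize_acquisition(surr, small_space, cfg, np.random.default_rng(18))
        p2, v2 = optimize_acquisition(surr, small_space, cfg, np.random.default_rng(18))
        assert p1 == p2 and v1 == v2
        small_space.validate_point(p1)

    def test_attains_enumerated_maximum_on_tiny_problem(self, tiny_space):
        rng = np.random.default_rng(19)
        obs = ObservationSet()
        # level 'b' clearly best
        for lev, peak in (("a", 0.2), ("b", 1.0), ("c", 0.4)):
            for x in (0.2, 0.5, 0.8):
                obs.add(
                    HybridPoint(z={"ligand": lev}, x={"x": x}),
                    peak * np.exp(-((x - 0.5) ** 2) / 0.08),
                )
        surr = FittedSurrogate.from_observations(obs, tiny_space, default_hyp(tiny_space))
        cfg = AcquisitionConfig(n_restarts=8, maxiter=60)
        point, value = optimize_acquisition(surr, tiny_space, cfg, np.random.default_rng(20))
        # oracle: per-level continuous optimization on a dense grid + polish
        best = -np.inf
        for lev in range(3):
            grid = np.linspace(0, 1, 2001)
            vals = surr.posterior_arrays(grid[:, None], np.full((2001, 1), lev))
            alpha_vals = vals[0] + 2.0 * np.sqrt(vals[1])
            best = max(best, float(alpha_vals.max()))
        assert value == pytest.approx(best, abs=1e-3)
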