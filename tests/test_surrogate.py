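import numpy as np
import pytest

from phbo import (
    CategoricalVariable,
    ContinuousVariable,
    FittedSurrogate,
    GPHyperparameters,
    HybridPoint,
    HybridSpace,
    ObservationSet,
    SurrogateConfig,
    fit_mle,
    gram_matrix,
    k_cat,
    k_con,
    k_hyb,
    log_marginal_likelihood,
)
from phbo.surrogate import _nll_and_grad, hybrid_kernel_matrix

from conftest import default_hyp, make_surrogate, random_observations


class TestCategoricalKernel:
    def test_equal_levels_give_one(self):
        for l in (0.01, 1.0, 100.0):
            assert k_cat("a", "a", l) == 1.0

    def test_unequal_levels_follow_exponential(self):
        assert k_cat("a", "b", 1.0) == pytest.approx(np.exp(-1.0))
        # large lengthscale makes levels indistinguishable
        assert k_cat("a", "b", 1e9) == pytest.approx(1.0, abs=1e-8)
        # tiny lengthscale makes them independent
        assert k_cat("a", "b", 0.01) < 1e-20

    def test_nonpositive_lengthscale_rejected(self):
        with pytest.raises(ValueError):
            k_cat("a", "b", 0.0)


class TestContinuousKernel:
    def test_zero_distance_is_one(self):
        assert k_con([0.3, 0.7], [0.3, 0.7], [0.5, 0.5]) == 1.0

    def test_matern52_closed_form_at_unit_scaled_distance(self):
        # single dimension, d/l = 1
        s5 = np.sqrt(5.0)
        expected = (1 + s5 + 5.0 / 3.0) * np.exp(-s5)
        assert k_con([0.0], [0.5], [0.5]) == pytest.approx(expected, rel=1e-12)

    def test_long_distance_decays_to_zero(self):
        assert k_con([0.0], [100.0], [0.1]) < 1e-12

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            k_con([0.0, 1.0], [0.0], [0.5, 0.5])


class TestHybridKernel:
    def test_mix_weight_extremes_reduce_to_sum_and_product(self, small_space):
        rng = np.random.default_rng(0)
        p, q = small_space.random_point(rng), small_space.random_point(rng)
        for _ in range(10):
            hyp0 = default_hyp(small_space, mix_weight=0.0)
            hyp1 = default_hyp(small_space, mix_weight=1.0)
            u1, c1 = small_space.normalize(p)
            u2, c2 = small_space.normalize(q)
            kc = k_con(u1, u2, hyp0.cont_lengthscales)
            kz = 1.0
            for j in range(2):
                kz *= k_cat(c1[j], c2[j], hyp0.cat_lengthscales[j])
            assert k_hyb(p, q, hyp0, small_space) == pytest.approx(kc + kz, rel=1e-12)
            assert k_hyb(p, q, hyp1, small_space) == pytest.approx(kc * kz, rel=1e-12)
            p, q = small_space.random_point(rng), small_space.random_point(rng)

    def test_self_similarity_is_two_minus_lambda(self, small_space):
        rng = np.random.default_rng(1)
        for lam in (0.0, 0.25, 0.5, 1.0):
            p = small_space.random_point(rng)
            hyp = default_hyp(small_space, mix_weight=lam)
            assert k_hyb(p, p, hyp, small_space) == pytest.approx(2.0 - lam, rel=1e-15)


class TestGramMatrix:
    def test_single_point_value(self, small_space):
        rng = np.random.default_rng(0)
        p = small_space.random_point(rng)
        u, c = small_space.normalize(p)
        hyp = default_hyp(small_space, mix_weight=0.5, noise_variance=0.01)
        K = gram_matrix(u[None], c[None], hyp)
        assert K.shape == (1, 1)
        assert K[0, 0] == pytest.approx(1.51, abs=1e-6)

    def test_random_gram_is_psd(self, small_space):
        rng = np.random.default_rng(2)
        for trial in range(5):
            U = rng.uniform(size=(30, 2))
            C = np.column_stack([rng.integers(3, size=30), rng.integers(2, size=30)])
            hyp = default_hyp(
                small_space,
                cont_lengthscales=rng.uniform(0.05, 2, 2),
                cat_lengthscales=rng.uniform(0.05, 2, 2),
                mix_weight=rng.uniform(),
            )
            K = gram_matrix(U, C, hyp)
            assert np.min(np.linalg.eigvalsh(K)) >= -1e-8

    def test_duplicated_rows_still_factorizable(self, small_space):
        rng = np.random.default_rng(3)
        p = small_space.random_point(rng)
        obs = ObservationSet()
        for _ in range(4):
            obs.add(p, 0.5)
        surr = FittedSurrogate.from_observations(obs, small_space, default_hyp(small_space))
        assert np.isfinite(surr.log_likelihood)


def dense_reference_gp(U, C, y, Us, Cs, hyp):
    """Independent closed-form GP regression (inline formulas, np.linalg)."""
    def kernel(U1, C1, U2, C2):
        out = np.zeros((len(U1), len(U2)))
        for i in range(len(U1)):
            for j in range(len(U2)):
                r = np.sqrt(np.sum(((U1[i] - U2[j]) / hyp.cont_lengthscales) ** 2))
                s5r = np.sqrt(5) * r
                kc = (1 + s5r + s5r**2 / 3) * np.exp(-s5r)
                kz = 1.0
                for m in range(C1.shape[1]):
                    kz *= 1.0 if C1[i, m] == C2[j, m] else np.exp(-1 / hyp.cat_lengthscales[m])
                lam = hyp.mix_weight
                out[i, j] = (1 - lam) * (kc + kz) + lam * kc * kz
        return out

    K = hyp.amplitude**2 * kernel(U, C, U, C) + (hyp.noise_variance + 1e-8) * np.eye(len(U))
    Ks = hyp.amplitude**2 * kernel(Us, Cs, U, C)
    Kinv = np.linalg.inv(K)
    resid = y - hyp.prior_mean
    mean = hyp.prior_mean + Ks @ Kinv @ resid
    prior = hyp.amplitude**2 * (2 - hyp.mix_weight)
    var = prior - np.einsum("ij,jk,ik->i", Ks, Kinv, Ks)
    _, logdet = np.linalg.slogdet(K)
    lml = -0.5 * resid @ Kinv @ resid - 0.5 * logdet - 0.5 * len(y) * np.log(2 * np.pi)
    return mean, var, lml


class TestPosterior:
    def test_noiseless_interpolation(self, small_space):
        rng = np.random.default_rng(4)
        p = small_space.random_point(rng)
        obs = ObservationSet()
        obs.add(p, 0.37)
        hyp = default_hyp(small_space, noise_variance=1e-10)
        surr = FittedSurrogate.from_observations(obs, small_space, hyp)
        mean, var = surr.posterior(p)
        assert mean == pytest.approx(0.37, abs=1e-5)
        assert var >= 0

    def test_reversion_to_prior_far_away(self, small_space):
        hyp = default_hyp(
            small_space,
            cont_lengthscales=np.array([0.01, 0.01]),
            cat_lengthscales=np.array([0.01, 0.01]),
        )
        obs = ObservationSet()
        for i, (x1, x2, y) in enumerate([(0.2, 2.2, 1.0), (0.3, 5.5, -0.4), (1.9, 2.5, 0.7)]):
            obs.add(
                HybridPoint(
                    z={"salt": "acetate", "ligand": "imidazole"},
                    x={"conc": x1, "time": x2},
                ),
                y,
            )
        surr = FittedSurrogate.from_observations(obs, small_space, hyp)
        # all categoricals differ and the continuous part is many
        # lengthscales away from every record
        probe = HybridPoint(
            z={"salt": "chloride", "ligand": "triazole"},
            x={"conc": 1.0, "time": 4.0},
        )
        mean, var = surr.posterior(probe)
        prior_mean = surr.y_shift + surr.y_scale * hyp.prior_mean
        prior_var = surr.y_scale**2 * hyp.amplitude**2 * (2 - hyp.mix_weight)
        assert mean == pytest.approx(prior_mean, abs=1e-6)
        assert var == pytest.approx(prior_var, rel=1e-6)

    def test_matches_dense_reference(self, small_space):
        rng = np.random.default_rng(7)
        for trial in range(3):
            obs = random_observations(small_space, 5, 10 + trial)
            hyp = default_hyp(
                small_space,
                mix_weight=float(rng.uniform()),
                amplitude=float(rng.uniform(0.5, 2)),
                noise_variance=float(rng.uniform(0.01, 0.1)),
                prior_mean=float(rng.normal()),
            )
            surr = FittedSurrogate.from_observations(
                obs, small_space, hyp, y_shift=0.0, y_scale=1.0
            )
            U, C, y, _ = obs.to_arrays(small_space)
            Us = rng.uniform(size=(4, 2))
            Cs = np.column_stack([rng.integers(3, size=4), rng.integers(2, size=4)])
            mean, var = surr.posterior_arrays(Us, Cs)
            m_ref, v_ref, _ = dense_reference_gp(U, C, y, Us, Cs, hyp)
            assert np.allclose(mean, m_ref, atol=1e-6)
            assert np.allclose(var, np.maximum(v_ref, 0), atol=1e-6)

    def test_gradients_match_finite_differences(self, small_space):
        surr = make_surrogate(small_space, n=12, seed=8)
        rng = np.random.default_rng(9)
        U = rng.uniform(size=(5, 2))
        C = np.column_stack([rng.integers(3, size=5), rng.integers(2, size=5)])
        mean, var, dmean, dvar = surr.posterior_grad_arrays(U, C)
        m0, v0 = surr.posterior_arrays(U, C)
        assert np.allclose(mean, m0) and np.allclose(var, v0)
        h = 1e-6
        for k in range(2):
            Up, Um = U.copy(), U.copy()
            Up[:, k] += h
            Um[:, k] -= h
            mp, vp = surr.posterior_arrays(Up, C)
            mm, vm = surr.posterior_arrays(Um, C)
            assert np.allclose((mp - mm) / (2 * h), dmean[:, k], atol=1e-5)
            assert np.allclose((vp - vm) / (2 * h), dvar[:, k], atol=1e-5)

    def test_added_observation_never_increases_variance(self, small_space):
        rng = np.random.default_rng(11)
        obs = random_observations(small_space, 8, 12)
        hyp = default_hyp(small_space)
        surr = FittedSurrogate.from_observations(obs, small_space, hyp)
        probes_U = rng.uniform(size=(50, 2))
        probes_C = np.column_stack(
            [rng.integers(3, size=50), rng.integers(2, size=50)]
        )
        _, var_before = surr.posterior_arrays(probes_U, probes_C)
        bigger = obs.copy()
        bigger.add(small_space.random_point(rng), 0.0)
        surr2 = surr.with_observations(bigger)
        _, var_after = surr2.posterior_arrays(probes_U, probes_C)
        assert np.all(var_after <= var_before + 1e-9)

    def test_level_relabeling_equivariance(self):
        """Predictions must not depend on the declared order of levels."""
        def build(levels):
            space = HybridSpace(
                categoricals=(CategoricalVariable("c", levels),),
                continuous=(ContinuousVariable("x", 0.0, 1.0),),
            )
            obs = ObservationSet()
            data = [("p", 0.2, 1.0), ("q", 0.8, -0.5), ("r", 0.5, 0.3), ("p", 0.6, 0.9)]
            for lev, x, y in data:
                obs.add(HybridPoint(z={"c": lev}, x={"x": x}), y)
            surr = FittedSurrogate.from_observations(obs, space, default_hyp(space))
            probe = HybridPoint(z={"c": "q"}, x={"x": 0.4})
            return surr.posterior(probe)

        m1, v1 = build(("p", "q", "r"))
        m2, v2 = build(("r", "q", "p"))
        assert m1 == pytest.approx(m2, rel=1e-12)
        assert v1 == pytest.approx(v2, rel=1e-12)


class TestLogMarginalLikelihood:
    def test_single_observation_closed_form(self, small_space):
        rng = np.random.default_rng(13)
        p = small_space.random_point(rng)
        obs = ObservationSet()
        obs.add(p, 1.7)
        hyp = default_hyp(small_space, mix_weight=0.5, amplitude=1.2, noise_variance=0.05, prior_mean=0.4)
        total_var = 1.2**2 * 1.5 + 0.05 + 1e-8
        expected = -0.5 * np.log(2 * np.pi * total_var) - (1.7 - 0.4) ** 2 / (2 * total_var)
        got = log_marginal_likelihood(obs, hyp, small_space)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_permutation_invariance(self, small_space):
        obs = random_observations(small_space, 7, 14)
        hyp = default_hyp(small_space)
        v1 = log_marginal_likelihood(obs, hyp, small_space)
        rev = ObservationSet(records=list(reversed(obs.records)))
        assert v1 == pytest.approx(log_marginal_likelihood(rev, hyp, small_space), rel=1e-12)

    def test_matches_dense_reference(self, small_space):
        obs = random_observations(small_space, 8, 15)
        hyp = default_hyp(small_space, amplitude=0.8, noise_variance=0.04, prior_mean=0.1)
        U, C, y, _ = obs.to_arrays(small_space)
        _, _, lml_ref = dense_reference_gp(U, C, y, U[:1], C[:1], hyp)
        assert log_marginal_likelihood(obs, hyp, small_space) == pytest.approx(lml_ref, abs=1e-8)

    def test_analytic_gradient_matches_finite_differences(self, small_space):
        obs = random_observations(small_space, 9, 16)
        U, C, y, s = obs.to_arrays(small_space)
        d, m = 2, 2
        Dsq = (U[:, None, :] - U[None, :, :]) ** 2
        NEQ = C[:, None, :] != C[None, :, :]
        args = (Dsq, NEQ, y, s, d, m, 1e-8, 1e-4)
        rng = np.random.default_rng(17)
        t = rng.normal(scale=0.5, size=d + m + 4)
        _, g = _nll_and_grad(t, *args)
        h = 1e-6
        for i in range(len(t)):
            tp, tm = t.copy(), t.copy()
            tp[i] += h
            tm[i] -= h
            fd = (_nll_and_grad(tp, *args)[0] - _nll_and_grad(tm, *args)[0]) / (2 * h)
            assert g[i] == pytest.approx(fd, rel=1e-4, abs=1e-7)


class TestMaximumLikelihoodFit:
    def test_requires_two_true_observations(self, small_space):
        obs = ObservationSet()
        obs.add(small_space.random_point(np.random.default_rng(0)), 1.0)
        with pytest.raises(ValueError):
            fit_mle(obs, small_space)

    def test_constant_objective_degenerates_gracefully(self, small_space):
        rng = np.random.default_rng(18)
        obs = ObservationSet()
        for _ in range(6):
            obs.add(small_space.random_point(rng), 0.42)
        surr = fit_mle(obs, small_space, SurrogateConfig(n_restarts=2), rng)
        mean, _ = surr.posterior(small_space.random_point(rng))
        assert mean == pytest.approx(0.42, abs=0.05)

    def test_likelihood_beats_every_initialization(self, small_space):
        obs = random_observations(small_space, 15, 19)
        cfg = SurrogateConfig(n_restarts=4)
        surr = fit_mle(obs, small_space, cfg, np.random.default_rng(20))
        default_init = default_hyp(small_space)
        ll_init = log_marginal_likelihood(
            ObservationSet(
                records=[
                    type(obs.records[0])(
                        point=r.point,
                        y=(r.y - surr.y_shift) / surr.y_scale,
                        is_liar=r.is_liar,
                        round_index=r.round_index,
                    )
                    for r in obs.records
                ]
            ),
            default_init,
            small_space,
        )
        assert surr.log_likelihood >= ll_init - 1e-9

    def test_recovers_product_kernel_structure(self, small_space):
        """Data simulated from a pure product kernel should refit with a
        large mix weight."""
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            hyp = default_hyp(
                small_space,
                mix_weight=1.0,
                cont_lengthscales=np.array([0.3, 0.3]),
                cat_lengthscales=np.array([0.3, 0.3]),
                amplitude=2.0,
                noise_variance=1e-4,
            )
            pts = [small_space.random_point(rng) for _ in range(60)]
            U = np.array([small_space.normalize(p)[0] for p in pts])
            C = np.array([small_space.normalize(p)[1] for p in pts])
            K = gram_matrix(U, C, hyp)
            y = np.linalg.cholesky(K) @ rng.normal(size=60)
            obs = ObservationSet()
            for p, yi in zip(pts, y):
                obs.add(p, float(yi))
            fitted = fit_mle(obs, small_space, SurrogateConfig(n_restarts=4), rng)
            hits += fitted.hyp.mix_weight > 0.5
        assert hits >= 4

    def test_recovers_continuous_lengthscales_within_factor_two(self, small_space):
        hits = 0
        true_ls = np.array([0.25, 0.6])
        for seed in range(5):
            rng = np.random.default_rng(200 + seed)
            hyp = default_hyp(
                small_space,
                mix_weight=0.5,
                cont_lengthscales=true_ls,
                cat_lengthscales=np.array([0.5, 0.5]),
                amplitude=1.0,
                noise_variance=1e-4,
            )
            pts = [small_space.random_point(rng) for _ in range(80)]
            U = np.array([small_space.normalize(p)[0] for p in pts])
            C = np.array([small_space.normalize(p)[1] for p in pts])
            K = gram_matrix(U, C, hyp)
            y = np.linalg.cholesky(K) @ rng.normal(size=80)
            obs = ObservationSet()
            for p, yi in zip(pts, y):
                obs.add(p, float(yi))
            fitted = fit_mle(obs, small_space, SurrogateConfig(n_restarts=4), rng)
            ratio = fitted.hyp.cont_lengthscales / true_ls
            hits += bool(np.all((ratio > 0.5) & (ratio < 2.0)))
        assert hits >= 4
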