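"""Hybrid-kernel Gaussian-process surrogate of the reaction space.

The categorical kernel treats two levels as unit-similar when equal and
``exp(-1/l)`` otherwise, with a learnable lengthscale ``l`` per categorical
variable (per-variable kernels combine by product).  Continuous coordinates
use an ARD Matern 5/2 kernel on the normalized unit cube.  The hybrid kernel
mixes the sum and the product of the two parts with a single learnable
weight ``lambda`` in [0, 1]::

    k_hyb = (1 - lambda) * (k_con + k_cat) + lambda * (k_con * k_cat)

so the prior variance at any point is ``amplitude**2 * (2 - lambda)``; the
kernel is kept in this form rather than renormalized.  All hyperparameters
(lengthscales, lambda, amplitude, homoscedastic noise, constant mean) are
fitted jointly by maximizing the log marginal likelihood with multistart
L-BFGS in unconstrained transforms (log for positives, logit for lambda),
using analytic gradients.  Objectives are z-scored before fitting and
predictions are mapped back to objective units.

Per-record noise scales (used to down-weight warm-start data transferred
from another campaign) multiply the noise variance on the Gram diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import minimize

from .observations import Observation, ObservationSet
from .space import HybridPoint, HybridSpace, normalize

__all__ = [
    "GPHyperparameters",
    "SurrogateConfig",
    "FittedSurrogate",
    "k_cat",
    "k_con",
    "k_hyb",
    "hybrid_kernel_matrix",
    "gram_matrix",
    "log_marginal_likelihood",
    "fit_mle",
]

_SQRT5 = np.sqrt(5.0)


@dataclass(frozen=True)
class GPHyperparameters:
    """Kernel and likelihood parameters, in standardized objective units."""

    cont_lengthscales: np.ndarray
    cat_lengthscales: np.ndarray
    mix_weight: float
    amplitude: float = 1.0
    noise_variance: float = 1e-2
    prior_mean: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "cont_lengthscales", np.atleast_1d(np.asarray(self.cont_lengthscales, dtype=float))
        )
        object.__setattr__(
            self, "cat_lengthscales", np.atleast_1d(np.asarray(self.cat_lengthscales, dtype=float))
        )
        if np.any(self.cont_lengthscales <= 0) or np.any(self.cat_lengthscales <= 0):
            raise ValueError("lengthscales must be strictly positive")
        if not 0.0 <= self.mix_weight <= 1.0:
            raise ValueError("mix_weight must lie in [0, 1]")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.noise_variance <= 0:
            raise ValueError("noise_variance must be positive")

    def to_dict(self) -> dict:
        return {
            "cont_lengthscales": [float(v) for v in self.cont_lengthscales],
            "cat_lengthscales": [float(v) for v in self.cat_lengthscales],
            "mix_weight": float(self.mix_weight),
            "amplitude": float(self.amplitude),
            "noise_variance": float(self.noise_variance),
            "prior_mean": float(self.prior_mean),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GPHyperparameters":
        return cls(
            cont_lengthscales=np.asarray(d["cont_lengthscales"], dtype=float),
            cat_lengthscales=np.asarray(d["cat_lengthscales"], dtype=float),
            mix_weight=float(d["mix_weight"]),
            amplitude=float(d["amplitude"]),
            noise_variance=float(d["noise_variance"]),
            prior_mean=float(d["prior_mean"]),
        )


@dataclass(frozen=True)
class SurrogateConfig:
    """Maximum-likelihood search settings.

    ``n_restarts`` multistarts draw initial lengthscales log-uniformly from
    ``ls_init_range`` (normalized units); the mix weight starts at 0.5.
    Unconstrained parameters are box-bounded to ``log_bound`` in transformed
    space.  ``jitter`` is added to the Gram diagonal and escalated tenfold up
    to ``max_jitter`` if the Cholesky factorization fails.
    """

    n_restarts: int = 8
    ls_init_range: tuple[float, float] = (0.05, 2.0)
    log_bound: float = 6.0
    noise_floor: float = 1e-6
    jitter: float = 1e-8
    max_jitter: float = 1e-4
    maxiter: int = 200


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------

def k_cat(z: int | str, z_other: int | str, lengthscale: float) -> float:
    """Categorical kernel: 1 for equal levels, exp(-1/l) otherwise."""
    if lengthscale <= 0:
        raise ValueError("categorical lengthscale must be positive")
    return 1.0 if z == z_other else float(np.exp(-1.0 / lengthscale))


def _matern52_from_r(r: np.ndarray) -> np.ndarray:
    sr = _SQRT5 * r
    return (1.0 + sr + sr * sr / 3.0) * np.exp(-sr)


def k_con(
    u: Sequence[float], u_other: Sequence[float], cont_lengthscales: Sequence[float]
) -> float:
    """ARD Matern 5/2 kernel on normalized continuous coordinates."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(u_other, dtype=float)
    ls = np.asarray(cont_lengthscales, dtype=float)
    if u.shape != v.shape or u.shape != ls.shape:
        raise ValueError(
            f"dimension mismatch: u {u.shape}, u' {v.shape}, lengthscales {ls.shape}"
        )
    r = np.sqrt(np.sum(((u - v) / ls) ** 2))
    return float(_matern52_from_r(np.asarray(r)))


def _cross_matrices(
    U1: np.ndarray,
    C1: np.ndarray,
    U2: np.ndarray,
    C2: np.ndarray,
    hyp: GPHyperparameters,
) -> tuple[np.ndarray, np.ndarray]:
    """(K_con, K_cat) between two batches of normalized points."""
    if U1.shape[1] > 0:
        diff = U1[:, None, :] - U2[None, :, :]
        r = np.sqrt(np.sum((diff / hyp.cont_lengthscales) ** 2, axis=-1))
        Kcon = _matern52_from_r(r)
    else:
        Kcon = np.ones((U1.shape[0], U2.shape[0]))
    Kcat = np.ones((C1.shape[0], C2.shape[0]))
    for j in range(C1.shape[1]):
        neq = C1[:, j, None] != C2[None, :, j]
        cj = np.exp(-1.0 / hyp.cat_lengthscales[j])
        Kcat = Kcat * np.where(neq, cj, 1.0)
    return Kcon, Kcat


def hybrid_kernel_matrix(
    U1: np.ndarray,
    C1: np.ndarray,
    U2: np.ndarray,
    C2: np.ndarray,
    hyp: GPHyperparameters,
) -> np.ndarray:
    """Unit-amplitude hybrid kernel between two normalized batches."""
    Kcon, Kcat = _cross_matrices(U1, C1, U2, C2, hyp)
    lam = hyp.mix_weight
    return (1.0 - lam) * (Kcon + Kcat) + lam * (Kcon * Kcat)


def k_hyb(p: HybridPoint, p_other: HybridPoint, hyp: GPHyperparameters, space: HybridSpace) -> float:
    """Scalar hybrid kernel between two points (before amplitude scaling)."""
    u1, c1 = normalize(p, space)
    u2, c2 = normalize(p_other, space)
    return float(
        hybrid_kernel_matrix(u1[None], c1[None], u2[None], c2[None], hyp)[0, 0]
    )


def _chol_with_jitter(
    K: np.ndarray, jitter: float, max_jitter: float
) -> tuple[np.ndarray, float]:
    """Cholesky of K, escalating extra diagonal jitter tenfold on failure.

    ``K`` is expected to already carry the base jitter; ``jitter`` is the
    starting extra amount tried after a first direct failure (0 means start
    from 1e-8).
    """
    j = 0.0
    while True:
        try:
            L = np.linalg.cholesky(
                K if j == 0.0 else K + j * np.eye(K.shape[0])
            )
            return L, j
        except np.linalg.LinAlgError:
            j = max(jitter, 1e-8) if j == 0.0 else j * 10.0
            if j > max_jitter:
                raise np.linalg.LinAlgError(
                    f"Gram matrix not factorizable up to jitter {max_jitter}"
                )


def gram_matrix(
    U: np.ndarray,
    C: np.ndarray,
    hyp: GPHyperparameters,
    noise_scale: np.ndarray | None = None,
    jitter: float = 1e-8,
) -> np.ndarray:
    """amplitude^2 * K_hyb + scaled noise + jitter on the diagonal."""
    K = hyp.amplitude**2 * hybrid_kernel_matrix(U, C, U, C, hyp)
    s = np.ones(U.shape[0]) if noise_scale is None else np.asarray(noise_scale)
    K[np.diag_indices_from(K)] += hyp.noise_variance * s + jitter
    return K


# ---------------------------------------------------------------------------
# marginal likelihood (value + analytic gradient in transformed parameters)
# ---------------------------------------------------------------------------

def log_marginal_likelihood(
    observations: ObservationSet | Sequence[Observation],
    hyp: GPHyperparameters,
    space: HybridSpace,
    jitter: float = 1e-8,
) -> float:
    """Gaussian-process log marginal likelihood of the observations.

    Unit-agnostic: the objective values and ``hyp`` (prior mean, amplitude,
    noise) are taken in the same units as given.
    """
    obs = observations if isinstance(observations, ObservationSet) else ObservationSet(list(observations))
    if len(obs) < 1:
        raise ValueError("need at least one observation")
    U, C, y, s = obs.to_arrays(space)
    K = gram_matrix(U, C, hyp, noise_scale=s, jitter=jitter)
    L, _ = _chol_with_jitter(K, 0.0, 1e-4)
    r = y - hyp.prior_mean
    alpha = cho_solve((L, True), r)
    return float(
        -0.5 * r @ alpha - np.sum(np.log(np.diag(L))) - 0.5 * len(y) * np.log(2 * np.pi)
    )


def _nll_and_grad(
    t: np.ndarray,
    Dsq: np.ndarray,
    NEQ: np.ndarray,
    y: np.ndarray,
    s: np.ndarray,
    d: int,
    m: int,
    jitter: float,
    max_jitter: float,
) -> tuple[float, np.ndarray]:
    """Negative log marginal likelihood and gradient in transformed params.

    Parameter layout: [log cont ls (d), log cat ls (m), logit lambda,
    log amplitude, log noise sd, prior mean].
    """
    n = len(y)
    ell = np.exp(t[:d])
    lcat = np.exp(t[d : d + m])
    lam = 1.0 / (1.0 + np.exp(-t[d + m]))
    amp2 = np.exp(2.0 * t[d + m + 1])
    noise = np.exp(2.0 * t[d + m + 2])
    mean = t[d + m + 3]

    if d > 0:
        r2 = np.tensordot(Dsq, 1.0 / ell**2, axes=([2], [0]))
        r = np.sqrt(np.maximum(r2, 0.0))
        sr = _SQRT5 * r
        expsr = np.exp(-sr)
        Kcon = (1.0 + sr + sr * sr / 3.0) * expsr
        dk_dr_factor = (5.0 / 3.0) * (1.0 + sr) * expsr  # dKcon/dlog ell_k = this * Dsq_k/ell_k^2
    else:
        Kcon = np.ones((n, n))
        dk_dr_factor = None

    Kcat = np.ones((n, n))
    cj_list = []
    for j in range(m):
        cj = np.exp(-1.0 / lcat[j])
        cj_list.append(cj)
        Kcat = Kcat * np.where(NEQ[:, :, j], cj, 1.0)

    Khyb = (1.0 - lam) * (Kcon + Kcat) + lam * (Kcon * Kcat)
    K = amp2 * Khyb
    K[np.diag_indices_from(K)] += noise * s + jitter

    try:
        L, _ = _chol_with_jitter(K, 0.0, max_jitter)
    except np.linalg.LinAlgError:
        return np.inf, np.zeros_like(t)

    resid = y - mean
    alpha = cho_solve((L, True), resid)
    nll = 0.5 * resid @ alpha + np.sum(np.log(np.diag(L))) + 0.5 * n * np.log(2 * np.pi)

    Kinv = cho_solve((L, True), np.eye(n))
    A = np.outer(alpha, alpha) - Kinv  # dLL/dtheta = 0.5 tr(A dK)

    grad = np.zeros_like(t)
    w_con = (1.0 - lam) + lam * Kcat  # dKhyb/dKcon
    w_cat = (1.0 - lam) + lam * Kcon
    for k in range(d):
        dKcon = dk_dr_factor * (Dsq[:, :, k] / ell[k] ** 2)
        dK = amp2 * (w_con * dKcon)
        grad[k] = -0.5 * np.sum(A * dK)
    for j in range(m):
        dKcat = Kcat * NEQ[:, :, j] * (1.0 / lcat[j])
        dK = amp2 * (w_cat * dKcat)
        grad[d + j] = -0.5 * np.sum(A * dK)
    dKhyb_dlam = -(Kcon + Kcat) + Kcon * Kcat
    grad[d + m] = -0.5 * np.sum(A * (amp2 * dKhyb_dlam)) * lam * (1.0 - lam)
    grad[d + m + 1] = -0.5 * np.sum(A * (2.0 * amp2 * Khyb))
    grad[d + m + 2] = -0.5 * np.sum(np.diag(A) * (2.0 * noise * s))
    grad[d + m + 3] = -np.sum(alpha)
    return float(nll), grad


# ---------------------------------------------------------------------------
# fitted surrogate
# ---------------------------------------------------------------------------

@dataclass
class FittedSurrogate:
    """A conditioned GP: hyperparameters plus cached posterior state.

    ``hyp`` lives in standardized objective units; ``y_shift``/``y_scale``
    map predictions back to raw units.  ``with_observations`` reconditions on
    a new dataset with the same hyperparameters and standardization (used for
    within-batch liar updates).
    """

    space: HybridSpace
    hyp: GPHyperparameters
    U: np.ndarray
    C: np.ndarray
    y_raw: np.ndarray
    noise_scale: np.ndarray
    y_shift: float
    y_scale: float
    L: np.ndarray = field(repr=False, default=None)
    alpha: np.ndarray = field(repr=False, default=None)
    log_likelihood: float = np.nan
    jitter: float = 1e-8

    def __post_init__(self) -> None:
        if self.L is None:
            self._recondition()

    def _recondition(self) -> None:
        y_std = (self.y_raw - self.y_shift) / self.y_scale
        K = gram_matrix(
            self.U, self.C, self.hyp, noise_scale=self.noise_scale, jitter=self.jitter
        )
        self.L, _ = _chol_with_jitter(K, 0.0, 1e-4)
        resid = y_std - self.hyp.prior_mean
        self.alpha = cho_solve((self.L, True), resid)
        n = len(y_std)
        self.log_likelihood = float(
            -0.5 * resid @ self.alpha
            - np.sum(np.log(np.diag(self.L)))
            - 0.5 * n * np.log(2 * np.pi)
        )

    @classmethod
    def from_observations(
        cls,
        observations: ObservationSet,
        space: HybridSpace,
        hyp: GPHyperparameters,
        *,
        y_shift: float | None = None,
        y_scale: float | None = None,
        jitter: float = 1e-8,
    ) -> "FittedSurrogate":
        """Condition a GP with fixed hyperparameters on a dataset.

        When standardization constants are omitted they are computed from the
        data; ``hyp`` is then interpreted in those standardized units.
        """
        U, C, y, s = observations.to_arrays(space)
        if y_shift is None:
            y_shift = float(np.mean(y))
        if y_scale is None:
            sd = float(np.std(y))
            y_scale = sd if sd > 1e-12 else 1.0
        return cls(
            space=space,
            hyp=hyp,
            U=U,
            C=C,
            y_raw=y,
            noise_scale=s,
            y_shift=y_shift,
            y_scale=y_scale,
            jitter=jitter,
        )

    @property
    def n_train(self) -> int:
        return len(self.y_raw)

    def with_observations(self, observations: ObservationSet) -> "FittedSurrogate":
        """Same hyperparameters and standardization, new dataset."""
        U, C, y, s = observations.to_arrays(self.space)
        return FittedSurrogate(
            space=self.space,
            hyp=self.hyp,
            U=U,
            C=C,
            y_raw=y,
            noise_scale=s,
            y_shift=self.y_shift,
            y_scale=self.y_scale,
            jitter=self.jitter,
        )

    # -- prediction --------------------------------------------------------
    def posterior_arrays(
        self, U: np.ndarray, C: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean and variance (of the latent objective) per row.

        Inputs are normalized coordinates; outputs are in raw objective
        units.  Variances are clipped at zero.
        """
        U = np.atleast_2d(np.asarray(U, dtype=float))
        C = np.asarray(C, dtype=int).reshape(U.shape[0], -1)
        Ks = self.hyp.amplitude**2 * hybrid_kernel_matrix(U, C, self.U, self.C, self.hyp)
        mean_std = self.hyp.prior_mean + Ks @ self.alpha
        V = solve_triangular(self.L, Ks.T, lower=True)
        prior_var = self.hyp.amplitude**2 * (2.0 - self.hyp.mix_weight)
        var_std = np.maximum(prior_var - np.sum(V * V, axis=0), 0.0)
        mean = self.y_shift + self.y_scale * mean_std
        var = self.y_scale**2 * var_std
        return mean, var

    def posterior(self, point: HybridPoint) -> tuple[float, float]:
        """Posterior (mean, variance) at one point, in objective units."""
        u, c = normalize(point, self.space)
        mean, var = self.posterior_arrays(u[None], c[None])
        return float(mean[0]), float(var[0])

    def posterior_grad_arrays(
        self, U: np.ndarray, C: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Posterior mean/variance and their gradients w.r.t. normalized u.

        Returns (mean, var, dmean, dvar) with dmean, dvar of shape (n, d),
        all in raw objective units.  Used by gradient-based acquisition
        optimization; values agree with :meth:`posterior_arrays`.
        """
        hyp = self.hyp
        U = np.atleast_2d(np.asarray(U, dtype=float))
        C = np.asarray(C, dtype=int).reshape(U.shape[0], -1)
        n, d = U.shape
        if d > 0:
            diff = U[:, None, :] - self.U[None, :, :]  # (n, m, d)
            inv_ls2 = 1.0 / hyp.cont_lengthscales**2
            r = np.sqrt(np.sum(diff**2 * inv_ls2, axis=-1))
            sr = _SQRT5 * r
            e = np.exp(-sr)
            Kcon = (1.0 + sr + sr * sr / 3.0) * e
            # dKcon/du_k = -(5/3)(1+sr)e * diff_k / ls_k^2
            dcon_factor = -(5.0 / 3.0) * (1.0 + sr) * e
        else:
            diff = np.zeros((n, self.U.shape[0], 0))
            inv_ls2 = np.zeros(0)
            Kcon = np.ones((n, self.U.shape[0]))
            dcon_factor = np.zeros_like(Kcon)
        Kcat = np.ones((n, self.U.shape[0]))
        for j in range(C.shape[1]):
            neq = C[:, j, None] != self.C[None, :, j]
            Kcat *= np.where(neq, np.exp(-1.0 / hyp.cat_lengthscales[j]), 1.0)
        lam = hyp.mix_weight
        amp2 = hyp.amplitude**2
        Ks = amp2 * ((1.0 - lam) * (Kcon + Kcat) + lam * Kcon * Kcat)
        w_con = amp2 * ((1.0 - lam) + lam * Kcat)

        mean_std = hyp.prior_mean + Ks @ self.alpha
        V = solve_triangular(self.L, Ks.T, lower=True)  # (m, n)
        prior_var = amp2 * (2.0 - lam)
        var_std = np.maximum(prior_var - np.sum(V * V, axis=0), 0.0)
        W = solve_triangular(self.L.T, V, lower=False)  # K^{-1} Ks^T, (m, n)

        dmean = np.zeros((n, d))
        dvar = np.zeros((n, d))
        for k in range(d):
            dKs_k = w_con * dcon_factor * diff[:, :, k] * inv_ls2[k]  # (n, m)
            dmean[:, k] = dKs_k @ self.alpha
            dvar[:, k] = -2.0 * np.sum(dKs_k * W.T, axis=1)
        mean = self.y_shift + self.y_scale * mean_std
        var = self.y_scale**2 * var_std
        return mean, var, self.y_scale * dmean, self.y_scale**2 * dvar


def posterior(surrogate: FittedSurrogate, point: HybridPoint) -> tuple[float, float]:
    return surrogate.posterior(point)


# ---------------------------------------------------------------------------
# maximum-likelihood fitting
# ---------------------------------------------------------------------------

def _hyp_to_vector(hyp: GPHyperparameters, bound: float) -> np.ndarray:
    lam = min(max(hyp.mix_weight, 1e-6), 1 - 1e-6)
    v = np.concatenate(
        [
            np.log(hyp.cont_lengthscales),
            np.log(hyp.cat_lengthscales),
            [np.log(lam / (1 - lam))],
            [np.log(hyp.amplitude)],
            [0.5 * np.log(hyp.noise_variance)],
            [hyp.prior_mean],
        ]
    )
    return np.clip(v, -bound, bound)


def _vector_to_hyp(t: np.ndarray, d: int, m: int, noise_floor: float) -> GPHyperparameters:
    return GPHyperparameters(
        cont_lengthscales=np.exp(t[:d]) if d > 0 else np.ones(0),
        cat_lengthscales=np.exp(t[d : d + m]) if m > 0 else np.ones(0),
        mix_weight=float(1.0 / (1.0 + np.exp(-t[d + m]))),
        amplitude=float(np.exp(t[d + m + 1])),
        noise_variance=float(max(np.exp(2.0 * t[d + m + 2]), noise_floor)),
        prior_mean=float(t[d + m + 3]),
    )


def fit_mle(
    observations: ObservationSet,
    space: HybridSpace,
    config: SurrogateConfig | None = None,
    rng: np.random.Generator | None = None,
    *,
    prior_mean_init: float = 0.0,
    extra_inits: Sequence[GPHyperparameters] = (),
) -> FittedSurrogate:
    """Fit all GP hyperparameters by multistart maximum likelihood.

    Requires at least two non-liar observations.  ``prior_mean_init`` and
    ``extra_inits`` support transfer learning: the constant-mean start can be
    taken from a source campaign, and full source hyperparameter vectors can
    be appended as additional restarts.  The restart draws consume the ``rng``
    stream in a fixed order, so adding ``extra_inits`` never changes the
    default restarts and the returned likelihood can only improve.
    """
    cfg = config or SurrogateConfig()
    rng = np.random.default_rng(0) if rng is None else rng
    if observations.n_true < 2:
        raise ValueError("fit_mle needs at least 2 non-liar observations")

    U, C, y, s = observations.to_arrays(space)
    y_shift = float(np.mean(y))
    sd = float(np.std(y))
    y_scale = sd if sd > 1e-12 else 1.0
    y_std = (y - y_shift) / y_scale

    n, d = U.shape
    m = C.shape[1]
    Dsq = (U[:, None, :] - U[None, :, :]) ** 2 if d > 0 else np.zeros((n, n, 0))
    NEQ = (
        (C[:, None, :] != C[None, :, :]) if m > 0 else np.zeros((n, n, 0), dtype=bool)
    )

    lo, hi = np.log(cfg.ls_init_range[0]), np.log(cfg.ls_init_range[1])
    inits: list[np.ndarray] = []
    for i in range(cfg.n_restarts):
        t0 = np.zeros(d + m + 4)
        t0[: d + m] = rng.uniform(lo, hi, size=d + m)
        t0[d + m] = 0.0  # lambda = 0.5
        t0[d + m + 1] = 0.0 if i == 0 else rng.normal(0.0, 0.3)  # log amplitude
        t0[d + m + 2] = 0.5 * np.log(0.01) if i == 0 else rng.uniform(
            0.5 * np.log(1e-4), 0.5 * np.log(0.25)
        )
        t0[d + m + 3] = prior_mean_init
        inits.append(np.clip(t0, -cfg.log_bound, cfg.log_bound))
    for h in extra_inits:
        inits.append(_hyp_to_vector(h, cfg.log_bound))

    bounds = [(-cfg.log_bound, cfg.log_bound)] * (d + m + 4)
    args = (Dsq, NEQ, y_std, s, d, m, cfg.jitter, cfg.max_jitter)

    best_t, best_nll = None, np.inf
    for t0 in inits:
        nll0, _ = _nll_and_grad(t0, *args)
        if np.isfinite(nll0) and nll0 < best_nll:
            best_t, best_nll = t0, nll0
        res = minimize(
            _nll_and_grad,
            t0,
            args=args,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": cfg.maxiter},
        )
        if np.isfinite(res.fun) and res.fun < best_nll:
            best_t, best_nll = res.x, float(res.fun)
    if best_t is None:
        raise RuntimeError("maximum-likelihood optimization failed on all restarts")

    hyp = _vector_to_hyp(best_t, d, m, cfg.noise_floor)
    surr = FittedSurrogate(
        space=space,
        hyp=hyp,
        U=U,
        C=C,
        y_raw=y,
        noise_scale=s,
        y_shift=y_shift,
        y_scale=y_scale,
        jitter=cfg.jitter,
    )
    return surr
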