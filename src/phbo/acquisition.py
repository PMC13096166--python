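"""Acquisition construction and optimization by probabilistic reparameterization.

The acquisition is the upper confidence bound alpha = mu + sqrt(beta) * sigma
of the GP posterior.  Categorical variables are reparameterized as
independent softmax distributions over their levels, and the optimized
objective becomes the expectation E_z[alpha(x, z)] over those distributions,
which is smooth in both the continuous settings x and the distribution
logits theta.  The continuous gradient is the probability-weighted average
of d alpha / d x; the logit gradient is estimated by the REINFORCE score
function estimator, optionally variance-reduced with a control-variate
baseline proportional to the running mean of sampled acquisition values.
Joint optimization runs multistart L-BFGS with frozen common random numbers
per restart, so the Monte Carlo objective seen by the optimizer is
deterministic.  The final categorical assignment is the per-variable argmax
of the optimized probabilities (point-mass extraction), followed by a
deterministic continuous polish at that assignment.

For spaces whose categorical product is small, an exact enumeration of the
expectation is available and serves as the oracle for the Monte Carlo
estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize

from .space import (
    HybridPoint,
    HybridSpace,
    enumerate_combination_indices,
    normalize,
)
from .surrogate import FittedSurrogate

__all__ = [
    "AcquisitionConfig",
    "CategoricalPolicy",
    "ucb",
    "exact_expected_acquisition",
    "mc_expected_acquisition",
    "grad_x_expected",
    "enumeration_grad_theta",
    "reinforce_grad_theta",
    "reinforce_grad_theta_cv",
    "optimize_acquisition",
]

AlphaFn = Callable[[np.ndarray, np.ndarray], np.ndarray]


@dataclass(frozen=True)
class AcquisitionConfig:
    """Settings for UCB construction and its gradient-based optimization.

    ``ucb_beta`` weights exploration (alpha = mu + sqrt(beta) * sigma).
    ``n_mc`` Monte Carlo draws feed each REINFORCE estimation; ``baseline_b``
    scales the running-mean control-variate baseline.  Logits are box-bounded
    to +/- ``logit_clip`` during optimization.  ``fd_step`` is the central
    finite-difference step for d alpha / d x in normalized coordinates.
    """

    ucb_beta: float = 4.0
    n_mc: int = 128
    baseline_b: float = 1.0
    n_restarts: int = 16
    logit_clip: float = 10.0
    fd_step: float = 1e-5
    maxiter: int = 60
    final_polish: bool = True
    sample_final_z: bool = False

    def __post_init__(self) -> None:
        if self.ucb_beta < 0:
            raise ValueError("ucb_beta must be nonnegative")
        if self.n_mc < 1 or self.n_restarts < 1:
            raise ValueError("n_mc and n_restarts must be >= 1")


class CategoricalPolicy:
    """Independent softmax distributions over each categorical variable."""

    def __init__(self, logits: Sequence[np.ndarray]):
        self.logits = [np.asarray(v, dtype=float).ravel() for v in logits]
        if any(v.size < 1 for v in self.logits):
            raise ValueError("each variable needs >= 1 logit")

    @classmethod
    def uniform(cls, space: HybridSpace) -> "CategoricalPolicy":
        return cls([np.zeros(k) for k in space.level_counts])

    @classmethod
    def point_mass(cls, indices: Sequence[int], level_counts: Sequence[int], clip: float = 10.0) -> "CategoricalPolicy":
        logits = []
        for idx, k in zip(indices, level_counts):
            v = np.full(k, -clip)
            v[idx] = clip
            logits.append(v)
        return cls(logits)

    @property
    def n_variables(self) -> int:
        return len(self.logits)

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(v.size for v in self.logits)

    def probs(self) -> list[np.ndarray]:
        out = []
        for v in self.logits:
            e = np.exp(v - np.max(v))
            out.append(e / np.sum(e))
        return out

    def combination_probs(self, combos: np.ndarray) -> np.ndarray:
        """Joint probability of each row of integer level indices."""
        p = self.probs()
        w = np.ones(combos.shape[0])
        for j in range(self.n_variables):
            w = w * p[j][combos[:, j]]
        return w

    def sample_indices(
        self, n: int, rng: np.random.Generator | None = None, uniforms: np.ndarray | None = None
    ) -> np.ndarray:
        """Draw n joint assignments; with ``uniforms`` given, deterministic
        inverse-CDF transform of frozen uniform draws (common random numbers).
        """
        if uniforms is None:
            if rng is None:
                raise ValueError("need rng or uniforms")
            uniforms = rng.uniform(size=(n, self.n_variables))
        out = np.zeros((n, self.n_variables), dtype=int)
        for j, pj in enumerate(self.probs()):
            edges = np.cumsum(pj)
            edges[-1] = 1.0 + 1e-12
            out[:, j] = np.searchsorted(edges, uniforms[:, j], side="right")
        return out


# ---------------------------------------------------------------------------
# acquisition values
# ---------------------------------------------------------------------------

def _as_alpha_fn(model: FittedSurrogate | AlphaFn, ucb_beta: float) -> AlphaFn:
    if isinstance(model, FittedSurrogate):

        def alpha(U: np.ndarray, C: np.ndarray) -> np.ndarray:
            mean, var = model.posterior_arrays(U, C)
            return mean + np.sqrt(ucb_beta) * np.sqrt(var)

        return alpha
    if callable(model):
        return model
    raise TypeError("model must be a FittedSurrogate or a callable alpha(U, C)")


def ucb(surrogate: FittedSurrogate, point: HybridPoint, ucb_beta: float = 4.0) -> float:
    """Upper confidence bound mu + sqrt(beta) * sigma at one point."""
    if ucb_beta < 0:
        raise ValueError("ucb_beta must be nonnegative")
    mean, var = surrogate.posterior(point)
    return float(mean + np.sqrt(ucb_beta) * np.sqrt(var))


def _alpha_over_combos(
    alpha: AlphaFn, u: np.ndarray, combos: np.ndarray
) -> np.ndarray:
    U = np.broadcast_to(u, (combos.shape[0], u.size)).copy()
    return np.asarray(alpha(U, combos), dtype=float)


def _as_alpha_value_grad(
    model: FittedSurrogate | AlphaFn, ucb_beta: float, fd_step: float
):
    """Batch evaluator returning (alpha values, d alpha / d u).

    Analytic posterior gradients for a GP surrogate; central finite
    differences for a bare callable.
    """
    if isinstance(model, FittedSurrogate):

        def value_grad(U: np.ndarray, C: np.ndarray):
            mean, var, dmean, dvar = model.posterior_grad_arrays(U, C)
            sd = np.sqrt(var)
            vals = mean + np.sqrt(ucb_beta) * sd
            safe = np.maximum(sd, 1e-9)[:, None]
            grads = dmean + np.sqrt(ucb_beta) * dvar / (2.0 * safe)
            return vals, grads

        return value_grad

    alpha = _as_alpha_fn(model, ucb_beta)

    def value_grad_fd(U: np.ndarray, C: np.ndarray):
        U = np.atleast_2d(np.asarray(U, dtype=float))
        vals = np.asarray(alpha(U, C), dtype=float)
        grads = np.zeros_like(U)
        for k in range(U.shape[1]):
            Up, Um = U.copy(), U.copy()
            Up[:, k] += fd_step
            Um[:, k] -= fd_step
            grads[:, k] = (
                np.asarray(alpha(Up, C), dtype=float)
                - np.asarray(alpha(Um, C), dtype=float)
            ) / (2.0 * fd_step)
        return vals, grads

    return value_grad_fd


def exact_expected_acquisition(
    model: FittedSurrogate | AlphaFn,
    u: np.ndarray,
    policy: CategoricalPolicy,
    ucb_beta: float = 4.0,
    cap: int = 10_000,
) -> float:
    """E_z[alpha(x, z)] by full enumeration of categorical combinations."""
    alpha = _as_alpha_fn(model, ucb_beta)
    combos = enumerate_combination_indices(policy.sizes, cap=cap)
    w = policy.combination_probs(combos)
    vals = _alpha_over_combos(alpha, np.asarray(u, dtype=float), combos)
    return float(w @ vals)


def mc_expected_acquisition(
    model: FittedSurrogate | AlphaFn,
    u: np.ndarray,
    policy: CategoricalPolicy,
    n_mc: int = 128,
    seed: int | np.random.Generator = 0,
    ucb_beta: float = 4.0,
) -> float:
    """Monte Carlo estimate of E_z[alpha(x, z)] from n_mc policy draws."""
    alpha = _as_alpha_fn(model, ucb_beta)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = policy.sample_indices(n_mc, rng=rng)
    uniq, counts = np.unique(draws, axis=0, return_counts=True)
    vals = _alpha_over_combos(alpha, np.asarray(u, dtype=float), uniq)
    return float((counts / n_mc) @ vals)


# ---------------------------------------------------------------------------
# gradients
# ---------------------------------------------------------------------------

def grad_x_expected(
    model: FittedSurrogate | AlphaFn,
    u: np.ndarray,
    policy: CategoricalPolicy,
    ucb_beta: float = 4.0,
    fd_step: float = 1e-5,
    cap: int = 10_000,
) -> np.ndarray:
    """Gradient of the exact expectation w.r.t. continuous coordinates.

    The policy does not depend on x, so this equals the probability-weighted
    sum of d alpha / d x; evaluated by central finite differences on the
    enumerated expectation.
    """
    u = np.asarray(u, dtype=float)
    alpha = _as_alpha_fn(model, ucb_beta)
    combos = enumerate_combination_indices(policy.sizes, cap=cap)
    w = policy.combination_probs(combos)
    grad = np.zeros_like(u)
    for i in range(u.size):
        up, um = u.copy(), u.copy()
        up[i] += fd_step
        um[i] -= fd_step
        fp = w @ _alpha_over_combos(alpha, up, combos)
        fm = w @ _alpha_over_combos(alpha, um, combos)
        grad[i] = (fp - fm) / (2.0 * fd_step)
    return grad


def enumeration_grad_theta(
    model: FittedSurrogate | AlphaFn,
    u: np.ndarray,
    policy: CategoricalPolicy,
    ucb_beta: float = 4.0,
    cap: int = 10_000,
) -> list[np.ndarray]:
    """Exact gradient of E_z[alpha] w.r.t. the softmax logits, by enumeration.

    Uses d p(z|theta) / d theta_{jk} = p(z) (1[z_j = k] - p_jk).
    """
    alpha = _as_alpha_fn(model, ucb_beta)
    combos = enumerate_combination_indices(policy.sizes, cap=cap)
    w = policy.combination_probs(combos)
    vals = _alpha_over_combos(alpha, np.asarray(u, dtype=float), combos)
    probs = policy.probs()
    grads = []
    for j, pj in enumerate(probs):
        onehot = np.eye(pj.size)[combos[:, j]]  # (n_combos, k_j)
        grads.append((w * vals) @ (onehot - pj))
    return grads


def _score_gradient(
    vals: np.ndarray,
    weights: np.ndarray,
    combos: np.ndarray,
    probs: list[np.ndarray],
    baseline: float,
) -> list[np.ndarray]:
    grads = []
    centered = (vals - baseline) * weights
    for j, pj in enumerate(probs):
        onehot = np.eye(pj.size)[combos[:, j]]
        grads.append(centered @ (onehot - pj))
    return grads


def reinforce_grad_theta(
    model: FittedSurrogate | AlphaFn,
    u: np.ndarray,
    policy: CategoricalPolicy,
    n_mc: int = 128,
    seed: int | np.random.Generator = 0,
    ucb_beta: float = 4.0,
) -> list[np.ndarray]:
    """REINFORCE estimate of the logit gradient of E_z[alpha(x, z)].

    (1/N) sum_i alpha(x, z_i) (I(z_i) - p(.|theta)), with I the per-variable
    one-hot indicator; unbiased under the softmax parameterization.
    """
    return reinforce_grad_theta_cv(
        model, u, policy, n_mc=n_mc, baseline=0.0, seed=seed, ucb_beta=ucb_beta
    )


def reinforce_grad_theta_cv(
    model: FittedSurrogate | AlphaFn,
    u: np.ndarray,
    policy: CategoricalPolicy,
    n_mc: int = 128,
    baseline: float = 0.0,
    seed: int | np.random.Generator = 0,
    ucb_beta: float = 4.0,
) -> list[np.ndarray]:
    """Control-variate REINFORCE: subtracts ``baseline`` from each sampled
    acquisition value.  The score function has zero mean, so the expectation
    is unchanged for any constant baseline; variance drops when the baseline
    tracks the mean acquisition level.
    """
    alpha = _as_alpha_fn(model, ucb_beta)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = policy.sample_indices(n_mc, rng=rng)
    uniq, counts = np.unique(draws, axis=0, return_counts=True)
    vals = _alpha_over_combos(alpha, np.asarray(u, dtype=float), uniq)
    return _score_gradient(vals, counts / n_mc, uniq, policy.probs(), baseline)


# ---------------------------------------------------------------------------
# joint optimization
# ---------------------------------------------------------------------------

def _unique_draws(
    draws: np.ndarray, sizes: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Unique joint assignments and their counts via mixed-radix encoding."""
    if draws.shape[1] == 0:
        return np.zeros((1, 0), dtype=int), np.array([draws.shape[0]])
    if int(np.prod(sizes)) > 1_000_000:  # bincount table would be too large
        uniq, counts = np.unique(draws, axis=0, return_counts=True)
        return uniq, counts
    mult = np.ones(len(sizes), dtype=np.int64)
    for j in range(len(sizes) - 2, -1, -1):
        mult[j] = mult[j + 1] * sizes[j + 1]
    codes = draws @ mult
    counts_all = np.bincount(codes, minlength=int(np.prod(sizes)))
    nz = np.nonzero(counts_all)[0]
    uniq = np.zeros((nz.size, len(sizes)), dtype=int)
    rem = nz.copy()
    for j, m in enumerate(mult):
        uniq[:, j], rem = np.divmod(rem, m)
    return uniq, counts_all[nz]


def _split(v: np.ndarray, d: int, sizes: Sequence[int]) -> tuple[np.ndarray, list[np.ndarray]]:
    u = v[:d]
    logits, off = [], d
    for k in sizes:
        logits.append(v[off : off + k])
        off += k
    return u, logits


def _polish_continuous(
    alpha: AlphaFn, u0: np.ndarray, c: np.ndarray, maxiter: int
) -> tuple[np.ndarray, float]:
    """Deterministic L-BFGS ascent of alpha(., z) at a fixed assignment."""
    if u0.size == 0:
        val = float(_alpha_over_combos(alpha, u0, c[None])[0])
        return u0, val

    def neg(uu: np.ndarray) -> float:
        return -float(alpha(uu[None], c[None])[0])

    res = minimize(
        neg,
        u0,
        method="L-BFGS-B",
        bounds=[(0.0, 1.0)] * u0.size,
        options={"maxiter": maxiter},
    )
    if np.isfinite(res.fun) and -res.fun >= -neg(u0):
        return res.x, float(-res.fun)
    return u0, float(-neg(u0))


def optimize_acquisition(
    surrogate: FittedSurrogate | AlphaFn,
    space: HybridSpace,
    config: AcquisitionConfig | None = None,
    rng: np.random.Generator | None = None,
    *,
    full_output: bool = False,
):
    """Maximize E_z[alpha(x, z)] jointly over x and the categorical logits.

    Runs ``config.n_restarts`` L-BFGS ascents from random starts (x uniform
    in the box, logits standard normal).  Each restart freezes one set of
    uniform draws and pushes them through the current policy by inverse CDF,
    so the Monte Carlo objective and its REINFORCE gradient are
    deterministic functions of the parameters.  The control-variate baseline
    is ``baseline_b`` times the running mean of all acquisition samples seen
    so far within this call.  The winning restart's probabilities are
    collapsed per-variable to their argmax level (ties to the lowest index),
    then the continuous part is polished by a deterministic L-BFGS at that
    fixed assignment.

    Returns ``(point, value)`` where ``value`` is the achieved expected
    acquisition (equal to alpha at the returned point for the collapsed
    assignment); with ``full_output=True`` also returns a dict with the
    optimized policy and per-restart values.
    """
    cfg = config or AcquisitionConfig()
    rng = np.random.default_rng(0) if rng is None else rng
    alpha = _as_alpha_fn(surrogate, cfg.ucb_beta)
    value_grad = _as_alpha_value_grad(surrogate, cfg.ucb_beta, cfg.fd_step)
    d = space.n_continuous
    sizes = list(space.level_counts)
    n_logits = int(np.sum(sizes))

    # one restart starts at the incumbent-best training point (point mass on
    # its categorical assignment), the rest at random
    incumbent = None
    if isinstance(surrogate, FittedSurrogate) and surrogate.n_train > 0:
        i_best = int(np.argmax(surrogate.y_raw))
        inc_logits = np.concatenate(
            [
                3.0 * (np.arange(k) == surrogate.C[i_best, j]) - 1.5
                for j, k in enumerate(sizes)
            ]
            or [np.zeros(0)]
        )
        incumbent = (surrogate.U[i_best].copy(), inc_logits)

    best = None  # (value, u, logits)
    restart_values = []
    for i_restart in range(cfg.n_restarts):
        rs = rng.spawn(1)[0]
        u0 = rs.uniform(size=d)
        logits0 = rs.normal(size=n_logits)
        if i_restart == 0 and incumbent is not None:
            u0, logits0 = incumbent
        uniforms = rs.uniform(size=(cfg.n_mc, len(sizes)))
        state = {"sum": 0.0, "count": 0}

        def neg_fg(v: np.ndarray) -> tuple[float, np.ndarray]:
            u, logit_list = _split(v, d, sizes)
            policy = CategoricalPolicy(logit_list) if sizes else None
            if policy is not None:
                draws = policy.sample_indices(cfg.n_mc, uniforms=uniforms)
                uniq, counts = _unique_draws(draws, sizes)
                weights = counts / cfg.n_mc
            else:
                uniq = np.zeros((1, 0), dtype=int)
                weights = np.ones(1)
            n_u = uniq.shape[0]
            U_batch = np.broadcast_to(u, (n_u, d)).copy()
            vals, grads_u = value_grad(U_batch, uniq)
            f = float(weights @ vals)
            grad = np.zeros(d + n_logits)
            grad[:d] = weights @ grads_u
            if policy is not None:
                # running-mean control-variate baseline over this call
                state["sum"] += f
                state["count"] += 1
                beta_cv = cfg.baseline_b * state["sum"] / state["count"]
                g_list = _score_gradient(
                    vals, weights, uniq, policy.probs(), beta_cv
                )
                grad[d:] = np.concatenate(g_list) if g_list else np.zeros(0)
            return -f, -grad

        v0 = np.concatenate([u0, logits0])
        bounds = [(0.0, 1.0)] * d + [(-cfg.logit_clip, cfg.logit_clip)] * n_logits
        res = minimize(
            neg_fg,
            v0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": cfg.maxiter},
        )
        v_best = res.x if np.isfinite(res.fun) else v0
        f_final = -neg_fg(v_best)[0]
        restart_values.append(f_final)
        if best is None or f_final > best[0]:
            u_fin, logit_fin = _split(v_best, d, sizes)
            best = (f_final, u_fin.copy(), [g.copy() for g in logit_fin])

    if best is None:
        raise RuntimeError("acquisition optimization failed on all restarts")

    value, u_star, logit_star = best
    policy_star = CategoricalPolicy(logit_star) if sizes else None
    if policy_star is not None:
        if cfg.sample_final_z:
            c_star = policy_star.sample_indices(1, rng=rng.spawn(1)[0])[0]
        else:
            c_star = np.array([int(np.argmax(p)) for p in policy_star.probs()])
    else:
        c_star = np.zeros(0, dtype=int)

    if cfg.final_polish:
        u_star, value = _polish_continuous(alpha, u_star, c_star, cfg.maxiter)
    else:
        value = float(_alpha_over_combos(alpha, u_star, c_star[None])[0])

    point = space.denormalize(np.clip(u_star, 0.0, 1.0), c_star)
    if full_output:
        info = {
            "policy": policy_star,
            "u": u_star,
            "c": c_star,
            "restart_values": restart_values,
        }
        return point, value, info
    return point, value
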