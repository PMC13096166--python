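"""Comparator optimizers and the shared campaign-runner harness.

``local_search_optimize`` is the alternating baseline: it fixes the
categorical assignment and ascends the continuous part with L-BFGS, then
fixes the continuous part and greedily swaps one categorical level at a
time, alternating until no improvement.  Everything else — surrogate,
nearby-liar batching, configuration — is shared with the
probabilistic-reparameterization optimizer, so campaign comparisons isolate
the acquisition-optimization strategy.  ``random_search_suggest`` is the
naive scripted baseline (uniform over the box and levels).

``run_campaign`` executes seeded suggest / evaluate / integrate rounds
against any objective callable and records a reproducible trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .acquisition import AcquisitionConfig, _as_alpha_fn, optimize_acquisition
from .batching import BatchConfig, integrate_results, space_filling_points, suggest_batch
from .observations import ObservationSet
from .space import HybridPoint, HybridSpace
from .surrogate import FittedSurrogate, SurrogateConfig

__all__ = [
    "CampaignTrace",
    "RoundRecord",
    "local_search_optimize",
    "random_search_suggest",
    "run_campaign",
]


@dataclass(frozen=True)
class RoundRecord:
    round_index: int
    points: tuple[HybridPoint, ...]
    values: tuple[float, ...]
    best_so_far: float


@dataclass
class CampaignTrace:
    """Per-round record of an optimization campaign."""

    method: str
    seed: int
    rounds: list[RoundRecord] = field(default_factory=list)

    @property
    def best_so_far(self) -> list[float]:
        return [r.best_so_far for r in self.rounds]

    @property
    def final_best(self) -> float:
        return self.rounds[-1].best_so_far if self.rounds else np.nan

    def all_points(self) -> list[HybridPoint]:
        return [p for r in self.rounds for p in r.points]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for rec in self.rounds:
            for p, y in zip(rec.points, rec.values):
                row = {"method": self.method, "seed": self.seed, "round": rec.round_index}
                row.update({k: v for k, v in p.z.items()})
                row.update({k: v for k, v in p.x.items()})
                row["y"] = y
                row["best_so_far"] = rec.best_so_far
                rows.append(row)
        return pd.DataFrame(rows)


def local_search_optimize(
    surrogate: FittedSurrogate | Callable,
    space: HybridSpace,
    config: AcquisitionConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[HybridPoint, float]:
    """Alternating acquisition ascent: L-BFGS over x, greedy level swaps over z.

    Multistart like the reparameterization optimizer; each restart alternates
    (up to 20 times) between continuous optimization at fixed categoricals
    and best-improvement single-variable level swaps at fixed continuous
    settings, accepting only improvements, until neither part improves.
    """
    cfg = config or AcquisitionConfig()
    rng = np.random.default_rng(0) if rng is None else rng
    alpha = _as_alpha_fn(surrogate, cfg.ucb_beta)
    d = space.n_continuous
    sizes = list(space.level_counts)

    def val(u: np.ndarray, c: np.ndarray) -> float:
        return float(alpha(u[None], c[None])[0])

    best_u, best_c, best_v = None, None, -np.inf
    for _ in range(cfg.n_restarts):
        rs = rng.spawn(1)[0]
        u = rs.uniform(size=d)
        c = np.array([rs.integers(k) for k in sizes], dtype=int)
        v = val(u, c)
        for _alt in range(20):
            improved = False
            # (i) continuous part at fixed categoricals
            if d > 0:
                res = minimize(
                    lambda uu: -float(alpha(uu[None], c[None])[0]),
                    u,
                    method="L-BFGS-B",
                    bounds=[(0.0, 1.0)] * d,
                    options={"maxiter": cfg.maxiter},
                )
                if np.isfinite(res.fun) and -res.fun > v + 1e-12:
                    u, v = res.x, float(-res.fun)
                    improved = True
            # (ii) greedy best-improvement level swaps at fixed continuous part
            while sizes:
                cand_C, cand_idx = [], []
                for j, k in enumerate(sizes):
                    for lev in range(k):
                        if lev == c[j]:
                            continue
                        cc = c.copy()
                        cc[j] = lev
                        cand_C.append(cc)
                        cand_idx.append((j, lev))
                if not cand_C:
                    break
                C_arr = np.array(cand_C, dtype=int)
                U_arr = np.broadcast_to(u, (C_arr.shape[0], d)).copy()
                vals = np.asarray(alpha(U_arr, C_arr), dtype=float)
                kbest = int(np.argmax(vals))
                if vals[kbest] > v + 1e-12:
                    c = C_arr[kbest]
                    v = float(vals[kbest])
                    improved = True
                else:
                    break
            if not improved:
                break
        if v > best_v:
            best_u, best_c, best_v = u.copy(), c.copy(), v
    point = space.denormalize(np.clip(best_u, 0.0, 1.0), best_c)
    return point, float(best_v)


def random_search_suggest(
    space: HybridSpace, q: int, rng: np.random.Generator
) -> list[HybridPoint]:
    """q points drawn uniformly over the box and the level sets."""
    if q < 1:
        raise ValueError("q must be >= 1")
    return [space.random_point(rng) for _ in range(q)]


_OPTIMIZERS: dict[str, Callable | None] = {
    "phbo": optimize_acquisition,
    "localsearch": local_search_optimize,
    "random": None,
}


def run_campaign(
    method: str,
    objective: Callable[[HybridPoint, np.random.Generator], float],
    space: HybridSpace,
    budget_rounds: int,
    batch_config: BatchConfig | None = None,
    seed: int = 0,
    *,
    surrogate_config: SurrogateConfig | None = None,
    acq_config: AcquisitionConfig | None = None,
    warm_start: ObservationSet | None = None,
    prior_init=None,
    n_init: int | None = None,
) -> tuple[CampaignTrace, ObservationSet]:
    """Run ``budget_rounds`` rounds of suggest -> evaluate -> integrate.

    Round 0 is initialization: the warm-start data when given (no new
    experiments), otherwise a seeded space-filling batch of ``n_init``
    evaluated points (default q), standing in for the prior database an
    expert would bring to a real campaign.  Rounds 1..budget are
    model-based for ``method`` in {"phbo", "localsearch"} and uniform for
    "random".  Traces are exactly reproducible for a fixed seed and
    deterministic objective.
    """
    if method not in _OPTIMIZERS:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(_OPTIMIZERS)}")
    bcfg = batch_config or BatchConfig()
    rng = np.random.default_rng(seed)
    trace = CampaignTrace(method=method, seed=seed)
    obs = ObservationSet()
    best = -np.inf

    def evaluate_batch(points: Sequence[HybridPoint], round_index: int) -> None:
        nonlocal obs, best
        eval_rng = rng.spawn(1)[0]
        try:
            values = [float(objective(p, eval_rng)) for p in points]
        except Exception as exc:
            raise RuntimeError(f"objective failed in round {round_index}") from exc
        obs = integrate_results(obs, points, values, round_index)
        best = max(best, max(values))
        trace.rounds.append(
            RoundRecord(round_index, tuple(points), tuple(values), best)
        )

    fit_kwargs: dict = {}
    if prior_init is not None:
        fit_kwargs["prior_mean_init"] = prior_init.prior_mean
        if prior_init.hyperparameters is not None:
            fit_kwargs["extra_inits"] = [prior_init.hyperparameters]

    if warm_start is not None and len(warm_start) > 0:
        obs = ObservationSet(records=list(warm_start.true_records))
        best = max(r.y for r in obs.true_records)
        trace.rounds.append(RoundRecord(-1, (), (), best))
    else:
        init_pts = space_filling_points(
            space, n_init if n_init is not None else bcfg.q, rng.spawn(1)[0]
        )
        evaluate_batch(init_pts, 0)

    for rnd in range(1, budget_rounds + 1):
        sugg_rng = rng.spawn(1)[0]
        if method == "random":
            points = random_search_suggest(space, bcfg.q, sugg_rng)
        else:
            points = suggest_batch(
                obs,
                space,
                surrogate_config,
                acq_config,
                bcfg,
                sugg_rng,
                optimizer=_OPTIMIZERS[method],
                fit_kwargs=fit_kwargs,
            )
        evaluate_batch(points, rnd)
    return trace, obs
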