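"""Nearby-liar parallel batch construction.

Batch suggestions are generated sequentially: after each acquisition
optimization, the suggested point receives a temporary "liar" objective —
the average measured objective of its nearest previously evaluated
neighbors in hybrid distance — and is merged into the working dataset so
that the reconditioned surrogate steers the next suggestion away from
already-covered regions.  Hyperparameters are fitted once per round on the
true data; liar records only recondition the posterior.  After the batch is
assembled all liar records are discarded, and the measured results are
merged in by :func:`integrate_results` to complete the round.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.stats import qmc

from .acquisition import AcquisitionConfig, optimize_acquisition
from .observations import Observation, ObservationSet
from .space import DistanceFn, HybridPoint, HybridSpace, distance
from .surrogate import FittedSurrogate, SurrogateConfig, fit_mle

__all__ = [
    "BatchConfig",
    "nearest_neighbors",
    "liar_value",
    "suggest_batch",
    "integrate_results",
    "space_filling_points",
]


@dataclass(frozen=True)
class BatchConfig:
    """Batch size ``q``, neighbor count ``n_nl`` for liar imputation, and
    the minimum hybrid distance ``dedupe_tol`` between suggestions."""

    q: int = 8
    n_nl: int = 3
    dedupe_tol: float = 1e-6
    max_dedupe_retries: int = 5

    def __post_init__(self) -> None:
        if self.q < 1 or self.n_nl < 1:
            raise ValueError("q and n_nl must be >= 1")
        if self.dedupe_tol < 0:
            raise ValueError("dedupe_tol must be nonnegative")


def nearest_neighbors(
    observations: ObservationSet,
    point: HybridPoint,
    n_nl: int,
    space: HybridSpace,
    metric: DistanceFn | None = None,
) -> list[Observation]:
    """The min(n_nl, available) non-liar records closest to ``point``.

    Sorted ascending by hybrid distance; ties keep insertion order.
    """
    true_recs = observations.true_records
    if not true_recs:
        raise ValueError("no non-liar observations available for neighbor search")
    dists = [distance(r.point, point, space, metric) for r in true_recs]
    order = np.argsort(dists, kind="stable")[: min(n_nl, len(true_recs))]
    return [true_recs[i] for i in order]


def liar_value(neighbors: Sequence[Observation]) -> float:
    """Imputed objective: arithmetic mean of the neighbors' objectives."""
    if len(neighbors) == 0:
        raise ValueError("liar_value needs at least one neighbor")
    return float(np.mean([r.y for r in neighbors]))


def space_filling_points(
    space: HybridSpace, q: int, rng: np.random.Generator
) -> list[HybridPoint]:
    """Seeded quasi-random initialization, standing in for a designed
    prior screen: scrambled Sobol over the continuous box, and balanced
    (stratified round-robin, independently shuffled) level assignments so
    every level of every categorical variable is covered as evenly as q
    allows."""
    if space.n_continuous > 0:
        sob = qmc.Sobol(d=space.n_continuous, scramble=True, seed=rng)
        n2 = 1 << max(0, int(np.ceil(np.log2(q))))  # draw a full power-of-2 block
        U = sob.random(n2)[:q]
    else:
        U = np.zeros((q, 0))
    level_cols = []
    for k in space.level_counts:
        col = np.tile(np.arange(k), int(np.ceil(q / k)))[:q]
        rng.shuffle(col)
        level_cols.append(col)
    pts = []
    for i in range(q):
        c = [int(col[i]) for col in level_cols]
        pts.append(space.denormalize(U[i], c))
    return pts


def suggest_batch(
    observations: ObservationSet,
    space: HybridSpace,
    surrogate_config: SurrogateConfig | None = None,
    acq_config: AcquisitionConfig | None = None,
    batch_config: BatchConfig | None = None,
    rng: np.random.Generator | None = None,
    *,
    optimizer: Callable | None = None,
    metric: DistanceFn | None = None,
    diagnostics: dict | None = None,
    fit_kwargs: dict | None = None,
) -> list[HybridPoint]:
    """Suggest ``q`` experimental conditions by sequential nearby-liar BO.

    With fewer than two non-liar observations, falls back to seeded
    space-filling initialization.  Otherwise: fit the surrogate by maximum
    likelihood on the true records, then loop q times — optimize the
    acquisition on the current (true + liar) working set, impute the
    suggestion's liar objective from its nearest true neighbors, append it
    as a liar record, recondition the posterior with unchanged
    hyperparameters.  The caller's observation set is never modified and the
    returned working history contains no liar records.

    ``optimizer`` defaults to the probabilistic-reparameterization
    optimizer; the alternating local-search baseline can be substituted so
    that everything but the acquisition optimization is shared.

    A ``diagnostics`` dict, when given, is filled with per-suggestion
    working-set sizes and liar values.
    """
    bcfg = batch_config or BatchConfig()
    acfg = acq_config or AcquisitionConfig()
    rng = np.random.default_rng(0) if rng is None else rng
    opt = optimizer or optimize_acquisition

    if diagnostics is not None:
        diagnostics["working_sizes"] = []
        diagnostics["liar_values"] = []
        diagnostics["n_liar_after"] = None

    if observations.n_true < 2:
        pts = space_filling_points(space, bcfg.q, rng)
        if diagnostics is not None:
            diagnostics["cold_start"] = True
        return pts

    true_set = ObservationSet(records=list(observations.true_records))
    fitted = fit_mle(
        true_set, space, surrogate_config, rng.spawn(1)[0], **(fit_kwargs or {})
    )
    working = true_set.copy()
    surr = fitted
    batch: list[HybridPoint] = []

    for _ in range(bcfg.q):
        child = rng.spawn(1)[0]
        if diagnostics is not None:
            diagnostics["working_sizes"].append(len(working))
        point = _suggest_distinct(surr, space, acfg, child, opt, batch, bcfg, metric)
        neighbors = nearest_neighbors(working, point, bcfg.n_nl, space, metric)
        liar_y = liar_value(neighbors)
        if diagnostics is not None:
            diagnostics["liar_values"].append(liar_y)
        batch.append(point)
        working.add(point, liar_y, is_liar=True, round_index=working.max_round)
        surr = fitted.with_observations(working)

    if diagnostics is not None:
        # the working set is discarded; no liar record survives the call
        diagnostics["n_liar_after"] = observations.n_liar
    return batch


def _suggest_distinct(
    surr: FittedSurrogate,
    space: HybridSpace,
    acfg: AcquisitionConfig,
    rng: np.random.Generator,
    opt: Callable,
    pending: list[HybridPoint],
    bcfg: BatchConfig,
    metric: DistanceFn | None,
) -> HybridPoint:
    """Optimize the acquisition, re-trying with fresh restart seeds (then a
    random continuous perturbation) until the point clears the dedupe
    tolerance against the pending batch."""
    point, _ = opt(surr, space, acfg, rng)
    if _is_distinct(point, pending, space, bcfg.dedupe_tol, metric):
        return point
    for _ in range(bcfg.max_dedupe_retries):
        point, _ = opt(surr, space, acfg, rng.spawn(1)[0])
        if _is_distinct(point, pending, space, bcfg.dedupe_tol, metric):
            return point
    # perturb the continuous part until distinct
    u, c = space.normalize(point)
    for scale in (0.05, 0.1, 0.2, 0.4, 0.8):
        u_p = np.clip(u + rng.normal(0.0, scale, size=u.shape), 0.0, 1.0)
        cand = space.denormalize(u_p, c)
        if _is_distinct(cand, pending, space, bcfg.dedupe_tol, metric):
            return cand
    raise RuntimeError(
        "could not produce a suggestion distinct from the pending batch"
    )


def _is_distinct(
    point: HybridPoint,
    pending: Sequence[HybridPoint],
    space: HybridSpace,
    tol: float,
    metric: DistanceFn | None,
) -> bool:
    return all(distance(point, p, space, metric) > tol for p in pending)


def integrate_results(
    observations: ObservationSet,
    batch_points: Sequence[HybridPoint],
    measured_values: Sequence[float],
    round_index: int,
) -> ObservationSet:
    """Merge a measured batch into the dataset, replacing any liar records.

    Returns a new set whose size is the previous true-record count plus the
    batch size; every appended record is a real (non-liar) observation.
    """
    if len(batch_points) != len(measured_values):
        raise ValueError(
            f"{len(batch_points)} points but {len(measured_values)} values"
        )
    vals = [float(v) for v in measured_values]
    if any(not np.isfinite(v) for v in vals):
        raise ValueError("measured values must be finite (record failed "
                         "reactions as objective 0, not NaN)")
    out = observations.drop_liars()
    for p, v in zip(batch_points, vals):
        out.add(p, v, is_liar=False, round_index=round_index)
    return out
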