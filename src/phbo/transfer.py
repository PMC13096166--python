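"""Transfer learning across target enzymes.

Two switchable mechanisms carry knowledge from a completed source campaign
(e.g. one enzyme) into a new one on the same variable schema:

* **BO warm-up** — the source observations are imported as initial data for
  the target campaign, flagged with round index -1 and an inflated
  observation-noise scale that mildly down-weights them against fresh
  target measurements.
* **GP prior parameter update** — the target surrogate's constant prior
  mean is initialized at the source fit's value, and the full source
  hyperparameter vector is added as one extra maximum-likelihood restart.
  Both act as soft initializations, not hard constraints.

Disabling both reproduces a cold-start campaign exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .observations import Observation, ObservationSet
from .space import HybridSpace, validate_point
from .surrogate import FittedSurrogate, GPHyperparameters

__all__ = ["TransferConfig", "PriorInit", "warm_start_dataset", "prior_from_source"]


@dataclass(frozen=True)
class TransferConfig:
    use_warmup: bool = True
    warmup_noise_multiplier: float = 2.0
    use_prior_update: bool = True

    def __post_init__(self) -> None:
        if self.warmup_noise_multiplier < 1.0:
            raise ValueError("warmup_noise_multiplier must be >= 1")


@dataclass(frozen=True)
class PriorInit:
    """Soft initialization extracted from a source surrogate."""

    prior_mean: float
    hyperparameters: GPHyperparameters | None


def warm_start_dataset(
    source_observations: ObservationSet,
    target_space: HybridSpace,
    config: TransferConfig | None = None,
) -> ObservationSet:
    """Import source records as warm-up data for the target campaign.

    Every source point must be valid in the target space (same variable
    schema).  Records are flagged with ``round_index = -1`` and carry the
    configured noise-scale multiplier; the target campaign treats them as
    true observations for surrogate fitting and neighbor search.
    """
    cfg = config or TransferConfig()
    out = ObservationSet()
    for rec in source_observations.true_records:
        validate_point(rec.point, target_space)
        out.add(
            rec.point,
            rec.y,
            is_liar=False,
            round_index=-1,
            replicate_sd=rec.replicate_sd,
            noise_scale=cfg.warmup_noise_multiplier if cfg.use_warmup else 1.0,
        )
    return out


def prior_from_source(source_surrogate: FittedSurrogate) -> PriorInit:
    """Prior initialization for the target fit from a fitted source GP.

    The constant prior mean (standardized units) seeds the target's mean
    parameter, and the full source hyperparameter vector is offered as one
    additional multistart restart.
    """
    if source_surrogate is None or source_surrogate.alpha is None:
        raise ValueError("source surrogate must be fitted")
    return PriorInit(
        prior_mean=float(source_surrogate.hyp.prior_mean),
        hyperparameters=source_surrogate.hyp,
    )
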