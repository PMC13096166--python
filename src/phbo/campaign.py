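"""Campaign persistence, observation I/O, assay utilities, and RSM export.

Objectives are stored internally as fractions (activity recovery 0.5 means
50%; values above 1 are legal) — the CLI prints percentages.  Failed
reactions that form no precipitate are recorded with objective 0 rather
than as missing data, so the surrogate learns the failure region.

Assay utilities implement the three standard immobilization figures of
merit: activity recovery AR = apparent / total activity; encapsulation
efficiency EE = (input - supernatant) / input enzyme quantity; relative
activity RA = apparent activity / free-enzyme activity at matched
concentration.

Response-surface export evaluates the fitted surrogate's posterior mean and
standard deviation on a 2-D grid over two continuous variables at a fixed
categorical combination, for contour plotting by downstream tools.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .acquisition import AcquisitionConfig
from .batching import BatchConfig
from .observations import Observation, ObservationSet
from .space import HybridPoint, HybridSpace, SpaceError, validate_point
from .surrogate import FittedSurrogate, GPHyperparameters, SurrogateConfig

logger = logging.getLogger("phbo")

__all__ = [
    "AssayRecord",
    "CampaignState",
    "compute_AR",
    "compute_EE",
    "compute_RA",
    "rsm_grid",
    "RSMGrid",
    "load_observations",
    "save_state",
    "load_state",
]


# ---------------------------------------------------------------------------
# assay utilities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssayRecord:
    """Raw assay quantities from which AR / EE / RA are derived."""

    apparent_activity: float
    total_activity: float
    supernatant_quantity: float | None = None
    input_quantity: float | None = None
    free_enzyme_activity_at_matched_conc: float | None = None


def compute_AR(apparent: float, total: float) -> float:
    """Activity recovery: apparent / total activity.  May exceed 1."""
    if total <= 0:
        raise ValueError(f"total activity must be positive, got {total}")
    return float(apparent) / float(total)


def compute_EE(input_qty: float, supernatant_qty: float) -> float:
    """Encapsulation efficiency: (input - supernatant) / input, in [0, 1].

    Assay noise can leave more enzyme in the supernatant than was put in;
    such records clamp to 0 with a logged warning rather than erroring.
    """
    if input_qty <= 0:
        raise ValueError(f"input quantity must be positive, got {input_qty}")
    if supernatant_qty > input_qty:
        logger.warning(
            "supernatant quantity %s exceeds input %s; clamping EE to 0",
            supernatant_qty,
            input_qty,
        )
        return 0.0
    return (float(input_qty) - float(supernatant_qty)) / float(input_qty)


def compute_RA(apparent: float, free_at_matched_conc: float) -> float:
    """Relative activity: apparent / free-enzyme activity.  May exceed 1."""
    if free_at_matched_conc <= 0:
        raise ValueError(
            f"free-enzyme activity must be positive, got {free_at_matched_conc}"
        )
    return float(apparent) / float(free_at_matched_conc)


# ---------------------------------------------------------------------------
# response-surface modeling
# ---------------------------------------------------------------------------

@dataclass
class RSMGrid:
    """Posterior mean/sd over a 2-D continuous grid at fixed categoricals."""

    axis_names: tuple[str, str]
    axis1: np.ndarray
    axis2: np.ndarray
    mean: np.ndarray  # (resolution, resolution), axis1 along rows
    sd: np.ndarray
    fixed_categoricals: dict[str, str]
    fixed_continuous: dict[str, float]

    def argmax(self) -> tuple[float, float]:
        i, j = np.unravel_index(int(np.argmax(self.mean)), self.mean.shape)
        return float(self.axis1[i]), float(self.axis2[j])

    def to_dataframe(self) -> pd.DataFrame:
        a1, a2 = np.meshgrid(self.axis1, self.axis2, indexing="ij")
        return pd.DataFrame(
            {
                self.axis_names[0]: a1.ravel(),
                self.axis_names[1]: a2.ravel(),
                "mean": self.mean.ravel(),
                "sd": self.sd.ravel(),
            }
        )


def rsm_grid(
    surrogate: FittedSurrogate,
    space: HybridSpace,
    fixed_categoricals: Mapping[str, str],
    fixed_continuous: Mapping[str, float],
    grid_axes: tuple[str, str],
    resolution: int = 64,
) -> RSMGrid:
    """Posterior response surface over two free continuous variables.

    Exactly two continuous variables (``grid_axes``) vary over their full
    ranges; every other continuous variable must appear in
    ``fixed_continuous`` and every categorical in ``fixed_categoricals``.
    Grid values equal pointwise posterior evaluations.
    """
    ax1, ax2 = grid_axes
    cont_names = [v.name for v in space.continuous]
    if ax1 not in cont_names or ax2 not in cont_names or ax1 == ax2:
        raise ValueError(f"grid_axes must be two distinct continuous variables, got {grid_axes}")
    free = {ax1, ax2}
    missing = [n for n in cont_names if n not in free and n not in fixed_continuous]
    if missing:
        raise ValueError(f"fixed_continuous must set {missing}")

    # categorical indices
    c = np.zeros(space.n_categorical, dtype=int)
    for j, var in enumerate(space.categoricals):
        if var.name not in fixed_categoricals:
            raise ValueError(f"fixed_categoricals must set {var.name!r}")
        c[j] = var.index_of(fixed_categoricals[var.name])

    by_name = {v.name: v for v in space.continuous}
    g1 = np.linspace(by_name[ax1].lower, by_name[ax1].upper, resolution)
    g2 = np.linspace(by_name[ax2].lower, by_name[ax2].upper, resolution)
    A1, A2 = np.meshgrid(g1, g2, indexing="ij")

    U = np.zeros((resolution * resolution, space.n_continuous))
    for i, var in enumerate(space.continuous):
        if var.name == ax1:
            vals = A1.ravel()
        elif var.name == ax2:
            vals = A2.ravel()
        else:
            x = float(fixed_continuous[var.name])
            if not var.lower <= x <= var.upper:
                raise SpaceError(
                    f"fixed value {x} for {var.name!r} outside bounds"
                )
            vals = np.full(resolution * resolution, x)
        U[:, i] = (vals - var.lower) / (var.upper - var.lower)
    C = np.broadcast_to(c, (U.shape[0], space.n_categorical))

    mean, var = surrogate.posterior_arrays(U, C)
    return RSMGrid(
        axis_names=(ax1, ax2),
        axis1=g1,
        axis2=g2,
        mean=mean.reshape(resolution, resolution),
        sd=np.sqrt(var).reshape(resolution, resolution),
        fixed_categoricals=dict(fixed_categoricals),
        fixed_continuous={k: float(v) for k, v in fixed_continuous.items()},
    )


# ---------------------------------------------------------------------------
# observation CSV I/O
# ---------------------------------------------------------------------------

def load_observations(csv_path, space: HybridSpace) -> ObservationSet:
    """Read a campaign CSV: one row per reaction.

    Required columns: every variable name plus ``objective``; optional
    ``objective_sd`` and ``round``.  Malformed rows are reported with their
    1-based data row number and offending column.
    """
    df = pd.read_csv(csv_path)
    needed = (
        [v.name for v in space.categoricals]
        + [v.name for v in space.continuous]
        + ["objective"]
    )
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"CSV {csv_path} is missing columns: {missing}")
    obs = ObservationSet()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = row._asdict()
        z = {v.name: str(row[v.name]) for v in space.categoricals}
        x = {}
        for v in space.continuous:
            try:
                x[v.name] = float(row[v.name])
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"row {i}: cannot parse column {v.name!r} value {row[v.name]!r}"
                ) from exc
        point = HybridPoint(z=z, x=x)
        try:
            validate_point(point, space)
        except SpaceError as exc:
            raise ValueError(f"row {i}: {exc}") from exc
        try:
            y = float(row["objective"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"row {i}: cannot parse column 'objective'") from exc
        if not np.isfinite(y):
            raise ValueError(f"row {i}: objective must be finite")
        sd = row.get("objective_sd")
        sd = None if sd is None or (isinstance(sd, float) and np.isnan(sd)) else float(sd)
        rnd = int(row.get("round", 0)) if not pd.isna(row.get("round", 0)) else 0
        obs.add(point, y, round_index=rnd, replicate_sd=sd)
    return obs


def observations_to_dataframe(obs: ObservationSet, space: HybridSpace) -> pd.DataFrame:
    rows = []
    for rec in obs.records:
        row = {}
        row.update(rec.point.z)
        row.update(rec.point.x)
        row["objective"] = rec.y
        row["objective_sd"] = rec.replicate_sd
        row["round"] = rec.round_index
        rows.append(row)
    cols = (
        [v.name for v in space.categoricals]
        + [v.name for v in space.continuous]
        + ["objective", "objective_sd", "round"]
    )
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# campaign state
# ---------------------------------------------------------------------------

@dataclass
class CampaignState:
    """Everything needed to resume a campaign deterministically."""

    space: HybridSpace
    observations: ObservationSet = field(default_factory=ObservationSet)
    round_index: int = 0
    seed: int = 0
    surrogate_config: SurrogateConfig = field(default_factory=SurrogateConfig)
    acq_config: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    batch_config: BatchConfig = field(default_factory=BatchConfig)
    fitted_hyperparameters: GPHyperparameters | None = None

    def to_dict(self) -> dict:
        recs = []
        for r in self.observations.records:
            recs.append(
                {
                    "z": dict(sorted(r.point.z.items())),
                    "x": dict(sorted(r.point.x.items())),
                    "y": r.y,
                    "is_liar": r.is_liar,
                    "round_index": r.round_index,
                    "replicate_sd": r.replicate_sd,
                    "noise_scale": r.noise_scale,
                }
            )
        return {
            "space": self.space.to_dict(),
            "observations": recs,
            "round_index": self.round_index,
            "seed": self.seed,
            "surrogate_config": vars(self.surrogate_config) | {},
            "acq_config": vars(self.acq_config) | {},
            "batch_config": vars(self.batch_config) | {},
            "fitted_hyperparameters": (
                self.fitted_hyperparameters.to_dict()
                if self.fitted_hyperparameters is not None
                else None
            ),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CampaignState":
        space = HybridSpace.from_dict(d["space"])
        obs = ObservationSet()
        for r in d["observations"]:
            obs.add(
                HybridPoint(z=r["z"], x=r["x"]),
                r["y"],
                is_liar=r["is_liar"],
                round_index=r["round_index"],
                replicate_sd=r["replicate_sd"],
                noise_scale=r["noise_scale"],
            )
        sc = d.get("surrogate_config", {})
        sc = SurrogateConfig(**{**sc, "ls_init_range": tuple(sc.get("ls_init_range", (0.05, 2.0)))})
        return cls(
            space=space,
            observations=obs,
            round_index=int(d["round_index"]),
            seed=int(d["seed"]),
            surrogate_config=sc,
            acq_config=AcquisitionConfig(**d.get("acq_config", {})),
            batch_config=BatchConfig(**d.get("batch_config", {})),
            fitted_hyperparameters=(
                GPHyperparameters.from_dict(d["fitted_hyperparameters"])
                if d.get("fitted_hyperparameters")
                else None
            ),
        )


def save_state(state: CampaignState, path) -> None:
    """Canonical JSON serialization: save -> load -> save is byte-identical."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(state.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_state(path) -> CampaignState:
    with open(path, "r", encoding="utf-8") as fh:
        return CampaignState.from_dict(json.load(fh))
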