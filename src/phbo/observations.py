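"""Evaluated conditions and their measured objectives.

An :class:`ObservationSet` is the campaign dataset D_t: one record per
reaction, holding the hybrid point, the measured objective (activity
recovery as a fraction; values above 1 are legal), a liar flag for
temporarily imputed values used during batch construction, the round index,
and an optional replicate standard deviation.  Warm-start records imported
from a source campaign carry round_index -1 and a noise-scale marker that
inflates their observation noise in the surrogate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np

from .space import HybridPoint, HybridSpace, normalize

__all__ = ["Observation", "ObservationSet"]


@dataclass(frozen=True)
class Observation:
    point: HybridPoint
    y: float
    is_liar: bool = False
    round_index: int = 0
    replicate_sd: float | None = None
    noise_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.round_index < -1:
            raise ValueError("round_index must be >= -1")
        if self.noise_scale <= 0:
            raise ValueError("noise_scale must be positive")


@dataclass
class ObservationSet:
    """Ordered collection of observations with liar bookkeeping."""

    records: list[Observation] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[Observation]:
        return iter(self.records)

    def add(
        self,
        point: HybridPoint,
        y: float,
        *,
        is_liar: bool = False,
        round_index: int = 0,
        replicate_sd: float | None = None,
        noise_scale: float = 1.0,
    ) -> None:
        if not np.isfinite(y):
            raise ValueError(f"objective value must be finite, got {y}")
        self.records.append(
            Observation(
                point=point,
                y=float(y),
                is_liar=is_liar,
                round_index=round_index,
                replicate_sd=replicate_sd,
                noise_scale=noise_scale,
            )
        )

    def copy(self) -> "ObservationSet":
        return ObservationSet(records=list(self.records))

    @property
    def true_records(self) -> list[Observation]:
        return [r for r in self.records if not r.is_liar]

    @property
    def n_true(self) -> int:
        return len(self.true_records)

    @property
    def n_liar(self) -> int:
        return sum(1 for r in self.records if r.is_liar)

    def drop_liars(self) -> "ObservationSet":
        return ObservationSet(records=self.true_records)

    @property
    def max_round(self) -> int:
        rounds = [r.round_index for r in self.records]
        return max(rounds) if rounds else -1

    def to_arrays(
        self, space: HybridSpace, records: Sequence[Observation] | None = None
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Normalized design matrices (U, C), objectives y and noise scales."""
        recs = self.records if records is None else list(records)
        n = len(recs)
        U = np.zeros((n, space.n_continuous))
        C = np.zeros((n, space.n_categorical), dtype=int)
        y = np.zeros(n)
        s = np.ones(n)
        for i, rec in enumerate(recs):
            U[i], C[i] = normalize(rec.point, space)
            y[i] = rec.y
            s[i] = rec.noise_scale
        return U, C, y, s

    @classmethod
    def from_records(cls, records: Iterable[Observation]) -> "ObservationSet":
        return cls(records=list(records))
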