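"""Hybrid categorical-continuous search spaces.

A campaign's domain mixes categorical variables (e.g. reagent identities:
zinc salt, organic ligand) with bounded continuous variables (e.g. precursor
concentrations in mol/L, reaction time in minutes).  This module defines the
space, its points, validation, the normalized internal representation used by
the kernels and optimizers, a pluggable hybrid distance, and exhaustive
enumeration of categorical combinations for small spaces.

All internal computation uses normalized coordinates: continuous values are
mapped affinely to [0, 1] and categorical levels to integer indices in their
declared order.  User-facing I/O stays in physical units and level labels.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "CategoricalVariable",
    "ContinuousVariable",
    "HybridSpace",
    "HybridPoint",
    "SpaceError",
    "BoundsError",
    "UnknownLevelError",
    "SchemaError",
    "EnumerationCapError",
    "validate_point",
    "normalize",
    "denormalize",
    "distance",
    "enumerate_categorical_combinations",
]


class SpaceError(ValueError):
    """Base class for search-space validation failures."""


class BoundsError(SpaceError):
    """A continuous value lies outside its variable's closed interval."""


class UnknownLevelError(SpaceError):
    """A categorical value is not one of the variable's declared levels."""


class SchemaError(SpaceError):
    """A point's variables do not match the space (missing/extra/duplicate)."""


class EnumerationCapError(SpaceError):
    """The categorical product exceeds the configured enumeration cap."""


@dataclass(frozen=True)
class CategoricalVariable:
    """A named unordered factor with a fixed set of level labels.

    Level order is storage order only and carries no ordinal meaning.
    """

    name: str
    levels: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(self.levels))
        if len(self.levels) < 1:
            raise SpaceError(f"categorical {self.name!r} needs >= 1 level")
        if len(set(self.levels)) != len(self.levels):
            raise SpaceError(f"categorical {self.name!r} has duplicate levels")

    def index_of(self, label: str) -> int:
        try:
            return self.levels.index(label)
        except ValueError:
            raise UnknownLevelError(
                f"unknown level {label!r} for variable {self.name!r}; "
                f"declared levels: {list(self.levels)}"
            ) from None


@dataclass(frozen=True)
class ContinuousVariable:
    """A named real variable on a finite closed interval, with units."""

    name: str
    lower: float
    upper: float
    units: str = ""

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lower) and np.isfinite(self.upper)):
            raise SpaceError(f"continuous {self.name!r} has non-finite bounds")
        if not self.lower < self.upper:
            raise SpaceError(
                f"continuous {self.name!r} needs lower < upper, "
                f"got [{self.lower}, {self.upper}]"
            )


@dataclass(frozen=True)
class HybridPoint:
    """One candidate condition: level labels ``z`` plus real settings ``x``."""

    z: Mapping[str, str]
    x: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "z", dict(self.z))
        object.__setattr__(self, "x", {k: float(v) for k, v in self.x.items()})


@dataclass(frozen=True)
class HybridSpace:
    """The joint domain X x Z of continuous and categorical variables."""

    categoricals: tuple[CategoricalVariable, ...] = ()
    continuous: tuple[ContinuousVariable, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "categoricals", tuple(self.categoricals))
        object.__setattr__(self, "continuous", tuple(self.continuous))
        names = [v.name for v in self.categoricals] + [
            v.name for v in self.continuous
        ]
        if len(names) == 0:
            raise SpaceError("space needs at least one variable")
        if len(set(names)) != len(names):
            raise SpaceError(f"duplicate variable names in space: {names}")

    # -- basic geometry ----------------------------------------------------
    @property
    def n_continuous(self) -> int:
        return len(self.continuous)

    @property
    def n_categorical(self) -> int:
        return len(self.categoricals)

    @property
    def level_counts(self) -> tuple[int, ...]:
        return tuple(len(v.levels) for v in self.categoricals)

    @property
    def n_combinations(self) -> int:
        out = 1
        for k in self.level_counts:
            out *= k
        return out

    @property
    def lowers(self) -> np.ndarray:
        return np.array([v.lower for v in self.continuous], dtype=float)

    @property
    def uppers(self) -> np.ndarray:
        return np.array([v.upper for v in self.continuous], dtype=float)

    # -- point handling ----------------------------------------------------
    def validate_point(self, point: HybridPoint) -> HybridPoint:
        return validate_point(point, self)

    def normalize(self, point: HybridPoint) -> tuple[np.ndarray, np.ndarray]:
        return normalize(point, self)

    def denormalize(self, u: Sequence[float], c: Sequence[int]) -> HybridPoint:
        return denormalize(u, c, self)

    def random_point(self, rng: np.random.Generator) -> HybridPoint:
        u = rng.uniform(size=self.n_continuous)
        c = [int(rng.integers(len(v.levels))) for v in self.categoricals]
        return self.denormalize(u, c)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "categoricals": [
                {"name": v.name, "levels": list(v.levels)}
                for v in self.categoricals
            ],
            "continuous": [
                {
                    "name": v.name,
                    "lower": v.lower,
                    "upper": v.upper,
                    "units": v.units,
                }
                for v in self.continuous
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "HybridSpace":
        if not isinstance(d, Mapping):
            raise SchemaError("space definition must be a JSON object")
        for key in d:
            if key not in ("categoricals", "continuous"):
                raise SchemaError(f"unknown key in space definition: {key!r}")
        cats = []
        for entry in d.get("categoricals", []):
            try:
                cats.append(
                    CategoricalVariable(
                        name=str(entry["name"]),
                        levels=tuple(str(s) for s in entry["levels"]),
                    )
                )
            except (KeyError, TypeError) as exc:
                raise SchemaError(f"bad categorical entry {entry!r}") from exc
        conts = []
        for entry in d.get("continuous", []):
            try:
                conts.append(
                    ContinuousVariable(
                        name=str(entry["name"]),
                        lower=float(entry["lower"]),
                        upper=float(entry["upper"]),
                        units=str(entry.get("units", "")),
                    )
                )
            except (KeyError, TypeError) as exc:
                raise SchemaError(f"bad continuous entry {entry!r}") from exc
        return cls(categoricals=tuple(cats), continuous=tuple(conts))

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "HybridSpace":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def validate_point(point: HybridPoint, space: HybridSpace) -> HybridPoint:
    """Check a point against the space's schema, levels and bounds.

    Returns the point unchanged when every invariant holds.  Bounds are
    closed: values exactly at a bound are valid.
    """
    cat_names = {v.name for v in space.categoricals}
    cont_names = {v.name for v in space.continuous}
    if set(point.z) != cat_names:
        missing = sorted(cat_names - set(point.z))
        extra = sorted(set(point.z) - cat_names)
        raise SchemaError(
            f"categorical variables mismatch: missing={missing} extra={extra}"
        )
    if set(point.x) != cont_names:
        missing = sorted(cont_names - set(point.x))
        extra = sorted(set(point.x) - cont_names)
        raise SchemaError(
            f"continuous variables mismatch: missing={missing} extra={extra}"
        )
    for var in space.categoricals:
        var.index_of(point.z[var.name])
    for var in space.continuous:
        val = point.x[var.name]
        if not np.isfinite(val):
            raise BoundsError(f"{var.name!r} value {val} is not finite")
        if not (var.lower <= val <= var.upper):
            raise BoundsError(
                f"{var.name!r} value {val} outside [{var.lower}, {var.upper}]"
                + (f" {var.units}" if var.units else "")
            )
    return point


def normalize(point: HybridPoint, space: HybridSpace) -> tuple[np.ndarray, np.ndarray]:
    """Map a valid point to (u in [0,1]^d, integer level indices)."""
    validate_point(point, space)
    u = np.array(
        [
            (point.x[v.name] - v.lower) / (v.upper - v.lower)
            for v in space.continuous
        ],
        dtype=float,
    )
    c = np.array(
        [v.index_of(point.z[v.name]) for v in space.categoricals], dtype=int
    )
    return u, c


def denormalize(
    u: Sequence[float], c: Sequence[int], space: HybridSpace
) -> HybridPoint:
    """Inverse of :func:`normalize`; clips u to [0,1] at floating tolerance."""
    u = np.asarray(u, dtype=float)
    c = np.asarray(c, dtype=int)
    if u.shape != (space.n_continuous,):
        raise SchemaError(
            f"expected {space.n_continuous} continuous coordinates, got {u.shape}"
        )
    if c.shape != (space.n_categorical,):
        raise SchemaError(
            f"expected {space.n_categorical} level indices, got {c.shape}"
        )
    x = {}
    for ui, var in zip(u, space.continuous):
        if ui < -1e-9 or ui > 1 + 1e-9:
            raise BoundsError(f"normalized coordinate {ui} for {var.name!r}")
        ui = min(max(float(ui), 0.0), 1.0)
        # guard 1-ulp overshoot from the affine map
        x[var.name] = min(max(var.lower + ui * (var.upper - var.lower), var.lower), var.upper)
    z = {}
    for ci, var in zip(c, space.categoricals):
        if not 0 <= ci < len(var.levels):
            raise UnknownLevelError(
                f"level index {ci} out of range for {var.name!r}"
            )
        z[var.name] = var.levels[int(ci)]
    return HybridPoint(z=z, x=x)


DistanceFn = Callable[[np.ndarray, np.ndarray, np.ndarray, np.ndarray], float]


def _euclidean_hamming(
    u1: np.ndarray, c1: np.ndarray, u2: np.ndarray, c2: np.ndarray
) -> float:
    # One categorical mismatch counts as one full unit of normalized travel.
    return float(np.sqrt(np.sum((u1 - u2) ** 2) + np.sum(c1 != c2)))


def distance(
    p1: HybridPoint,
    p2: HybridPoint,
    space: HybridSpace,
    metric: DistanceFn | None = None,
) -> float:
    """Hybrid distance between two points of the same space.

    The default metric is Euclidean on normalized continuous coordinates
    combined with a unit Hamming penalty per mismatched categorical level,
    under a joint square root.  Any callable on the normalized representation
    may be substituted.
    """
    u1, c1 = normalize(p1, space)
    u2, c2 = normalize(p2, space)
    fn = metric if metric is not None else _euclidean_hamming
    return fn(u1, c1, u2, c2)


def pairwise_distances(
    points: Iterable[HybridPoint],
    space: HybridSpace,
    metric: DistanceFn | None = None,
) -> np.ndarray:
    pts = list(points)
    n = len(pts)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = distance(pts[i], pts[j], space, metric)
    return out


def enumerate_categorical_combinations(
    space: HybridSpace, cap: int = 10_000
) -> list[dict[str, str]]:
    """All categorical assignments of the space, in declared-level order.

    With no categorical variables this is the single empty assignment.
    Raises :class:`EnumerationCapError` when the product of level counts
    exceeds ``cap``.
    """
    total = space.n_combinations
    if total > cap:
        raise EnumerationCapError(
            f"{total} categorical combinations exceed cap {cap}"
        )
    names = [v.name for v in space.categoricals]
    out = []
    for combo in itertools.product(*(v.levels for v in space.categoricals)):
        out.append(dict(zip(names, combo)))
    return out


def enumerate_combination_indices(
    level_counts: Sequence[int], cap: int = 10_000
) -> np.ndarray:
    """Integer-index version of the categorical enumeration.

    Returns an array of shape (prod(level_counts), len(level_counts)); a
    single empty row when there are no categorical variables.
    """
    total = 1
    for k in level_counts:
        total *= int(k)
    if total > cap:
        raise EnumerationCapError(f"{total} combinations exceed cap {cap}")
    if len(level_counts) == 0:
        return np.zeros((1, 0), dtype=int)
    grids = np.meshgrid(*[np.arange(k) for k in level_counts], indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1)
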