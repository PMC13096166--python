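"""Synthetic objectives with known optima for desk-scale optimizer studies.

The enzyme-immobilization landscape emulates a one-pot co-precipitation
campaign: two categorical precursors (zinc salt, organic ligand) and three
continuous settings (zinc concentration, ligand concentration, reaction
time), with activity recovery (AR, a fraction that may exceed 1) as the
objective.  Its structure encodes the qualitative behavior of such systems:

* a salt-ligand **compatibility** weight — most pairs are mediocre, a few
  excel;
* a **ratio optimum** — AR peaks near a pair-specific ligand/zinc molar
  ratio, with a Gaussian profile in log-ratio;
* **time saturation** — AR rises with reaction time as 1 - exp(-t/tau);
* a **high-ligand penalty** — strongly alkaline high-ligand conditions lose
  activity (sigmoid cutoff in ligand concentration);
* a **precipitation failure** region — ratios below a floor form no solid
  and score exactly 0.

Evaluation noise is homoscedastic Gaussian, truncated at zero.  Generation
and evaluation are pure functions of (seed, parameters, point).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .space import (
    CategoricalVariable,
    ContinuousVariable,
    HybridPoint,
    HybridSpace,
    validate_point,
)

__all__ = [
    "SyntheticLandscape",
    "LandscapeEvaluation",
    "make_enzyme_landscape",
    "make_task_pair",
    "evaluate_landscape",
    "true_optimum",
    "pair_optimum",
]

SALT_VAR = "zinc_salt"
LIGAND_VAR = "ligand"
CZN_VAR = "zinc_conc"
CLIG_VAR = "ligand_conc"
TIME_VAR = "reaction_time"


@dataclass(frozen=True)
class SyntheticLandscape:
    """Parameterized ground-truth activity-recovery response."""

    salts: tuple[str, ...]
    ligands: tuple[str, ...]
    compatibility: np.ndarray  # (n_salts, n_ligands) in [0, 1]
    optimal_log_ratio: np.ndarray  # (n_salts, n_ligands)
    ratio_width: float = 0.8  # sd of the log-ratio Gaussian; active ratios span roughly a 2-5x band around the optimum
    time_constant: float = 90.0  # min
    ligand_penalty_threshold: float = 6.0  # mol/L
    ligand_penalty_steepness: float = 0.5  # mol/L
    precipitate_ratio_floor: float = 0.2  # ligand/zinc molar ratio
    noise_sd: float = 0.03
    value_cap: float = 1.1
    czn_bounds: tuple[float, float] = (0.02, 2.0)  # mol/L
    clig_bounds: tuple[float, float] = (0.02, 8.0)  # mol/L
    time_bounds: tuple[float, float] = (1.0, 720.0)  # min
    # Concentrations span ~2 decades, so the search space exposes them on a
    # log10 scale (the response ridge log(c_lig/c_zn) = r* is then planar).
    log_concentration_space: bool = True

    def __post_init__(self) -> None:
        w = np.asarray(self.compatibility, dtype=float)
        r = np.asarray(self.optimal_log_ratio, dtype=float)
        object.__setattr__(self, "compatibility", w)
        object.__setattr__(self, "optimal_log_ratio", r)
        if w.shape != (len(self.salts), len(self.ligands)):
            raise ValueError("compatibility shape must be (n_salts, n_ligands)")
        if np.any(w < 0) or np.any(w > 1):
            raise ValueError("compatibility entries must lie in [0, 1]")
        if r.shape != w.shape:
            raise ValueError("optimal_log_ratio shape must match compatibility")

    @property
    def space(self) -> HybridSpace:
        if self.log_concentration_space:
            czn = ContinuousVariable(
                CZN_VAR, *(float(np.log10(b)) for b in self.czn_bounds), units="log10 mol/L"
            )
            clig = ContinuousVariable(
                CLIG_VAR, *(float(np.log10(b)) for b in self.clig_bounds), units="log10 mol/L"
            )
        else:
            czn = ContinuousVariable(CZN_VAR, *self.czn_bounds, units="mol/L")
            clig = ContinuousVariable(CLIG_VAR, *self.clig_bounds, units="mol/L")
        return HybridSpace(
            categoricals=(
                CategoricalVariable(SALT_VAR, self.salts),
                CategoricalVariable(LIGAND_VAR, self.ligands),
            ),
            continuous=(
                czn,
                clig,
                ContinuousVariable(TIME_VAR, *self.time_bounds, units="min"),
            ),
        )

    def _to_molar(self, value: float) -> float:
        return float(10.0**value) if self.log_concentration_space else float(value)

    # -- vectorized noiseless response ------------------------------------
    def noiseless_value(
        self,
        s_idx: np.ndarray,
        l_idx: np.ndarray,
        c_zn: np.ndarray,
        c_lig: np.ndarray,
        t: np.ndarray,
    ) -> np.ndarray:
        c_zn = np.asarray(c_zn, dtype=float)
        c_lig = np.asarray(c_lig, dtype=float)
        t = np.asarray(t, dtype=float)
        if np.any(c_zn <= 0) or np.any(c_lig <= 0):
            raise ValueError("concentrations must be positive")
        w = self.compatibility[s_idx, l_idx]
        r_star = self.optimal_log_ratio[s_idx, l_idx]
        log_ratio = np.log(c_lig / c_zn)
        ratio_factor = np.exp(-((log_ratio - r_star) ** 2) / (2.0 * self.ratio_width**2))
        time_factor = 1.0 - np.exp(-t / self.time_constant)
        penalty = 1.0 / (
            1.0
            + np.exp(
                (c_lig - self.ligand_penalty_threshold) / self.ligand_penalty_steepness
            )
        )
        val = self.value_cap * w * ratio_factor * time_factor * penalty
        failed = (c_lig / c_zn) < self.precipitate_ratio_floor
        return np.where(failed, 0.0, val)

    def evaluate(
        self,
        point: HybridPoint,
        rng: np.random.Generator | None = None,
        noiseless: bool = False,
    ) -> "LandscapeEvaluation":
        return evaluate_landscape(self, point, rng=rng, noiseless=noiseless)

    def make_objective(self) -> Callable[[HybridPoint, np.random.Generator], float]:
        """Noisy objective callable for campaign runners."""

        def objective(point: HybridPoint, rng: np.random.Generator) -> float:
            return self.evaluate(point, rng=rng).noisy_value

        return objective

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "salts": list(self.salts),
            "ligands": list(self.ligands),
            "compatibility": self.compatibility.tolist(),
            "optimal_log_ratio": self.optimal_log_ratio.tolist(),
            "ratio_width": self.ratio_width,
            "time_constant": self.time_constant,
            "ligand_penalty_threshold": self.ligand_penalty_threshold,
            "ligand_penalty_steepness": self.ligand_penalty_steepness,
            "precipitate_ratio_floor": self.precipitate_ratio_floor,
            "noise_sd": self.noise_sd,
            "value_cap": self.value_cap,
            "czn_bounds": list(self.czn_bounds),
            "clig_bounds": list(self.clig_bounds),
            "time_bounds": list(self.time_bounds),
            "log_concentration_space": self.log_concentration_space,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticLandscape":
        return cls(
            salts=tuple(d["salts"]),
            ligands=tuple(d["ligands"]),
            compatibility=np.asarray(d["compatibility"], dtype=float),
            optimal_log_ratio=np.asarray(d["optimal_log_ratio"], dtype=float),
            ratio_width=float(d["ratio_width"]),
            time_constant=float(d["time_constant"]),
            ligand_penalty_threshold=float(d["ligand_penalty_threshold"]),
            ligand_penalty_steepness=float(d["ligand_penalty_steepness"]),
            precipitate_ratio_floor=float(d["precipitate_ratio_floor"]),
            noise_sd=float(d["noise_sd"]),
            value_cap=float(d["value_cap"]),
            czn_bounds=tuple(d["czn_bounds"]),
            clig_bounds=tuple(d["clig_bounds"]),
            time_bounds=tuple(d["time_bounds"]),
            log_concentration_space=bool(d.get("log_concentration_space", True)),
        )

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "SyntheticLandscape":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class LandscapeEvaluation:
    """One evaluation with its factor breakdown."""

    point: HybridPoint
    noiseless_value: float
    noisy_value: float
    compatibility: float
    ratio_factor: float
    time_factor: float
    penalty_factor: float
    precipitate_failed: bool


def make_enzyme_landscape(
    seed: int = 0,
    n_salts: int = 7,
    n_ligands: int = 17,
    n_elite_pairs: int = 6,
    noise_sd: float = 0.03,
) -> SyntheticLandscape:
    """Seeded random landscape over ``n_salts x n_ligands`` precursor pairs.

    Compatibility has multiplicative salt and ligand main effects — certain
    salts and ligands recur among the productive combinations, as observed
    in real co-precipitation screens — with most pairs mapped to a mediocre
    range [0.05, 0.55].  ``n_elite_pairs`` pairs, drawn preferentially from
    the good-salt x good-ligand block, are boosted into [0.9, 1.0]: only a
    handful of combinations yield highly active hybrids, but their location
    is learnable from the main effects.  Optimal molar ratios share one
    landscape-wide center (log-uniform in [0.8, 8] — each enzyme system has
    a characteristic ligand/zinc ratio vicinity where high activity
    concentrates) with pair-specific log-normal jitter of sd 0.6, clipped
    to [0.5, 16].
    """
    if n_salts < 1 or n_ligands < 1:
        raise ValueError("need at least one salt and one ligand")
    rng = np.random.default_rng(seed)
    salts = tuple(f"salt{i + 1:02d}" for i in range(n_salts))
    ligands = tuple(f"lig{i + 1:02d}" for i in range(n_ligands))
    a = rng.uniform(0.4, 1.0, size=n_salts)
    b = rng.uniform(0.4, 1.0, size=n_ligands)
    base = np.outer(a, b)
    lo, hi = base.min(), base.max()
    spread = hi - lo if hi > lo else 1.0
    w = 0.05 + 0.5 * (base - lo) / spread
    n_elite = min(n_elite_pairs, n_salts * n_ligands)
    pref = base.ravel() ** 4
    flat = rng.choice(n_salts * n_ligands, size=n_elite, replace=False, p=pref / pref.sum())
    w.ravel()[flat] = rng.uniform(0.9, 1.0, size=n_elite)
    center = rng.uniform(np.log(0.8), np.log(8.0))
    r_star = np.clip(
        center + rng.normal(0.0, 0.6, size=(n_salts, n_ligands)),
        np.log(0.5),
        np.log(16.0),
    )
    return SyntheticLandscape(
        salts=salts,
        ligands=ligands,
        compatibility=w,
        optimal_log_ratio=r_star,
        noise_sd=noise_sd,
    )


def make_task_pair(
    seed: int = 0,
    n_salts: int = 7,
    n_ligands: int = 17,
    ratio_shift_sd: float = 0.3,
    compat_jitter_sd: float = 0.05,
) -> tuple[SyntheticLandscape, SyntheticLandscape]:
    """A correlated (source, target) landscape pair for transfer studies.

    The two landscapes share the salt-ligand compatibility structure (the
    target's weights are jittered by ``compat_jitter_sd`` and re-clipped)
    while the target's optimal log-ratios are shifted by independent
    Gaussian perturbations of sd ``ratio_shift_sd`` — the same precursor
    chemistry with enzyme-specific optima, as when moving a campaign from
    one enzyme to another.
    """
    source = make_enzyme_landscape(seed=seed, n_salts=n_salts, n_ligands=n_ligands)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 10_007]))
    w_t = np.clip(
        source.compatibility + rng.normal(0.0, compat_jitter_sd, source.compatibility.shape),
        0.0,
        1.0,
    )
    r_t = np.clip(
        source.optimal_log_ratio + rng.normal(0.0, ratio_shift_sd, source.optimal_log_ratio.shape),
        np.log(0.5),
        np.log(16.0),
    )
    target = replace(source, compatibility=w_t, optimal_log_ratio=r_t)
    return source, target


def evaluate_landscape(
    landscape: SyntheticLandscape,
    point: HybridPoint,
    rng: np.random.Generator | None = None,
    noiseless: bool = False,
) -> LandscapeEvaluation:
    """Evaluate one condition; noisy draws need an ``rng``.

    Precipitation-failed conditions score exactly 0 (noiseless and noisy);
    otherwise the noisy value is the noiseless response plus Gaussian noise,
    truncated at zero.
    """
    space = landscape.space
    validate_point(point, space)
    s_idx = np.array([space.categoricals[0].index_of(point.z[SALT_VAR])])
    l_idx = np.array([space.categoricals[1].index_of(point.z[LIGAND_VAR])])
    c_zn = np.array([landscape._to_molar(point.x[CZN_VAR])])
    c_lig = np.array([landscape._to_molar(point.x[CLIG_VAR])])
    t = np.array([point.x[TIME_VAR]])

    ratio = float(c_lig[0] / c_zn[0])
    failed = ratio < landscape.precipitate_ratio_floor
    val = float(landscape.noiseless_value(s_idx, l_idx, c_zn, c_lig, t)[0])

    w = float(landscape.compatibility[s_idx[0], l_idx[0]])
    r_star = float(landscape.optimal_log_ratio[s_idx[0], l_idx[0]])
    ratio_factor = float(
        np.exp(-((np.log(ratio) - r_star) ** 2) / (2 * landscape.ratio_width**2))
    )
    time_factor = float(1.0 - np.exp(-t[0] / landscape.time_constant))
    penalty = float(
        1.0
        / (
            1.0
            + np.exp(
                (c_lig[0] - landscape.ligand_penalty_threshold)
                / landscape.ligand_penalty_steepness
            )
        )
    )

    if failed:
        noisy = 0.0
    elif noiseless:
        noisy = val
    else:
        if rng is None:
            raise ValueError("noisy evaluation needs an rng")
        noisy = max(0.0, val + rng.normal(0.0, landscape.noise_sd))
    return LandscapeEvaluation(
        point=point,
        noiseless_value=val,
        noisy_value=noisy,
        compatibility=w,
        ratio_factor=ratio_factor,
        time_factor=time_factor,
        penalty_factor=penalty,
        precipitate_failed=bool(failed),
    )


def _pair_grid_max(
    landscape: SyntheticLandscape, s: int, l: int, resolution: int
) -> tuple[float, np.ndarray]:
    """Grid max for one pair, gridding uniformly in search-space coordinates.

    Returns the value and the (search-space) coordinates of the maximizer.
    """
    space = landscape.space
    axes = [np.linspace(v.lower, v.upper, resolution) for v in space.continuous]
    G = np.meshgrid(*axes, indexing="ij")
    flat = [g.ravel() for g in G]
    c_zn = 10.0 ** flat[0] if landscape.log_concentration_space else flat[0]
    c_lig = 10.0 ** flat[1] if landscape.log_concentration_space else flat[1]
    vals = landscape.noiseless_value(
        np.full(flat[0].shape, s), np.full(flat[0].shape, l), c_zn, c_lig, flat[2]
    )
    k = int(np.argmax(vals))
    return float(vals[k]), np.array([flat[0][k], flat[1][k], flat[2][k]])


def true_optimum(
    landscape: SyntheticLandscape, grid_resolution: int = 64
) -> tuple[HybridPoint, float]:
    """Noiseless grid-search optimum over all pairs and a continuous grid."""
    if grid_resolution < 10:
        raise ValueError("grid_resolution must be >= 10 per continuous dim")
    best_val, best_xyz, best_pair = -np.inf, None, None
    order = np.argsort(-landscape.compatibility, axis=None)
    for flat in order:
        s, l = np.unravel_index(flat, landscape.compatibility.shape)
        # pairs whose analytic ceiling cannot beat the incumbent are skipped
        if landscape.value_cap * landscape.compatibility[s, l] <= best_val:
            break
        v, xyz = _pair_grid_max(landscape, int(s), int(l), grid_resolution)
        if v > best_val:
            best_val, best_xyz, best_pair = v, xyz, (int(s), int(l))
    space = landscape.space
    point = HybridPoint(
        z={
            SALT_VAR: landscape.salts[best_pair[0]],
            LIGAND_VAR: landscape.ligands[best_pair[1]],
        },
        x={CZN_VAR: best_xyz[0], CLIG_VAR: best_xyz[1], TIME_VAR: best_xyz[2]},
    )
    return validate_point(point, space), best_val


def pair_optimum(
    landscape: SyntheticLandscape, s: int, l: int
) -> tuple[float, dict[str, float]]:
    """Closed-form continuous optimum for one salt-ligand pair.

    The time factor is maximal at the upper time bound, the penalty is
    decreasing in ligand concentration, and the ratio factor is maximal at
    the pair's optimal log-ratio; so the optimum takes t at its upper bound
    and the smallest feasible ligand concentration achieving the exact
    optimal ratio (falling back to the nearest achievable log-ratio when the
    box truncates it).
    """
    r_star = float(landscape.optimal_log_ratio[s, l])
    czn_lo, czn_hi = landscape.czn_bounds
    clig_lo, clig_hi = landscape.clig_bounds
    ratio = np.exp(r_star)
    # smallest c_lig with c_lig / c_zn = ratio inside both boxes
    c_lig = max(clig_lo, czn_lo * ratio)
    c_zn = c_lig / ratio
    log_ratio = r_star
    if c_zn > czn_hi:  # ratio too small for the box; best achievable ratio
        c_zn = czn_hi
        c_lig = max(clig_lo, c_zn * landscape.precipitate_ratio_floor)
        log_ratio = np.log(c_lig / c_zn)
    t = landscape.time_bounds[1]
    val = float(
        landscape.noiseless_value(
            np.array([s]), np.array([l]), np.array([c_zn]), np.array([c_lig]), np.array([t])
        )[0]
    )
    if landscape.log_concentration_space:
        coords = {CZN_VAR: float(np.log10(c_zn)), CLIG_VAR: float(np.log10(c_lig)), TIME_VAR: t}
    else:
        coords = {CZN_VAR: c_zn, CLIG_VAR: c_lig, TIME_VAR: t}
    return val, coords
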