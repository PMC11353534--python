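"""Grid Daisyworld: albedo-mediated planetary self-regulation under a sweep sun.

A toroidal X-by-X world is lit evenly at luminosity ``l``.  Each cell absorbs
``l * (1 - albedo)`` — the albedo of its daisy if occupied, of bare ground
otherwise — and relaxes its temperature halfway toward the local heating
``72 * ln(absorbed) + 80`` (or 80 when nothing is absorbed).  Temperatures
then diffuse: every cell gives away a fixed fraction of its temperature,
split equally among its 8 neighbors.  Daisies age and die past a maximum
age; survivors seed a random empty neighbor with probability
``0.1457 T - 0.0032 T^2 - 0.6443`` (clamped to [0, 1]), a parabola peaking
near 22.5 degrees C, so darker daisies warm and lighter daisies cool their
own growth conditions.  These update rules and constants follow the
canonical NetLogo formulation of the model; every constant is a config field
so deviations are explicit.

Extensions: any number of species with their own albedos; offspring mutation
(with some probability a seedling's albedo shifts by a small uniform
amount); and a plague perturbation killing a random fraction of one species
at a given tick.

Trials vary only the random initial daisy placement; the observable per
trial is the set of all cell temperatures at the final step, which feeds the
continuous entropy estimator and the incoherence measure in
:func:`luminosity_sweep`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .entropy import (
    ContinuousEnsemble,
    ContinuousEntropyConfig,
    ObservationSet,
    normalize_observations,
)
from .measures import MeasureReport, measure_continuous

__all__ = [
    "Species",
    "Plague",
    "DaisyworldConfig",
    "DaisyworldState",
    "bare_world_temperature",
    "growth_probability",
    "initial_state",
    "step",
    "run_trial",
    "luminosity_sweep",
]

EMPTY = -1


@dataclass(frozen=True)
class Species:
    """A daisy species: its albedo and how many cells it starts on."""

    albedo: float
    initial_count: int | None = None  # None = 20% of cells

    def __post_init__(self) -> None:
        if not 0.0 <= self.albedo <= 1.0:
            raise ValueError("albedo must be in [0, 1]")


@dataclass(frozen=True)
class Plague:
    """Kill a random fraction of one species at a given tick."""

    time: int
    fraction: float
    species_index: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must be in [0, 1]")


def _default_species() -> tuple[Species, ...]:
    return (Species(albedo=0.25), Species(albedo=0.75))  # black, white


@dataclass(frozen=True)
class DaisyworldConfig:
    grid_side: int = 29
    luminosity: float = 1.0
    surface_albedo: float = 0.4
    species: tuple[Species, ...] = field(default_factory=_default_species)
    max_age: int = 25
    diffusion_fraction: float = 0.5
    mutation_prob: float = 0.0
    mutation_scale: float = 0.05
    plague: Plague | None = None
    n_steps: int = 500
    trials: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_side < 3:
            raise ValueError("grid_side must be >= 3")
        if self.luminosity < 0:
            raise ValueError("luminosity must be non-negative")
        for frac in (self.surface_albedo, self.diffusion_fraction, self.mutation_prob):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must be in [0, 1]")
        object.__setattr__(self, "species", tuple(self.species))
        total = sum(self.count_for(i) for i in range(len(self.species)))
        if total > self.grid_side**2:
            raise ValueError("initial populations do not fit on the grid")

    def count_for(self, species_index: int) -> int:
        sp = self.species[species_index]
        if sp.initial_count is not None:
            return sp.initial_count
        return int(0.20 * self.grid_side**2)


@dataclass
class DaisyworldState:
    """Mutable world state: cell temperatures plus daisy occupancy."""

    temperature: np.ndarray  # (X, X) float, degrees C
    species_idx: np.ndarray  # (X, X) int, EMPTY where bare
    albedo: np.ndarray  # (X, X) float, daisy albedo (undefined where bare)
    age: np.ndarray  # (X, X) int
    tick: int = 0

    def copy(self) -> "DaisyworldState":
        return DaisyworldState(
            self.temperature.copy(),
            self.species_idx.copy(),
            self.albedo.copy(),
            self.age.copy(),
            self.tick,
        )

    @property
    def n_daisies(self) -> int:
        return int(np.count_nonzero(self.species_idx != EMPTY))


def bare_world_temperature(cfg: DaisyworldConfig) -> float:
    """Fixed point of a daisy-free world.

    With uniform temperature, diffusion is the identity and the halfway
    relaxation converges to the local heating itself:
    ``72 * ln(l * (1 - surface_albedo)) + 80``, or 80 if nothing is absorbed.
    """
    absorbed = cfg.luminosity * (1.0 - cfg.surface_albedo)
    return 72.0 * math.log(absorbed) + 80.0 if absorbed > 0 else 80.0


def growth_probability(temperature: np.ndarray) -> np.ndarray:
    """Seeding probability ``0.1457 T - 0.0032 T^2 - 0.6443`` clamped to [0, 1]."""
    t = np.asarray(temperature, dtype=float)
    return np.clip(0.1457 * t - 0.0032 * t * t - 0.6443, 0.0, 1.0)


def initial_state(cfg: DaisyworldConfig, rng: np.random.Generator) -> DaisyworldState:
    """Place each species' initial population uniformly without collisions.

    Initial ages are uniform on ``0 .. max_age - 1`` so the founding cohort
    does not die in a single synchronized wave.
    """
    x = cfg.grid_side
    species_idx = np.full((x, x), EMPTY, dtype=np.int64)
    albedo = np.zeros((x, x))
    age = np.zeros((x, x), dtype=np.int64)
    counts = [cfg.count_for(i) for i in range(len(cfg.species))]
    chosen = rng.choice(x * x, size=sum(counts), replace=False)
    offset = 0
    for i, c in enumerate(counts):
        cells = chosen[offset : offset + c]
        offset += c
        species_idx.flat[cells] = i
        albedo.flat[cells] = cfg.species[i].albedo
        age.flat[cells] = rng.integers(0, max(cfg.max_age, 1), size=c)
    return DaisyworldState(
        temperature=np.zeros((x, x)), species_idx=species_idx, albedo=albedo, age=age
    )


def _neighbor_indices(x: int) -> np.ndarray:
    """Flat indices of the 8 toroidal neighbors for every cell; shape (x*x, 8)."""
    rows, cols = np.divmod(np.arange(x * x), x)
    out = np.empty((x * x, 8), dtype=np.int64)
    j = 0
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            out[:, j] = ((rows + dr) % x) * x + (cols + dc) % x
            j += 1
    return out


def _diffuse(temp: np.ndarray, fraction: float) -> np.ndarray:
    """Each cell gives ``fraction`` of its temperature, split 8 ways."""
    if fraction == 0.0:
        return temp
    acc = np.zeros_like(temp)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            acc += np.roll(np.roll(temp, dr, axis=0), dc, axis=1)
    return (1.0 - fraction) * temp + (fraction / 8.0) * acc


def step(
    state: DaisyworldState,
    cfg: DaisyworldConfig,
    rng: np.random.Generator,
    neighbors: np.ndarray | None = None,
) -> DaisyworldState:
    """Advance the world one tick in place (the state is also returned).

    Order: absorb and relax temperatures; diffuse; age and cull; seed (each
    surviving daisy, visited in random order, may claim one random currently
    empty neighbor); apply the plague if scheduled this tick.
    """
    x = cfg.grid_side
    if neighbors is None:
        neighbors = _neighbor_indices(x)
    occupied = state.species_idx != EMPTY

    # 1. local heating and halfway relaxation
    cell_albedo = np.where(occupied, state.albedo, cfg.surface_albedo)
    absorbed = cfg.luminosity * (1.0 - cell_albedo)
    with np.errstate(divide="ignore"):
        heating = np.where(absorbed > 0, 72.0 * np.log(np.maximum(absorbed, 1e-300)) + 80.0, 80.0)
    state.temperature = 0.5 * (state.temperature + heating)

    # 2. diffusion over the torus
    state.temperature = _diffuse(state.temperature, cfg.diffusion_fraction)

    # 3. aging and death
    state.age[occupied] += 1
    dead = occupied & (state.age > cfg.max_age)
    state.species_idx[dead] = EMPTY

    # 4. seeding, in random order so scan position carries no advantage
    flat_species = state.species_idx.ravel()
    flat_albedo = state.albedo.ravel()
    flat_age = state.age.ravel()
    alive = np.flatnonzero(flat_species != EMPTY)
    if alive.size:
        p_seed = growth_probability(state.temperature.ravel()[alive])
        seeders = alive[rng.random(alive.size) < p_seed]
        rng.shuffle(seeders)
        for cell in seeders:
            nbs = neighbors[cell]
            empty = nbs[flat_species[nbs] == EMPTY]
            if empty.size == 0:
                continue
            target = empty[rng.integers(empty.size)]
            child_albedo = flat_albedo[cell]
            if cfg.mutation_prob > 0 and rng.random() < cfg.mutation_prob:
                child_albedo += rng.uniform(-cfg.mutation_scale, cfg.mutation_scale)
                child_albedo = min(max(child_albedo, 0.0), 1.0)
            flat_species[target] = flat_species[cell]
            flat_albedo[target] = child_albedo
            flat_age[target] = 0

    # 5. plague perturbation
    state.tick += 1
    if cfg.plague is not None and state.tick == cfg.plague.time:
        members = np.flatnonzero(flat_species == cfg.plague.species_index)
        n_kill = int(round(cfg.plague.fraction * members.size))
        if n_kill > 0:
            victims = rng.choice(members, size=n_kill, replace=False)
            flat_species[victims] = EMPTY
    return state


def run_trial(cfg: DaisyworldConfig, trial_index: int = 0) -> ObservationSet:
    """One full simulation; returns the final-step cell temperatures.

    Trials differ only through their RNG stream ``seed + trial_index``, which
    controls initial placement and all subsequent stochastic choices.
    """
    rng = np.random.default_rng(cfg.seed + trial_index)
    state = initial_state(cfg, rng)
    neighbors = _neighbor_indices(cfg.grid_side)
    for _ in range(cfg.n_steps):
        step(state, cfg, rng, neighbors)
    return ObservationSet(state.temperature.ravel().copy())


def luminosity_sweep(
    l_grid: Sequence[float],
    cfg_template: DaisyworldConfig | None = None,
    entropy_cfg: ContinuousEntropyConfig | None = None,
) -> pd.DataFrame:
    """Measure temperature-ensemble incoherence at each luminosity.

    Per luminosity: K trials varying only initial daisy placement; the
    final-step temperature sets are jointly normalized to [0, 1] and fed
    through the continuous measure battery.  Columns: ``l``, population and
    temperature summaries (pooled mean, mean of trial means, sd of trial
    means, sd of trial sds), and every :class:`MeasureReport` field.
    """
    cfg_template = cfg_template or DaisyworldConfig()
    rows = []
    for i, l in enumerate(l_grid):
        cfg = replace(cfg_template, luminosity=float(l), seed=cfg_template.seed + 10_000 * i)
        trials = [run_trial(cfg, t) for t in range(cfg.trials)]
        ensemble = normalize_observations(ContinuousEnsemble(tuple(trials)))
        report = measure_continuous(ensemble, entropy_cfg)
        means = np.array([t.values.mean() for t in trials])
        sds = np.array([t.values.std() for t in trials])
        row = {
            "l": float(l),
            "pooled_mean_temperature": float(
                np.mean(np.concatenate([t.values for t in trials]))
            ),
            "mean_of_means": float(means.mean()),
            "sd_of_means": float(means.std()),
            "sd_of_sds": float(sds.std()),
        }
        row.update(report.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)
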