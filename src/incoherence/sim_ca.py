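"""Elementary (Wolfram-rule) cellular automata and their ensemble incoherence.

A rule number 0–255 encodes the update table of a 1-D binary automaton: bit
``m`` of the rule gives the next state of a cell whose (left, center, right)
neighborhood reads ``m = 4*left + 2*center + right``.  Evolution uses
periodic (wrap-around) boundaries.

Per-cell entropies are computed from the frequency of the cell's boolean
states over a time window, either down a fixed column or along a wrapped
space-time diagonal (diagonals expose travelling stripe patterns that look
disordered column-wise but are perfectly ordered along their direction of
motion).  The *stable* window drops the first half of the evolution so
transients do not contaminate the frequencies.

The ensemble protocol varies only the random initial row across samples:
each sample's scalar entropy is the mean of its per-cell entropies, the
pooled entropy is the mean over cells of the entropy of the per-cell state
distribution averaged across samples, and incoherence is applied with
``Hmax = 1`` bit (binary states).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .entropy import DiscreteDistribution, shannon_entropy
from .measures import EnsembleEntropySummary, MeasureReport, report_from_summary

__all__ = [
    "CAConfig",
    "apply_rule",
    "rule_table",
    "evolve",
    "random_initial_row",
    "cell_time_entropy",
    "cell_state_frequencies",
    "ca_ensemble_summary",
    "ca_ensemble_incoherence",
    "ca_p_sweep",
]

ORIENTATIONS = ("column", "diagonal", "diagonal_left")
WINDOWS = ("stable", "full")


@dataclass(frozen=True)
class CAConfig:
    """Parameters of one cellular-automaton ensemble."""

    rule: int
    n_cells: int = 100
    n_steps: int = 200
    ones_fraction: float = 0.5
    samples: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.rule <= 255:
            raise ValueError("rule must be in 0..255")
        if self.n_cells < 3 or self.n_steps < 2:
            raise ValueError("need at least 3 cells and 2 steps")
        if not 0.0 <= self.ones_fraction <= 1.0:
            raise ValueError("ones_fraction must be in [0, 1]")
        if self.samples < 1:
            raise ValueError("samples must be >= 1")


def rule_table(rule: int) -> np.ndarray:
    """The 8 output bits of a rule, indexed by ``4*left + 2*center + right``."""
    if not 0 <= rule <= 255:
        raise ValueError("rule must be in 0..255")
    return (rule >> np.arange(8)) & 1


def apply_rule(rule: int, left: int, center: int, right: int) -> int:
    """Next state of a single cell under the given rule."""
    return int(rule_table(rule)[4 * left + 2 * center + right])


def evolve(rule: int, initial_row: Sequence[int], n_steps: int) -> np.ndarray:
    """Evolve an initial row for ``n_steps`` rows total (row 0 = initial).

    Returns a ``(n_steps, n_cells)`` 0/1 matrix; boundaries are periodic.
    """
    row = np.asarray(initial_row, dtype=np.int8)
    if row.ndim != 1 or not np.isin(row, (0, 1)).all():
        raise ValueError("initial_row must be a 1-D binary vector")
    table = rule_table(rule).astype(np.int8)
    grid = np.empty((n_steps, row.size), dtype=np.int8)
    grid[0] = row
    for t in range(1, n_steps):
        left = np.roll(grid[t - 1], 1)
        right = np.roll(grid[t - 1], -1)
        grid[t] = table[4 * left + 2 * grid[t - 1] + right]
    return grid


def random_initial_row(
    n_cells: int, ones_fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Each cell independently 1 with probability ``ones_fraction``."""
    return (rng.random(n_cells) < ones_fraction).astype(np.int8)


def _window_rows(n_steps: int, window: str) -> slice:
    if window == "full":
        return slice(0, n_steps)
    if window == "stable":
        # strictly after the midpoint, so transients are excluded
        return slice(n_steps // 2 + 1, n_steps)
    raise ValueError(f"unknown window {window!r}")


def _oriented(grid: np.ndarray, orientation: str) -> np.ndarray:
    """Re-index the grid so 'columns' follow the requested orientation."""
    if orientation == "column":
        return grid
    if orientation not in ("diagonal", "diagonal_left"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sign = 1 if orientation == "diagonal" else -1
    t = np.arange(grid.shape[0])[:, None]
    a = np.arange(grid.shape[1])[None, :]
    return grid[t, (a + sign * t) % grid.shape[1]]


def cell_state_frequencies(
    grid: np.ndarray, window: str = "stable", orientation: str = "column"
) -> np.ndarray:
    """Per-cell ``[P(0), P(1)]`` frequencies over the chosen window/orientation.

    Returns an ``(n_cells, 2)`` matrix.  For diagonals, cell ``a``'s sequence
    is ``grid[t, (a ± t) % n]`` so each trace follows one wrapped stripe.
    """
    rows = _oriented(np.asarray(grid), orientation)[_window_rows(grid.shape[0], window)]
    if rows.shape[0] < 1:
        raise ValueError("window contains no rows")
    p1 = rows.mean(axis=0)
    return np.stack([1.0 - p1, p1], axis=1)


def cell_time_entropy(
    grid: np.ndarray, window: str = "stable", orientation: str = "column"
) -> np.ndarray:
    """Per-cell binary entropy (bits) of the windowed state frequencies."""
    freqs = cell_state_frequencies(grid, window, orientation)
    return np.array([shannon_entropy(DiscreteDistribution(f)) for f in freqs])


def ca_ensemble_summary(
    cfg: CAConfig, window: str = "stable", orientation: str = "column"
) -> EnsembleEntropySummary:
    """Entropy summary over samples differing only in their random initial row.

    Sample entropy ``H_k`` = mean per-cell entropy; pooled entropy = mean over
    cells of the entropy of the per-cell distribution averaged across samples
    (cells are distinguishable, like labeled nodes); ``Hmax`` = 1 bit.
    """
    freqs = []
    entropies = []
    for k in range(cfg.samples):
        rng = np.random.default_rng(cfg.seed + k)
        grid = evolve(
            cfg.rule, random_initial_row(cfg.n_cells, cfg.ones_fraction, rng), cfg.n_steps
        )
        f = cell_state_frequencies(grid, window, orientation)
        freqs.append(f)
        entropies.append(
            float(np.mean([shannon_entropy(DiscreteDistribution(row)) for row in f]))
        )
    pooled = np.mean(freqs, axis=0)  # per-cell mean distribution across samples
    h_pool = float(
        np.mean([shannon_entropy(DiscreteDistribution(row)) for row in pooled])
    )
    return EnsembleEntropySummary(
        pooled_entropy=h_pool, member_entropies=np.array(entropies), h_max=1.0
    )


def ca_ensemble_incoherence(
    cfg: CAConfig, window: str = "stable", orientations: Sequence[str] = ("column", "diagonal")
) -> dict[str, MeasureReport]:
    """A :class:`MeasureReport` per orientation for one CA ensemble."""
    return {
        o: report_from_summary(ca_ensemble_summary(cfg, window, o)) for o in orientations
    }


def ca_p_sweep(
    rule: int,
    p_grid: Sequence[float],
    n_cells: int = 100,
    n_steps: int = 200,
    samples: int = 10,
    seed: int = 0,
    window: str = "stable",
    orientation: str = "column",
) -> pd.DataFrame:
    """Sweep the initial ones-fraction ``p`` for one rule.

    Columns: ``rule``, ``p``, CA dimensions, and every report field.
    """
    rows = []
    for i, p in enumerate(p_grid):
        cfg = CAConfig(
            rule=rule,
            n_cells=n_cells,
            n_steps=n_steps,
            ones_fraction=float(p),
            samples=samples,
            seed=seed + 10_000 * i,
        )
        if orientation == "diagonal_both":
            # stripes can travel either way depending on the ones-fraction, so
            # average the measures over the two diagonal directions
            reports = [
                report_from_summary(ca_ensemble_summary(cfg, window, o)).to_dict()
                for o in ("diagonal", "diagonal_left")
            ]
            merged = {
                k: (None if reports[0][k] is None else 0.5 * (reports[0][k] + reports[1][k]))
                for k in reports[0]
            }
            report = MeasureReport(**merged)
        else:
            report = report_from_summary(ca_ensemble_summary(cfg, window, orientation))
        row = {
            "rule": rule,
            "p": float(p),
            "n_cells": n_cells,
            "n_steps": n_steps,
            "samples": samples,
        }
        row.update(report.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)
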