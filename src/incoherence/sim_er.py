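"""Erdős–Rényi graph ensembles: degree-distribution and connectivity entropy.

A standard G(n, p) graph draws each of the n(n-1)/2 candidate edges
independently with probability p.  The systemically randomized variant draws
one ``r ~ U(0, 1)`` per graph and uses the effective edge probability
``p (1 - q) + r q``: at ``q = 0`` it reduces to the standard model, at
``q = 1`` the nominal ``p`` is ignored entirely.  The per-graph ``r``
introduces structural (system-level) disorder on top of the edge-level noise,
which incoherence should flag while per-trial entropies barely move.

Two trial summaries are available: the degree-frequency distribution over the
fixed state space of degrees ``0 .. n-1`` (shared across trials so pooling is
well defined), and the binary connectivity state ``[1, 0]`` (disconnected) /
``[0, 1]`` (connected) used to locate the connectivity phase transition near
``p = ln(n) / n``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .entropy import DiscreteDistribution, DiscreteEnsemble
from .measures import MeasureReport, measure_discrete

__all__ = [
    "ERConfig",
    "generate_graph",
    "degree_distribution",
    "connectivity_state",
    "er_ensemble",
    "er_sweep",
]


@dataclass(frozen=True)
class ERConfig:
    """Parameters of one random-graph ensemble."""

    n_nodes: int
    edge_prob: float
    system_noise: float = 0.0
    trials: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be >= 2")
        if not 0.0 <= self.edge_prob <= 1.0:
            raise ValueError("edge_prob must be in [0, 1]")
        if not 0.0 <= self.system_noise <= 1.0:
            raise ValueError("system_noise must be in [0, 1]")
        if self.trials < 1:
            raise ValueError("trials must be >= 1")


def generate_graph(cfg: ERConfig, trial_index: int = 0) -> nx.Graph:
    """One undirected simple graph on labeled nodes ``0 .. n-1``.

    The per-graph modifier ``r`` is drawn once from U(0, 1); each candidate
    edge is then included independently with ``p (1 - q) + r q``.  Trial RNG
    streams are ``seed + trial_index`` for reproducible independence.
    """
    rng = np.random.default_rng(cfg.seed + trial_index)
    r = rng.uniform()
    p_eff = cfg.edge_prob * (1.0 - cfg.system_noise) + r * cfg.system_noise
    n = cfg.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    mask = rng.random(iu.size) < p_eff
    g = nx.empty_graph(n)
    g.add_edges_from(zip(iu[mask].tolist(), ju[mask].tolist()))
    return g


def degree_distribution(graph: nx.Graph) -> DiscreteDistribution:
    """Fraction of nodes at each degree, over the fixed space ``0 .. n-1``."""
    n = graph.number_of_nodes()
    counts = np.bincount([d for _, d in graph.degree()], minlength=n)
    return DiscreteDistribution.from_counts(counts, labels=range(n))


def connectivity_state(graph: nx.Graph) -> DiscreteDistribution:
    """``[1, 0]`` if the graph is disconnected, ``[0, 1]`` if connected."""
    connected = graph.number_of_nodes() > 0 and nx.is_connected(graph)
    probs = np.array([0.0, 1.0]) if connected else np.array([1.0, 0.0])
    return DiscreteDistribution(probs, labels=("disconnected", "connected"))


def er_ensemble(cfg: ERConfig, mode: str = "degree") -> DiscreteEnsemble:
    """K independent trials summarized as a discrete ensemble."""
    if mode not in ("degree", "connectivity"):
        raise ValueError("mode must be 'degree' or 'connectivity'")
    summarize = degree_distribution if mode == "degree" else connectivity_state
    return DiscreteEnsemble(
        tuple(summarize(generate_graph(cfg, t)) for t in range(cfg.trials))
    )


def er_sweep(
    n_nodes: int,
    p_grid: Sequence[float],
    q: float = 0.0,
    trials: int = 100,
    seed: int = 0,
    mode: str = "degree",
) -> pd.DataFrame:
    """Measure the ensemble at every edge probability on the grid.

    Each grid point gets its own deterministic seed block (``seed + 10_000 *
    index``) so grids of different lengths stay reproducible.  Columns: ``p``,
    ``q``, ``n``, ``trials``, every :class:`MeasureReport` field, and
    ``fraction_connected`` in connectivity mode.
    """
    rows = []
    for i, p in enumerate(p_grid):
        cfg = ERConfig(
            n_nodes=n_nodes,
            edge_prob=float(p),
            system_noise=q,
            trials=trials,
            seed=seed + 10_000 * i,
        )
        ensemble = er_ensemble(cfg, mode=mode)
        report = measure_discrete(ensemble)
        row = {"p": float(p), "q": q, "n": n_nodes, "trials": trials}
        row.update(report.to_dict())
        if mode == "connectivity":
            row["fraction_connected"] = float(
                np.mean([m.probs[1] for m in ensemble.members])
            )
        rows.append(row)
    return pd.DataFrame(rows)
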