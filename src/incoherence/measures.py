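"""Incoherence and comparator divergences over an ensemble of trials.

The central statistic is *incoherence*

    I^2 = sum_k w_k (H~ - H_k)^2 / (H~ * Hmax)

the root-mean-square deviation between each member's entropy ``H_k`` and the
pooled entropy ``H~``, normalized by the pooled entropy and the maximum
entropy of the state space.  It is 0 for an ensemble of identical trials and
1 for an identity matrix (each trial certain of a different outcome), and —
unlike the raw Jensen–Shannon divergence it builds on — it is invariant to
the number of trials, the number of states, and the ensemble's baseline
entropy.  Dividing by the pooled entropy deliberately amplifies divergence in
otherwise ordered (low-entropy) ensembles, and the second moment over-weights
outlier trials; both are wanted properties for flagging aleatoric
uncertainty.

Classical comparators (KL, Hellinger, total variation, earth mover's
distance, chi-squared / ANOVA / Kruskal–Wallis p-values) are computed
alongside for reference; each member is compared against the pooled
distribution and the comparisons averaged, mirroring how the Jensen–Shannon
divergence relates members to the pool.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields as dataclass_fields

import numpy as np
from scipy import stats

from .entropy import (
    ContinuousEnsemble,
    ContinuousEntropyConfig,
    DiscreteDistribution,
    DiscreteEnsemble,
    ObservationSet,
    continuous_entropy,
    gf_complexity,
    max_entropy_discrete,
    pooled_distribution,
    pooled_observations,
    shannon_entropy,
)

__all__ = [
    "EnsembleEntropySummary",
    "MeasureReport",
    "jensen_shannon",
    "incoherence",
    "t_variant",
    "l_variant",
    "kl_divergence",
    "hellinger",
    "total_variation",
    "earth_mover",
    "comparator_tests",
    "summarize_discrete",
    "summarize_continuous",
    "measure_discrete",
    "measure_continuous",
]

#: pooled entropies below this are treated as exactly zero
_ZERO_TOL = 1e-12


@dataclass(frozen=True)
class EnsembleEntropySummary:
    """Entropies of an ensemble: pooled, per member, and the theoretical max.

    Any entropy estimator may stand behind the numbers; only this summary is
    needed to compute the Jensen–Shannon divergence, incoherence and its
    variants.  Note that member entropies may individually exceed the pooled
    entropy (e.g. one uniform trial among many point masses), so no ordering
    between ``pooled_entropy`` and ``member_entropies`` is assumed.
    """

    pooled_entropy: float
    member_entropies: np.ndarray
    h_max: float
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        hk = np.atleast_1d(np.asarray(self.member_entropies, dtype=float))
        if hk.size < 1:
            raise ValueError("need at least one member entropy")
        if self.h_max < 0:
            raise ValueError("h_max must be non-negative")
        tol = 1e-9 * max(1.0, self.h_max)
        if np.any(hk < -tol) or np.any(hk > self.h_max + tol):
            raise ValueError("member entropies must lie in [0, Hmax]")
        if not -tol <= self.pooled_entropy <= self.h_max + tol:
            raise ValueError("pooled entropy must lie in [0, Hmax]")
        object.__setattr__(self, "member_entropies", hk)
        if self.weights is None:
            w = np.full(hk.size, 1.0 / hk.size)
        else:
            w = np.asarray(self.weights, dtype=float)
            w = w / w.sum()
        object.__setattr__(self, "weights", w)

    @property
    def n_members(self) -> int:
        return int(self.member_entropies.size)


def jensen_shannon(s: EnsembleEntropySummary) -> float:
    """Generalized Jensen–Shannon divergence ``H~ - sum_k w_k H_k`` (bits)."""
    return float(s.pooled_entropy - s.weights @ s.member_entropies)


def incoherence(s: EnsembleEntropySummary) -> float:
    """Incoherence ``I`` in ``[0, 1]``.

    Degenerate conventions: a pooled entropy of zero means every member is a
    point mass on the same state — maximally coherent, so ``I = 0``; a
    single-state space (``Hmax = 0``) likewise yields 0.  Floating error can
    push the square marginally past 1, so the result is clamped.
    """
    if s.h_max <= _ZERO_TOL or abs(s.pooled_entropy) <= _ZERO_TOL:
        return 0.0
    sq = s.weights @ (s.pooled_entropy - s.member_entropies) ** 2
    i2 = sq / (s.pooled_entropy * s.h_max)
    return float(np.clip(math.sqrt(max(i2, 0.0)), 0.0, 1.0))


def t_variant(s: EnsembleEntropySummary) -> float:
    """Un-normalized variant ``T = I * sqrt(H~ / Hmax)`` (no pooled-entropy boost)."""
    if s.h_max <= _ZERO_TOL:
        return 0.0
    sq = s.weights @ (s.pooled_entropy - s.member_entropies) ** 2
    return float(math.sqrt(max(sq, 0.0)) / s.h_max)


def l_variant(s: EnsembleEntropySummary) -> float:
    """State-count-sensitive variant ``L = I * sqrt(Hmax)``."""
    if abs(s.pooled_entropy) <= _ZERO_TOL:
        return 0.0
    sq = s.weights @ (s.pooled_entropy - s.member_entropies) ** 2
    return float(math.sqrt(max(sq, 0.0) / s.pooled_entropy))


# ---------------------------------------------------------------------------
# pairwise divergences
# ---------------------------------------------------------------------------

def _pair(p, q) -> tuple[np.ndarray, np.ndarray]:
    if not isinstance(p, DiscreteDistribution):
        p = DiscreteDistribution(np.asarray(p, dtype=float))
    if not isinstance(q, DiscreteDistribution):
        q = DiscreteDistribution(np.asarray(q, dtype=float))
    if not p.same_space(q):
        raise ValueError("distributions live on different state spaces")
    return p.probs, q.probs


def kl_divergence(p, q) -> float:
    """Kullback–Leibler divergence in bits; ``+inf`` where Q lacks P's support."""
    pv, qv = _pair(p, q)
    mask = pv > 0
    if np.any(qv[mask] == 0):
        return math.inf
    return float(np.sum(pv[mask] * np.log2(pv[mask] / qv[mask])))


def hellinger(p, q) -> float:
    """Hellinger distance ``sqrt(0.5 * sum (sqrt P - sqrt Q)^2)``, in [0, 1]."""
    pv, qv = _pair(p, q)
    return float(math.sqrt(0.5 * np.sum((np.sqrt(pv) - np.sqrt(qv)) ** 2)))


def total_variation(p, q) -> float:
    """Total variation distance ``0.5 * sum |P - Q|``, in [0, 1]."""
    pv, qv = _pair(p, q)
    return float(0.5 * np.sum(np.abs(pv - qv)))


def earth_mover(p, q) -> float:
    """1-Wasserstein distance.

    Discrete distributions are placed at unit-spaced integer coordinates
    (state index); observation sets are compared empirically.
    """
    if isinstance(p, ObservationSet) and isinstance(q, ObservationSet):
        return float(stats.wasserstein_distance(p.values, q.values))
    pv, qv = _pair(p, q)
    coords = np.arange(pv.size)
    return float(stats.wasserstein_distance(coords, coords, pv, qv))


# ---------------------------------------------------------------------------
# classical hypothesis tests
# ---------------------------------------------------------------------------

def comparator_tests(e: DiscreteEnsemble | ContinuousEnsemble) -> dict[str, float | None]:
    """Classical homogeneity tests for baseline comparison.

    Discrete ensembles get a chi-squared contingency p-value computed on the
    probability rows scaled by 10 (used directly as fractional contingency
    weights); continuous ensembles get one-way ANOVA and Kruskal–Wallis
    p-values.  Degenerate inputs (constant data, empty table) yield ``None``.
    """
    if e.n_members < 2:
        raise ValueError("comparator tests need at least two members")
    out: dict[str, float | None] = {"chi2_p": None, "anova_p": None, "kruskal_p": None}
    if isinstance(e, DiscreteEnsemble):
        table = 10.0 * e.as_matrix()
        table = table[:, table.sum(axis=0) > 0]  # drop states unseen everywhere
        try:
            if table.shape[1] < 2:
                raise ValueError("degenerate table")
            res = stats.chi2_contingency(table)
            out["chi2_p"] = float(res.pvalue)
        except ValueError:
            pass
        return out
    groups = [m.values for m in e.members]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            p = float(stats.f_oneway(*groups).pvalue)
            out["anova_p"] = None if math.isnan(p) else p
        except ValueError:
            pass
        try:
            p = float(stats.kruskal(*groups).pvalue)
            out["kruskal_p"] = None if math.isnan(p) else p
        except ValueError:
            pass
    return out


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeasureReport:
    """Every measure computed for one ensemble; ``None`` marks not-applicable."""

    incoherence: float
    t_variant: float
    l_variant: float
    js_divergence: float
    js_normalized: float
    kl_mean: float | None = None
    hellinger_mean: float | None = None
    total_variation_mean: float | None = None
    earth_mover_mean: float | None = None
    cgf_max: float | None = None
    chi2_p: float | None = None
    anova_p: float | None = None
    kruskal_p: float | None = None

    def to_dict(self) -> dict[str, float | None]:
        return {f.name: getattr(self, f.name) for f in dataclass_fields(self)}

    @staticmethod
    def field_names() -> list[str]:
        return [f.name for f in dataclass_fields(MeasureReport)]


def summarize_discrete(e: DiscreteEnsemble) -> EnsembleEntropySummary:
    """Shannon-entropy summary of a discrete ensemble (Hmax = log2 n_states)."""
    hk = np.array([shannon_entropy(m) for m in e.members])
    h_pool = shannon_entropy(pooled_distribution(e))
    return EnsembleEntropySummary(
        pooled_entropy=h_pool,
        member_entropies=hk,
        h_max=max_entropy_discrete(e.n_states),
        weights=e.weights,
    )


def summarize_continuous(
    e: ContinuousEnsemble, cfg: ContinuousEntropyConfig | None = None
) -> EnsembleEntropySummary:
    """KDE-variance-entropy summary of a continuous ensemble (Hmax = 1)."""
    cfg = cfg or ContinuousEntropyConfig()
    hk = np.array([continuous_entropy(m, cfg) for m in e.members])
    h_pool = continuous_entropy(pooled_observations(e), cfg)
    return EnsembleEntropySummary(pooled_entropy=h_pool, member_entropies=hk, h_max=1.0)


def report_from_summary(
    s: EnsembleEntropySummary,
    *,
    comparators: dict[str, float | None] | None = None,
    pairwise: dict[str, float | None] | None = None,
) -> MeasureReport:
    """Assemble a :class:`MeasureReport` from an entropy summary."""
    djs = jensen_shannon(s)
    cgf = max(gf_complexity(min(h, s.h_max), s.h_max) for h in s.member_entropies)
    extras = dict(comparators or {})
    extras.update(pairwise or {})
    return MeasureReport(
        incoherence=incoherence(s),
        t_variant=t_variant(s),
        l_variant=l_variant(s),
        js_divergence=djs,
        js_normalized=(djs / s.h_max) if s.h_max > 0 else 0.0,
        cgf_max=cgf,
        **extras,
    )


def measure_discrete(e: DiscreteEnsemble) -> MeasureReport:
    """All measures for a discrete ensemble.

    Pairwise comparators are member-vs-pooled means; the chi-squared test is
    only attempted for two or more members.
    """
    s = summarize_discrete(e)
    pool = pooled_distribution(e)
    pairwise = {
        "kl_mean": float(np.mean([kl_divergence(m, pool) for m in e.members])),
        "hellinger_mean": float(np.mean([hellinger(m, pool) for m in e.members])),
        "total_variation_mean": float(
            np.mean([total_variation(m, pool) for m in e.members])
        ),
        "earth_mover_mean": float(np.mean([earth_mover(m, pool) for m in e.members])),
    }
    comp = comparator_tests(e) if e.n_members >= 2 else {}
    return report_from_summary(s, comparators=comp, pairwise=pairwise)


def measure_continuous(
    e: ContinuousEnsemble, cfg: ContinuousEntropyConfig | None = None
) -> MeasureReport:
    """All measures for a continuous ensemble.

    KL / Hellinger / total variation need probability vectors and are left
    absent; the earth mover's distance is computed on the empirical samples.
    """
    cfg = cfg or ContinuousEntropyConfig()
    s = summarize_continuous(e, cfg)
    pool = pooled_observations(e)
    pairwise = {
        "earth_mover_mean": float(np.mean([earth_mover(m, pool) for m in e.members]))
    }
    comp = comparator_tests(e) if e.n_members >= 2 else {}
    return report_from_summary(s, comparators=comp, pairwise=pairwise)
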