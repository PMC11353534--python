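"""Benchmark case generators comparing incoherence with classical measures.

Each case builds a small, fully specified ensemble family parameterised by a
sweep value ``x``.  The discrete cases are deterministic constructions probing
the measure's bounds and invariances (shape between the extremes, identity
matrices, outlier decay, duplication, state padding); the continuous cases
draw random observation sets (Gaussian mean/spread outliers, shrinking
uniforms, sample-size effects, a continuous identity-matrix analogue, and a
point-mass-vs-uniform pairing) and are repeated ``M`` times with the mean and
standard deviation of every measure reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .entropy import (
    ContinuousEnsemble,
    ContinuousEntropyConfig,
    DiscreteEnsemble,
    normalize_observations,
)
from .measures import MeasureReport, measure_continuous, measure_discrete

__all__ = [
    "BaselineCase",
    "DISCRETE_CASES",
    "CONTINUOUS_CASES",
    "generate_discrete_case",
    "generate_continuous_case",
    "run_case",
]

#: default number of observations per continuous trial
DEFAULT_N_OBS = 1000

#: default number of repeats for stochastic cases
DEFAULT_REPEATS = 50


# ---------------------------------------------------------------------------
# discrete cases (deterministic)
# ---------------------------------------------------------------------------

def _shape_sweep(x: float) -> DiscreteEnsemble:
    """Two 2-state trials moving from identical (x=0) to disjoint (x=1)."""
    if not 0.0 <= x <= 1.0:
        raise ValueError("shape_sweep requires x in [0, 1]")
    return DiscreteEnsemble.from_rows([[1.0, 0.0], [1.0 - x, x]])


def _identity_size(x: float) -> DiscreteEnsemble:
    """Identity matrix of size x: each trial certain of a different state."""
    m = _as_int(x, minimum=2, name="identity_size")
    return DiscreteEnsemble.from_rows(np.eye(m))


def _outlier_decay(x: float) -> DiscreteEnsemble:
    """One uniform [1/2, 1/2] trial among x point-mass [1, 0] trials."""
    m = _as_int(x, minimum=1, name="outlier_decay")
    return DiscreteEnsemble.from_rows([[0.5, 0.5]] + [[1.0, 0.0]] * m)


def _duplication(x: float) -> DiscreteEnsemble:
    """x copies of the ([1/2, 1/2], [1, 0]) pair; divergences should not move."""
    m = _as_int(x, minimum=1, name="duplication")
    return DiscreteEnsemble.from_rows([[0.5, 0.5], [1.0, 0.0]] * m)


def _state_padding_maxmin(x: float) -> DiscreteEnsemble:
    """Uniform over x states vs a point mass, padded to x states."""
    m = _as_int(x, minimum=2, name="state_padding_maxmin")
    uniform = np.full(m, 1.0 / m)
    point = np.zeros(m)
    point[0] = 1.0
    return DiscreteEnsemble.from_rows([uniform, point])


def _state_padding_disjoint(x: float) -> DiscreteEnsemble:
    """Two disjoint point masses padded to x states; agreement on the zeros grows."""
    m = _as_int(x, minimum=2, name="state_padding_disjoint")
    a = np.zeros(m)
    b = np.zeros(m)
    a[0] = 1.0
    b[1] = 1.0
    return DiscreteEnsemble.from_rows([a, b])


def _as_int(x: float, minimum: int, name: str) -> int:
    m = int(round(x))
    if abs(m - x) > 1e-9 or m < minimum:
        raise ValueError(f"{name} requires an integer x >= {minimum}")
    return m


DISCRETE_CASES = {
    "shape_sweep": _shape_sweep,
    "identity_size": _identity_size,
    "outlier_decay": _outlier_decay,
    "duplication": _duplication,
    "state_padding_maxmin": _state_padding_maxmin,
    "state_padding_disjoint": _state_padding_disjoint,
}


def generate_discrete_case(case_id: str, x: float) -> DiscreteEnsemble:
    """Build the exact deterministic ensemble a case defines at sweep value x."""
    try:
        builder = DISCRETE_CASES[case_id]
    except KeyError:
        raise ValueError(f"unknown discrete case {case_id!r}") from None
    return builder(x)


# ---------------------------------------------------------------------------
# continuous cases (stochastic)
# ---------------------------------------------------------------------------

def _gauss_mean_shift(x, rng, n_obs):
    """12 N(1, 0.01) trials plus one mean-shifted N(1+x, 0.01) outlier."""
    rows = [rng.normal(1.0, 0.01, n_obs) for _ in range(12)]
    rows.append(rng.normal(1.0 + x, 0.01, n_obs))
    return rows


def _gauss_sigma_shift(x, rng, n_obs):
    """12 N(1, 0.1) trials plus one spread outlier N(1, 0.1+x)."""
    rows = [rng.normal(1.0, 0.1, n_obs) for _ in range(12)]
    rows.append(rng.normal(1.0, 0.1 + x, n_obs))
    return rows


def _uniform_width(x, rng, n_obs):
    """Three uniforms of width x anchored left / centre / right of [0, 1]."""
    if not 0.0 < x <= 1.0:
        raise ValueError("uniform_width requires x in (0, 1]")
    return [
        rng.uniform(0.0, x, n_obs),
        rng.uniform(0.5 - x / 2, 0.5 + x / 2, n_obs),
        rng.uniform(1.0 - x, 1.0, n_obs),
    ]


def _sample_size(x, rng, n_obs):
    """20 N(1, 0.2) trials with only x observations each."""
    m = _as_int(x, minimum=2, name="sample_size")
    return [rng.normal(1.0, 0.2, m) for _ in range(20)]


def _identity_continuous(x, rng, n_obs):
    """x point-mass trials at distinct levels i/x — a continuous identity matrix."""
    m = _as_int(x, minimum=2, name="identity_continuous")
    return [np.full(n_obs, i / m) for i in range(1, m + 1)]


def _identical_minmax(x, rng, n_obs):
    """x point-mass trials (all values 1) alongside x U(0, 1) trials."""
    m = _as_int(x, minimum=1, name="identical_minmax")
    return [np.ones(n_obs) for _ in range(m)] + [rng.random(n_obs) for _ in range(m)]


CONTINUOUS_CASES = {
    "gauss_mean_shift": _gauss_mean_shift,
    "gauss_sigma_shift": _gauss_sigma_shift,
    "uniform_width": _uniform_width,
    "sample_size": _sample_size,
    "identity_continuous": _identity_continuous,
    "identical_minmax": _identical_minmax,
}


def generate_continuous_case(
    case_id: str,
    x: float,
    rng: np.random.Generator,
    n_obs: int = DEFAULT_N_OBS,
    normalize: bool = True,
) -> ContinuousEnsemble:
    """Sample a continuous case ensemble, jointly range-normalized to [0, 1]."""
    try:
        builder = CONTINUOUS_CASES[case_id]
    except KeyError:
        raise ValueError(f"unknown continuous case {case_id!r}") from None
    e = ContinuousEnsemble.from_rows(builder(x, rng, n_obs))
    return normalize_observations(e) if normalize else e


# ---------------------------------------------------------------------------
# sweep runner
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BaselineCase:
    """A sweep specification for one benchmark case."""

    case_id: str
    sweep_values: tuple[float, ...]
    repeats: int = DEFAULT_REPEATS
    seed: int = 0
    n_obs: int = DEFAULT_N_OBS

    def __post_init__(self) -> None:
        if self.case_id not in DISCRETE_CASES and self.case_id not in CONTINUOUS_CASES:
            raise ValueError(f"unknown case {self.case_id!r}")
        if len(self.sweep_values) == 0:
            raise ValueError("sweep_values must be non-empty")
        object.__setattr__(self, "sweep_values", tuple(self.sweep_values))

    @property
    def is_discrete(self) -> bool:
        return self.case_id in DISCRETE_CASES


def run_case(
    case: BaselineCase, cfg: ContinuousEntropyConfig | None = None
) -> pd.DataFrame:
    """Evaluate every measure across the sweep.

    Deterministic (discrete) cases are evaluated once per sweep value with a
    standard deviation of zero; stochastic (continuous) cases are repeated
    ``case.repeats`` times with per-repeat seeds ``seed + repeat`` and
    aggregated to mean ± sd.  Columns: ``case_id``, ``x``, then
    ``<measure>_mean`` and ``<measure>_sd`` for every report field.
    """
    cfg = cfg or ContinuousEntropyConfig()
    rows = []
    for x in case.sweep_values:
        if case.is_discrete:
            reports = [measure_discrete(generate_discrete_case(case.case_id, x))]
        else:
            reports = []
            for rep in range(case.repeats):
                rng = np.random.default_rng(case.seed + rep)
                e = generate_continuous_case(case.case_id, x, rng, case.n_obs)
                reports.append(measure_continuous(e, cfg))
        row: dict[str, float] = {"case_id": case.case_id, "x": x}
        for name in MeasureReport.field_names():
            vals = np.array(
                [np.nan if getattr(r, name) is None else getattr(r, name) for r in reports],
                dtype=float,
            )
            row[f"{name}_mean"] = float(np.nanmean(vals)) if not np.all(np.isnan(vals)) else np.nan
            row[f"{name}_sd"] = (
                float(np.nanstd(vals)) if not np.all(np.isnan(vals)) else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)
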