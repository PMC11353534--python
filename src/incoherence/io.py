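"""Reading and writing ensembles and measure reports.

Long-format files carry one record per row:

* discrete: columns ``trial_id, state_label, weight`` — per-trial weights are
  normalized into probability vectors over the union of state labels seen in
  any trial (missing states fill with 0, so ragged inputs pool cleanly);
* continuous: columns ``trial_id, value`` — raw observations, jointly
  range-normalized to [0, 1] unless disabled.

JSON inputs are lists of lists: probability rows (discrete) or observation
rows (continuous).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .entropy import (
    ContinuousEnsemble,
    DiscreteDistribution,
    DiscreteEnsemble,
    ObservationSet,
    normalize_observations,
)
from .measures import MeasureReport

__all__ = [
    "read_ensemble",
    "write_discrete_ensemble",
    "write_continuous_ensemble",
    "report_to_json",
    "report_to_csv_row",
]

logger = logging.getLogger("incoherence")


def _read_table(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        return pd.read_csv(path, sep=sep)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"could not parse {path}: {exc}") from exc


def _discrete_from_table(df: pd.DataFrame) -> DiscreteEnsemble:
    required = {"trial_id", "state_label", "weight"}
    if not required.issubset(df.columns):
        raise ValueError(f"discrete input needs columns {sorted(required)}")
    weights = pd.to_numeric(df["weight"], errors="coerce")
    if weights.isna().any():
        line = int(weights.index[weights.isna()][0]) + 2  # 1-based + header
        raise ValueError(f"non-numeric weight near line {line}")
    if (weights < 0).any():
        raise ValueError("weights must be non-negative")
    labels = list(dict.fromkeys(df["state_label"]))  # first-seen order
    members = []
    for trial_id, group in df.groupby("trial_id", sort=False):
        totals = group.groupby("state_label", sort=False)["weight"].sum()
        counts = np.array([float(totals.get(lab, 0.0)) for lab in labels])
        if counts.sum() <= 0:
            raise ValueError(f"trial {trial_id!r} has no positive weight")
        members.append(DiscreteDistribution.from_counts(counts, labels=labels))
    if not members:
        raise ValueError("no trials found")
    return DiscreteEnsemble(tuple(members))


def _continuous_from_table(df: pd.DataFrame, normalize: bool) -> ContinuousEnsemble:
    required = {"trial_id", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"continuous input needs columns {sorted(required)}")
    values = pd.to_numeric(df["value"], errors="coerce")
    if values.isna().any():
        line = int(values.index[values.isna()][0]) + 2
        raise ValueError(f"non-numeric value near line {line}")
    members = []
    for trial_id, group in df.groupby("trial_id", sort=False):
        if len(group) == 0:
            raise ValueError(f"trial {trial_id!r} is empty")
        members.append(ObservationSet(group["value"].to_numpy(dtype=float)))
    if not members:
        raise ValueError("no trials found")
    e = ContinuousEnsemble(tuple(members))
    if len(members) == 1:
        logger.warning("single-member ensemble: incoherence is 0 by definition")
    return normalize_observations(e) if normalize else e


def read_ensemble(
    path: str | Path, mode: str, normalize: bool = True
) -> DiscreteEnsemble | ContinuousEnsemble:
    """Load an ensemble from CSV/TSV (long format) or JSON (lists of lists)."""
    path = Path(path)
    if mode not in ("discrete", "continuous"):
        raise ValueError("mode must be 'discrete' or 'continuous'")
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
        if not isinstance(rows, list) or not rows:
            raise ValueError("JSON input must be a non-empty list of lists")
        if mode == "discrete":
            members = tuple(
                DiscreteDistribution.from_counts(np.asarray(r, dtype=float)) for r in rows
            )
            return DiscreteEnsemble(members)
        e = ContinuousEnsemble.from_rows(rows)
        if len(rows) == 1:
            logger.warning("single-member ensemble: incoherence is 0 by definition")
        return normalize_observations(e) if normalize else e
    df = _read_table(path)
    if mode == "discrete":
        return _discrete_from_table(df)
    return _continuous_from_table(df, normalize)


def write_discrete_ensemble(e: DiscreteEnsemble, path: str | Path) -> None:
    """Write the long-format CSV representation of a discrete ensemble."""
    records = []
    labels = e.members[0].labels or tuple(range(e.n_states))
    for k, m in enumerate(e.members):
        for lab, p in zip(labels, m.probs):
            records.append({"trial_id": k, "state_label": lab, "weight": p})
    pd.DataFrame(records).to_csv(path, index=False)


def write_continuous_ensemble(e: ContinuousEnsemble, path: str | Path) -> None:
    """Write the long-format CSV representation of a continuous ensemble."""
    records = []
    for k, m in enumerate(e.members):
        for v in m.values:
            records.append({"trial_id": k, "value": v})
    pd.DataFrame(records).to_csv(path, index=False)


def report_to_json(report: MeasureReport) -> str:
    """Full-precision JSON object, fixed field names."""
    return json.dumps(report.to_dict(), indent=2)


def report_to_csv_row(report: MeasureReport) -> pd.DataFrame:
    """One-row frame with the fixed report field order."""
    return pd.DataFrame([report.to_dict()])
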