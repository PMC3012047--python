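"""Network condensation: two-sided thresholding of scored links.

Condensation is the programmatic analogue of the interactive slider:
links whose score falls between a lower (shutdown) and an upper (startup)
cutoff are deleted, and nodes left without any incident link are pruned.
Cutoffs are given either as absolute score values or as tail quantiles of
the empirical signed-score distribution (e.g. 0.03/0.03 keeps the most
extreme ~3% of links on each side).

Also provides the optional preprocessing the method's inputs commonly
receive upstream: elementwise log transform followed by quantile
normalisation across sample columns, then per-condition mean/variance
summarisation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import StateError
from .model import MeasurementTable
from .scoring import ScoredLink

__all__ = [
    "ThresholdSpec", "CondensationResult", "preprocess", "quantile_normalize",
    "resolve_thresholds", "condense", "condensation_series",
    "write_edge_report", "write_summary_json",
]

_LOG_FNS = {"none": None, "log2": np.log2, "ln": np.log, "log10": np.log10}


@dataclass(frozen=True)
class ThresholdSpec:
    """Two-sided cutoff specification.

    ``absolute`` mode: ``lower <= 0 <= upper`` are score values.
    ``quantile`` mode: ``lower``/``upper`` are tail masses in [0, 0.5),
    resolved against the empirical score distribution as Q(lower) and
    Q(1 - upper).
    """

    mode: str  # "absolute" | "quantile"
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.mode not in ("absolute", "quantile"):
            raise ValueError(f"unknown threshold mode {self.mode!r}")
        if self.mode == "quantile":
            if not (0 <= self.lower < 0.5 and 0 <= self.upper < 0.5):
                raise ValueError("quantile tails must lie in [0, 0.5)")
        else:
            if not (self.lower <= 0 <= self.upper):
                raise ValueError("absolute thresholds require lower <= 0 <= upper")

    @classmethod
    def quantile(cls, q: float) -> "ThresholdSpec":
        return cls("quantile", q, q)

    @classmethod
    def absolute(cls, lower: float, upper: float) -> "ThresholdSpec":
        return cls("absolute", lower, upper)


@dataclass
class CondensationResult:
    """Outcome of one condensation pass."""

    kept: list[ScoredLink]
    removed_count: int
    removed_fraction: float
    retained_nodes: set[str]
    thresholds_resolved: tuple[float, float]
    spec: ThresholdSpec
    unscored_removed: int = 0
    metadata: dict = field(default_factory=dict)

    @property
    def kept_count(self) -> int:
        return len(self.kept)


def quantile_normalize(frame: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalise sample columns (rank-mean substitution).

    Each value is replaced by the mean, across columns, of the values
    sharing its within-column rank; tied ranks receive the average of the
    corresponding rank means.  Identical columns are left unchanged.
    """
    arr = frame.to_numpy(dtype=float)
    rank_means = np.sort(arr, axis=0).mean(axis=1)
    ranks = frame.rank(method="average").to_numpy() - 1.0  # 0-based, ties averaged
    normalized = np.interp(ranks, np.arange(arr.shape[0]), rank_means)
    return pd.DataFrame(normalized, index=frame.index, columns=frame.columns)


def preprocess(values: pd.DataFrame, e1_columns: Sequence[str],
               e2_columns: Sequence[str], *, log_base: str = "none",
               quantile_normalise: bool = False) -> MeasurementTable:
    """Turn a raw per-sample value matrix into a :class:`MeasurementTable`.

    ``values`` is indexed by node with one column per sample.  The log
    transform (if any) is applied elementwise first, quantile
    normalisation across all named sample columns second, and condition
    means/variances are computed afterwards from the replicate columns.
    With a single column per condition no variances are produced.
    """
    if log_base not in _LOG_FNS:
        raise ValueError(f"unknown log base {log_base!r}")
    cols = list(e1_columns) + list(e2_columns)
    missing = [c for c in cols if c not in values.columns]
    if missing:
        raise StateError(f"missing sample columns {missing}")
    frame = values[cols].astype(float).copy()
    fn = _LOG_FNS[log_base]
    if fn is not None:
        nonpos = frame.index[(frame <= 0).any(axis=1)]
        if len(nonpos):
            raise ValueError(
                f"log transform requires positive values; offending nodes: "
                f"{nonpos.tolist()}")
        frame = fn(frame)
    if quantile_normalise:
        frame = quantile_normalize(frame)
    e1 = frame[list(e1_columns)]
    e2 = frame[list(e2_columns)]
    data = pd.DataFrame({"m_e1": e1.mean(axis=1), "m_e2": e2.mean(axis=1)})
    if len(e1_columns) >= 2 and len(e2_columns) >= 2:
        data["var_e1"] = e1.var(axis=1, ddof=1)
        data["var_e2"] = e2.var(axis=1, ddof=1)
        return MeasurementTable(data, n1=len(e1_columns), n2=len(e2_columns))
    return MeasurementTable(data)


def resolve_thresholds(scores: Iterable[float], spec: ThresholdSpec) -> tuple[float, float]:
    """Resolve a spec to absolute (lower_cutoff, upper_cutoff) score values.

    Quantile mode uses linear interpolation on the empirical distribution
    (the "type 7" convention) over the *signed* scores, so the two tails
    are cut independently.
    """
    if spec.mode == "absolute":
        return (spec.lower, spec.upper)
    scores = [s for s in scores if s is not None]
    if not scores:
        raise StateError("quantile thresholds need a nonempty score list")
    arr = np.asarray(scores, dtype=float)
    lower = float(np.quantile(arr, spec.lower, method="linear"))
    upper = float(np.quantile(arr, 1.0 - spec.upper, method="linear"))
    return (lower, upper)


def condense(links: Sequence[ScoredLink], spec: ThresholdSpec) -> CondensationResult:
    """Apply a two-sided threshold and prune orphaned nodes.

    A link survives iff its score is <= the lower cutoff or >= the upper
    cutoff (boundaries inclusive).  Unscored links never survive and are
    counted among the removals.  Retained nodes are exactly the endpoints
    of surviving links.
    """
    scored = [l for l in links if l.scored]
    unscored = len(links) - len(scored)
    if spec.mode == "quantile" and not scored:
        raise StateError("cannot resolve quantile thresholds on a network "
                         "with no scored links")
    lower, upper = resolve_thresholds([l.score for l in scored], spec)
    kept = [l for l in scored if l.score <= lower or l.score >= upper]
    total = len(links)
    removed = total - len(kept)
    retained: set[str] = set()
    for l in kept:
        retained.add(l.edge.source)
        retained.add(l.edge.target)
    return CondensationResult(
        kept=kept,
        removed_count=removed,
        removed_fraction=(removed / total) if total else 0.0,
        retained_nodes=retained,
        thresholds_resolved=(lower, upper),
        spec=spec,
        unscored_removed=unscored,
    )


def condensation_series(links: Sequence[ScoredLink],
                        specs: Sequence[ThresholdSpec]) -> list[CondensationResult]:
    """Condense once per spec (ordered lenient -> stringent).

    With monotone specs the kept sets are nested decreasing — the batch
    analogue of dragging the threshold slider.
    """
    return [condense(links, spec) for spec in specs]


def write_edge_report(links: Sequence[ScoredLink], result: CondensationResult,
                      path: str | Path) -> Path:
    """Write the per-edge TSV report (all input links, kept flag included)."""
    kept_ids = {l.edge.edge_id for l in result.kept}
    rows = []
    for l in links:
        rows.append({
            "edge_id": l.edge.edge_id,
            "source": l.edge.source,
            "type": l.edge.interaction_type.value,
            "target": l.edge.target,
            "d_source": "" if l.d_source is None else repr(l.d_source),
            "d_target": "" if l.d_target is None else repr(l.d_target),
            "score": "" if l.score is None else repr(l.score),
            "consistency_class": (l.consistency_class.value
                                  if l.consistency_class else ""),
            "kept": str(l.edge.edge_id in kept_ids).lower(),
        })
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def write_summary_json(result: CondensationResult, path: str | Path) -> Path:
    """Write the JSON condensation summary (counts, fractions, cutoffs)."""
    total = result.kept_count + result.removed_count
    summary = {
        "total_links": total,
        "kept_links": result.kept_count,
        "removed_links": result.removed_count,
        "removed_fraction": round(result.removed_fraction, 6),
        "removed_percent_2dp": round(100 * result.removed_fraction, 2),
        "unscored_removed": result.unscored_removed,
        "retained_nodes": len(result.retained_nodes),
        "threshold_mode": result.spec.mode,
        "threshold_spec": [result.spec.lower, result.spec.upper],
        "resolved_cutoffs": list(result.thresholds_resolved),
    }
    path = Path(path)
    path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return path
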