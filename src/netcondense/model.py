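"""Core domain containers: typed networks and two-condition measurements.

A *typed network* is a set of genes/proteins connected by edges labelled as
one of three relationship kinds — undirected physical ``interaction``,
directed ``stimulation`` and directed ``inhibition`` — the activity-flow
vocabulary of SBGN, with the matching Systems Biology Ontology terms
(SBO:0000231 / SBO:0000170 / SBO:0000169) accepted as synonyms.

A *measurement table* holds, per node, one value for each of two
experimental conditions E1 and E2 (e.g. expression before/after an
intervention), optionally with per-condition replicate variances and the
two replicate counts n1 and n2.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import pandas as pd

from .errors import IntegrityError, SchemaError, TypingError


class InteractionType(str, enum.Enum):
    """Canonical edge relationship kinds."""

    INTERACTION = "interaction"
    STIMULATION = "stimulation"
    INHIBITION = "inhibition"


#: Default raw-value -> canonical mapping: the three literal names plus the
#: three SBO activity-flow terms.
DEFAULT_TYPE_MAPPING: Mapping[str, InteractionType] = {
    "interaction": InteractionType.INTERACTION,
    "stimulation": InteractionType.STIMULATION,
    "inhibition": InteractionType.INHIBITION,
    "SBO:0000231": InteractionType.INTERACTION,
    "SBO:0000170": InteractionType.STIMULATION,
    "SBO:0000169": InteractionType.INHIBITION,
}


def resolve_type(raw: str, mapping: Mapping[str, InteractionType] | None = None,
                 context: str = "") -> InteractionType:
    """Map a raw edge-type token to the canonical enum.

    Matching is case-insensitive on the literal names; SBO terms must match
    exactly. Unmapped values raise :class:`TypingError`.
    """
    if isinstance(raw, InteractionType):
        return raw
    table = dict(DEFAULT_TYPE_MAPPING)
    if mapping:
        table.update(mapping)
    if raw in table:
        return InteractionType(table[raw])
    lowered = str(raw).strip().lower()
    for key, value in table.items():
        if key.lower() == lowered:
            return InteractionType(value)
    raise TypingError(
        f"unmapped interaction type {raw!r}"
        + (f" on edge {context}" if context else "")
        + "; known values: " + ", ".join(sorted(table))
    )


@dataclass(frozen=True)
class TypedEdge:
    """A single typed link.

    For a ``stimulation`` or ``inhibition`` the source is the stimulator /
    inhibitor and the target the regulated node.  ``interaction`` edges are
    undirected; they are stored with endpoints in lexicographic order so
    that output is deterministic.
    """

    source: str
    target: str
    interaction_type: InteractionType
    edge_id: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "interaction_type",
                           InteractionType(self.interaction_type))
        if (self.interaction_type is InteractionType.INTERACTION
                and self.target < self.source):
            src, tgt = self.target, self.source
            object.__setattr__(self, "source", src)
            object.__setattr__(self, "target", tgt)

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.source, self.target, self.interaction_type.value)


@dataclass
class TypedNetwork:
    """A set of nodes plus a list of :class:`TypedEdge`.

    Invariants (checked on construction): every edge endpoint is a node,
    and edge ids are unique.  Duplicate edges (same endpoints and type) are
    legal and kept distinct; self-loops are legal.
    """

    nodes: set[str]
    edges: list[TypedEdge]
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = set(self.nodes)
        seen: set[str] = set()
        for edge in self.edges:
            if edge.edge_id in seen:
                raise IntegrityError(f"duplicate edge_id {edge.edge_id!r}")
            seen.add(edge.edge_id)
            for endpoint in (edge.source, edge.target):
                if endpoint not in self.nodes:
                    raise IntegrityError(
                        f"edge {edge.edge_id!r} endpoint {endpoint!r} is not a node"
                    )

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def restricted_to(self, keep: Iterable[str]) -> "TypedNetwork":
        """Induced subnetwork on ``keep`` (edges with both endpoints kept)."""
        keep = set(keep)
        edges = [e for e in self.edges if e.source in keep and e.target in keep]
        return TypedNetwork(nodes=self.nodes & keep, edges=edges,
                            metadata=dict(self.metadata))


_VALUE_COLUMNS = ("m_e1", "m_e2")
_VAR_COLUMNS = ("var_e1", "var_e2")


@dataclass
class MeasurementTable:
    """Per-node two-condition measurements.

    ``data`` is indexed by node identifier with columns ``m_e1``/``m_e2``
    (means, or single values) and optionally ``var_e1``/``var_e2``
    (replicate variances).  When variances are present, the replicate
    counts ``n1``/``n2`` are required and must be at least 2 — variance of
    a single measurement is meaningless.
    """

    data: pd.DataFrame
    n1: int | None = None
    n2: int | None = None

    def __post_init__(self) -> None:
        df = self.data
        for col in _VALUE_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"measurement table lacks column {col!r}")
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise IntegrityError(f"duplicate node identifiers: {dupes}")
        has_var = all(c in df.columns for c in _VAR_COLUMNS)
        if any(c in df.columns for c in _VAR_COLUMNS) and not has_var:
            raise SchemaError("variance requires both var_e1 and var_e2 columns")
        if has_var:
            if self.n1 is None or self.n2 is None:
                raise SchemaError("variance columns require replicate counts n1, n2")
            if self.n1 < 2 or self.n2 < 2:
                raise SchemaError("replicate counts must be >= 2 when variances are given")
            for col in _VAR_COLUMNS:
                vals = df[col]
                if vals.isna().any():
                    missing = df.index[vals.isna()].tolist()
                    raise SchemaError(f"missing {col} for nodes {missing}")
                if (vals < 0).any():
                    bad = df.index[vals < 0].tolist()
                    raise SchemaError(f"negative {col} for nodes {bad}")
        for col in _VALUE_COLUMNS:
            bad = df.index[~df[col].apply(lambda v: isinstance(v, (int, float))
                                          and math.isfinite(v))]
            if len(bad):
                raise SchemaError(f"non-finite {col} for nodes {bad.tolist()}")

    @property
    def has_variance(self) -> bool:
        return all(c in self.data.columns for c in _VAR_COLUMNS)

    @property
    def node_ids(self) -> set[str]:
        return set(self.data.index)

    def covers(self, node: str) -> bool:
        return node in self.data.index

    def row(self, node: str) -> pd.Series:
        return self.data.loc[node]

    def swap_conditions(self) -> "MeasurementTable":
        """Return the table with E1 and E2 exchanged (antisymmetry checks)."""
        df = self.data.copy()
        df[["m_e1", "m_e2"]] = df[["m_e2", "m_e1"]].to_numpy()
        if self.has_variance:
            df[["var_e1", "var_e2"]] = df[["var_e2", "var_e1"]].to_numpy()
            return MeasurementTable(df, n1=self.n2, n2=self.n1)
        return replace(self, data=df)

    def pooled_values(self) -> list[float]:
        """All measurement values from both conditions (node-color scale)."""
        return list(self.data["m_e1"]) + list(self.data["m_e2"])
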