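"""Synthetic typed networks with planted startups and shutdowns.

Real inputs to this method are a curated regulatory network and a
two-condition microarray-style measurement table.  This module generates
both from a seed: a random typed network, log-scale baseline expression
per node, and a chosen number of *planted* edges whose endpoints are
shifted between conditions in the pattern their edge type rewards —
correlated shifts for interactions/stimulations, anticorrelated for
inhibitions — so the planted edges carry link scores of ±2·effect while
background edges score only noise.  Planted edges are chosen with
pairwise-disjoint endpoints so the constructions never interfere.

Topology is uniform random (no connectivity or degree-law constraints);
the scoring method itself is topology-agnostic.
"""

from __future__ import annotations

import zipfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import InteractionType, MeasurementTable, TypedEdge, TypedNetwork

__all__ = ["PlantSpec", "generate", "make_session_fixture"]

_TYPES = (InteractionType.INTERACTION, InteractionType.STIMULATION,
          InteractionType.INHIBITION)


@dataclass(frozen=True)
class PlantSpec:
    """Parameters of one synthetic dataset.

    ``effect_size`` is the mean |differential| planted on each endpoint of
    a planted edge (log2 units, matching log-transformed microarray
    values); ``noise_sd`` is the s.d. of the condition-independent noise
    added to every node and condition.  ``replicates`` switches the table
    to mean/variance mode with the given per-condition replicate counts.
    """

    n_nodes: int = 50
    n_edges: int = 100
    type_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    n_planted_startups: int = 3
    n_planted_shutdowns: int = 3
    effect_size: float = 2.0
    noise_sd: float = 0.1
    replicates: tuple[int, int] | None = None
    seed: int = 0
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.n_planted_startups + self.n_planted_shutdowns > self.n_edges:
            raise ValueError("more planted edges than edges")
        if abs(sum(self.type_mix) - 1.0) > 1e-9:
            raise ValueError("type_mix probabilities must sum to 1")
        if self.effect_size <= 0 or self.noise_sd < 0:
            raise ValueError("effect_size must be > 0 and noise_sd >= 0")
        if self.replicates is not None and min(self.replicates) < 2:
            raise ValueError("replicate counts must be >= 2")


def _random_edges(rng: np.random.Generator, nodes: list[str], n_edges: int,
                  type_mix: tuple[float, float, float]) -> list[TypedEdge]:
    edges = []
    for i in range(n_edges):
        src, tgt = rng.choice(len(nodes), size=2, replace=False)
        itype = _TYPES[rng.choice(3, p=np.asarray(type_mix, dtype=float))]
        edges.append(TypedEdge(nodes[src], nodes[tgt], itype, f"e{i + 1}"))
    return edges


def _pick_disjoint(rng: np.random.Generator, edges: list[TypedEdge],
                   count: int, used: set[str]) -> list[TypedEdge]:
    """Greedily pick ``count`` planted edges whose endpoints are pairwise
    disjoint AND not connected to any other shifted node by a background
    edge.  This keeps every background |score| strictly below the planted
    2*effect, so noiseless recovery is exact by construction."""
    adjacency: dict[str, set[str]] = {}
    multiplicity: dict[frozenset, int] = {}
    for e in edges:
        adjacency.setdefault(e.source, set()).add(e.target)
        adjacency.setdefault(e.target, set()).add(e.source)
        pair = frozenset((e.source, e.target))
        multiplicity[pair] = multiplicity.get(pair, 0) + 1
    if count == 0:
        return []
    order = rng.permutation(len(edges))
    picked = []
    for strict in (True, False):
        for idx in order:
            e = edges[idx]
            u, v = e.source, e.target
            if u in used or v in used or u == v:
                continue
            if strict:
                if multiplicity[frozenset((u, v))] > 1:
                    continue  # a parallel edge would tie the planted score
                if (adjacency[u] & used) or (adjacency[v] & used):
                    continue  # edge into the shifted set could score 2*effect
            if e in picked:
                continue
            picked.append(e)
            used.update((u, v))
            if len(picked) == count:
                return picked
        # dense graph: relax the isolation constraint, keep plain endpoint
        # disjointness (recovery is then exact only w.h.p., not certain)
    raise ValueError("cannot plant that many endpoint-disjoint edges; "
                     "increase n_nodes or n_edges")


def generate(spec: PlantSpec) -> tuple[TypedNetwork, MeasurementTable, dict[str, str]]:
    """Generate (network, measurements, ground truth) from a :class:`PlantSpec`.

    Ground truth maps each planted edge_id to ``"startup"`` or
    ``"shutdown"``.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    nodes = [f"G{i + 1:04d}" for i in range(spec.n_nodes)]
    edges = _random_edges(rng, nodes, spec.n_edges, spec.type_mix)
    net = TypedNetwork(nodes=set(nodes), edges=list(edges),
                       metadata={"name": f"synthetic-seed{spec.seed}"})

    used: set[str] = set()
    startups = _pick_disjoint(rng, edges, spec.n_planted_startups, used)
    shutdowns = _pick_disjoint(rng, edges, spec.n_planted_shutdowns, used)
    ground_truth = {e.edge_id: "startup" for e in startups}
    ground_truth.update({e.edge_id: "shutdown" for e in shutdowns})

    # per-node shift between conditions: the Figure-2-style planted patterns
    shift = dict.fromkeys(nodes, 0.0)
    for e, sign in [(e, +1.0) for e in startups] + [(e, -1.0) for e in shutdowns]:
        if e.interaction_type is InteractionType.INHIBITION:
            shift[e.source] = sign * spec.effect_size
            shift[e.target] = -sign * spec.effect_size
        else:
            shift[e.source] = sign * spec.effect_size
            shift[e.target] = sign * spec.effect_size

    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=spec.n_nodes)
    shifts = np.array([shift[n] for n in nodes])
    if spec.replicates is None:
        m1 = baseline + rng.normal(0.0, spec.noise_sd, size=spec.n_nodes)
        m2 = baseline + shifts + rng.normal(0.0, spec.noise_sd, size=spec.n_nodes)
        table = MeasurementTable(pd.DataFrame(
            {"m_e1": m1, "m_e2": m2}, index=pd.Index(nodes, name="id")))
    else:
        n1, n2 = spec.replicates
        rep1 = baseline[:, None] + rng.normal(0.0, spec.noise_sd,
                                              size=(spec.n_nodes, n1))
        rep2 = (baseline + shifts)[:, None] + rng.normal(
            0.0, spec.noise_sd, size=(spec.n_nodes, n2))
        table = MeasurementTable(pd.DataFrame(
            {"m_e1": rep1.mean(axis=1), "m_e2": rep2.mean(axis=1),
             "var_e1": rep1.var(axis=1, ddof=1),
             "var_e2": rep2.var(axis=1, ddof=1)},
            index=pd.Index(nodes, name="id")), n1=n1, n2=n2)
    return net, table, ground_truth


def make_session_fixture(net: TypedNetwork, table: MeasurementTable | None,
                         path: str | Path) -> Path:
    """Package a network (+ optional measurements) as a minimal zip-of-XGMML
    session archive, the same container layout Cytoscape session files
    use, for exercising session extraction without any download."""
    from .io_formats import write_network  # deferred: io_formats imports scoring

    path = Path(path)
    tmp = path.with_suffix(".tmp.xgmml")
    write_network(net, tmp, format="xgmml",
                  include_attributes=table is not None, table=table)
    name = (net.metadata.get("name") or "network") + ".xgmml"
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as archive:
        archive.writestr(f"session/{name}", tmp.read_bytes())
    tmp.unlink()
    return path
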