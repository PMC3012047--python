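"""Node differentials, signed link scores and consistency classification.

The method quantifies, for every edge of a typed network, how strongly the
relationship it encodes *starts up* or *shuts down* between two
experimental conditions E1 and E2.  Per node A the differential is

    D_A = M_A,E2 - M_A,E1

or, when replicate variances are available, the Welch-standardised form

    D_A = (M_A,E2 - M_A,E1) / sqrt(Var_A,E1/n1 + Var_A,E2/n2),

the Welch two-sample t statistic (no p-value is attached).  The link score
is then

    score = D_src + D_tgt   for interaction and stimulation edges,
    score = D_src - D_tgt   for inhibition edges,

so correlated change is rewarded on interactions/stimulations and
anticorrelated change on inhibitions.  A positive score is read as a
startup, a negative one as a shutdown.  On log-scale abundances the
interaction score equals log[(A2*B2)/(A1*B1)], the change in mass-action
complex formation.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from .errors import DegenerateVarianceError, NetcondenseError
from .model import InteractionType, MeasurementTable, TypedEdge, TypedNetwork

__all__ = [
    "Basis", "Direction", "ConsistencyClass", "Differential", "ScoredLink",
    "differential", "differential_welch", "link_score", "classify_consistency",
    "score_network",
]


class Basis(str, enum.Enum):
    SINGLE = "single"
    WELCH = "welch"


class Direction(str, enum.Enum):
    STARTUP = "startup"
    SHUTDOWN = "shutdown"
    NEUTRAL = "neutral"


class ConsistencyClass(str, enum.Enum):
    CONSISTENT = "consistent"
    SOURCE_PRINCIPLE = "source_principle"
    TARGET_PRINCIPLE = "target_principle"
    INCONSISTENT = "inconsistent"
    NO_CHANGE = "no_change"


@dataclass(frozen=True)
class Differential:
    node: str
    d: float
    basis: Basis


@dataclass(frozen=True)
class ScoredLink:
    """An edge with its endpoint differentials and signed link score.

    ``score`` is ``None`` for edges whose endpoints lack measurements
    (kept only under the ``keep_unscored`` attachment policy); such links
    never survive condensation.
    """

    edge: TypedEdge
    d_source: float | None
    d_target: float | None
    score: float | None
    consistency_class: ConsistencyClass | None

    @property
    def direction(self) -> Direction:
        if self.score is None or self.score == 0:
            return Direction.NEUTRAL
        return Direction.STARTUP if self.score > 0 else Direction.SHUTDOWN

    @property
    def scored(self) -> bool:
        return self.score is not None


def differential(m_e1: float, m_e2: float) -> float:
    """Signed single-measurement differential D = m_e2 - m_e1."""
    if not (math.isfinite(m_e1) and math.isfinite(m_e2)):
        raise ValueError(f"non-finite measurement pair ({m_e1}, {m_e2})")
    return m_e2 - m_e1


def differential_welch(m_e1: float, m_e2: float, var_e1: float, var_e2: float,
                       n1: int, n2: int, *,
                       variance_floor: float | None = None) -> float:
    """Welch-standardised differential.

    Divides the raw differential by the pooled standard error
    ``sqrt(var_e1/n1 + var_e2/n2)``.  A zero pooled variance makes the
    statistic undefined: by default that raises
    :class:`DegenerateVarianceError`; passing ``variance_floor`` instead
    substitutes that floor for the pooled variance (an explicit opt-in, so
    infinite scores are never fabricated silently).
    """
    if not all(math.isfinite(v) for v in (m_e1, m_e2, var_e1, var_e2)):
        raise ValueError("non-finite input to Welch differential")
    if var_e1 < 0 or var_e2 < 0:
        raise ValueError("variances must be nonnegative")
    if n1 < 1 or n2 < 1:
        raise ValueError("replicate counts must be positive")
    pooled = var_e1 / n1 + var_e2 / n2
    if pooled <= 0:
        if variance_floor is None:
            raise DegenerateVarianceError(
                "pooled variance is zero; Welch differential undefined "
                "(pass variance_floor to substitute a floor)"
            )
        pooled = variance_floor
    return (m_e2 - m_e1) / math.sqrt(pooled)


def link_score(edge_type: InteractionType, d_source: float, d_target: float) -> float:
    """Signed link score for one edge.

    Interactions and stimulations reward correlated change (sum of
    differentials); inhibitions reward anticorrelated change (difference).
    The interaction form is symmetric in its arguments.
    """
    edge_type = InteractionType(edge_type)
    if edge_type is InteractionType.INHIBITION:
        return d_source - d_target
    return d_source + d_target


def classify_consistency(edge_type: InteractionType, d_source: float,
                         d_target: float, epsilon: float = 0.0) -> ConsistencyClass:
    """Classify an edge by how its endpoint changes relate to its type.

    With a dead-band ``epsilon`` (differentials of magnitude <= epsilon
    count as "no change"), let s and t be the dead-banded signs of the
    source and target differentials.  "Agreement" means s == t for
    interactions/stimulations and s == -t for inhibitions:

    * both signs zero                                     -> no_change
    * both nonzero and agreeing                           -> consistent
    * source change dominates a zero/disagreeing target   -> source_principle
    * target change dominates a zero/disagreeing source   -> target_principle
    * otherwise (incl. equal-magnitude disagreement)      -> inconsistent

    The two *principles* encode the hypothesis that a sufficiently large
    change on one endpoint alone justifies calling a startup/shutdown,
    attributing the other endpoint's behaviour to unmodelled counteracting
    or cooperating effectors.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")
    edge_type = InteractionType(edge_type)

    def banded_sign(d: float) -> int:
        if abs(d) <= epsilon:
            return 0
        return 1 if d > 0 else -1

    s, t = banded_sign(d_source), banded_sign(d_target)
    if s == 0 and t == 0:
        return ConsistencyClass.NO_CHANGE
    if edge_type is InteractionType.INHIBITION:
        agree = s != 0 and t != 0 and s == -t
    else:
        agree = s != 0 and t != 0 and s == t
    if agree:
        return ConsistencyClass.CONSISTENT
    if s != 0 and abs(d_source) > abs(d_target):
        return ConsistencyClass.SOURCE_PRINCIPLE
    if t != 0 and abs(d_target) > abs(d_source):
        return ConsistencyClass.TARGET_PRINCIPLE
    return ConsistencyClass.INCONSISTENT


def node_differentials(net: TypedNetwork, table: MeasurementTable, *,
                       variance_floor: float | None = None) -> dict[str, Differential]:
    """Differential per covered node, Welch-standardised iff the table
    carries variances (the basis is uniform across the network)."""
    out: dict[str, Differential] = {}
    welch = table.has_variance
    for node in sorted(net.nodes):
        if not table.covers(node):
            continue
        row = table.row(node)
        if welch:
            try:
                d = differential_welch(float(row["m_e1"]), float(row["m_e2"]),
                                       float(row["var_e1"]), float(row["var_e2"]),
                                       table.n1, table.n2,
                                       variance_floor=variance_floor)
            except DegenerateVarianceError as exc:
                raise DegenerateVarianceError(f"node {node!r}: {exc}") from exc
            out[node] = Differential(node, float(d), Basis.WELCH)
        else:
            out[node] = Differential(
                node, float(differential(float(row["m_e1"]), float(row["m_e2"]))),
                Basis.SINGLE)
    return out


def score_network(net: TypedNetwork, table: MeasurementTable, *,
                  epsilon: float = 0.0, include_unscored: bool = False,
                  variance_floor: float | None = None) -> list[ScoredLink]:
    """Score every edge of ``net`` against ``table``.

    Differentials are computed once per node and reused across its edges.
    Edges with an unmeasured endpoint are skipped unless
    ``include_unscored`` is set, in which case they appear with
    ``score=None`` (and are unconditionally dropped by condensation).
    """
    diffs = node_differentials(net, table, variance_floor=variance_floor)
    links: list[ScoredLink] = []
    for edge in net.edges:
        ds, dt = diffs.get(edge.source), diffs.get(edge.target)
        if ds is None or dt is None:
            if include_unscored:
                links.append(ScoredLink(edge, None, None, None, None))
            continue
        score = link_score(edge.interaction_type, ds.d, dt.d)
        cls = classify_consistency(edge.interaction_type, ds.d, dt.d, epsilon)
        links.append(ScoredLink(edge, ds.d, dt.d, score, cls))
    return links
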