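"""Visual encodings: two-half node colors and score-driven edge styles.

Nodes follow the heat-map metaphor.  The pooled list of measurement
values (both conditions) is anchored at its 10%, 50% and 90% quantiles;
values at or below the 10% anchor are a fixed green, values at or above
the 90% anchor a fixed red, and everything between is linearly
interpolated through white at the median.  Each node shows its E1 value
on the left half and its E2 value on the right half.

Edges are red for startups (positive score), green for shutdowns
(negative score); color saturation and line width grow linearly with the
score magnitude.  Links whose endpoint changes are not plainly consistent
with the edge type (source/target principle or inconsistent) are flagged
``wavy`` and drawn dashed in static renderings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .condense import CondensationResult
from .errors import StateError
from .model import MeasurementTable
from .scoring import ConsistencyClass, ScoredLink

__all__ = ["ColorScale", "StyleMap", "build_color_scale", "value_to_color",
           "style_network", "render_figure",
           "GREEN", "WHITE", "RED", "EDGE_RED", "EDGE_GREEN"]

RGB = tuple[int, int, int]

GREEN: RGB = (0, 200, 0)
WHITE: RGB = (255, 255, 255)
RED: RGB = (220, 0, 0)
#: Fully saturated edge colors (interpolated toward white at low |score|).
EDGE_RED: RGB = (220, 0, 0)
EDGE_GREEN: RGB = (0, 160, 0)

_WAVY_CLASSES = {ConsistencyClass.SOURCE_PRINCIPLE,
                 ConsistencyClass.TARGET_PRINCIPLE,
                 ConsistencyClass.INCONSISTENT}


@dataclass(frozen=True)
class ColorScale:
    """Piecewise-linear value->color map anchored at three quantiles."""

    q10: float
    q50: float
    q90: float
    color_low: RGB = GREEN
    color_mid: RGB = WHITE
    color_high: RGB = RED

    def __post_init__(self) -> None:
        if not (self.q10 <= self.q50 <= self.q90):
            raise ValueError("color-scale anchors must be ordered")


@dataclass
class StyleMap:
    """Computed per-node and per-edge visual attributes."""

    node_styles: dict[str, tuple[RGB, RGB]] = field(default_factory=dict)
    edge_styles: dict[str, tuple[RGB, float, bool]] = field(default_factory=dict)


def build_color_scale(values: Sequence[float], q_low: float = 0.10,
                      q_mid: float = 0.50, q_high: float = 0.90,
                      palette: tuple[RGB, RGB, RGB] = (GREEN, WHITE, RED),
                      ) -> ColorScale:
    """Anchor a color scale at empirical quantiles of the pooled values."""
    if len(values) == 0:
        raise StateError("cannot build a color scale from no values")
    if not (0 <= q_low < q_mid < q_high <= 1):
        raise ValueError("quantile anchors must satisfy 0 <= low < mid < high <= 1")
    arr = np.asarray(values, dtype=float)
    lo, mid, hi = (float(np.quantile(arr, q, method="linear"))
                   for q in (q_low, q_mid, q_high))
    return ColorScale(lo, mid, hi, *palette)


def _lerp(a: RGB, b: RGB, t: float) -> RGB:
    return tuple(int(round(a[i] + (b[i] - a[i]) * t)) for i in range(3))


def value_to_color(v: float, scale: ColorScale) -> RGB:
    """Map a measurement value to RGB: clamped below q10 / above q90,
    linear per channel within [q10, q50] and [q50, q90]."""
    if scale.q10 == scale.q90:
        return scale.color_mid  # degenerate (constant-valued) scale
    if v <= scale.q10:
        return scale.color_low
    if v >= scale.q90:
        return scale.color_high
    if v <= scale.q50:
        span = scale.q50 - scale.q10
        t = (v - scale.q10) / span if span else 1.0
        return _lerp(scale.color_low, scale.color_mid, t)
    span = scale.q90 - scale.q50
    t = (v - scale.q50) / span if span else 1.0
    return _lerp(scale.color_mid, scale.color_high, t)


def _edge_style(score: float, max_abs: float,
                width_range: tuple[float, float]) -> tuple[RGB, float]:
    wmin, wmax = width_range
    if max_abs <= 0:
        # all kept scores are zero (degenerate single-point scaling rule)
        return WHITE, wmax
    t = min(abs(score) / max_abs, 1.0)
    base = EDGE_RED if score > 0 else EDGE_GREEN if score < 0 else WHITE
    color = _lerp(WHITE, base, t)  # saturation grows with |score|
    return color, wmin + (wmax - wmin) * t


def style_network(links: Sequence[ScoredLink], table: MeasurementTable,
                  scale: ColorScale,
                  width_range: tuple[float, float] = (1.0, 8.0)) -> StyleMap:
    """Compute the full style map for a set of (kept) scored links.

    Edge width and saturation are linear in |score| over the kept-score
    range; when all kept scores share one magnitude every edge gets the
    maximum width.
    """
    if width_range[0] <= 0 or width_range[1] < width_range[0]:
        raise ValueError("width range must satisfy 0 < min <= max")
    style = StyleMap()
    scored = [l for l in links if l.scored]
    max_abs = max((abs(l.score) for l in scored), default=0.0)
    for link in scored:
        color, width = _edge_style(link.score, max_abs, width_range)
        wavy = link.consistency_class in _WAVY_CLASSES
        style.edge_styles[link.edge.edge_id] = (color, width, wavy)
        for node in (link.edge.source, link.edge.target):
            if node in style.node_styles or not table.covers(node):
                continue
            row = table.row(node)
            style.node_styles[node] = (value_to_color(row["m_e1"], scale),
                                       value_to_color(row["m_e2"], scale))
    return style


def _hex(rgb: RGB) -> str:
    return "#{:02X}{:02X}{:02X}".format(*rgb)


def render_figure(result: CondensationResult, style: StyleMap,
                  path: str | Path, layout_seed: int = 0) -> Path:
    """Static rendering of a condensed network (matplotlib).

    Deterministic for a fixed ``layout_seed``; node halves are drawn as
    two semicircle wedges (E1 left, E2 right), wavy links dashed, with a
    legend for the color scale.  Attribute exports, not pixels, are the
    tested contract.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.lines import Line2D
    from matplotlib.patches import Wedge
    import networkx as nx

    g = nx.MultiGraph()
    g.add_nodes_from(sorted(result.retained_nodes))
    for link in result.kept:
        g.add_edge(link.edge.source, link.edge.target, edge_id=link.edge.edge_id)
    pos = nx.spring_layout(g, seed=layout_seed) if g.number_of_nodes() else {}

    fig, ax = plt.subplots(figsize=(8, 8))
    for link in result.kept:
        color, width, wavy = style.edge_styles.get(
            link.edge.edge_id, (WHITE, 1.0, False))
        (x1, y1), (x2, y2) = pos[link.edge.source], pos[link.edge.target]
        ax.plot([x1, x2], [y1, y2], color=_hex(color), linewidth=width,
                linestyle="--" if wavy else "-", zorder=1)
    radius = 0.04
    for node in sorted(result.retained_nodes):
        left, right = style.node_styles.get(node, (WHITE, WHITE))
        x, y = pos[node]
        ax.add_patch(Wedge((x, y), radius, 90, 270, facecolor=_hex(left),
                           edgecolor="black", zorder=2))
        ax.add_patch(Wedge((x, y), radius, -90, 90, facecolor=_hex(right),
                           edgecolor="black", zorder=2))
        ax.annotate(node, (x, y + radius * 1.3), ha="center", fontsize=7,
                    zorder=3)
    legend = [Line2D([0], [0], color=_hex(EDGE_RED), lw=3, label="startup"),
              Line2D([0], [0], color=_hex(EDGE_GREEN), lw=3, label="shutdown"),
              Line2D([0], [0], color="grey", lw=1.5, linestyle="--",
                     label="wavy (principle/inconsistent)")]
    ax.legend(handles=legend, loc="lower left", fontsize=8)
    ax.set_axis_off()
    ax.set_aspect("equal")
    path = Path(path)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path
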