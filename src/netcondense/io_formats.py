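"""Reading and writing networks and measurement tables.

Supported network formats are the Cytoscape-era interchange trio:

* **SIF** — one line per edge, ``source  relationship  target[ target2 ...]``
  (whitespace- or tab-delimited; lines with several targets fan out into
  one edge per target; a single-token line declares an isolated node);
* **GraphML** — read/written through :mod:`networkx`;
* **XGMML** — the Cytoscape 2.x XML dialect with ``<att>`` children on
  nodes and edges, parsed with :mod:`lxml`.

Edge types are carried in an attribute (default name ``Interactiontype``)
and normalised to the canonical interaction/stimulation/inhibition enum;
both the literal names and the SBO activity-flow terms are understood, and
the mapping can be user-extended.  Measurement tables are TSV.
"""

from __future__ import annotations

import enum
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd
from lxml import etree

from .condense import CondensationResult
from .errors import (CoverageError, FormatError, IntegrityError, ParseError,
                     SchemaError, TypingError)
from .model import (DEFAULT_TYPE_MAPPING, InteractionType, MeasurementTable,
                    TypedEdge, TypedNetwork, resolve_type)
from .scoring import ScoredLink

__all__ = [
    "read_network", "write_network", "read_measurements", "attach_measurements",
    "extract_session_networks", "MissingPolicy", "AttachmentReport",
]

TYPE_ATTRIBUTE = "Interactiontype"
XGMML_NS = "http://www.cs.rpi.edu/XGMML"

_FORMAT_BY_SUFFIX = {".sif": "sif", ".graphml": "graphml", ".xgmml": "xgmml"}


class MissingPolicy(str, enum.Enum):
    DROP_NODE = "drop_node"
    ERROR = "error"
    KEEP_UNSCORED = "keep_unscored"


@dataclass
class AttachmentReport:
    """Which network nodes lack measurements, and the policy applied."""

    uncovered: list[str] = field(default_factory=list)
    policy: MissingPolicy = MissingPolicy.KEEP_UNSCORED

    @property
    def fully_covered(self) -> bool:
        return not self.uncovered


# ---------------------------------------------------------------- reading

def read_network(path: str | Path, format: str = "auto",
                 type_attribute: str = TYPE_ATTRIBUTE,
                 type_mapping: Mapping[str, InteractionType] | None = None,
                 ) -> TypedNetwork:
    """Load a typed network from SIF, GraphML or XGMML.

    ``format="auto"`` dispatches on the file extension.  Every edge's raw
    type value is resolved through ``type_mapping`` (defaults cover the
    three literal names and the three SBO terms); an unmapped value raises
    :class:`TypingError` naming the value and edge.  Edges lacking the
    type attribute entirely are rejected rather than silently defaulted.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format == "auto":
        try:
            format = _FORMAT_BY_SUFFIX[path.suffix.lower()]
        except KeyError:
            raise FormatError(
                f"cannot infer format from suffix {path.suffix!r} of {path}")
    if format == "sif":
        net = _read_sif(path, type_mapping)
    elif format == "graphml":
        net = _read_graphml(path, type_attribute, type_mapping)
    elif format == "xgmml":
        net = _read_xgmml_file(path, type_attribute, type_mapping)
    else:
        raise FormatError(f"unknown network format {format!r}")
    net.metadata.setdefault("source_file", str(path))
    net.metadata.setdefault("format", format)
    return net


def _read_sif(path: Path, mapping: Mapping[str, InteractionType] | None) -> TypedNetwork:
    nodes: set[str] = set()
    edges: list[TypedEdge] = []
    counter = 0
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        tokens = line.split("\t") if "\t" in line else line.split()
        tokens = [t.strip() for t in tokens if t.strip()]
        if len(tokens) == 1:
            nodes.add(tokens[0])
            continue
        if len(tokens) == 2:
            raise FormatError(
                f"{path}:{lineno}: SIF line has a relationship but no target")
        source, reltype, *targets = tokens
        itype = resolve_type(reltype, mapping, context=f"{path}:{lineno}")
        nodes.add(source)
        for target in targets:
            nodes.add(target)
            counter += 1
            edges.append(TypedEdge(source, target, itype, f"e{counter}"))
    return TypedNetwork(nodes=nodes, edges=edges)


def _read_graphml(path: Path, type_attribute: str,
                  mapping: Mapping[str, InteractionType] | None) -> TypedNetwork:
    try:
        graph = nx.read_graphml(path, force_multigraph=True)
    except Exception as exc:  # networkx wraps lxml/expat errors variously
        raise FormatError(f"unparseable GraphML {path}: {exc}") from exc
    return _from_multigraph(graph, type_attribute, mapping, str(path))


def _from_multigraph(graph: "nx.MultiGraph", type_attribute: str,
                     mapping: Mapping[str, InteractionType] | None,
                     context: str) -> TypedNetwork:
    nodes = {str(n) for n in graph.nodes}
    edges: list[TypedEdge] = []
    counter = 0
    for u, v, _key, data in graph.edges(keys=True, data=True):
        raw = data.get(type_attribute)
        if raw is None:
            raise TypingError(
                f"{context}: edge {u!r}->{v!r} lacks the {type_attribute!r} attribute")
        itype = resolve_type(str(raw), mapping, context=f"{context} {u!r}->{v!r}")
        counter += 1
        edge_id = str(data.get("edge_id") or f"e{counter}")
        edges.append(TypedEdge(str(u), str(v), itype, edge_id))
    return TypedNetwork(nodes=nodes, edges=edges)


def _read_xgmml_file(path: Path, type_attribute: str,
                     mapping: Mapping[str, InteractionType] | None) -> TypedNetwork:
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"unparseable XGMML {path}: {exc}") from exc
    net, _ = _parse_xgmml_graph(tree.getroot(), type_attribute, mapping, str(path))
    return net


def _xg(tag: str) -> str:
    return f"{{{XGMML_NS}}}{tag}"


def _atts_of(element) -> dict[str, str]:
    out = {}
    for att in element:
        if etree.QName(att).localname != "att":
            continue
        name = att.get("name")
        if name is not None and att.get("value") is not None:
            out[name] = att.get("value")
    return out


def _parse_xgmml_graph(root, type_attribute: str,
                       mapping: Mapping[str, InteractionType] | None,
                       context: str) -> tuple[TypedNetwork, pd.DataFrame]:
    if etree.QName(root).localname != "graph":
        raise FormatError(f"{context}: root element is not an XGMML <graph>")
    label_by_id: dict[str, str] = {}
    node_attrs: dict[str, dict[str, str]] = {}
    nodes: set[str] = set()
    edges: list[TypedEdge] = []
    counter = 0
    for el in root:
        local = etree.QName(el).localname
        if local == "node":
            nid = el.get("id")
            label = el.get("label") or nid
            label_by_id[nid] = label
            nodes.add(label)
            atts = _atts_of(el)
            if atts:
                node_attrs[label] = atts
        elif local == "edge":
            src = label_by_id.get(el.get("source"), el.get("source"))
            tgt = label_by_id.get(el.get("target"), el.get("target"))
            atts = _atts_of(el)
            raw = atts.get(type_attribute)
            if raw is None:
                # Cytoscape encodes the relationship in "src (type) tgt" labels
                label = el.get("label") or ""
                if "(" in label and ")" in label:
                    raw = label.split("(", 1)[1].split(")", 1)[0]
            if raw is None:
                raise TypingError(
                    f"{context}: edge {src!r}->{tgt!r} lacks {type_attribute!r}")
            itype = resolve_type(raw, mapping, context=f"{context} {src!r}->{tgt!r}")
            counter += 1
            edge_id = atts.get("edge_id", f"e{counter}")
            nodes.update((src, tgt))
            edges.append(TypedEdge(src, tgt, itype, edge_id))
    net = TypedNetwork(nodes=nodes, edges=edges,
                       metadata={"name": root.get("label") or ""})
    attrs = pd.DataFrame.from_dict(node_attrs, orient="index")
    return net, attrs


# ---------------------------------------------------------------- writing

def write_network(obj: TypedNetwork | CondensationResult, path: str | Path,
                  format: str = "auto", include_attributes: bool = False,
                  table: MeasurementTable | None = None) -> Path:
    """Write a network (or the kept part of a condensation) to disk.

    Round-trip safe on (nodes, edges, types) for all three formats.  With
    ``include_attributes``, per-edge link scores / consistency classes and
    per-node measurement values (when ``table`` is given) are written as
    attributes — embedded in GraphML/XGMML, as TSV sidecars next to a SIF
    file.
    """
    path = Path(path)
    if format == "auto":
        format = _FORMAT_BY_SUFFIX.get(path.suffix.lower(), "")
        if not format:
            raise FormatError(f"cannot infer format for {path}")
    links: list[ScoredLink] | None = None
    if isinstance(obj, CondensationResult):
        links = obj.kept
        net = TypedNetwork(nodes=set(obj.retained_nodes),
                           edges=[l.edge for l in obj.kept])
    else:
        net = obj
    try:
        if format == "sif":
            _write_sif(net, path, links if include_attributes else None,
                       table if include_attributes else None)
        elif format == "graphml":
            _write_graphml(net, path, links if include_attributes else None,
                           table if include_attributes else None)
        elif format == "xgmml":
            _write_xgmml(net, path, links if include_attributes else None,
                         table if include_attributes else None)
        else:
            raise FormatError(f"unknown network format {format!r}")
    except OSError as exc:
        raise FormatError(f"cannot write {path}: {exc}") from exc
    return path


def _edge_attr_rows(links: Sequence[ScoredLink]) -> pd.DataFrame:
    return pd.DataFrame([
        {"edge_id": l.edge.edge_id, "link_score": l.score,
         "consistency_class": (l.consistency_class.value
                               if l.consistency_class else "")}
        for l in links])


def _write_sif(net: TypedNetwork, path: Path, links, table) -> None:
    lines = [f"{e.source}\t{e.interaction_type.value}\t{e.target}"
             for e in net.edges]
    connected = {n for e in net.edges for n in (e.source, e.target)}
    lines += sorted(net.nodes - connected)
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    if links is not None:
        _edge_attr_rows(links).to_csv(path.with_suffix(".edge_attrs.tsv"),
                                      sep="\t", index=False)
    if table is not None:
        covered = sorted(n for n in net.nodes if table.covers(n))
        table.data.loc[covered].to_csv(path.with_suffix(".node_attrs.tsv"),
                                       sep="\t", index_label="id")


def _write_graphml(net: TypedNetwork, path: Path, links, table) -> None:
    g = nx.MultiDiGraph()
    score_by_id = {l.edge.edge_id: l for l in links} if links else {}
    for node in sorted(net.nodes):
        attrs = {}
        if table is not None and table.covers(node):
            row = table.row(node)
            attrs["m_e1"] = float(row["m_e1"])
            attrs["m_e2"] = float(row["m_e2"])
        g.add_node(node, **attrs)
    for e in net.edges:
        attrs = {TYPE_ATTRIBUTE: e.interaction_type.value, "edge_id": e.edge_id}
        link = score_by_id.get(e.edge_id)
        if link is not None and link.scored:
            attrs["link_score"] = float(link.score)
            attrs["consistency_class"] = link.consistency_class.value
        g.add_edge(e.source, e.target, **attrs)
    nx.write_graphml(g, path)


def _write_xgmml(net: TypedNetwork, path: Path, links, table) -> None:
    root = etree.Element(_xg("graph"), nsmap={None: XGMML_NS})
    root.set("label", net.metadata.get("name", "network"))
    root.set("directed", "1")
    ids = {node: str(-(i + 1)) for i, node in enumerate(sorted(net.nodes))}
    for node in sorted(net.nodes):
        el = etree.SubElement(root, _xg("node"),
                              id=ids[node], label=node)
        if table is not None and table.covers(node):
            row = table.row(node)
            for name in ("m_e1", "m_e2"):
                etree.SubElement(el, _xg("att"), name=name, type="real",
                                 value=repr(float(row[name])))
    score_by_id = {l.edge.edge_id: l for l in links} if links else {}
    for e in net.edges:
        el = etree.SubElement(
            root, _xg("edge"), source=ids[e.source], target=ids[e.target],
            label=f"{e.source} ({e.interaction_type.value}) {e.target}")
        etree.SubElement(el, _xg("att"), name=TYPE_ATTRIBUTE, type="string",
                         value=e.interaction_type.value)
        etree.SubElement(el, _xg("att"), name="edge_id", type="string",
                         value=e.edge_id)
        link = score_by_id.get(e.edge_id)
        if link is not None and link.scored:
            etree.SubElement(el, _xg("att"), name="link_score", type="real",
                             value=repr(float(link.score)))
            etree.SubElement(el, _xg("att"), name="consistency_class",
                             type="string", value=link.consistency_class.value)
    Path(path).write_bytes(etree.tostring(root, xml_declaration=True,
                                          encoding="UTF-8", pretty_print=True))


# ------------------------------------------------------------ measurements

def read_measurements(path: str | Path, id_column: str, e1: str, e2: str,
                      var_e1: str | None = None, var_e2: str | None = None,
                      n1: int | None = None, n2: int | None = None,
                      ) -> MeasurementTable:
    """Read a per-node measurement TSV.

    ``e1``/``e2`` name the value (or mean) columns for the two conditions.
    Naming variance columns switches the table to replicate mode, which
    requires both replicate counts.  Duplicate identifiers are an error —
    mapping data onto the network relies on identifier uniqueness.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    frame = pd.read_csv(path, sep="\t")
    wanted = [id_column, e1, e2] + [c for c in (var_e1, var_e2) if c]
    missing = [c for c in wanted if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}; "
                          f"found {list(frame.columns)}")
    if (var_e1 is None) != (var_e2 is None):
        raise SchemaError("variance columns must be named for both conditions")
    ids = frame[id_column].astype(str)
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique())
        raise IntegrityError(f"{path}: duplicate identifiers {dupes}")
    rename = {e1: "m_e1", e2: "m_e2"}
    if var_e1:
        rename.update({var_e1: "var_e1", var_e2: "var_e2"})
    data = frame[list(rename)].rename(columns=rename)
    for col in data.columns:
        coerced = pd.to_numeric(data[col], errors="coerce")
        bad = data.index[coerced.isna() & data[col].notna()]
        if len(bad):
            # +2: one for the header line, one for 0-based indexing
            rows = [int(i) + 2 for i in bad]
            raise ParseError(f"{path}: non-numeric value in column mapped to "
                             f"{col!r} at line(s) {rows}")
        if coerced.isna().any():
            rows = [int(i) + 2 for i in data.index[coerced.isna()]]
            raise ParseError(f"{path}: empty value in column mapped to "
                             f"{col!r} at line(s) {rows}")
        data[col] = coerced.astype(float)
    data.index = pd.Index(ids, name="id")
    if var_e1:
        return MeasurementTable(data, n1=n1, n2=n2)
    return MeasurementTable(data)


def attach_measurements(net: TypedNetwork, table: MeasurementTable,
                        on_missing: MissingPolicy | str = MissingPolicy.KEEP_UNSCORED,
                        ) -> tuple[TypedNetwork, MeasurementTable, AttachmentReport]:
    """Reconcile a network with a measurement table.

    Policy for nodes without measurements: ``drop_node`` removes them (and
    their edges), ``error`` raises, ``keep_unscored`` (default) keeps them
    — their edges stay unscored and vanish at any positive threshold.
    """
    policy = MissingPolicy(on_missing)
    uncovered = sorted(n for n in net.nodes if not table.covers(n))
    report = AttachmentReport(uncovered=uncovered, policy=policy)
    if not uncovered:
        return net, table, report
    if policy is MissingPolicy.ERROR:
        raise CoverageError(f"nodes without measurements: {uncovered}")
    if policy is MissingPolicy.DROP_NODE:
        covered = net.nodes - set(uncovered)
        return net.restricted_to(covered), table, report
    return net, table, report


# ---------------------------------------------------------------- sessions

def extract_session_networks(path: str | Path,
                             type_attribute: str = TYPE_ATTRIBUTE,
                             type_mapping: Mapping[str, InteractionType] | None = None,
                             ) -> list[tuple[str, TypedNetwork, pd.DataFrame]]:
    """Extract every XGMML network embedded in a Cytoscape session archive.

    A session file is a zip container holding one XGMML document per
    network (plus attribute files).  Returns ``(name, network,
    node-attribute table)`` triples so supplementary sessions can be
    replayed.  Convenience only — nothing else in the library needs it.
    """
    path = Path(path)
    if not zipfile.is_zipfile(path):
        raise FormatError(f"{path} is not a zip/session archive")
    results = []
    with zipfile.ZipFile(path) as archive:
        names = [n for n in archive.namelist() if n.lower().endswith(".xgmml")]
        for name in sorted(names):
            with archive.open(name) as handle:
                try:
                    root = etree.parse(handle).getroot()
                except etree.XMLSyntaxError as exc:
                    raise FormatError(f"{path}!{name}: {exc}") from exc
            net, attrs = _parse_xgmml_graph(root, type_attribute, type_mapping,
                                            f"{path}!{name}")
            net.metadata["source_file"] = f"{path}!{name}"
            results.append((net.metadata.get("name") or name, net, attrs))
    if not results:
        raise FormatError(f"{path}: no embedded XGMML networks")
    return results
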