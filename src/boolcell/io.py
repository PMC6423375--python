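"""Readers and writers for logical-network files.

Supported input dialects:

* **GraphML** — nodes carry ``kind`` (gene|receptor|output|fate), ``action``
  (fate nodes) and ``rule`` (expression) data keys; edges carry ``sign``.
* **GXL** — the same attributes expressed as ``<attr name=...><string>``
  children of ``<node>``/``<edge>`` elements.
* **GINML** — the GINsim regulatory-graph dialect, restricted to Boolean
  models (every node ``maxvalue`` must be 1).  Logical parameters are
  converted to truth tables; node kinds are inferred (see
  :func:`_ginml_kind`).

The canonical serialization is a plain-text format, one record per line::

    node <id> kind=<kind> [action=<action>] [rule="<expression>"]
    edge <source> <target> sign=<sign>

Mutation-profile tables are delimited text with header
``clone,gene,constraint,fraction`` where constraint is ``force_active``,
``force_inactive`` or ``rule:<expression>``.
"""

from __future__ import annotations

import csv
import shlex
from pathlib import Path
from typing import Iterable

import networkx as nx
from lxml import etree

from .errors import NetworkParseError, NetworkValidationError, UnsupportedModelError
from .network import (
    Constraint,
    Edge,
    EdgeSign,
    FateAction,
    MutationProfile,
    NetworkModel,
    NodeKind,
    NodeSpec,
)
from .rules import BooleanRule

_FATE_NAME_MAP = {
    "proliferation": FateAction.PROLIFERATION,
    "apoptosis": FateAction.APOPTOSIS,
    "necrosis": FateAction.NECROSIS,
    "growth_arrest": FateAction.GROWTH_ARREST,
    "growtharrest": FateAction.GROWTH_ARREST,
    "arrest": FateAction.GROWTH_ARREST,
}


def _default_rules(nodes: list[NodeSpec]) -> list[NodeSpec]:
    """Nodes without a rule (and not receptors) default to self-maintaining."""
    out = []
    for n in nodes:
        if n.rule is None and n.kind != NodeKind.RECEPTOR:
            from dataclasses import replace

            n = replace(n, rule=BooleanRule.identity(n.id))
        out.append(n)
    return out


# ---------------------------------------------------------------------------
# format detection and dispatch


def detect_format(path: str | Path) -> str:
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise NetworkParseError(f"{path}: malformed XML: {exc}") from exc
    root = tree.getroot()
    tag = etree.QName(root).localname
    if tag == "graphml":
        return "graphml"
    if tag == "gxl":
        graph = root.find("graph")
        if graph is not None and graph.get("class") == "regulatory":
            return "ginml"
        return "gxl"
    raise NetworkParseError(f"{path}: unrecognized root element <{tag}>")


def parse_network(path: str | Path, format: str = "auto") -> NetworkModel:
    """Parse a logical-network file in GINML, GraphML or GXL dialect."""
    path = Path(path)
    if not path.exists():
        raise NetworkParseError(f"{path}: file not found")
    if format == "auto":
        format = detect_format(path)
    if format == "graphml":
        return _parse_graphml(path)
    if format == "gxl":
        return _parse_gxl(path)
    if format == "ginml":
        return _parse_ginml(path)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# GraphML


def _node_from_attrs(node_id: str, attrs: dict) -> NodeSpec:
    kind_s = attrs.get("kind", "gene")
    try:
        kind = NodeKind(kind_s)
    except ValueError as exc:
        raise NetworkParseError(
            f"node {node_id!r}: unknown kind {kind_s!r}"
        ) from exc
    action = FateAction.NONE
    if kind == NodeKind.FATE:
        action_s = attrs.get("action")
        if action_s is None:
            raise NetworkParseError(f"fate node {node_id!r} lacks an action")
        action = FateAction(action_s)
    rule = None
    if "rule" in attrs and attrs["rule"] not in (None, ""):
        rule = BooleanRule.from_expression(str(attrs["rule"]))
    return NodeSpec(id=node_id, kind=kind, fate_action=action, rule=rule)


def _parse_graphml(path: Path) -> NetworkModel:
    try:
        g = nx.read_graphml(str(path))
    except Exception as exc:  # nx wraps lxml/expat errors diversely
        raise NetworkParseError(f"{path}: not parseable as GraphML: {exc}") from exc
    if not g.is_directed():
        raise NetworkParseError(f"{path}: network GraphML must be directed")
    nodes = [_node_from_attrs(str(nid), dict(data)) for nid, data in g.nodes(data=True)]
    edges = [
        Edge(
            source=str(u),
            target=str(v),
            sign=EdgeSign(data.get("sign", "activation")),
        )
        for u, v, data in g.edges(data=True)
    ]
    try:
        return NetworkModel(nodes=_default_rules(nodes), edges=edges, name=path.stem)
    except NetworkValidationError:
        raise


def write_graphml(network: NetworkModel, path: str | Path) -> None:
    g = nx.DiGraph()
    for n in network.nodes:
        attrs = {"kind": n.kind.value}
        if n.kind == NodeKind.FATE:
            attrs["action"] = n.fate_action.value
        if n.rule is not None:
            attrs["rule"] = n.rule.to_expression()
        g.add_node(n.id, **attrs)
    for e in network.edges:
        g.add_edge(e.source, e.target, sign=e.sign.value)
    nx.write_graphml(g, str(path))


# ---------------------------------------------------------------------------
# GXL


def _gxl_attrs(elem) -> dict:
    out = {}
    for attr in elem.findall("attr"):
        name = attr.get("name")
        val_el = attr.find("string")
        if val_el is None:
            val_el = attr.find("bool")
        if name is not None and val_el is not None and val_el.text is not None:
            out[name] = val_el.text.strip()
    return out


def _parse_gxl(path: Path) -> NetworkModel:
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise NetworkParseError(f"{path}: malformed XML: {exc}") from exc
    graph = tree.getroot().find("graph")
    if graph is None:
        raise NetworkParseError(f"{path}: GXL file lacks a <graph> element")
    nodes = []
    for el in graph.findall("node"):
        node_id = el.get("id")
        if node_id is None:
            raise NetworkParseError(f"{path}: <node> without id attribute")
        nodes.append(_node_from_attrs(node_id, _gxl_attrs(el)))
    edges = []
    for el in graph.findall("edge"):
        src, dst = el.get("from"), el.get("to")
        if src is None or dst is None:
            raise NetworkParseError(f"{path}: <edge> lacks from/to attributes")
        sign = _gxl_attrs(el).get("sign", "activation")
        edges.append(Edge(source=src, target=dst, sign=EdgeSign(sign)))
    return NetworkModel(nodes=_default_rules(nodes), edges=edges, name=path.stem)


def write_gxl(network: NetworkModel, path: str | Path) -> None:
    root = etree.Element("gxl")
    graph = etree.SubElement(root, "graph", id=network.name, edgemode="directed")
    for n in network.nodes:
        el = etree.SubElement(graph, "node", id=n.id)
        attrs = {"kind": n.kind.value}
        if n.kind == NodeKind.FATE:
            attrs["action"] = n.fate_action.value
        if n.rule is not None:
            attrs["rule"] = n.rule.to_expression()
        for name, value in attrs.items():
            attr = etree.SubElement(el, "attr", name=name)
            etree.SubElement(attr, "string").text = value
    for e in network.edges:
        el = etree.SubElement(graph, "edge")
        el.set("from", e.source)
        el.set("to", e.target)
        attr = etree.SubElement(el, "attr", name="sign")
        etree.SubElement(attr, "string").text = e.sign.value
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# GINML (GINsim regulatory graphs, Boolean restriction)


def _ginml_kind(node_id: str, has_incoming: bool, has_outgoing: bool,
                is_input: bool) -> tuple[NodeKind, FateAction]:
    """GINML carries no explicit node taxonomy; infer it.

    Inputs (declared or edge-free) become receptors.  Sink nodes whose id
    names a cellular action become fate nodes; other sinks become outputs.
    Everything else is a gene.
    """
    key = node_id.lower().replace("-", "_")
    if is_input or not has_incoming:
        return NodeKind.RECEPTOR, FateAction.NONE
    if not has_outgoing:
        if key in _FATE_NAME_MAP:
            return NodeKind.FATE, _FATE_NAME_MAP[key]
        return NodeKind.OUTPUT, FateAction.NONE
    return NodeKind.GENE, FateAction.NONE


def _parse_ginml(path: Path) -> NetworkModel:
    try:
        parser = etree.XMLParser(load_dtd=False, no_network=True, resolve_entities=False)
        tree = etree.parse(str(path), parser)
    except etree.XMLSyntaxError as exc:
        raise NetworkParseError(f"{path}: malformed XML: {exc}") from exc
    graph = tree.getroot().find("graph")
    if graph is None:
        raise NetworkParseError(f"{path}: GINML file lacks a <graph> element")

    node_els = graph.findall("node")
    edge_els = graph.findall("edge")
    node_ids = []
    for el in node_els:
        nid = el.get("id")
        if nid is None:
            raise NetworkParseError(f"{path}: <node> without id attribute")
        maxval = int(el.get("maxvalue", "1"))
        if maxval > 1:
            raise UnsupportedModelError(
                f"{path}: node {nid!r} has maximum level {maxval} > 1; only "
                "Boolean models are supported"
            )
        node_ids.append(nid)
    idset = set(node_ids)

    # incoming edges per target, keeping GINML edge ids for the logical
    # parameters' idActiveInteractions references
    incoming: dict[str, list[tuple[str, str]]] = {nid: [] for nid in node_ids}
    outgoing: dict[str, bool] = {nid: False for nid in node_ids}
    edges = []
    for el in edge_els:
        src, dst = el.get("from"), el.get("to")
        eid = el.get("id") or f"{src}:{dst}"
        if src not in idset or dst not in idset:
            raise NetworkValidationError(
                f"{path}: edge {eid!r} references unknown node"
            )
        sign = EdgeSign.INHIBITION if el.get("sign") == "negative" else EdgeSign.ACTIVATION
        incoming[dst].append((eid, src))
        outgoing[src] = True
        edges.append(Edge(source=src, target=dst, sign=sign))

    nodes = []
    for el in node_els:
        nid = el.get("id")
        is_input = el.get("input", "false").lower() in ("true", "1")
        kind, action = _ginml_kind(
            nid, bool(incoming[nid]), outgoing[nid], is_input
        )
        rule = None
        if kind != NodeKind.RECEPTOR:
            rule = _ginml_rule(el, incoming[nid])
        nodes.append(NodeSpec(id=nid, kind=kind, fate_action=action, rule=rule))

    return NetworkModel(nodes=_default_rules(nodes), edges=edges, name=path.stem)


def _ginml_rule(node_el, incoming: list[tuple[str, str]]) -> BooleanRule | None:
    """Convert GINsim logical parameters to a truth table.

    A table row is 1 iff some logical parameter with target value 1 matches
    the parent assignment, where a parameter matches when its set of active
    interactions equals the set of incoming edges whose source is active.
    """
    if not incoming:
        return None
    parents = tuple(src for _, src in incoming)
    edge_ids = [eid for eid, _ in incoming]
    params = []
    for p in node_el.findall("parameter"):
        if int(p.get("val", "0")) != 1:
            continue
        active = p.get("idActiveInteractions", "")
        params.append(frozenset(active.split()) if active.strip() else frozenset())
    k = len(parents)
    table = []
    for idx in range(1 << k):
        active_edges = frozenset(
            edge_ids[j] for j in range(k) if (idx >> j) & 1
        )
        table.append(1 if active_edges in params else 0)
    return BooleanRule.from_table(parents, table)


# ---------------------------------------------------------------------------
# canonical plain-text serialization


def write_canonical(network: NetworkModel, path: str | Path) -> None:
    lines = [f"# boolcell network: {network.name}"]
    for n in network.nodes:
        parts = [f"node {n.id} kind={n.kind.value}"]
        if n.kind == NodeKind.FATE:
            parts.append(f"action={n.fate_action.value}")
        if n.rule is not None:
            expr = n.rule.to_expression()
            parts.append(f'rule="{expr}"')
        lines.append(" ".join(parts))
    for e in network.edges:
        lines.append(f"edge {e.source} {e.target} sign={e.sign.value}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_canonical(path: str | Path) -> NetworkModel:
    path = Path(path)
    nodes: list[NodeSpec] = []
    edges: list[Edge] = []
    name = path.stem
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "network:" in line:
                name = line.split("network:", 1)[1].strip()
            continue
        try:
            tokens = shlex.split(line)
        except ValueError as exc:
            raise NetworkParseError(f"{path}:{lineno}: {exc}") from exc
        record, rest = tokens[0], tokens[1:]
        if record == "node":
            if not rest:
                raise NetworkParseError(f"{path}:{lineno}: node record without id")
            node_id = rest[0]
            attrs = dict(t.split("=", 1) for t in rest[1:] if "=" in t)
            nodes.append(_node_from_attrs(node_id, attrs))
        elif record == "edge":
            if len(rest) < 2:
                raise NetworkParseError(
                    f"{path}:{lineno}: edge record needs source and target"
                )
            attrs = dict(t.split("=", 1) for t in rest[2:] if "=" in t)
            edges.append(
                Edge(
                    source=rest[0],
                    target=rest[1],
                    sign=EdgeSign(attrs.get("sign", "activation")),
                )
            )
        else:
            raise NetworkParseError(
                f"{path}:{lineno}: unknown record type {record!r}"
            )
    return NetworkModel(nodes=_default_rules(nodes), edges=edges, name=name)


# ---------------------------------------------------------------------------
# mutation profile tables


def _parse_constraint(text: str) -> Constraint:
    text = text.strip()
    if text == "force_active":
        return Constraint(locked_value=1)
    if text == "force_inactive":
        return Constraint(locked_value=0)
    if text.startswith("rule:"):
        return Constraint(rule=BooleanRule.from_expression(text[len("rule:"):]))
    raise NetworkValidationError(f"unknown constraint {text!r}")


def read_mutation_profiles(path: str | Path) -> list[MutationProfile]:
    """Read a ``clone,gene,constraint,fraction`` delimited table."""
    profiles: dict[str, MutationProfile] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"clone", "gene", "constraint", "fraction"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise NetworkParseError(
                f"{path}: mutation profile table must have header "
                "clone,gene,constraint,fraction"
            )
        for row in reader:
            label = row["clone"].strip()
            prof = profiles.setdefault(label, MutationProfile(clone_label=label))
            gene = row["gene"].strip()
            if gene:
                prof.constraints[gene] = _parse_constraint(row["constraint"])
            frac = (row.get("fraction") or "").strip()
            if frac:
                prof.initial_fraction = float(frac)
    return list(profiles.values())


def write_mutation_profiles(
    profiles: Iterable[MutationProfile], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["clone", "gene", "constraint", "fraction"])
        for p in profiles:
            if not p.constraints:
                writer.writerow([p.clone_label, "", "", p.initial_fraction])
            for i, (gene, c) in enumerate(p.constraints.items()):
                if c.locked_value is not None:
                    text = "force_active" if c.locked_value else "force_inactive"
                else:
                    text = f"rule:{c.rule.to_expression()}"
                frac = p.initial_fraction if i == 0 else ""
                writer.writerow([p.clone_label, gene, text, frac])
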