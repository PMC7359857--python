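"""Weighted signed interaction networks built from KEGG KGML pathways.

The model is a directed multigraph over genes, small-molecule compounds and
complexes. Edges carry a qualitative interaction kind (activation,
inhibition, phosphorylation, ...) and an integer influence weight; a
self-inhibition loop on every node models degradation of expression over
simulation time. Networks from several pathways are merged by node id, with
pathway provenance recorded on each edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import networkx as nx
from lxml import etree

logger = logging.getLogger(__name__)

__all__ = [
    "EdgeKind",
    "WeightScheme",
    "DEFAULT_WEIGHT_SCHEME",
    "NetworkNode",
    "InteractionEdge",
    "PathwayNetwork",
    "KGMLParseError",
    "NetworkMergeError",
    "parse_kgml",
    "merge_networks",
    "add_self_inhibition",
    "assign_weights",
    "read_network",
    "write_network",
]


class EdgeKind(str, Enum):
    """Qualitative interaction kinds, matching KGML relation subtypes."""

    ACTIVATION = "activation"
    INHIBITION = "inhibition"
    EXPRESSION = "expression"
    REPRESSION = "repression"
    PHOSPHORYLATION = "phosphorylation"
    DEPHOSPHORYLATION = "dephosphorylation"
    UBIQUITINATION = "ubiquitination"
    BINDING_ASSOCIATION = "binding_association"
    DISSOCIATION = "dissociation"
    SELF_INHIBITION = "self_inhibition"
    INDIRECT = "indirect"
    UNKNOWN = "unknown"


#: KGML relation ``subtype`` name -> EdgeKind. Unlisted subtypes map to UNKNOWN.
KGML_SUBTYPE_MAP: dict[str, EdgeKind] = {
    "activation": EdgeKind.ACTIVATION,
    "inhibition": EdgeKind.INHIBITION,
    "expression": EdgeKind.EXPRESSION,
    "repression": EdgeKind.REPRESSION,
    "phosphorylation": EdgeKind.PHOSPHORYLATION,
    "dephosphorylation": EdgeKind.DEPHOSPHORYLATION,
    "ubiquitination": EdgeKind.UBIQUITINATION,
    "binding/association": EdgeKind.BINDING_ASSOCIATION,
    "dissociation": EdgeKind.DISSOCIATION,
    "indirect effect": EdgeKind.INDIRECT,
}


@dataclass(frozen=True)
class WeightScheme:
    """Mapping from interaction kind to integer influence weight."""

    kind_to_weight: Mapping[EdgeKind, int]

    def weight_for(self, kind: EdgeKind) -> int:
        try:
            return self.kind_to_weight[kind]
        except KeyError:
            raise KeyError(
                f"edge kind {kind.value!r} is not covered by the weight scheme"
            ) from None


#: Default weights: positive influences +2, negative influences -1,
#: uninformative kinds 0. Expression/repression follow activation/inhibition.
DEFAULT_WEIGHT_SCHEME = WeightScheme(
    {
        EdgeKind.ACTIVATION: 2,
        EdgeKind.INHIBITION: -1,
        EdgeKind.EXPRESSION: 2,
        EdgeKind.REPRESSION: -1,
        EdgeKind.PHOSPHORYLATION: 2,
        EdgeKind.DEPHOSPHORYLATION: -1,
        EdgeKind.UBIQUITINATION: -1,
        EdgeKind.BINDING_ASSOCIATION: 2,
        EdgeKind.DISSOCIATION: -1,
        EdgeKind.SELF_INHIBITION: -1,
        EdgeKind.INDIRECT: 0,
        EdgeKind.UNKNOWN: 0,
    }
)


@dataclass(frozen=True)
class NetworkNode:
    id: str
    kind: str = "gene"  # gene | compound | complex
    aliases: frozenset[str] = field(default_factory=frozenset)


@dataclass(frozen=True)
class InteractionEdge:
    source: str
    target: str
    kind: EdgeKind
    weight: int
    provenance: frozenset[str] = field(default_factory=frozenset)


class KGMLParseError(ValueError):
    pass


class NetworkMergeError(ValueError):
    pass


class PathwayNetwork:
    """Directed signed multigraph of genes/compounds/complexes.

    Backed by a :class:`networkx.MultiDiGraph` whose edge keys are the
    interaction-kind labels, so (source, target, kind) is unique.
    """

    def __init__(self, name: str = "network") -> None:
        self.name = name
        self.graph = nx.MultiDiGraph(name=name)

    # -- construction -----------------------------------------------------

    def add_node(self, node_id: str, kind: str = "gene",
                 aliases: Iterable[str] = ()) -> None:
        if node_id in self.graph:
            existing = self.graph.nodes[node_id]
            if existing["kind"] != kind:
                raise NetworkMergeError(
                    f"node id {node_id!r} already present with kind "
                    f"{existing['kind']!r}, refusing to re-add as {kind!r}"
                )
            existing["aliases"] = existing["aliases"] | frozenset(aliases)
        else:
            self.graph.add_node(node_id, kind=kind, aliases=frozenset(aliases))

    def add_edge(self, source: str, target: str, kind: EdgeKind,
                 weight: int | None = None,
                 provenance: Iterable[str] = ()) -> None:
        """Add or merge an edge; duplicate (source, target, kind) edges are
        collapsed with provenance union."""
        for endpoint in (source, target):
            if endpoint not in self.graph:
                self.add_node(endpoint)
        if weight is None:
            weight = DEFAULT_WEIGHT_SCHEME.weight_for(kind)
        key = kind.value
        if self.graph.has_edge(source, target, key=key):
            data = self.graph[source][target][key]
            data["provenance"] = data["provenance"] | frozenset(provenance)
            if data["weight"] != weight:
                logger.warning(
                    "conflicting weights for edge %s-[%s]->%s (%d vs %d); "
                    "keeping %d", source, kind.value, target,
                    data["weight"], weight, data["weight"],
                )
        else:
            self.graph.add_edge(source, target, key=key, kind=kind,
                                weight=weight,
                                provenance=frozenset(provenance))

    # -- views ------------------------------------------------------------

    @property
    def nodes(self) -> list[NetworkNode]:
        return [
            NetworkNode(n, d["kind"], d["aliases"])
            for n, d in sorted(self.graph.nodes(data=True))
        ]

    @property
    def node_ids(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[InteractionEdge]:
        return sorted(
            (
                InteractionEdge(s, t, d["kind"], d["weight"], d["provenance"])
                for s, t, d in self.graph.edges(data=True)
            ),
            key=lambda e: (e.source, e.target, e.kind.value),
        )

    def node_kind(self, node_id: str) -> str:
        return self.graph.nodes[node_id]["kind"]

    def in_edges(self, node_id: str) -> list[InteractionEdge]:
        return [
            InteractionEdge(s, t, d["kind"], d["weight"], d["provenance"])
            for s, t, d in self.graph.in_edges(node_id, data=True)
        ]

    def copy(self) -> "PathwayNetwork":
        out = PathwayNetwork(self.name)
        out.graph = self.graph.copy()
        return out

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PathwayNetwork):
            return NotImplemented
        mine = {(n.id, n.kind) for n in self.nodes}
        theirs = {(n.id, n.kind) for n in other.nodes}
        if mine != theirs:
            return False
        edges_a = {(e.source, e.target, e.kind, e.weight) for e in self.edges}
        edges_b = {(e.source, e.target, e.kind, e.weight) for e in other.edges}
        return edges_a == edges_b

    def __repr__(self) -> str:
        return (f"PathwayNetwork({self.name!r}, "
                f"{self.graph.number_of_nodes()} nodes, "
                f"{self.graph.number_of_edges()} edges)")


# ---------------------------------------------------------------------------
# KGML parsing
# ---------------------------------------------------------------------------

def _entry_symbols(entry: etree._Element) -> list[str]:
    """Node symbols for a KGML entry: comma-separated graphics label tokens,
    trailing '...' dropped; falls back to the KEGG entry id."""
    graphics = entry.find("graphics")
    label = graphics.get("name") if graphics is not None else None
    if label:
        symbols = [tok.strip().rstrip(".") for tok in label.split(",")]
        symbols = [s for s in symbols if s]
        if symbols:
            return symbols
    entry_id = entry.get("id", "?")
    logger.warning("KGML entry %s has no resolvable name; using entry id",
                   entry_id)
    return [f"entry{entry_id}"]


def parse_kgml(document: str | bytes, name: str | None = None) -> PathwayNetwork:
    """Parse a KGML pathway document into a :class:`PathwayNetwork`.

    Multi-gene entries are expanded to one node per symbol, with relations
    duplicated to every member. Group entries become single complex-kind
    nodes. No self-inhibition edges are added here.
    """
    if isinstance(document, str):
        document = document.encode()
    try:
        root = etree.fromstring(document)
    except etree.XMLSyntaxError as exc:
        raise KGMLParseError(f"malformed KGML document: {exc}") from exc
    if root.tag != "pathway":
        raise KGMLParseError(
            f"expected root element <pathway>, found <{root.tag}>")

    pathway = name or root.get("name") or root.get("title") or "pathway"
    net = PathwayNetwork(pathway)

    # entry id -> list of node ids it expands to
    entry_nodes: dict[str, list[str]] = {}
    deferred_groups: list[etree._Element] = []

    for entry in root.findall("entry"):
        entry_id = entry.get("id")
        if entry_id is None:
            raise KGMLParseError("KGML <entry> element missing 'id' attribute")
        entry_type = entry.get("type", "gene")
        if entry_type == "group":
            deferred_groups.append(entry)
            continue
        kind = "compound" if entry_type == "compound" else "gene"
        aliases = frozenset((entry.get("name") or "").split())
        symbols = _entry_symbols(entry)
        for symbol in symbols:
            net.add_node(symbol, kind=kind, aliases=aliases)
        entry_nodes[entry_id] = symbols

    # groups reference member entries; resolve after all plain entries exist
    for entry in deferred_groups:
        entry_id = entry.get("id")
        members: list[str] = []
        for component in entry.findall("component"):
            ref = component.get("id")
            if ref not in entry_nodes:
                raise KGMLParseError(
                    f"group entry {entry_id} references unknown entry {ref!r}")
            members.extend(entry_nodes[ref])
        if members:
            complex_id = "+".join(sorted(set(members)))
        else:
            complex_id = f"complex{entry_id}"
        aliases = frozenset((entry.get("name") or "").split())
        net.add_node(complex_id, kind="complex", aliases=aliases)
        entry_nodes[entry_id] = [complex_id]

    for relation in root.findall("relation"):
        src_ref, dst_ref = relation.get("entry1"), relation.get("entry2")
        for ref in (src_ref, dst_ref):
            if ref not in entry_nodes:
                raise KGMLParseError(
                    f"relation references unknown entry {ref!r}")
        subtypes = relation.findall("subtype")
        kinds = (
            [KGML_SUBTYPE_MAP.get(s.get("name", ""), EdgeKind.UNKNOWN)
             for s in subtypes]
            if subtypes else [EdgeKind.UNKNOWN]
        )
        for kind in kinds:
            for src in entry_nodes[src_ref]:
                for dst in entry_nodes[dst_ref]:
                    net.add_edge(src, dst, kind, provenance=[pathway])
    return net


# ---------------------------------------------------------------------------
# Merging and augmentation
# ---------------------------------------------------------------------------

def merge_networks(parts: list[PathwayNetwork],
                   name: str = "merged") -> PathwayNetwork:
    """Union of pathway networks by node id.

    Duplicate (source, target, kind) edges collapse with provenance union;
    the same node pair may keep several edges of different kinds. A node id
    appearing with different kinds (gene vs compound) is an error.
    """
    if not parts:
        raise ValueError("merge_networks requires at least one network")
    merged = PathwayNetwork(name)
    for part in parts:
        for node in part.nodes:
            merged.add_node(node.id, node.kind, node.aliases)
        for e in part.edges:
            merged.add_edge(e.source, e.target, e.kind, e.weight, e.provenance)
    return merged


def add_self_inhibition(net: PathwayNetwork) -> PathwayNetwork:
    """Return a copy where every node carries one degradation self-loop
    (kind self_inhibition, weight -1). Idempotent."""
    out = net.copy()
    for node_id in out.node_ids:
        out.add_edge(node_id, node_id, EdgeKind.SELF_INHIBITION, weight=-1)
    return out


def assign_weights(net: PathwayNetwork,
                   scheme: WeightScheme = DEFAULT_WEIGHT_SCHEME
                   ) -> PathwayNetwork:
    """Return a copy with every edge's weight set to scheme[kind]."""
    out = net.copy()
    for _, _, data in out.graph.edges(data=True):
        data["weight"] = scheme.weight_for(data["kind"])
    return out


# ---------------------------------------------------------------------------
# Serialization: SIF and GraphML
# ---------------------------------------------------------------------------

def _write_sif(net: PathwayNetwork, path: str) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for e in net.edges:
            fh.write(f"{e.source}\t{e.kind.value}\t{e.target}\n")


def _read_sif(path: str, name: str | None = None) -> PathwayNetwork:
    net = PathwayNetwork(name or "network")
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: SIF line needs source<TAB>kind<TAB>"
                    f"target, got {line!r}")
            source, kind_label, *targets = fields
            kind = EdgeKind(kind_label)
            for target in targets:
                net.add_edge(source, target, kind)
    return net


def _write_graphml(net: PathwayNetwork, path: str) -> None:
    g = nx.MultiDiGraph(name=net.name)
    for node in net.nodes:
        g.add_node(node.id, kind=node.kind,
                   aliases="|".join(sorted(node.aliases)))
    for e in net.edges:
        g.add_edge(e.source, e.target, key=e.kind.value, kind=e.kind.value,
                   weight=e.weight,
                   provenance="|".join(sorted(e.provenance)))
    nx.write_graphml(g, path)


def _read_graphml(path: str, name: str | None = None) -> PathwayNetwork:
    g = nx.read_graphml(path, force_multigraph=True)
    net = PathwayNetwork(name or g.graph.get("name", "network"))
    for node_id, data in g.nodes(data=True):
        aliases = [a for a in data.get("aliases", "").split("|") if a]
        net.add_node(node_id, kind=data.get("kind", "gene"), aliases=aliases)
    for s, t, data in g.edges(data=True):
        kind = EdgeKind(data.get("kind", "unknown"))
        provenance = [p for p in data.get("provenance", "").split("|") if p]
        net.add_edge(s, t, kind, weight=int(data.get("weight", 0)),
                     provenance=provenance)
    return net


def write_network(net: PathwayNetwork, path: str, fmt: str = "graphml") -> None:
    """Write a network as SIF or GraphML. SIF keeps only (source, kind,
    target) triples; GraphML round-trips all attributes."""
    fmt = fmt.lower()
    if fmt == "sif":
        _write_sif(net, path)
    elif fmt == "graphml":
        _write_graphml(net, path)
    else:
        raise ValueError(f"unknown network format {fmt!r} (use 'sif' or 'graphml')")


def read_network(path: str, fmt: str | None = None,
                 name: str | None = None) -> PathwayNetwork:
    if fmt is None:
        fmt = "sif" if str(path).lower().endswith(".sif") else "graphml"
    fmt = fmt.lower()
    if fmt == "sif":
        return _read_sif(path, name)
    if fmt == "graphml":
        return _read_graphml(path, name)
    raise ValueError(f"unknown network format {fmt!r} (use 'sif' or 'graphml')")
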