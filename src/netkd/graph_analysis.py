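"""Static network analyses: signal distances and reduced subnetworks.

Signal distance is the minimum number of directed edges from a set of
signal sources (ligand nodes) to a target, ignoring edge sign and weight
and excluding degradation self-loops. Because influence propagates one edge
per synchronous step, the distance lower-bounds the first step at which a
perturbation at the sources can reach the target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import networkx as nx

from .network_model import EdgeKind, PathwayNetwork

logger = logging.getLogger(__name__)

__all__ = ["SignalDistance", "signal_distance", "reduced_network"]


@dataclass(frozen=True)
class SignalDistance:
    """Shortest directed source->target path summary.

    ``edge_count`` / ``intermediate_nodes`` / ``path`` are None when the
    target is unreachable from every source.
    """

    target: str
    edge_count: int | None
    intermediate_nodes: int | None
    path: tuple[str, ...] | None

    @property
    def reachable(self) -> bool:
        return self.edge_count is not None


def _traversal_graph(net: PathwayNetwork) -> nx.DiGraph:
    """Simple digraph of all non-self-inhibition edges, unweighted."""
    g = nx.DiGraph()
    g.add_nodes_from(net.graph.nodes)
    for e in net.edges:
        if e.kind is not EdgeKind.SELF_INHIBITION:
            g.add_edge(e.source, e.target)
    return g


def signal_distance(net: PathwayNetwork, sources: Iterable[str],
                    target: str) -> SignalDistance:
    """Multi-source shortest directed path to the target.

    Breadth-first over all sources simultaneously (distance = minimum over
    sources). One witness path is returned, ties broken by lexicographic
    node order. An unreachable target yields an explicit unreachable result
    rather than an exception.
    """
    sources = sorted(set(sources))
    if not sources:
        raise ValueError("at least one source node is required")
    missing = [n for n in [*sources, target] if n not in net.graph]
    if missing:
        raise KeyError(f"node(s) not in network: {missing}")

    g = _traversal_graph(net)
    # distance from each node TO the target, via BFS on the reverse graph
    dist_to_target = nx.single_source_shortest_path_length(g.reverse(copy=False),
                                                           target)
    reachable_sources = [s for s in sources if s in dist_to_target]
    if not reachable_sources:
        return SignalDistance(target, None, None, None)

    d = min(dist_to_target[s] for s in reachable_sources)
    # lexicographically smallest witness: greedy forward walk along nodes
    # whose remaining distance decreases by one at each hop
    current = min(s for s in reachable_sources if dist_to_target[s] == d)
    path = [current]
    remaining = d
    while remaining > 0:
        current = min(v for v in g.successors(current)
                      if dist_to_target.get(v, -1) == remaining - 1)
        path.append(current)
        remaining -= 1
    return SignalDistance(target, d, max(d - 1, 0), tuple(path))


def reduced_network(net: PathwayNetwork, seed_genes: Iterable[str],
                    name: str = "reduced") -> PathwayNetwork:
    """Induced subnetwork on the seed genes plus their direct interactors.

    Interactors are the direct predecessors and successors across
    non-degradation edges; self-loops of included nodes are preserved.
    Seeds missing from the network are logged and skipped.
    """
    seeds = sorted(set(seed_genes))
    if not seeds:
        raise ValueError("seed gene set is empty")
    present = [s for s in seeds if s in net.graph]
    for s in set(seeds) - set(present):
        logger.warning("seed gene %s not in network; skipped", s)
    if not present:
        raise ValueError("none of the seed genes are in the network")

    keep = set(present)
    for seed in present:
        keep.update(v for _, v, d in net.graph.out_edges(seed, data=True)
                    if d["kind"] is not EdgeKind.SELF_INHIBITION)
        keep.update(u for u, _, d in net.graph.in_edges(seed, data=True)
                    if d["kind"] is not EdgeKind.SELF_INHIBITION)

    out = PathwayNetwork(name)
    for node in net.nodes:
        if node.id in keep:
            out.add_node(node.id, node.kind, node.aliases)
    for e in net.edges:
        if e.source in keep and e.target in keep:
            out.add_edge(e.source, e.target, e.kind, e.weight, e.provenance)
    return out
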