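"""Topological characterization of the coalteration network.

The graph is treated as simple, undirected and unweighted (kappa colors
edges but never acts as a path weight).  Provided metrics: node degree
(pathoconnectivity hubs), edge betweenness (shortest-route load), k-core
decomposition (the maximal non-empty core is reported as the core
subnetwork), interhemispheric vs intrahemispheric edge counts, and a
region-level view that merges same-region nodes while keeping edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import networkx as nx

from .coalteration import CoalterationNetwork

logger = logging.getLogger(__name__)

EdgeKey = frozenset


def _as_graph(network) -> nx.Graph:
    if isinstance(network, CoalterationNetwork):
        return network.graph
    if isinstance(network, nx.Graph):
        return network
    raise TypeError("expected a CoalterationNetwork or networkx Graph")


def node_degree(network) -> dict[str, int]:
    """Number of edges incident to each node, sorted descending."""
    g = _as_graph(network)
    return dict(sorted(g.degree, key=lambda kv: (-kv[1], str(kv[0]))))


def edge_betweenness(network, tie_mode: str = "fractional") -> dict:
    """Edge betweenness: accumulation over connected unordered node pairs
    of shortest s-t paths traversing the edge.

    ``tie_mode="fractional"`` (default) splits ties among equal shortest
    paths, so each pair contributes a total of 1; ``tie_mode="integral"``
    counts every shortest path through the edge integrally.  Keys are
    ``frozenset({u, v})``; an edgeless graph yields an empty map.
    """
    g = _as_graph(network)
    if g.number_of_edges() == 0:
        return {}
    if tie_mode == "fractional":
        raw = nx.edge_betweenness_centrality(g, normalized=False)
        return {EdgeKey(e): v for e, v in raw.items()}
    if tie_mode != "integral":
        raise ValueError(f"unknown tie_mode {tie_mode!r}")
    out = {EdgeKey(e): 0.0 for e in g.edges}
    for s, t in combinations(g.nodes, 2):
        if not nx.has_path(g, s, t):
            continue
        for path in nx.all_shortest_paths(g, s, t):
            for u, v in zip(path[:-1], path[1:]):
                out[EdgeKey((u, v))] += 1.0
    return out


def k_core(network) -> tuple[dict[str, int], int, set[str]]:
    """Core decomposition by iterative pruning.

    Returns (core_number per node, max_k, core subnetwork node set), where
    core_number(v) is the largest k for which v survives pruning of nodes
    with degree < k, and the core subnetwork is the set of survivors at the
    maximal non-empty k.
    """
    g = _as_graph(network)
    if g.number_of_nodes() == 0:
        return {}, 0, set()
    core = nx.core_number(g)
    max_k = max(core.values())
    core_nodes = {v for v, c in core.items() if c >= max_k}
    return core, max_k, core_nodes


def hemisphere_split(network) -> tuple[int, int]:
    """(interhemispheric, intrahemispheric) edge counts.

    An edge is interhemispheric iff its endpoints carry hemisphere tags
    {L, R}; edges touching a midline-tagged node count as intrahemispheric
    (logged).  A node without a hemisphere tag is an error.
    """
    g = _as_graph(network)
    inter = intra = 0
    for u, v in g.edges:
        tags = []
        for n in (u, v):
            h = g.nodes[n].get("hemisphere")
            if h is None:
                raise ValueError(f"node {n!r} has no hemisphere tag")
            tags.append(h)
        if set(tags) == {"L", "R"}:
            inter += 1
        else:
            if "M" in tags:
                logger.info("edge (%s, %s) touches a midline node; "
                            "counted as intrahemispheric", u, v)
            intra += 1
    return inter, intra


def merge_nodes_by_region(network) -> tuple[nx.Graph, dict]:
    """Contract same-region nodes into region-level nodes.

    Multi-edges between two regions collapse to one edge keeping the
    maximum kappa (multiplicity recorded on the edge); intra-region edges
    become self-loops and are dropped (counted in the report).
    """
    g = _as_graph(network)
    merged = nx.Graph()
    for n, data in g.nodes(data=True):
        region = data.get("region", n)
        if region not in merged:
            merged.add_node(region, hemisphere=data.get("hemisphere"),
                            n_members=0)
        merged.nodes[region]["n_members"] += 1
    dropped_self_loops = 0
    for u, v, data in g.edges(data=True):
        ru = g.nodes[u].get("region", u)
        rv = g.nodes[v].get("region", v)
        if ru == rv:
            dropped_self_loops += 1
            continue
        kappa = data.get("kappa")
        if merged.has_edge(ru, rv):
            e = merged.edges[ru, rv]
            e["multiplicity"] += 1
            if kappa is not None and (e["kappa"] is None or kappa > e["kappa"]):
                e["kappa"] = kappa
        else:
            merged.add_edge(ru, rv, kappa=kappa, multiplicity=1)
    report = {"dropped_self_loops": dropped_self_loops,
              "n_regions": merged.number_of_nodes(),
              "n_region_edges": merged.number_of_edges()}
    return merged, report


@dataclass
class TopologyReport:
    """Summary of the network's topology."""

    degree: dict[str, int]
    edge_betweenness: dict
    core_number: dict[str, int]
    max_k: int
    core_subnetwork: set[str]
    inter_count: int
    intra_count: int

    def summary(self) -> dict:
        return {
            "n_nodes": len(self.degree),
            "n_edges": sum(self.degree.values()) // 2,
            "max_degree": max(self.degree.values(), default=0),
            "max_k": self.max_k,
            "core_size": len(self.core_subnetwork),
            "interhemispheric_edges": self.inter_count,
            "intrahemispheric_edges": self.intra_count,
        }


def analyze_topology(network, tie_mode: str = "fractional") -> TopologyReport:
    """Compute all topology metrics in one pass."""
    g = _as_graph(network)
    core, max_k, core_nodes = k_core(g)
    try:
        inter, intra = hemisphere_split(g)
    except ValueError:
        inter = intra = 0
    return TopologyReport(
        degree=node_degree(g),
        edge_betweenness=edge_betweenness(g, tie_mode=tie_mode),
        core_number=core, max_k=max_k, core_subnetwork=core_nodes,
        inter_count=inter, intra_count=intra)
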