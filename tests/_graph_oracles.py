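"""Brute-force graph-metric oracles, independent of the implementation."""

from itertools import combinations

import networkx as nx

from coalternet.network import EdgeKey


def brute_degree(g):
    out = {n: 0 for n in g.nodes}
    for u, v in g.edges:
        out[u] += 1
        out[v] += 1
    return out


def brute_edge_betweenness(g):
    """Exhaustive all-pairs shortest-path enumeration, fractional ties."""
    out = {EdgeKey(e): 0.0 for e in g.edges}
    for s, t in combinations(g.nodes, 2):
        if not nx.has_path(g, s, t):
            continue
        paths = list(nx.all_shortest_paths(g, s, t))
        w = 1.0 / len(paths)
        for path in paths:
            for u, v in zip(path[:-1], path[1:]):
                out[EdgeKey((u, v))] += w
    return out


def brute_core_number(g):
    """v's core number = max over vertex subsets containing v of the
    minimum induced degree."""
    nodes = list(g.nodes)
    n = len(nodes)
    best = {v: 0 for v in nodes}
    for mask in range(1, 2 ** n):
        subset = [nodes[i] for i in range(n) if mask >> i & 1]
        sub = g.subgraph(subset)
        k = min(dict(sub.degree).values())
        for v in subset:
            best[v] = max(best[v], k)
    return best
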