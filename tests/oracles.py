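"""Independent oracles used by the test suite.

Everything here is deliberately naive — brute force, direct summation,
exhaustive enumeration — and shares no code path with the implementation
it checks.
"""

from __future__ import annotations

import math
from itertools import chain, combinations, permutations

import networkx as nx


def all_digraph_edge_sets(vertices: tuple[str, ...]):
    """Every subset of ordered pairs on the given vertices (2^(k(k-1)))."""
    pairs = list(permutations(vertices, 2))
    for mask in range(1 << len(pairs)):
        yield frozenset(pairs[i] for i in range(len(pairs)) if mask >> i & 1)


def nx_weakly_connected(vertices, edges) -> bool:
    g = nx.DiGraph()
    g.add_nodes_from(vertices)
    g.add_edges_from(edges)
    return nx.is_weakly_connected(g)


def bruteforce_connected_subnetworks(labels, edges, size):
    """All connected induced size-subnetworks of one digraph, the slow way:
    every vertex subset, induced edges by membership test, connectivity via
    networkx."""
    edges = set(edges)
    found = set()
    for subset in combinations(sorted(labels), size):
        induced = frozenset(
            (u, v) for u, v in permutations(subset, 2) if (u, v) in edges
        )
        if nx_weakly_connected(subset, induced):
            found.add(induced)
    return found


def connected_3_digraphs():
    """All weakly connected digraphs on 3 fixed labeled vertices."""
    verts = ("a", "b", "c")
    return [
        es for es in all_digraph_edge_sets(verts)
        if es and nx_weakly_connected(verts, es)
    ]


def isomorphism_classes(edge_sets, vertices=("a", "b", "c")):
    """Group labeled digraphs into isomorphism classes via networkx."""
    classes: list[list[frozenset]] = []
    for es in edge_sets:
        g = nx.DiGraph()
        g.add_nodes_from(vertices)
        g.add_edges_from(es)
        for cls in classes:
            rep = nx.DiGraph()
            rep.add_nodes_from(vertices)
            rep.add_edges_from(cls[0])
            if nx.is_isomorphic(g, rep):
                cls.append(es)
                break
        else:
            classes.append([es])
    return classes


def binom_tail_direct(count: int, n: int, p: float) -> float:
    """P(X >= count) by direct summation of binomial pmf terms."""
    return sum(
        math.comb(n, i) * p**i * (1.0 - p) ** (n - i) for i in range(count, n + 1)
    )


def holm_by_hand(p_values, m):
    """Step-down Holm adjustment written independently (dict-based)."""
    indexed = sorted(enumerate(p_values), key=lambda t: t[1])
    adjusted = {}
    best = 0.0
    for rank, (idx, p) in enumerate(indexed):
        best = max(best, min(1.0, (m - rank) * p))
        adjusted[idx] = best
    return [adjusted[i] for i in range(len(p_values))]


def er_subnetwork_probability_exhaustive(key_edges, vertices, q) -> float:
    """Probability, under i.i.d. edges at density q on ``vertices``, that the
    induced subnetwork on the key's endpoint set equals the key — computed by
    summing the product measure over all 2^(k(k-1)) digraphs."""
    key_edges = frozenset(key_edges)
    subset = frozenset(chain.from_iterable(key_edges))
    within = set(permutations(sorted(subset), 2))
    pairs = list(permutations(vertices, 2))
    total = 0.0
    for es in all_digraph_edge_sets(tuple(vertices)):
        prob = 1.0
        for pair in pairs:
            prob *= q if pair in es else (1.0 - q)
        induced = frozenset(p for p in es if p in within)
        if induced == key_edges:
            total += prob
    return total
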