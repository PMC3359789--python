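"""Exhaustive enumeration of connected induced subnetworks.

For each member network every combination of ν_S vertices is examined for
the subnetwork it induces; a weakly connected induced edge set becomes a
canonical :class:`~labmotif.core.SubnetworkKey`, and occurrences are counted
across the whole sample.  Because all vertices carry distinct labels, a
given key can occur at most once per network, so census counts lie in
[1, n].

The module also knows the size of the multiple-testing family: the number
of distinct weakly connected labeled ν_S-subnetworks on ν labels,
C(ν, ν_S) · W(ν_S), where W(k) counts weakly connected digraphs on k
labeled vertices (W(2) = 3, W(3) = 54).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations, permutations
from math import comb

from .core import (
    GraphValidationError,
    LabeledDigraph,
    LabelError,
    NetworkSample,
    SubnetworkKey,
    _is_weakly_connected_edges,
)

__all__ = [
    "SubnetworkCensus",
    "induced_edges",
    "is_weakly_connected",
    "enumerate_connected_subnetworks",
    "census",
    "family_size",
    "num_weakly_connected_digraphs",
]


def induced_edges(
    network: LabeledDigraph, vertex_subset: frozenset[str] | set[str]
) -> set[tuple[str, str]]:
    """Edges of ``network`` with both endpoints inside ``vertex_subset``.

    Induced-subgraph semantics: an edge is reported iff it is present in the
    network, and absent edges inside the subset stay absent.
    """
    subset = set(vertex_subset)
    unknown = subset - set(network.labels)
    if unknown:
        raise LabelError(f"labels {sorted(unknown)!r} are not in the network")
    edges = network.edges
    return {(u, v) for u, v in permutations(subset, 2) if (u, v) in edges}


def is_weakly_connected(
    vertex_subset: frozenset[str] | set[str], edges: set[tuple[str, str]]
) -> bool:
    """True iff every vertex of the subset is reachable ignoring direction."""
    return _is_weakly_connected_edges(frozenset(vertex_subset), edges)


def _check_size(num_labels: int, size: int) -> None:
    if not 2 <= size <= num_labels:
        raise GraphValidationError(
            f"subnetwork size must lie in [2, {num_labels}], got {size}"
        )


def enumerate_connected_subnetworks(
    network: LabeledDigraph, size: int
) -> set[SubnetworkKey]:
    """All connected induced ``size``-subnetworks of one network.

    Examines every one of the C(ν, ν_S) vertex subsets (lexicographic label
    order) and emits a key whenever the induced edge set is weakly
    connected.  Distinct subsets yield distinct keys, so the result size is
    at most C(ν, ν_S).
    """
    _check_size(network.num_vertices, size)
    edges = network.edges
    keys: set[SubnetworkKey] = set()
    for subset in combinations(network.labels, size):
        induced = [
            (u, v) for u, v in permutations(subset, 2) if (u, v) in edges
        ]
        if _is_weakly_connected_edges(frozenset(subset), induced):
            keys.add(SubnetworkKey(edges=tuple(sorted(induced))))
    return keys


@dataclass(frozen=True)
class SubnetworkCensus:
    """Occurrence counts of every observed ν_S-subnetwork over a sample."""

    size: int
    counts: dict[SubnetworkKey, int]
    n: int

    def total(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.counts)


def census(sample: NetworkSample, size: int) -> SubnetworkCensus:
    """Count each distinct connected induced subnetwork across the sample.

    ``counts[key]`` is the number of sample members that contain ``key``;
    keys occurring in no member are absent from the map.
    """
    _check_size(sample.num_labels, size)
    counter: Counter[SubnetworkKey] = Counter()
    for network in sample:
        counter.update(enumerate_connected_subnetworks(network, size))
    return SubnetworkCensus(size=size, counts=dict(counter), n=sample.n)


@lru_cache(maxsize=None)
def _weak_count_bruteforce(k: int) -> int:
    """W(k) by exhaustive generation of all 2^{k(k-1)} labeled digraphs."""
    verts = frozenset(str(i) for i in range(k))
    pairs = list(permutations(sorted(verts), 2))
    total = 0
    for mask in range(1 << len(pairs)):
        edges = [pairs[i] for i in range(len(pairs)) if mask >> i & 1]
        if _is_weakly_connected_edges(verts, edges):
            total += 1
    return total


@lru_cache(maxsize=None)
def _weak_count_recurrence(k: int) -> int:
    """W(k) by the standard inclusion–exclusion over the component of one
    distinguished vertex:  W(k) = D(k) − Σ_{j<k} C(k−1, j−1) W(j) D(k−j),
    with D(m) = 2^{m(m−1)} the number of all digraphs on m labeled vertices.
    """
    if k == 1:
        return 1
    def d(m: int) -> int:
        return 1 << (m * (m - 1))
    return d(k) - sum(
        comb(k - 1, j - 1) * _weak_count_recurrence(j) * d(k - j)
        for j in range(1, k)
    )


def num_weakly_connected_digraphs(size: int, *, method: str = "auto") -> int:
    """W(size): weakly connected digraphs on ``size`` labeled vertices.

    ``method`` selects ``"bruteforce"`` (feasible for size ≤ 4),
    ``"recurrence"``, or ``"auto"`` (bruteforce up to 4, recurrence beyond);
    the two routes are cross-checked in the test suite.
    """
    if size < 1:
        raise GraphValidationError(f"size must be positive, got {size}")
    if method == "auto":
        method = "bruteforce" if size <= 4 else "recurrence"
    if method == "bruteforce":
        if size > 4:
            raise GraphValidationError("bruteforce W(k) is limited to k <= 4")
        return _weak_count_bruteforce(size)
    if method == "recurrence":
        return _weak_count_recurrence(size)
    raise ValueError(f"unknown method {method!r}")


def family_size(num_labels: int, size: int) -> int:
    """Number of distinct connected labeled ν_S-subnetworks on ν labels.

    This is the multiple-testing family when "all subnetworks of size ν_S"
    are tested: C(ν, ν_S) vertex subsets times W(ν_S) connected patterns
    per subset (e.g. 36 · 3 = 108 for pairs on 9 labels, 84 · 54 = 4536
    for triples).
    """
    _check_size(num_labels, size)
    return comb(num_labels, size) * num_weakly_connected_digraphs(size)
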