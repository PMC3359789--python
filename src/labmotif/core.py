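"""Domain types for labeled directed networks and their subnetworks.

The central objects are samples of simple directed graphs that all share one
set of pairwise-different vertex labels (for instance the nine EEG electrodes
F3, Fz, F4, C3, Cz, C4, P3, Pz, P4 of an effective-connectivity study).
Because every vertex carries a unique label, two subnetworks are identical
exactly when they have the same set of labeled edges — isomorphism never
enters. All downstream machinery (enumeration, null model, significance)
builds on the types defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "EDGE_SEP",
    "EDGE_JOIN",
    "GraphValidationError",
    "LoopError",
    "LabelError",
    "ShapeError",
    "MotifKeyError",
    "SubnetworkKey",
    "LabeledDigraph",
    "NetworkSample",
    "MotifTestResult",
    "validate_network",
    "make_key",
]

#: separator between tail and head inside one serialized edge ("F3>Fz")
EDGE_SEP = ">"
#: separator between edges inside one serialized key ("F3>Fz;Fz>F3")
EDGE_JOIN = ";"


class GraphValidationError(ValueError):
    """A network or subnetwork violates a structural invariant."""


class LoopError(GraphValidationError):
    """A self-loop (edge whose tail and head coincide) was supplied."""


class LabelError(GraphValidationError):
    """Vertex labels are duplicated, unknown, or malformed."""


class ShapeError(GraphValidationError):
    """An adjacency matrix has the wrong shape or non-binary entries."""


class MotifKeyError(GraphValidationError):
    """An edge set cannot form a canonical subnetwork key."""


def _check_labels(labels: Sequence[str]) -> tuple[str, ...]:
    labels = tuple(str(lab) for lab in labels)
    if len(labels) == 0:
        raise LabelError("label set must be nonempty")
    if len(set(labels)) != len(labels):
        raise LabelError(f"duplicate vertex labels in {labels!r}")
    for lab in labels:
        if EDGE_SEP in lab or EDGE_JOIN in lab:
            raise LabelError(
                f"label {lab!r} contains reserved character "
                f"{EDGE_SEP!r} or {EDGE_JOIN!r}"
            )
        if lab == "" or lab != lab.strip():
            raise LabelError(f"label {lab!r} is empty or has surrounding whitespace")
    return labels


def _is_weakly_connected_edges(
    vertices: frozenset[str], edges: Iterable[tuple[str, str]]
) -> bool:
    """BFS on the underlying undirected graph restricted to ``vertices``."""
    if not vertices:
        return False
    neighbours: dict[str, set[str]] = {v: set() for v in vertices}
    for u, v in edges:
        neighbours[u].add(v)
        neighbours[v].add(u)
    start = next(iter(vertices))
    seen = {start}
    stack = [start]
    while stack:
        for w in neighbours[stack.pop()]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return len(seen) == len(vertices)


@dataclass(frozen=True)
class SubnetworkKey:
    """Canonical identity of one labeled connected subnetwork.

    A candidate motif S is a weakly connected set of directed labeled edges;
    two subnetworks are identical iff they share the same edge set.  The key
    stores the edges sorted lexicographically by (tail, head), which makes
    equality, hashing and serialization deterministic.

    Attributes
    ----------
    edges:
        Canonically ordered tuple of ``(tail, head)`` label pairs.
    """

    edges: tuple[tuple[str, str], ...]

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "SubnetworkKey":
        """Build a key from an edge set, validating connectivity."""
        canon = tuple(sorted({(str(u), str(v)) for u, v in edges}))
        if not canon:
            raise MotifKeyError("a subnetwork key needs at least one edge")
        verts = set()
        for u, v in canon:
            if u == v:
                raise LoopError(f"self-loop {u!r}->{v!r} in key edges")
            verts.add(u)
            verts.add(v)
        _check_labels(sorted(verts))
        if not _is_weakly_connected_edges(frozenset(verts), canon):
            raise MotifKeyError(
                f"edge set {canon!r} is not weakly connected; "
                "only connected subnetworks form keys"
            )
        return cls(edges=canon)

    @classmethod
    def from_string(cls, key_string: str) -> "SubnetworkKey":
        """Parse a serialized key such as ``"C3>Cz;Cz>C3"``."""
        parts = [p for p in key_string.strip().split(EDGE_JOIN) if p]
        edges = []
        for part in parts:
            ends = part.split(EDGE_SEP)
            if len(ends) != 2:
                raise MotifKeyError(f"malformed edge {part!r} in key {key_string!r}")
            edges.append((ends[0].strip(), ends[1].strip()))
        return cls.from_edges(edges)

    @property
    def vertex_set(self) -> frozenset[str]:
        return frozenset(v for e in self.edges for v in e)

    @property
    def size(self) -> int:
        """Number of vertices ν_S spanned by the edge set."""
        return len(self.vertex_set)

    @property
    def eta(self) -> int:
        """Number of edges η_S."""
        return len(self.edges)

    @property
    def eta_max(self) -> int:
        """Maximum possible edge count ν_S(ν_S − 1)."""
        return self.size * (self.size - 1)

    @property
    def key_string(self) -> str:
        return EDGE_JOIN.join(f"{u}{EDGE_SEP}{v}" for u, v in self.edges)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.key_string


def make_key(edges: Iterable[tuple[str, str]]) -> SubnetworkKey:
    """Canonical key for a weakly connected labeled edge set.

    Raises :class:`MotifKeyError` on an empty or disconnected edge set.
    """
    return SubnetworkKey.from_edges(edges)


@dataclass(frozen=True)
class LabeledDigraph:
    """One sample member: a simple directed graph on labeled vertices.

    Vertex identity is the label string; internally labels are normalized to
    sorted order so that graphs read from differently ordered input files
    compare equal.  No self-loops and no multi-edges (a mutual connection
    u↔v is simply the two edges (u, v) and (v, u)).
    """

    labels: tuple[str, ...]
    edges: frozenset[tuple[str, str]]

    def __init__(self, labels: Sequence[str], edges: Iterable[tuple[str, str]]):
        labels = tuple(sorted(_check_labels(labels)))
        labset = set(labels)
        eset = set()
        for u, v in edges:
            u, v = str(u), str(v)
            if u == v:
                raise LoopError(f"self-loop on vertex {u!r}")
            if u not in labset or v not in labset:
                raise LabelError(f"edge ({u!r}, {v!r}) uses labels outside {labels!r}")
            eset.add((u, v))
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "edges", frozenset(eset))

    @property
    def num_vertices(self) -> int:
        return len(self.labels)

    @property
    def edge_count(self) -> int:
        """Number of edges k_i; satisfies 0 ≤ k_i ≤ ν(ν−1)."""
        return len(self.edges)

    @property
    def adjacency(self) -> np.ndarray:
        """ν×ν binary matrix in sorted label order; A[i, j] = 1 ⇔ u_i → u_j."""
        index = {lab: i for i, lab in enumerate(self.labels)}
        mat = np.zeros((len(self.labels), len(self.labels)), dtype=np.int8)
        for u, v in self.edges:
            mat[index[u], index[v]] = 1
        return mat

    def has_edge(self, tail: str, head: str) -> bool:
        return (tail, head) in self.edges


def validate_network(
    labels: Sequence[str], adjacency: np.ndarray | Sequence[Sequence[int]]
) -> LabeledDigraph:
    """Validate an adjacency matrix and return the corresponding digraph.

    ``adjacency[i, j] == 1`` encodes the directed edge labels[i] → labels[j]
    (row = tail, column = head).  The diagonal must be zero — loops are
    structurally forbidden — and all entries must be 0 or 1.  Asymmetry is
    *not* required: a symmetric pair of ones encodes a mutual edge.
    """
    labels = _check_labels(labels)
    mat = np.asarray(adjacency)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ShapeError(f"adjacency must be square, got shape {mat.shape}")
    if mat.shape[0] != len(labels):
        raise ShapeError(
            f"{len(labels)} labels but adjacency is {mat.shape[0]}x{mat.shape[1]}"
        )
    if not np.isin(mat, (0, 1)).all():
        raise ShapeError("adjacency entries must all be 0 or 1")
    if np.any(np.diagonal(mat) != 0):
        raise LoopError("nonzero diagonal: self-loops are not allowed")
    edges = [
        (labels[i], labels[j])
        for i, j in zip(*np.nonzero(mat))
    ]
    return LabeledDigraph(labels, edges)


@dataclass(frozen=True)
class NetworkSample:
    """A sample (𝒩_1, …, 𝒩_n) of digraphs over one shared label set."""

    networks: tuple[LabeledDigraph, ...]
    labels: tuple[str, ...] = field(default=())

    def __init__(self, networks: Sequence[LabeledDigraph]):
        networks = tuple(networks)
        if len(networks) == 0:
            raise GraphValidationError("a sample needs at least one network")
        labels = networks[0].labels
        for i, net in enumerate(networks):
            if net.labels != labels:
                raise LabelError(
                    f"network {i} has label set {net.labels!r}, expected {labels!r}"
                )
        object.__setattr__(self, "networks", networks)
        object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        return len(self.networks)

    @property
    def num_labels(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.networks)

    def __len__(self) -> int:
        return len(self.networks)

    def mean_edge_count(self) -> float:
        return float(np.mean([g.edge_count for g in self.networks]))

    def label_subsets(self, size: int) -> Iterable[tuple[str, ...]]:
        """All C(ν, size) vertex subsets in lexicographic label order."""
        return combinations(self.labels, size)


@dataclass(frozen=True)
class MotifTestResult:
    """Significance assessment of one candidate subnetwork.

    ``count`` is the number of sample members containing the key as induced
    subnetwork (Σ X_i); ``p_null`` the per-network occurrence probability
    under the i.i.d.-edge null; ``p_value`` the exact binomial upper tail
    P(X ≥ count); ``p_holm`` the Holm step-down adjusted p-value.  The
    ``log10_*`` companions are computed in log space so that extreme
    p-values survive reporting without underflowing to zero.
    """

    key: SubnetworkKey
    count: int
    n: int
    p_null: float
    p_value: float
    p_holm: float
    is_motif: bool
    log10_p_value: float = float("nan")
    log10_p_holm: float = float("nan")

    @property
    def mean_count(self) -> float:
        """count / n — the per-sample mean occurrence reported for motifs."""
        return self.count / self.n

    def __post_init__(self) -> None:
        if not (0 <= self.count <= self.n):
            raise GraphValidationError(
                f"count {self.count} outside [0, {self.n}]"
            )
        if not (0.0 <= self.p_null <= 1.0):
            raise GraphValidationError(f"p_null {self.p_null} outside [0, 1]")
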