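"""Synthetic network samples with the statistical structure the method assumes.

Three generators are provided: pure i.i.d.-edge null samples, samples
dimensioned like the EEG effective-connectivity study (nine electrode-labeled
vertices, sixteen networks, edge density 36.79/72 ≈ 0.511), and samples with
a specific labeled subnetwork planted at a chosen penetrance for power and
recovery experiments.  All generators are pure functions of their
configuration and seed: a single root seed deterministically derives one
substream per network, so changing n never reshuffles the other members.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Optional, Sequence

import numpy as np

from .core import (
    GraphValidationError,
    LabeledDigraph,
    LabelError,
    NetworkSample,
    SubnetworkKey,
    _check_labels,
)

__all__ = [
    "ELECTRODE_LABELS",
    "ECN_EDGE_DENSITY",
    "GeneratorConfig",
    "generate_null_sample",
    "plant_subnetwork",
    "generate_ecn_like_sample",
]

#: the nine EEG electrodes of the motivating study, frontal to parietal
ELECTRODE_LABELS = ("F3", "Fz", "F4", "C3", "Cz", "C4", "P3", "Pz", "P4")

#: mean edge density of the study's effective-connectivity networks
#: (mean 36.79 of 72 possible directed edges among 9 electrodes)
ECN_EDGE_DENSITY = 36.79 / 72.0


def default_labels(num_labels: int) -> tuple[str, ...]:
    """Electrode labels for ν = 9, generic v1..vν otherwise."""
    if num_labels == 9:
        return ELECTRODE_LABELS
    return tuple(f"v{i}" for i in range(1, num_labels + 1))


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of one synthetic sample.

    Defaults mirror the study conditions: ν = 9 electrode labels, n = 16
    networks, edge probability q = 36.79/72.  ``plant`` optionally names a
    subnetwork key and a penetrance in [0, 1] with which the key is forced
    into each member.
    """

    num_labels: int = 9
    n: int = 16
    q: float = ECN_EDGE_DENSITY
    seed: int = 0
    labels: Optional[Sequence[str]] = None
    plant: Optional[tuple[SubnetworkKey, float]] = None

    def resolved_labels(self) -> tuple[str, ...]:
        labels = (
            tuple(self.labels) if self.labels is not None
            else default_labels(self.num_labels)
        )
        labels = _check_labels(labels)
        if len(labels) != self.num_labels:
            raise LabelError(
                f"{self.num_labels} labels expected, got {len(labels)}"
            )
        return labels

    def __post_init__(self) -> None:
        if self.num_labels < 2:
            raise GraphValidationError("need at least 2 vertices")
        if self.n < 1:
            raise GraphValidationError("sample size must be >= 1")
        if not 0.0 <= self.q <= 1.0:
            raise GraphValidationError(f"q={self.q} outside [0, 1]")
        self.resolved_labels()
        if self.plant is not None:
            key, penetrance = self.plant
            if not 0.0 <= penetrance <= 1.0:
                raise GraphValidationError(
                    f"penetrance {penetrance} outside [0, 1]"
                )
            if not key.vertex_set <= set(self.resolved_labels()):
                raise LabelError(
                    f"planted key {key.key_string!r} uses labels outside "
                    f"{self.resolved_labels()!r}"
                )


def _network_rng(seed: int, index: int, stream: int = 0) -> np.random.Generator:
    # spawn_key keyed by (stream, index): per-network substream independent of n
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(stream, index))
    )


def _draw_null_network(
    labels: tuple[str, ...], q: float, rng: np.random.Generator
) -> LabeledDigraph:
    pairs = list(permutations(labels, 2))
    present = rng.random(len(pairs)) < q
    edges = [p for p, keep in zip(pairs, present) if keep]
    return LabeledDigraph(labels, edges)


def generate_null_sample(config: GeneratorConfig) -> NetworkSample:
    """Draw n networks with every ordered pair present independently w.p. q.

    If ``config.plant`` is set, the planted key is subsequently forced in
    via :func:`plant_subnetwork` (using a separate substream of the same
    root seed).
    """
    labels = config.resolved_labels()
    networks = [
        _draw_null_network(labels, config.q, _network_rng(config.seed, i))
        for i in range(config.n)
    ]
    sample = NetworkSample(networks)
    if config.plant is not None:
        key, penetrance = config.plant
        sample = plant_subnetwork(sample, key, penetrance, seed=config.seed)
    return sample


def plant_subnetwork(
    sample: NetworkSample,
    key: SubnetworkKey,
    penetrance: float,
    seed: int,
) -> NetworkSample:
    """Force ``key`` into each member independently with prob. ``penetrance``.

    Planting makes the *induced* subnetwork on the key's vertex set equal
    the key exactly: the key's edges are added and every other ordered pair
    inside its vertex set is removed (counting is by induced subnetwork, so
    forcing only the presence of edges would yield a different pattern
    whenever background edges land inside the subset).  Edges outside the
    key's vertex set are untouched.
    """
    if not 0.0 <= penetrance <= 1.0:
        raise GraphValidationError(f"penetrance {penetrance} outside [0, 1]")
    if not key.vertex_set <= set(sample.labels):
        raise LabelError(
            f"key {key.key_string!r} uses labels outside the sample's "
            f"label set {sample.labels!r}"
        )
    subset = key.vertex_set
    within = set(permutations(sorted(subset), 2))
    key_edges = set(key.edges)
    networks = []
    for i, network in enumerate(sample):
        rng = _network_rng(seed, i, stream=1)
        if rng.random() < penetrance:
            edges = (set(network.edges) - within) | key_edges
            networks.append(LabeledDigraph(sample.labels, edges))
        else:
            networks.append(network)
    return NetworkSample(networks)


def generate_ecn_like_sample(
    group_seed: int = 0,
    n: int = 16,
    plant: Optional[tuple[SubnetworkKey, float]] = None,
) -> NetworkSample:
    """Sample dimensioned like one group of the EEG study.

    Nine electrode-labeled vertices, n = 16 networks (15 in one of the
    study's eight groups), i.i.d. edges at density 36.79/72.
    """
    config = GeneratorConfig(
        num_labels=9, n=n, q=ECN_EDGE_DENSITY, seed=group_seed, plant=plant
    )
    return generate_null_sample(config)
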