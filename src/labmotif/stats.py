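"""Analytic null model and significance machinery.

The null model treats every ordered vertex pair as an independent Bernoulli
edge with probability q, the normalized mean edge count of the sample:

    q = (1 / (n ν(ν−1))) Σ_i k_i.

Under this model a fixed subnetwork S with η_S edges on ν_S vertices occurs
as induced subnetwork of a random network with probability

    P(X_i = 1) = q^{η_S} (1 − q)^{η_Smax − η_S},    η_Smax = ν_S(ν_S − 1),

and its count over the n-member sample is Binomial(n, P(X_i = 1)).  Each
observed subnetwork is tested one-sided for overrepresentation with the
exact binomial upper tail, and the family of tests is controlled at
familywise level α by the Holm step-down correction.  No random-network
ensembles are simulated anywhere — the test is fully analytic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln, logsumexp

from .core import (
    GraphValidationError,
    MotifTestResult,
    NetworkSample,
    SubnetworkKey,
)
from .enumeration import census, family_size

__all__ = [
    "NullModel",
    "MotifTable",
    "ConsistencyError",
    "fit_null",
    "occurrence_probability",
    "binomial_upper_tail",
    "log10_binomial_upper_tail",
    "holm_adjust",
    "detect_motifs",
]

FAMILY_MODES = ("all-possible", "observed-only")


class ConsistencyError(GraphValidationError):
    """Observed counts are impossible under the fitted null density."""


@dataclass(frozen=True)
class NullModel:
    """I.i.d.-edge (Erdős–Rényi) null for a sample of labeled digraphs.

    ``q`` is the edge probability; the expected edge count of a null
    network is q·ν(ν−1).
    """

    q: float
    num_labels: int
    n: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.q <= 1.0:
            raise GraphValidationError(f"q={self.q} outside [0, 1]")

    @property
    def mean_edges(self) -> float:
        return self.q * self.num_labels * (self.num_labels - 1)


@dataclass(frozen=True)
class MotifTable:
    """Full result of a motif scan, ordered by ascending p-value."""

    results: tuple[MotifTestResult, ...]
    alpha: float
    family: int
    family_mode: str
    q: float
    n: int
    num_labels: int
    size: int

    @property
    def motifs(self) -> tuple[MotifTestResult, ...]:
        return tuple(r for r in self.results if r.is_motif)

    def __len__(self) -> int:
        return len(self.results)

    def __iter__(self):
        return iter(self.results)


def fit_null(sample: NetworkSample) -> NullModel:
    """Estimate q as the sample's normalized mean number of edges."""
    nu = sample.num_labels
    if nu < 2:
        raise GraphValidationError("need at least two vertices to define q")
    total = sum(g.edge_count for g in sample)
    q = total / (sample.n * nu * (nu - 1))
    return NullModel(q=q, num_labels=nu, n=sample.n)


def occurrence_probability(key: SubnetworkKey, null: NullModel) -> float:
    """P(X_i = 1) = q^{η_S} (1 − q)^{η_Smax − η_S} for one subnetwork.

    Evaluated in log space for q strictly inside (0, 1); the edge cases use
    the convention 0^0 = 1.
    """
    q = null.q
    eta, zeros = key.eta, key.eta_max - key.eta
    if q == 0.0:
        return 1.0 if eta == 0 else 0.0
    if q == 1.0:
        return 1.0 if zeros == 0 else 0.0
    return math.exp(eta * math.log(q) + zeros * math.log1p(-q))


def _binom_logpmf(i: np.ndarray, n: int, p: float) -> np.ndarray:
    return (
        gammaln(n + 1)
        - gammaln(i + 1)
        - gammaln(n - i + 1)
        + i * math.log(p)
        + (n - i) * math.log1p(-p)
    )


def binomial_upper_tail(count: int, n: int, p: float) -> float:
    """Exact P(X ≥ count) for X ~ Binomial(n, p).

    Uses the regularized-incomplete-beta survival function, not a normal
    approximation; ``count = 0`` returns 1 exactly.
    """
    if not 0 <= count <= n:
        raise GraphValidationError(f"count {count} outside [0, {n}]")
    if not 0.0 <= p <= 1.0:
        raise GraphValidationError(f"p={p} outside [0, 1]")
    if count == 0:
        return 1.0
    return float(sps.binom.sf(count - 1, n, p))


def log10_binomial_upper_tail(count: int, n: int, p: float) -> float:
    """log10 P(X ≥ count), by log-space summation of the pmf terms.

    Keeps extreme tails representable (reported in scientific notation)
    where the plain survival function would underflow to zero.
    """
    if not 0 <= count <= n:
        raise GraphValidationError(f"count {count} outside [0, {n}]")
    if count == 0:
        return 0.0
    if p == 0.0:
        return -math.inf
    if p == 1.0:
        return 0.0
    i = np.arange(count, n + 1, dtype=float)
    return float(logsumexp(_binom_logpmf(i, n, p))) / math.log(10.0)


def holm_adjust(p_values: Sequence[float], family: int) -> np.ndarray:
    """Holm step-down adjusted p-values with family size ``family``.

    Sorting the raw p-values ascending, the k-th adjusted value is
    max_{j ≤ k} min(1, (m − j + 1) p_(j)); rejections at level α are those
    with adjusted p ≤ α.  ``family`` may exceed the number of supplied
    p-values: hypotheses in the family but not supplied behave as p = 1
    (never rejected) while still inflating the multipliers.  The result is
    returned in the input order.
    """
    p = np.asarray(p_values, dtype=float)
    m = int(family)
    if m < p.size:
        raise GraphValidationError(
            f"family size {m} smaller than number of p-values {p.size}"
        )
    if p.size and (p.min() < 0.0 or p.max() > 1.0):
        raise GraphValidationError("p-values must lie in [0, 1]")
    order = np.argsort(p, kind="stable")
    adjusted = np.empty_like(p)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, (m - rank) * p[idx]))
        adjusted[idx] = running
    return adjusted


def _holm_adjust_log10(log10_p: np.ndarray, family: int) -> np.ndarray:
    """Holm adjustment on the log10 scale (same step-down, capped at 0)."""
    m = int(family)
    order = np.argsort(log10_p, kind="stable")
    adjusted = np.empty_like(log10_p)
    running = -math.inf
    for rank, idx in enumerate(order):
        running = max(running, min(0.0, math.log10(m - rank) + log10_p[idx]))
        adjusted[idx] = running
    return adjusted


def detect_motifs(
    sample: NetworkSample,
    size: int,
    alpha: float = 0.05,
    family_mode: str = "all-possible",
) -> MotifTable:
    """End-to-end motif scan for subnetworks of ``size`` vertices.

    Pipeline: subnetwork census → fit q → per-key occurrence probability →
    exact binomial upper tail → Holm correction → rejection at multiple
    level ``alpha``.  With ``family_mode="all-possible"`` (default, the
    conservative reading of testing *all* size-ν_S subnetworks) the Holm
    family is C(ν, ν_S)·W(ν_S); ``"observed-only"`` restricts the family to
    the keys actually observed, for sensitivity analysis.

    Results are sorted by ascending p-value, ties broken by canonical key
    string.
    """
    if not 0.0 < alpha < 1.0:
        raise GraphValidationError(f"alpha={alpha} outside (0, 1)")
    if family_mode not in FAMILY_MODES:
        raise GraphValidationError(
            f"family_mode must be one of {FAMILY_MODES}, got {family_mode!r}"
        )
    cens = census(sample, size)
    null = fit_null(sample)
    if null.q == 0.0 and len(cens) > 0:
        raise ConsistencyError("q = 0 but the census is nonempty")

    keys = sorted(cens.counts, key=lambda k: k.key_string)
    counts = np.array([cens.counts[k] for k in keys], dtype=int)
    p_null = np.array([occurrence_probability(k, null) for k in keys])
    bad = (p_null == 0.0) & (counts > 0)
    if bad.any():
        raise ConsistencyError(
            "observed subnetworks have zero occurrence probability under "
            "the fitted null (inconsistent input)"
        )
    p_value = np.array(
        [binomial_upper_tail(c, sample.n, p) for c, p in zip(counts, p_null)]
    )
    log10_p = np.array(
        [log10_binomial_upper_tail(c, sample.n, p) for c, p in zip(counts, p_null)]
    )
    m = family_size(sample.num_labels, size) if family_mode == "all-possible" else len(keys)
    if len(keys):
        p_holm = holm_adjust(p_value, m)
        log10_holm = _holm_adjust_log10(log10_p, m)
    else:
        p_holm = np.empty(0)
        log10_holm = np.empty(0)

    results = [
        MotifTestResult(
            key=k,
            count=int(c),
            n=sample.n,
            p_null=float(pn),
            p_value=float(pv),
            p_holm=float(ph),
            is_motif=bool(ph <= alpha),
            log10_p_value=float(lpv),
            log10_p_holm=float(lph),
        )
        for k, c, pn, pv, ph, lpv, lph in zip(
            keys, counts, p_null, p_value, p_holm, log10_p, log10_holm
        )
    ]
    results.sort(key=lambda r: (r.log10_p_value, r.key.key_string))
    return MotifTable(
        results=tuple(results),
        alpha=alpha,
        family=m,
        family_mode=family_mode,
        q=null.q,
        n=sample.n,
        num_labels=sample.num_labels,
        size=size,
    )
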