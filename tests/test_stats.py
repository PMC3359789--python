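"""Null model, exact binomial test, Holm correction, end-to-end detection."""

import math
from itertools import permutations

import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

from labmotif import (
    GraphValidationError,
    LabeledDigraph,
    NetworkSample,
    NullModel,
    SubnetworkKey,
    binomial_upper_tail,
    detect_motifs,
    fit_null,
    holm_adjust,
    log10_binomial_upper_tail,
    make_key,
    occurrence_probability,
)
from labmotif.simulate import ELECTRODE_LABELS

from oracles import (
    binom_tail_direct,
    connected_3_digraphs,
    er_subnetwork_probability_exhaustive,
    holm_by_hand,
)


def _er_network(labels, q, rng):
    pairs = list(permutations(labels, 2))
    return LabeledDigraph(labels, [p for p in pairs if rng.random() < q])


class TestFitNull:
    def test_half_density(self, electrodes):
        rng = np.random.default_rng(0)
        net = LabeledDigraph(
            electrodes,
            list(map(tuple, rng.permutation(list(permutations(electrodes, 2)))[:36])),
        )
        assert fit_null(NetworkSample([net])).q == 0.5

    def test_study_density(self, electrodes):
        # edge counts averaging 36.79 per network, e.g. alternating 36/37/37/37...
        counts = [37] * 79 + [36] * 21  # mean 36.79 over 100 networks
        rng = np.random.default_rng(1)
        pairs = list(permutations(electrodes, 2))
        nets = [
            LabeledDigraph(
                electrodes, list(map(tuple, rng.permutation(pairs)[:k]))
            )
            for k in counts
        ]
        q = fit_null(NetworkSample(nets)).q
        assert q == pytest.approx(36.79 / 72, rel=1e-12)

    def test_empty_sample_of_networks(self, empty_nine):
        assert fit_null(NetworkSample([empty_nine] * 4)).q == 0.0

    def test_mean_edges(self):
        assert NullModel(q=0.5, num_labels=9, n=16).mean_edges == 36.0


class TestOccurrenceProbability:
    def test_symmetric_at_half(self):
        null = NullModel(q=0.5, num_labels=9, n=16)
        for edges in ({("a", "b"), ("b", "c")}, {("a", "b"), ("b", "c"), ("c", "a")}):
            key = make_key(edges)
            assert occurrence_probability(key, null) == pytest.approx(1 / 64)

    def test_mutual_pair(self):
        null = NullModel(q=0.5, num_labels=9, n=16)
        key = make_key({("a", "b"), ("b", "a")})
        assert occurrence_probability(key, null) == pytest.approx(0.25)

    def test_study_density_value(self):
        q = 0.51097
        null = NullModel(q=q, num_labels=9, n=16)
        key = make_key({("P4", "Cz"), ("Cz", "F3")})
        assert occurrence_probability(key, null) == pytest.approx(
            q**2 * (1 - q) ** 4, rel=1e-12
        )

    @pytest.mark.parametrize("q", [0.2, 0.5, 0.51097, 0.8])
    def test_normalizes_over_all_patterns(self, q):
        """Sum of q^eta (1-q)^(6-eta) over all 64 patterns on 3 vertices is 1."""
        null = NullModel(q=q, num_labels=3, n=1)
        total = sum(
            math.comb(6, eta) * q**eta * (1 - q) ** (6 - eta) for eta in range(7)
        )
        assert total == pytest.approx(1.0, abs=1e-12)
        # and the implementation matches the same weights for connected keys
        key = make_key({("a", "b")})
        assert occurrence_probability(key, null) == pytest.approx(
            q * (1 - q), rel=1e-12
        )

    @pytest.mark.parametrize("q", [0.2, 0.5, 0.51097, 0.8])
    def test_exhaustive_three_vertex_oracle(self, q):
        """Eq.-style product formula equals the summed ER measure over all
        64 digraphs, for every connected 3-vertex pattern."""
        null = NullModel(q=q, num_labels=3, n=1)
        for edge_set in connected_3_digraphs():
            key = SubnetworkKey.from_edges(edge_set)
            exact = er_subnetwork_probability_exhaustive(edge_set, ("a", "b", "c"), q)
            assert occurrence_probability(key, null) == pytest.approx(
                exact, abs=1e-12
            )

    def test_degenerate_densities(self):
        key = make_key({("a", "b")})
        assert occurrence_probability(key, NullModel(q=0.0, num_labels=3, n=1)) == 0.0
        assert occurrence_probability(key, NullModel(q=1.0, num_labels=3, n=1)) == 0.0
        full = make_key(set(permutations(("a", "b"), 2)))
        assert occurrence_probability(full, NullModel(q=1.0, num_labels=2, n=1)) == 1.0


class TestBinomialUpperTail:
    def test_count_zero_is_one(self):
        assert binomial_upper_tail(0, 16, 0.3) == 1.0

    def test_count_equals_n(self):
        assert binomial_upper_tail(16, 16, 0.4) == pytest.approx(0.4**16, rel=1e-12)

    def test_frozen_exact_value(self):
        assert binomial_upper_tail(12, 16, 0.5) == pytest.approx(
            2517 / 65536, rel=1e-12
        )

    def test_matches_direct_summation(self):
        for n in (1, 2, 5, 16, 32):
            for p in (0.01, 0.25, 0.5, 0.51097, 0.9):
                for count in range(n + 1):
                    expect = binom_tail_direct(count, n, p)
                    assert binomial_upper_tail(count, n, p) == pytest.approx(
                        expect, rel=1e-12
                    )

    def test_nonincreasing_in_count(self):
        vals = [binomial_upper_tail(c, 20, 0.3) for c in range(21)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_log_variant_consistent(self):
        for count, n, p in [(12, 16, 0.5), (16, 16, 1 / 64), (3, 8, 0.1)]:
            assert 10 ** log10_binomial_upper_tail(count, n, p) == pytest.approx(
                binomial_upper_tail(count, n, p), rel=1e-10
            )

    def test_invalid_count(self):
        with pytest.raises(GraphValidationError):
            binomial_upper_tail(17, 16, 0.5)
        with pytest.raises(GraphValidationError):
            binomial_upper_tail(-1, 16, 0.5)


class TestHolmAdjust:
    def test_hand_computed_chain(self):
        adj = holm_adjust([0.001, 0.01, 0.03], family=3)
        assert adj == pytest.approx([0.003, 0.02, 0.03])
        assert (adj <= 0.05).all()

    def test_blocking_chain(self):
        adj = holm_adjust([0.03, 0.04], family=2)
        assert adj == pytest.approx([0.06, 0.06])
        assert not (adj <= 0.05).any()

    def test_single(self):
        assert holm_adjust([0.2], family=1) == pytest.approx([0.2])

    def test_family_larger_than_tests(self):
        # unobserved hypotheses inflate the first multipliers
        adj = holm_adjust([0.001, 0.01], family=10)
        assert adj == pytest.approx([0.01, 0.09])

    def test_family_too_small(self):
        with pytest.raises(GraphValidationError):
            holm_adjust([0.1, 0.2], family=1)

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = rng.random(rng.integers(1, 30))
            ours = holm_adjust(p, family=len(p))
            theirs = multipletests(p, method="holm")[1]
            assert ours == pytest.approx(theirs, rel=1e-12)

    def test_matches_independent_hand_oracle_with_inflation(self):
        rng = np.random.default_rng(4)
        p = rng.random(12)
        assert holm_adjust(p, family=40) == pytest.approx(holm_by_hand(p, 40))

    def test_all_equal_reduces_to_bonferroni_on_smallest(self):
        adj = holm_adjust([0.002] * 5, family=5)
        assert adj[0] == pytest.approx(5 * 0.002)
        assert (adj == adj[0]).all()


class TestDetectMotifs:
    def test_fully_penetrant_key_is_detected(self):
        """A 3-edge key present in all 16 members of a half-density sample
        survives Holm over the 4536-member family."""
        rng = np.random.default_rng(123)
        labels = ELECTRODE_LABELS
        key = make_key({("C3", "Cz"), ("Cz", "C4"), ("C4", "C3")})
        within = set(permutations(sorted(key.vertex_set), 2))
        nets = []
        for _ in range(16):
            g = _er_network(labels, 0.5, rng)
            edges = (set(g.edges) - within) | set(key.edges)
            nets.append(LabeledDigraph(labels, edges))
        table = detect_motifs(NetworkSample(nets), size=3, alpha=0.05)
        top = table.results[0]
        assert top.key == key
        assert top.count == 16 and top.mean_count == 1.0
        assert top.is_motif
        # p-value is about (q^3 (1-q)^3)^16 — astronomically small
        assert top.log10_p_value < -25
        assert table.family == 4536

    def test_empty_sample_yields_empty_table(self, empty_nine):
        table = detect_motifs(NetworkSample([empty_nine] * 16), size=3)
        assert len(table) == 0
        assert table.motifs == ()
        assert table.q == 0.0

    def test_observed_only_family_mode(self, complete_sample):
        table = detect_motifs(complete_sample, size=3, family_mode="observed-only")
        assert table.family == len(table) == 84

    def test_results_sorted_by_p_value(self):
        rng = np.random.default_rng(5)
        nets = [_er_network(ELECTRODE_LABELS, 0.5, rng) for _ in range(16)]
        table = detect_motifs(NetworkSample(nets), size=3)
        ps = [r.p_value for r in table.results]
        assert ps == sorted(ps)
        for r in table.results:
            assert r.p_holm >= r.p_value
            assert r.is_motif == (r.p_holm <= table.alpha)

    def test_invalid_alpha(self, complete_sample):
        with pytest.raises(GraphValidationError):
            detect_motifs(complete_sample, size=3, alpha=1.5)
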