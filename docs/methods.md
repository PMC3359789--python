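# Methods

## Model and assumptions

The unit of analysis is a sample 𝒩 = (𝒩₁, …, 𝒩ₙ) of simple directed graphs
on one shared set 𝒱 of ν pairwise-differently labeled vertices (no loops,
no multi-edges; a mutual connection u↔v is the two directed edges (u, v)
and (v, u)). Vertex identity is the label string: subnetworks are compared
by labeled edge set, so isomorphism classes play no role and each candidate
subnetwork occurs at most once per member network. Member networks need not
be connected; connectivity is required only of candidate subnetworks.

**Enumeration.** For size ν_S (2 ≤ ν_S ≤ ν), every one of the C(ν, ν_S)
vertex subsets of every member is examined for its *induced* subnetwork —
exactly the member's edges with both endpoints inside the subset. Induced
(not partial) semantics are essential: the null probability below contains
the factor (1−q)^{η_Smax−η_S}, which requires absent within-subset edges to
be genuinely absent. A subset contributes a candidate iff its induced edge
set is **weakly** connected (every subset vertex reachable ignoring edge
direction). Weak connectivity is the notion that yields the classical
census of 54 labeled connected 3-digraphs in 13 isomorphism classes;
strong connectivity would give different counts. Subsets are visited in
lexicographic label order purely for determinism; results are sets/maps.

**Null model and test.** The null is an i.i.d.-edge (Erdős–Rényi) digraph
whose density q is the sample's normalized mean edge count,
q = Σᵢ kᵢ / (n ν(ν−1)). A candidate S with η_S edges on ν_S vertices then
occurs per network with probability q^{η_S}(1−q)^{η_Smax−η_S}
(η_Smax = ν_S(ν_S−1)), and its sample count is Binomial(n, ·). Testing is
**one-sided** (overrepresentation only) with the exact binomial upper tail
P(X ≥ count) — the survival function, never a normal approximation.
Familywise error across the family of all size-ν_S subnetworks is
controlled by the Holm step-down procedure at α (default 0.05), not FDR.

**Family size.** "All subnetworks of size ν_S" admits two readings. The
default (`family_mode="all-possible"`) takes m = C(ν, ν_S)·W(ν_S) — e.g.
36·3 = 108 for pairs and 84·54 = 4536 for triples on nine labels — treating
unobserved candidates as p = 1 hypotheses that inflate the Holm multipliers
but can never be rejected. This is the conservative reading;
`"observed-only"` (m = number of observed keys) is provided for
sensitivity analysis, and the mode and m used are recorded in all output.
W(k), the number of weakly connected digraphs on k labeled vertices, is
computed by exhaustive generation for k ≤ 4 and by the standard
inclusion–exclusion recurrence W(k) = 2^{k(k−1)} − Σ_{j<k} C(k−1, j−1)
W(j) 2^{(k−j)(k−j−1)} beyond; the two routes are cross-checked in tests
(1, 3, 54, 3834 for k = 1…4).

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `size` (ν_S) | subnetwork size | 3 (CLI) | 2 and 3 are the physiologically interpretable sizes for nine-electrode networks; larger sizes are supported but need larger samples |
| `alpha` | multiple significance level | 0.05 | conventional familywise level |
| `family_mode` | Holm family | `all-possible` | conservative reading of testing all size-ν_S subnetworks |
| `q` (generator) | edge probability | 36.79/72 ≈ 0.5110 | the mean edge density of the motivating study's nine-electrode networks |
| `n` (generator) | sample size | 16 | the study's per-group sample size (one group had 15) |
| penetrance | per-member planting probability | 1.0 (CLI) | full penetrance is the canonical recovery experiment |

## Numerical choices

- The occurrence probability is evaluated in log space for q ∈ (0, 1)
  (`exp(η log q + (η_max−η) log1p(−q))`); q = 0 and q = 1 use the
  convention 0⁰ = 1.
- The binomial tail uses the regularized-incomplete-beta survival function;
  a parallel log₁₀ tail (log-sum-exp over pmf terms) is carried through the
  pipeline so extreme p-values are reported in scientific notation instead
  of underflowing to a printed 0.
- Holm adjustment is plain step-down float arithmetic
  (max-running min(1, (m−j+1)·p₍ⱼ₎)); ties in p are processed in canonical
  key order, which affects only reporting order, never adjusted values.
  A log₁₀-scale twin of the step-down is used for the reported log values.
- Degenerate densities: q = 0 with a nonempty census, or an observed key
  with zero null probability (possible only for inconsistent hand-built
  input), raise a consistency error rather than producing p = 0 tests.
- Motif tables print floats at six significant digits; a table re-read and
  re-written is byte-identical. Adjacency orientation is fixed as
  row = tail, column = head — transposing an input matrix silently reverses
  every motif, so both readers validate label sets and the convention is
  documented wherever matrices appear.

## Synthetic data: what it does and does not emulate

`generate_null_sample` draws every ordered vertex pair independently with
probability q — exactly the null the test assumes. `generate_ecn_like_sample`
fixes the study dimensions (nine electrode labels, n = 16, q = 36.79/72).
`plant_subnetwork` forces, per member with probability equal to the
penetrance, the *induced* subnetwork on the planted key's vertex set to
equal the key — its edges are added and the complementary within-subset
pairs are removed, because counting is by induced pattern and planting only
edge presence would produce a different pattern whenever background edges
land inside the subset. A single root seed derives one substream per member
(numpy `SeedSequence` spawn keys), so changing n never reshuffles other
members' draws and all generators are pure functions of config + seed.

Real effective-connectivity networks are *not* i.i.d.-edge: they have
structured degree sequences, hemispheric and fronto-parietal asymmetries,
and between-subject correlation. Passing calibration and recovery tests on
these generators therefore demonstrates correctness of the statistics under
the method's own null and power under idealized planting — not robustness
of the i.i.d.-edge null to real-data structure, which is the method's known
modeling simplification.

## Problem sizes used in the test and acceptance runs

Monte-Carlo checks use 200 pure-null samples (ν = 9, n = 16, q = 0.51) for
the familywise false-positive calibration, 100 seeds for full-penetrance
recovery, 60 ECN-like samples for density calibration, and up to 10 000
networks for generator moment checks — sizes at which binomial standard
errors make the assertions sharp while the whole suite completes in about a
minute.

## Known limitations

- The i.i.d.-edge null ignores degree heterogeneity; hubs inflate the
  occurrence of hub-incident subnetworks relative to the null, a
  conservative-vs-anticonservative trade-off the analytic approach accepts
  in exchange for exactness and speed.
- q is estimated from the same sample that is tested; for n in the study's
  range (15–16) this plug-in uncertainty is not propagated.
- Detection requires the subnetwork to recur across members; patterns
  private to few members are invisible by design.
- Only overrepresentation is tested; underrepresented ("forbidden")
  patterns are out of scope.
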