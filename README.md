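# labmotif

Analytical network-motif detection for **samples of directed networks that
share one set of pairwise-different vertex labels** — for example effective
connectivity networks (ECNs) from an EEG study, where each participant's
directed interactions among the nine electrodes F3, Fz, F4, C3, Cz, C4, P3,
Pz, P4 form one simple digraph on the same labeled vertex set.

## The method

Because every vertex carries a unique label, two subnetworks are identical
exactly when they have the same set of labeled edges; isomorphism testing
never arises, and a given subnetwork can occur **at most once per network**.
Motifs are therefore defined over the whole sample 𝒩 = (𝒩₁, …, 𝒩ₙ):

1. **Exhaustive enumeration.** For every member network, every combination
   of ν_S vertices is examined for the subnetwork it induces; weakly
   connected induced edge sets are counted across the sample.
2. **Analytic null model.** With ν vertices and edge counts k_i, the null
   treats every ordered pair as an independent Bernoulli edge of density

       q = (1 / (n ν(ν−1))) Σᵢ kᵢ .

   A subnetwork S with η_S edges on ν_S vertices (η_Smax = ν_S(ν_S−1))
   occurs in a null network with probability

       P(Xᵢ = 1) = q^{η_S} (1 − q)^{η_Smax − η_S},

   and its sample count Σ Xᵢ is Binomial(n, P(Xᵢ = 1)).
3. **Exact one-sided test + Holm.** Each observed subnetwork is tested for
   overrepresentation with the exact binomial upper tail; the family of all
   size-ν_S subnetworks (C(ν, ν_S) · W(ν_S) hypotheses, where W(ν_S)
   counts weakly connected labeled digraphs — W(2)=3, W(3)=54) is
   controlled at familywise level α = 0.05 by the Holm step-down
   correction. No random-network ensembles are ever simulated.

The package provides the library (`labmotif.core`, `.enumeration`,
`.stats`), a synthetic-sample generator that emulates the ECN study
conditions (ν = 9 electrodes, n = 16 networks, mean density 36.79/72 ≈
0.511, optional planted subnetworks at chosen penetrance), plain-text I/O
(edge lists, labeled adjacency CSV, TSV motif tables), and a CLI.

## Worked example

Simulate a 16-member sample at the study's density with the mutual pair
C3↔Cz planted into every member, then scan for 2-motifs:

```bash
labmotif simulate --seed 42 --plant "C3>Cz;Cz>C3" --penetrance 1.0 --outdir sample
labmotif detect --input sample --size 2 --alpha 0.05 --output motifs.tsv
```

which prints

```
wrote 16 networks to sample
1 motif(s) of size 2 at alpha=0.05 -> motifs.tsv
```

and the top of `motifs.tsv` reads

```
# n: 16
# q: 0.539931
# family_mode: all-possible
# family: 108
subnetwork	size	eta	count	mean_count	p_null	p_value	p_holm	is_motif
C3>Cz;Cz>C3	2	2	16	1	0.291525	2.72153e-09	2.93925e-07	1
Fz>C4	2	1	8	0.5	0.248406	0.0261406	1	0
```

Reading the motif row: the planted mutual pair occurred in all 16 networks
(`mean_count = 1`); under the fitted null density q ≈ 0.54 a specific
mutual pair occurs per network with probability q² ≈ 0.2915, so 16/16
occurrences have exact binomial tail p ≈ 2.7·10⁻⁹, which survives the Holm
correction over the 108-member family (adjusted p ≈ 2.9·10⁻⁷ ≤ 0.05). The
next-ranked subnetwork (8/16 occurrences) does not.

The same pipeline is available programmatically:

```python
from labmotif import generate_ecn_like_sample, detect_motifs
table = detect_motifs(generate_ecn_like_sample(1), size=3, alpha=0.05)
print(table.q, len(table), len(table.motifs))   # 0.4948 1019 0  (pure null)
```

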