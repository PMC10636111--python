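# Methods

This note documents the models and procedures implemented in `milkshare`,
the defaults chosen where the design was genuinely open, and what the
synthetic cohorts do and do not establish about real data.

## Data model

The pipeline consumes post-denoising artifacts: an integer ASV count matrix
(samples × ASVs), ASV sequences, a taxonomy table (ASV → genus/species) and
per-sample metadata (family, body site, isolation kit, sequencing
chemistry, replicate, DNA yield). Sequences are normalized to uppercase DNA
with U→T; IUPAC ambiguity codes are rejected by default (optionally masked
to N) because sharing calls are exact string comparisons and must be
unambiguous. ASVs are expected to fall in an amplicon length window —
400–431 bp for short-read 16S V3–V4 mode, 1900–3000 bp for long-read
16S-ITS-23S mode; `validate_dataset` reports (and under `strict` rejects)
out-of-window ASVs and any cross-file inconsistency. A DNA yield of 0 means
"below detection limit" and is distinct from a missing measurement (empty
field → None).

### Replicate reconstruction from published summaries

Per-kit read counts in method-comparison tables are printed as
"median (range)" over 1–3 replicates. `reconstruct_replicate_values`
inverts this: n=1 → {median}; n=3 → {lo, median, hi}; n=2 → {lo, hi} with a
consistency check that the printed median is the midpoint up to the
0.5 integer-rounding slack (a warning otherwise). The midpoint rule for n=2
is a reconstruction convention, not information in the table, and is
flagged as such. Integer read-count medians are rounded half away from
zero, matching the publication convention.

## Compositional analysis

- **Zeros.** A pseudocount of 0.5 is added to genus *counts* before closure
  and CLR (configurable). This is the standard count-zero treatment and
  keeps technical replicates comparable; raw compositions may be
  transformed with pseudocount 0, in which case zeros are an error.
- **Closure.** Relative abundances default to closure over all retained
  reads with genus-unclassified ASVs pooled into `OTHER_UNCLASSIFIED`; a
  `classified` mode drops unclassified reads from the denominator, since
  published figures are ambiguous about which convention they use.
- **CLR / Aitchison.** `clr_ij = ln(x_ij / g(x_i))`; rows sum to 0 by
  construction, and CLR (hence the Aitchison distance) is invariant to
  per-sample count rescaling. Distances are Euclidean on CLR rows.
- **PCoA** double-centres the squared distance matrix
  (`G = -J D² J / 2`) and eigendecomposes it. Negative eigenvalues
  (non-Euclidean inputs) are reported, never silently clipped; variance
  fractions are over positive eigenvalues. On Aitchison matrices the
  embedding reproduces the input distances to < 1e-6.
- **PERMANOVA** uses sequential (type-I) sums of squares in the user-given
  term order via cumulative hat matrices on the Gower-centred inner-product
  matrix, 999 unrestricted row permutations by default, and
  `p = (1 + #{F* ≥ F}) / (1 + n_perm)`. Single-level and collinear terms
  are skipped with a warning. An exhaustive mode enumerates all n!
  permutations for small n. The implementation is cross-checked in the
  test suite against vegan's `adonis2` (SS/R²/F to 1e-6), against a
  brute-force within/between-group oracle, and for type-I calibration
  (empirical rejection rate at α=0.05 within [0.03, 0.07] over 1000 null
  simulations).
- **Per-genus linear models.** OLS of CLR abundance on the factor of
  interest plus categorical fixed effects (dummy coding); the factor is
  tested jointly by partial F-test and BH-adjusted across genera.
  Rank-deficient designs raise an error naming the collinear factors.
- **Dunn's post hoc** after Kruskal–Wallis uses rank-based z statistics
  with tie correction; the BH family is all pairwise comparisons within one
  omnibus test.
- **Summaries.** Core genera: detection prevalence ≥ 70% of selected
  samples. Display rule: keep genera present in ≥ 2 samples reaching ≥ 2%
  relative abundance in at least one sample, aggregate the rest (plus
  unclassified) into "Other"; dominant genera reach ≥ 15% in ≥ 1 sample.
  Mock profiles are compared to their reference by detected/missing/
  unexpected genera (unexpected below 0.02% flagged as trace), per-genus
  log-ratio bias, and the Aitchison distance over the union of genera with
  multiplicative zero replacement (1e-6).

## Contamination

An ASV with ≥ 1 read in both a biological sample and a matched negative
control is a potential contaminant (no abundance floor; an optional minimum
count exists but defaults off, matching the binary presence definition).
"Matched" means: all isolation controls processed with the same isolation
kit, and all library-prep controls globally — the matching policy is
recorded in the report. Contaminated read fractions are computed per
sample; attribution runs the same computation separately against each
control class, so a read can count against both when its ASV occurs in both
kinds of control. Nothing is removed: the analysis quantifies contamination
rather than filtering it. The yield association is a Spearman
rank correlation over samples with complete (yield, fraction) pairs; < 3
pairs is an error and constant vectors give an undefined (NaN) rho.

## Sharing

- Pairing: every milk sample × every sample of the second type; related ⟺
  same family. A family with replicate samples of a type is an error by
  default (`replicate_policy="first"` keeps the lowest replicate instead).
- Candidate genera: detected (≥ 1 read) in both members of ≥ 2 related
  pairs.
- A sharing event is exact normalized-sequence identity with ≥ 1 read in
  both members (threshold configurable). Identity is alignment-free; MSA
  cannot change the equality of identical strings.
- The per-genus 2×2 table defaults to all pairs in the not-shared margin
  (absent pairs pooled with present-not-shared), because panel percentages
  are over all pairs; a `present-both` denominator restricts to pairs where
  the genus is present in both members. Both modes are reported because the
  source convention is unstated.
- Fisher's exact test is two-sided by the probability-mass method: sum of
  hypergeometric probabilities of tables (fixed margins) whose point
  probability is ≤ the observed one up to a 1e-7 relative tolerance, with
  point probabilities as exact integer weights. BH family: the candidate
  genera of one comparison panel (a `global` family across panels is
  available in the CLI). Stars: FDR < 0.05/0.01/0.001.
- **MSA.** Progressive alignment in the ClustalW style: all-pairs global
  affine-gap alignments (match +2, mismatch −1, gap open −5, gap extend −2;
  configurable) give identity distances 1 − identical/columns; an
  average-linkage guide tree fixes the merge order; profiles are merged by
  affine-gap dynamic programming with average-of-pairs column scoring
  (averaging keeps gap penalties on the single-sequence scale independent
  of profile size). Ties break deterministically by state priority
  substitution > gap-in-B > gap-in-A. Substitution-only pools align
  gap-free; `stack_alignment` shortcuts equal-length inputs.
- **Hamming distances** count differing alignment columns; gap vs base is a
  difference, gap vs gap is equal, so distance 0 ⟺ identical gapped rows.
- **Trees** are neighbour-joining (standard Q-criterion, via scikit-bio) on
  the per-genus Hamming matrix, serialized as Newick with negative branch
  lengths clamped to 0 (logged). NJ recovers additive metrics exactly,
  which the tests verify on random additive 4–8-taxon matrices.
  Maximum-likelihood phylogenetics and bootstrap support are out of scope.

## Synthetic cohorts

The generator emulates the *structure* of a pilot milk-transmission study,
not its biology. Defaults: 14 families with one milk, infant-oral,
infant-faecal and maternal-faecal sample each; five milk-typical genera
with log-normal relative abundances (Staphylococcus/Streptococcus-skewed),
prevalence 0.5–0.9; read depth log-normal around 20 000 reads (σ_log 0.3);
ASV pools of same-length sequences derived from a per-genus ancestor by
point substitutions (rate 0.02), 420 bp in short mode, 2200 bp in long
mode; negative-control depths uniform on 0–5000 reads (the observed
low-read regime); four kit contaminant ASVs per isolation method injected
into matching biological samples with probability 0.5 at log-normal low
counts; mock communities multinomial around a softmax-perturbed reference
(log-normal dispersion 0.3).

Sharing model: each carrying sample always has a sample-private ASV;
related-pair events are planted with probability `p_share` via a
family-specific ASV placed in both members; background sharing arises only
through one per-genus background ASV carried independently with probability
`sqrt(p_bg)`, making the unrelated-pair coincidence rate ≈ `p_bg`. At
`p_bg = 0`, identical ASVs across a pair exist iff an event was planted, so
the truth log is exact. Carried ASVs are floored to 1 read after
multinomial sampling, so presence is deterministic given carriage (sample
depth is then approximate, not exact). All draws derive from
order-insensitive per-role/per-sample RNG streams keyed on the seed;
identical configs are bit-identical.

What passing tests on these cohorts show: the analysis stack recovers
planted parameters (sharing fractions, contaminant sets, mock compositions)
under its own generative assumptions. What they do not show: robustness to
chimeras, sequencing error, PCR bias, indel-rich ASV families, taxonomy
misassignment or compositional effects of unmodelled taxa — none of which
the generator emulates.

## Problem sizes and numerical choices

The test suite and `scripts/acceptance.py` use deliberately desk-scale
sizes chosen as the smallest that make the statistical checks meaningful:
exact-test enumeration over all 2×2 tables with row margins ≤ 30; PERMANOVA
calibration over 1000 (tests) / 500 (script) null datasets of 12 samples at
99 permutations (p-resolution 0.01); sharing-fraction recovery over 200
(tests) / 100 (script) 14-family cohorts at depth 3000; exhaustive
permutation checks at n = 6. Distance-matrix symmetry uses an absolute
1e-8 tolerance; PERMANOVA permutation tie comparison uses F* ≥ F − 1e-12;
PCoA retains eigenvalues > 1e-9; design ranks use a relative 1e-10 SVD
cutoff.

## Known limitations

- The progressive MSA is a textbook implementation intended for within-genus
  ASV families (tens of sequences); it is not a general-purpose aligner and
  its guide tree uses identity distances rather than model-based distances.
- PERMANOVA permutations are unrestricted; no strata/blocking.
- Sharing direction (mother → infant vs infant → mother) is not
  identifiable from presence data and is not modelled.
- The generator's parameters are stand-ins; outputs echo them in the truth
  log and manifest, and they must not be read as estimates of any real
  cohort.
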