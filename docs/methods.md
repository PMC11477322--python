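# Methods

## Scope and conventions

The package analyses sets of in-frame coding sequences, one per species,
for one or two genes. All statistics share three conventions, chosen to
match common CodonW usage and the 59-codon layout of published RSCU tables:

- a single terminal stop codon is removed (`trim_stop`, default) or
  retained on the record but excluded from every count (`strict`); internal
  stop codons are hard validation errors;
- Met (AUG) and Trp (UGG) carry no synonymous choice and are excluded from
  RSCU, CAI, CBI/Fop and silent-site composition, leaving 59 reported
  codons;
- the six-fold amino acids Leu, Ser and Arg are treated as single
  six-codon families (not 2+4 splits) in both RSCU and ENC — the published
  six-fold RSCU values are only consistent with a denominator of 6.

Codons are presented in the RNA alphabet (UUC, not TTC); storage is DNA.
Species labels default to the first whitespace-delimited FASTA header
token, overridable by a header regex, since GenBank header layouts vary.

## Index definitions

**RSCU.** For codon *i* of an amino acid with *N* synonyms observed *G_i*
times, RSCU = N·G_i / Σ_j G_j. A family with zero observations yields
undefined (NaN) RSCU, never 0. Family sums equal the family size for
per-sequence and pooled scopes; group-mean tables (arithmetic means of
per-species RSCU) do not satisfy this identity and are labelled as such.

**Silent-site composition.** T3s/C3s/A3s/G3s are fractions of third-position
bases over codons whose amino acid has ≥ 2 synonyms; all four share one
denominator, so they sum to 1 and GC3s = C3s + G3s. GC is computed over all
positions of the counted codons. Summary tables report these as percentages.

**ENC (Wright).** Per family with n ≥ 2 observations,
F = (n·Σp_i² − 1)/(n − 1); F̄_k averages F over observed families of fold
class k ∈ {2,3,4,6}; Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆, clamped to
[20, 61]. Families with n ≤ 1 are excluded (the estimator divides by
n − 1), as are families with F = 0 (uninformative at small n). A missing
three-fold class (Ile absent) is substituted by (F̄₂ + F̄₄)/2, Wright's
recommendation; any other missing class makes the estimate undefined
(`enc_undefined`).

**CAI (Sharp & Li).** Relative adaptiveness w = count/max-count within each
family of a reference count table; unobserved reference codons are floored
at w = 0.01 so the geometric mean stays finite; CAI = exp(mean ln w) over
counted codons, AUG/UGG excluded. No organism-specific built-in weight
table ships with the package: published weight sets are third-party data
better supplied by the user (via `CaiReference.from_counts` or
`from_weights`). The default reference derives weights from the pooled
counts of the five lowest-ENC species in the input set — the same
most-biased group the ΔRSCU analysis treats as "high expression". Because
reference choice shifts CAI's absolute level, published CAI columns are not
reproduction targets; correlations and rankings are robust to the choice.

**CBI / Fop.** Over degenerate families only, with one optimal codon per
family (default: most frequent in the pooled input, ties broken
alphabetically): Fop = N_opt/N_tot and CBI = (N_opt − N_rand)/(N_tot −
N_rand) with N_rand = Σ N_family/N_i, clamped to [−1, 1].

**Gravy / Aromo.** Mean Kyte–Doolittle hydropathy and aromatic fraction
(F, Y, W) of the translated protein.

## Comparative stages

High/low-frequency codon sets use strict inequalities (RSCU > 1, < 1); a
codon at exactly 1.00 belongs to neither — required for the published
shared-set counts to be reproducible from printed 2-dp tables, which the
`precision` flag mimics by rounding half-even before comparison.

Expression groups are ranked by ENC: the five largest-Nc species form the
low-expression group, the five smallest-Nc the high-expression group (ties
broken by species label for determinism). ΔRSCU uses group means of
per-species RSCU (not RSCU of pooled group counts); a codon is optimal when
ΔRSCU ≥ 0.08 and its high-group mean exceeds 1 while its low-group mean is
below 1. The 0.08 threshold is conventional rather than derived; it is a
parameter with that default.

PR2 coordinates are x = A3/(A3 + T3), y = G3/(G3 + C3). The vertical axis
follows the parity-rule-2 literature (G vs C at third positions); both axes
are scale-invariant ratios, so percent or fraction inputs agree. Points
with a zero denominator are reported missing.

## Multivariate stages

Correlations are Pearson r with two-sided t-test p-values (n − 2 df),
unadjusted, starred at 0.05/0.01/0.001/0.0001 — the usual heatmap
convention. Hierarchical clustering defaults to Euclidean distance with
Ward linkage (both configurable; the original figures' tool defaults are
unknowable). PCA runs on column-centered, unscaled RSCU — RSCU is already
dimensionless and family-normalized, so variance scaling would only inflate
rare-codon noise. k-means on the two-gene CAI plane normalizes each gene's
CAI independently (z-score default, min-max available), uses k = 3 and the
best of 50 seeded restarts. Species missing an entire amino-acid family get
that family's RSCU imputed at the neutral value 1.0 (with a warning) for
clustering/PCA only, so no species is dropped.

All stochastic steps take an explicit seed (default 20241004) and are
bit-reproducible.

## Neighbor joining and bootstrap

Trees are built from pairwise Euclidean distances between species RSCU
profiles — an alignment-free stand-in for sequence-distance trees that
addresses the same question (usage-pattern relatedness) but is not claimed
to reproduce alignment-based topologies node for node. A p-distance option
exists for pre-aligned equal-length input. The NJ agglomeration is the
standard Saitou–Nei Q-criterion with deterministic tie-breaking by the
lexicographically smallest cluster-label pair; negative branch lengths are
clamped to zero with a warning (the usual convention). Bootstrap resamples
the 59 codon columns of the RSCU matrix with replacement (default B =
1000); support is the percentage of replicates containing each internal
bipartition of the point-estimate tree. The implementation is checked in
the test suite against scikit-bio's independent NJ on random matrices and
against exact recovery on additive matrices.

## Synthetic generator

`SyntheticSpec` draws amino acids i.i.d. from a frequency vector (default:
uniform over the 18 degenerate amino acids, Met/Trp at 0.02 — guaranteeing
every fold class is observed) and codons from a within-family softmax with
a single GC3-bias parameter β: p(codon) ∝ exp(β·[third base ∈ {G,C}]).
β = 0 is unbiased (expected RSCU = 1 everywhere); β ≈ 1 yields GC3s near
72%, matching the strongly GC-ended usage of the real tables; clade offsets
on β plant a recoverable phylogenetic signal. Defaults (24 species, 500
codons) mirror the study's shape: two genes, two dozen species, CDS of a
few hundred codons.

The generator emulates the central axis of real codon-usage variation
(GC3-driven bias shared within clades) and deliberately omits much that
real data have: amino-acid composition differences between genes,
position-dependent codon context, selection–mutation balance, indels and
misannotation. Passing tests therefore demonstrate that the estimators
recover known usage structure from clean in-frame CDS — not that they are
robust to annotation artifacts.

Expected values are closed-form: expected RSCU = N_i·p(codon); expected
GC3s averages each family's G/C probability mass weighted by the
amino-acid frequencies over degenerate families. Estimator-recovery tests
compare seed-averaged empirical RSCU against these expectations under a
3·√(N_i/N_family) binomial bound; averaging over seeds keeps the bound
conservative, which a single draw's 59-codon maximum would not be.

## Numerical choices

- Printed-table comparisons round half-even at the printed precision
  (2 dp for composition/RSCU, 3 dp for indices).
- RSCU/ENC/CAI are exact arithmetic on counts; no tolerance enters except
  the 1e-12 oracle comparisons in tests.
- Degenerate inputs: empty or stop-only sequences, families with zero
  counts, zero-variance columns, and zero PR2 denominators all yield
  explicit errors or NaN ("missing"), never silent zeros.

## Known limitations

- Two quantities published for this two-gene study are internally
  inconsistent in their source tables and cannot be reproduced from them:
  six of 59 pooled DDR1 RSCU cells differ at 2 dp from RSCU recomputed
  from the same table's counts (the printed column is likely
  species-averaged), and the printed DDR1 CAI and Nc columns correlate at
  +0.72, not the stated −0.52. The corresponding checks in
  `tests/test_acceptance.py` assert the published claims as stated and
  fail, by design; the docstring there documents both.
- Absolute CAI levels depend on the reference set, which is user-supplied
  or derived from the input (see above).
- Usage-distance NJ trees are not sequence-distance trees; branch lengths
  are in RSCU space and only topology/support should be interpreted.
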