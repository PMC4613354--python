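# Methods

## The measurement

A circular bacterial chromosome is partitioned at its replication origin
(*ori*) and terminus (*ter*) into two replichores. On the arc running
*ori → ter* in increasing published-sequence coordinates the published
(+) strand is the leading strand; on the complementary arc it is the
reverse complement. All coordinates are 0-based half-open internally;
GFF3's 1-based inclusive convention is converted at the I/O boundary.
ori/ter supplied as intervals (DoriC-style) are collapsed to midpoints,
computed modulo the chromosome length for origin-wrapping intervals,
because the downstream arithmetic needs single breakpoints.

**Composition-bias score.** `(|G − C| + |T − A|) / L` with bases counted
over the whole composite leading strand (published bases over arc 1 plus
complemented bases over arc 2) — intergenic sequence included, which is
the literal whole-arc reading of "bases in leading strands". Ambiguity
codes are excluded from the base tallies, but the denominator stays the
full chromosome length; a genome with *no* unambiguous bases propagates
NA rather than a spurious 0. By complementarity, the lagging strand
yields the identical score (asserted as a property test).

**Gene classification.** A gene is leading-strand iff it is coded on the
leading strand of the arc containing its *midpoint* (modulo length for
origin-wrapping genes). The midpoint rule is deterministic and makes
every gene classifiable, including genes spanning ori or ter, for which
no convention is otherwise forced.

**RF indices.** For the per-gene skews `(G_i − C_i)/L_i` (and TA
analogue) of the leading-strand genes, read in coding orientation, the
index is the sample variance (N−1 denominator) divided by the mean. The
defining expression can also be read with a square root over the
variance term; the package defaults to the literal variance/mean and
offers `rf_variant: sd_over_mean` (the coefficient of variation) as a
configuration switch — both readings preserve the sign behaviour,
including negative RF for negative-mean genomes. A mean of exactly zero
leaves RF undefined and propagates NA. Genes whose sequence contains no
unambiguous bases are dropped with a warning.

## COG/KEGG statistics

pCOG counts one unit per (gene, subcategory-letter) pair, drops the
letters R, S and X before counting, and normalizes to sum to 1; a gene
annotated "KL" contributes half a unit to each letter, keeping the
vector normalized. The strong-biased genome group (SBG) is the top
`floor(N/2)` genomes by score (ties broken by genome id, so the split is
reproducible); the rest form the WBG.

The SBG:WBG ratio is computed **per COG ortholog group** by default, the
AVDT of a subcategory is the mean of its groups' ratios, and SCOG/WCOG
selection (ratio > 5 / < 0.2) operates at group level. The defining text
can also be read entirely at subcategory level, but under that reading
the weak-side selection is empty whenever every subcategory's AVDT
exceeds 0.2 while per-genome WCOG proportions are still expected to
exist; only the group-level reading makes all downstream quantities
simultaneously computable. `diff_level: subcategory` provides the
literal alternative. Groups absent from the WBG have an undefined ratio
and are excluded with a warning (a `pseudocount` option adds a constant
to both counts instead). SCOG/WCOG proportions use COG-annotated genes
as the denominator; KEGG replication-and-repair pathway proportions
(ten fixed pathway classes) use all genes of the genome.

## Cohort statistics

Spearman correlations use average ranks for ties and the two-sided
asymptotic *t* approximation with n − 2 df (delegated to
`scipy.stats.spearmanr`; an O(n²) midrank-then-Pearson brute force
serves as the independent oracle in the tests). Missing values are
removed pairwise per feature; constant features yield NA rows with a
warning. No multiple-testing correction is applied — the report instead
annotates the two raw-p conventions (0.05 overall, 1e-8 for the COG
subcategory screen). The obligate-intracellular comparison is a Welch
two-sample t-test by default (`t_test_equal_var: true` gives the pooled
variant); the defining analysis says only "t-test", and Welch is the
safer default under unequal group variances. Phylum summaries report
sd/variance as NA for single-member phyla.

**Principal component regression.** Features are z-standardized
(rows with any missing value dropped, logged — listwise, versus pairwise
for correlations), components come from the eigendecomposition of the
feature correlation matrix with unit-norm loadings, and all components
with nonnegligible variance are retained (no retention rule is forced
by the analysis being reproduced; retaining all of them makes the
decomposition exact). Because the components are orthogonal and
centred, `R²_m = corr(component_m, score)²` sums over m to the OLS R²
of the score on all components, and the per-feature contribution
`Σ_m loading²_fm · R²_m` sums exactly to that total (orthonormality of
the loading matrix). Two numerical conventions make this deterministic:
components with eigenvalue below 1e-10 of the largest are dropped as
rank deficiency, and within blocks of numerically equal eigenvalues —
where any orthonormal basis of the eigenspace is a valid PCA — the
basis is rotated to be maximally feature-aligned, so that for an exactly
orthogonal feature set the components coincide with the features. The
total R² is invariant to this choice; only its attribution is made
well-defined. By default PCR runs on the features passing the strict
battery cutoff (p < 1e-8), falling back to the core feature set (size,
GC, density, gcRF, taRF, SCOG/WCOG fractions) when fewer than two pass;
constant features are dropped with a log line; an explicit
`pcr_features` list overrides the selection.

## The synthetic-data generator

The generator emulates the *data model* of the analysis, not bacterial
evolution. Bases are drawn site-independently on the composite leading
strand with

    P(G) = gc/2 + δ_gc/2,  P(C) = gc/2 − δ_gc/2,
    P(T) = (1−gc)/2 + δ_ta/2,  P(A) = (1−gc)/2 − δ_ta/2,

then complemented onto the published strand over the second replichore.
Every statistic under study depends only on per-strand base frequencies,
so this is the minimal sufficient generative model; it deliberately has
no codon structure, no operons, one chromosome per genome, and genes are
whole non-overlapping loci placed with uniform-multinomial gaps. The
expected score with no rearrangements is exactly |δ_gc| + |δ_ta|, and
every drawn parameter is written to a ground-truth table. Inversion
events reverse-complement segments chosen to avoid ori and ter (keeping
the replichore map fixed, which the RF indices presuppose), mirroring
contained genes and deleting genes that straddle a breakpoint.

Cohort defaults are the study conditions: 200 genomes at a 500 kb base
length (a deliberately scaled-down chromosome that keeps the sequence-
sampling standard error of the score, ~1.4 × 10⁻³, an order of magnitude
below the simulated bias spread), bias level b ~ U(0.005, 0.075) split
60/40 between δ_gc and δ_ta — spanning the same order as observed
per-phylum mean scores (~0.01–0.1) — leading-gene placement probability
0.7 ± a planted coupling, GC base 0.5, and an obligate-intracellular
rate of 0.2 with a +0.015 bias offset (large enough for the direction of
the group difference to be reliably significant at this cohort size).
Planted relationships: density rises with b (coefficient 3), GC falls
(2), genome size falls (10), and the COG label distribution tilts the
D/F/J/L/V subcategory tier up ∝ t⁴ in the normalized bias t and the
A/C/I/Q tier down symmetrically, so strong-/weak-biased ortholog groups
(ratio > 5 / < 0.2) exist by construction and the per-genome SCOG/WCOG
proportions correlate with the score in the expected directions. The
gcRF/taRF anticorrelation with the score is **not** planted: per-gene
skew variance is ≈ composition/L_gene regardless of b while the mean
skew equals δ, so variance/mean falls mechanically as bias rises.

The **null preset** sets the bias itself to zero, not merely constant:
at any fixed nonzero δ the realized genome-wide skew and the per-gene
skew mean fluctuate together (they are computed from the same bases),
which couples the score to RF with a Spearman rho near −0.25 — a real
property of the estimators, not a battery artifact. With δ = 0 the
score is pure folded sampling noise and every cohort correlation has
expectation zero, which is what a type-I calibration requires.

What passing tests on this generator do **not** show: behaviour under
codon-level selection, strand-specific repair heterogeneity along the
chromosome, multi-replicon genomes, linear chromosomes, or annotation
noise — real cohorts have all of these, and effect sizes recovered here
say nothing about real-data effect sizes, only that the estimators
recover what was planted.

## Problem sizes and determinism

The test suite and the acceptance script use 200-genome × 500 kb cohorts
(5 seeds) for cohort-level checks, 1 Mb single genomes for parameter
recovery, 20 seeds × {0, 8, 32} events at 500 kb for the inversion
trend, and ≤ 10 kb genomes for brute-force oracle comparisons — sizes at
which Monte-Carlo standard errors are small relative to every asserted
margin. All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical (inputs, config, seed) produce
byte-identical output files, asserted end to end.

## Known limitations

* The score's denominator convention (full chromosome length even when
  ambiguity codes are excluded from the tallies) slightly deflates the
  score of low-quality assemblies; it follows the defining formula
  literally.
* Whether the original analysis counted whole replichores or
  concatenated leading-strand genes for the score, and CDS or whole loci
  for RF, is not decidable from its description; whole arcs and whole
  loci are used, and the per-gene machinery accepts any interval set.
* The PCR attribution rule (squared loadings × per-component R²) is one
  defensible decomposition among several; it is chosen because it sums
  exactly to the regression R², matching an additive per-feature
  presentation.
* Spearman p-values are asymptotic; for n < 10 they are rough (the
  package is meant for cohorts of hundreds).
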