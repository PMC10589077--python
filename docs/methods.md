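# Methods

## The question and the statistic

Given two species — a focal species A whose plastic response is assayed
as a two-condition contrast (e.g. alternative trophic morphs, blocked
by family) and a reference species B assayed as a shared control
against several treatment timepoints — the package asks whether genes
underlying A's plasticity are disproportionately the orthologs of genes
underlying B's plasticity.  The statistic is the count k of one-to-one
ortholog pairs whose members are significant DEGs in both species,
referred to a permutation null in which DEG-sized gene sets are drawn
uniformly without replacement from each species' expression-filtered
universe.  The permutation deliberately ignores the ortholog map when
drawing (genes are sampled from the full filtered universes; the map
only enters when the overlap is recounted): the null hypothesis is
"DEG status is unrelated to cross-species pairing", not "DEGs are
confined to mapped genes".  A map-restricted variant can be built by
passing universes intersected with the mapped genes, but it answers a
different (conditional) question and is not the default.

The empirical p is the fraction of permutations with overlap ≥ k
(one-sided, greater).  Because this estimator can return exactly 0, the
add-one estimator (#{≥ k} + 1)/(n_perm + 1) is always reported
alongside; the plain fraction remains the headline number for
comparability with the permutation-test convention it implements.

### Analytic null moments

For M mapped pairs, draws of n_A from N_A and n_B from N_B, each pair
is jointly selected with probability p = (n_A/N_A)(n_B/N_B), so
E[k] = M·p.  The map is injective, hence two distinct pairs never share
a gene in either species, and the joint inclusion of two pairs factors
into per-species pairwise without-replacement probabilities
q_A = n_A(n_A−1)/(N_A(N_A−1)):

Var[k] = M·p(1−p) + M(M−1)(q_A·q_B − p²).

These moments are verified against exhaustive enumeration of all
C(N_A,n_A)·C(N_B,n_B) outcomes on small instances, and the sampled null
is verified against the same enumeration by total-variation distance.

### DEG classification

Each focal DEG falls into exactly one class: **shared** (its ortholog
is a reference DEG), **not significant** (ortholog tested in B but not
significant), **unaligned** (no ortholog in the map), or **mapped but
untested** (ortholog excluded by B's expression filter or failing to
converge).  The fourth class keeps the partition exhaustive; reports
that fold it into "not plastic" should say so explicitly.  Direction
concordance between the species' fold changes is only evaluated under a
user-declared correspondence of contrast orientations (+1 or −1); the
package never infers which reference condition "corresponds" to which
focal morph.

## Expression units and filter

TPM is computed as count/length rates renormalized to 1e6 per sample;
genes with abundance below 1 TPM are excluded as biologically dubious.
The aggregation rule is configurable (`mean` across samples, default;
`all-samples`; `any-sample`) because "< 1 TPM" underdetermines it; mean
is the least aggressive common reading.  The boundary is inclusive
(exactly 1 TPM is retained).  log2-CPM uses a prior count of 2.0 scaled
proportionally to each library so zeros stay finite and comparable
across depths.  QC ordination is classical (Torgerson) metric MDS on
Euclidean distances over the 500 most variable genes — chosen over
leading-log-fold-change pairwise distances for determinism and
simplicity; eigenvalues at numerical zero are truncated so duplicated
samples coincide exactly.

## Differential expression

The DE test is a fully specified NB-GLM chain rather than a numeric
clone of any reference package; it is validated by calibration, not by
identity of output.

- **TMM factors**: reference sample = closest 75th-percentile count
  fraction to the mean; per sample, precision-weighted mean of M-values
  after trimming 30% by M and 5% by A; factors rescaled to geometric
  mean 1.  A sample sharing no expressed genes with the reference gets
  factor 1 with a warning.
- **Dispersions**: pooled method of moments within condition × block
  cells on counts rescaled to a common effective library size, from
  Var = μ + φμ².  The denominator uses m² − s²/n per cell (the unbiased
  estimate of μ²); without this correction the estimator is biased low
  and the likelihood-ratio test measurably anticonservative.  Raw
  values are floored at 1e-6 and shrunk toward the across-gene median
  with weight prior_df/(prior_df + residual_df), prior_df = 10.
  Genes with degenerate or all-zero cells fall back to the common
  value.
- **GLM fit**: log link, intercept + condition indicator + block
  dummies, offset log(library size × TMM factor).  IRLS vectorized
  across genes (one shared design matrix), ridge 1e-8 on the normal
  equations for separable patterns, step halving on deviance increase,
  convergence at relative deviance change < 1e-8 or 50 iterations.
  Genes all-zero within the contrast are excluded from testing and
  from the BH family; non-convergent genes carry `tested = False` and
  NaN p.
- **Test**: deviance difference between the full model and the model
  without the condition term, referred to χ²(1); two-sided by
  construction, direction from the coefficient sign.  BH adjustment is
  per contrast.  For genes with a separated condition (all zeros in one
  group) the coefficient magnitude is ridge-limited and should not be
  interpreted; the p-value remains valid.

Calibration (recomputed by the test suite and `scripts/acceptance.py`):
a global-null simulation at 2,000 genes, 3+3 samples in each of two
blocks, pooled over 5 seeds, and a power simulation at |log2FC| = 2,
φ = 0.2, 3+3 samples.  The type-I rate sits near the upper half of its
tolerance band — the moment estimator's per-gene noise leaves a small
anticonservative remainder — which is an acknowledged limitation.

## Ortholog mapping

Best hit per query = max bitscore, ties broken by min E-value, then max
percent identity, then lexicographically smallest subject id (fully
deterministic).  Multiple HSPs of one query–subject pair collapse to
the single best HSP; no HSP score summing.  A pair (a, b) is kept iff
each is the other's best hit, which is one-to-one by construction.
Hits are pre-filtered at E ≤ 1e-5 by default (configurable).  Alignment
execution is out of scope: inputs are 12-column outfmt-6-style tables
at whatever identifier level the analysis uses.

## Enrichment

Over-representation uses the hypergeometric upper tail
P[X ≥ k] with X ~ Hypergeom(N = |background|, K = |set ∩ background|,
n = |query|), BH-corrected across sets with overlap ≥ 2 (configurable).
The background defaults to the expression-filtered universe, with the
option to supply an external proteome-style background.  This is a
deterministic offline substitute for web-service enrichment; term lists
from services with live annotation databases and other correction
schemes will differ term-for-term.

## Synthetic data generator

The generator emulates the design the analysis assumes, with these
default study conditions:

| parameter | default | meaning |
|---|---|---|
| n_genes_a / n_genes_b | 4000 / 3810 | gene catalogs (ratio matches ~56% shared, ~24%/~20% private) |
| frac_shared_orthologs | 0.562 | shared fraction of the union catalog |
| samples_a | 2 families × (3+3) | morph contrast with family blocks |
| samples_b | 3 control + 3×3 treatment | three timepoints vs a shared control |
| frac_de_a | 0.30 | truly DE fraction in the focal contrast (about a third of genes, as in strongly divergent morphs) |
| frac_de_b_per_timepoint | 0.02 | truly DE fraction per reference timepoint (an order of magnitude fewer) |
| rho_shared | 0.0 | fraction of DE ortholog pairs forced DE in both species (0 = lineage-specific scenario) |
| logfc_range | (0.8, 3.0) | |log2FC| of planted effects, spanning the magnitudes typical of reported shared DEGs |
| baseline_logmean_params | (4.0, 1.5) | log-normal abundance shape |
| dispersion_params | (0.05, 2.0) | φ(μ) = φ0 + a/μ |
| libsize_cv | 0.2 | log-normal library-size variation |
| frac_low_abundance | 0.10 | genes planted strictly below the 1-TPM filter |
| block_sigma | 0.1 | per-(gene, block) multiplicative log-normal effect |
| prob_concordant | 0.5 | forced shared pairs concordant in sign with this probability |

Baseline abundances are drawn as a log-normal shape rescaled so true
TPMs sum to 1e6 with above-filter genes floored at 2 TPM and
below-filter genes in (0.05, 0.6) TPM — the margin keeps the planted
filter truth recoverable under sampling noise.  Expected counts are
library size × read fraction (TPM × length, normalized) × block effect
× 2^(±log2FC) on treatment-like samples; counts are negative-binomial.
DE genes are drawn stratified by mapped/unmapped status (so the DE rate
among ortholog pairs matches the configured fraction up to rounding)
and only from above-filter genes.  Forced shared pairs are chosen per
timepoint from the mapped focal DE genes; remaining reference DE genes
are drawn uniformly, so chance sharing still occurs at rho_shared = 0 —
that is the null, not a defect.  Hit tables encode true pairs as mutual
best hits with decoy alignments strictly below the true bitscore
(aimed at mapped partners of the other species, so decoys can never
fabricate a reciprocal pair); an optional flag injects exact
bitscore/E-value ties to exercise tie-breaking.  All draws flow from a
single seeded generator.

What the generator does **not** emulate: read-level noise and mapping
ambiguity, transcript isoforms and assembly artifacts, GC/length bias,
correlated gene modules, and dispersion trends estimated from real
data.  Passing calibration on synthetic data therefore shows the
inference chain is internally correct under its own model, not that the
model captures every property of real RNA-seq.

## Reference table

The package ships a 53-row curated table of shared DEGs between the two
spadefoot species' plasticity contrasts (gene symbol, reference
treatment, both log2FCs and p-values, higher-expression sides, repeat
flags), guarded by a SHA-256 checksum.  Its tallies — 5/35/13 rows per
treatment and 46 unique symbols after collapsing the 7 genes recurring
in two treatments — are recomputed, never hard-coded, by
`shared_deg_tallies`.

## Problem sizes and numerical choices

The test suite and acceptance script run at desk scale: 2,000-gene DE
simulations, 10,000-gene universes with 5,000 mapped pairs and 500-gene
DEG sets for overlap calibration (50 replicates per scenario, 400
permutations each), 100,000 draws against exhaustive enumeration on
6-gene universes, and a full pipeline run at the generator's default
4,000/3,810-gene catalogs with 1,000 permutations.  Linear-model means
are clipped at exp(±30); NB deviance uses the Poisson limit below
φ = 1e-10; BH q-values are computed with the step-up minimum and
clipped to [0, 1]; DEG selection uses strict q < threshold, following
the q < 0.05 convention.

## Known limitations

- The DE test's type-I error is mildly anticonservative at small
  sample sizes (see calibration above); quasi-likelihood or
  empirical-Bayes dispersion machinery would tighten it at the cost of
  a far larger specification.
- The permutation p has resolution 1/n_perm; use the add-one estimator
  for downstream arithmetic.
- The RBH map is strictly one-to-one; paralog families and
  many-to-many orthology are out of scope.
- Concordance interpretation depends entirely on the declared condition
  correspondence.
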