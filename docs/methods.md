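# Methods

This note documents the models implemented in `epifst`, the defaults and
why they were chosen, what the synthetic data do and do not emulate, and
the numerical conventions the code relies on.

## Coordinate and format conventions

All internal coordinates are 0-based half-open. Converters sit at every
format boundary: GFF3 (1-based inclusive) and VCF POS (1-based) are
shifted on read; coverage files come in two dialects — `zero_based`
(column 2 already 0-based, as produced by methylation extractors run with
a zero-based flag) and `one_based` — and the dialect is an explicit
argument, never guessed. The percent column of coverage files is ignored
and recomputed from the counts. Tiles are anchored at coordinate 0 of
each chromosome and are non-overlapping (step = tile size = 100 bp);
overlapping tilings are rejected rather than silently supported.

## Weir–Cockerham θ

`fst.wc_theta` implements the 1984 method-of-moments estimator for an
arbitrary number of populations from per-population (nᵢ, pᵢ, hᵢ). Design
choices:

* **Estimator fixed to WC84.** Genotyping pipelines rarely name their
  estimator; WC84 is the de facto standard and has an unambiguous
  published formula that a brute-force oracle can check to 1e−12
  (the test suite does exactly that on 1,000 random instances).
* **Missingness.** Missing genotypes reduce nᵢ per locus per population;
  populations with nᵢ = 0 at a locus are dropped from that locus's
  terms; loci with < 2 informative populations, n̄ ≤ 1, or a zero
  denominator (globally monomorphic) get θ = NaN and are excluded from
  summaries.
* **"Mean F_ST" is ambiguous**, so both the arithmetic mean of per-locus
  θ (the headline number) and the ratio-of-sums Σa/Σ(a+b+c) are always
  reported. For the default design they differ by < 0.001.
* **Gene-level F_ST** is Σa/Σ(a+b+c) over loci in the gene body (2 kb
  upstream through 2 kb downstream): weighting by the component
  denominator is the natural pooled estimator when per-locus weights are
  unspecified. Genes without loci are absent rather than zero-filled.

Locus filters mirror RAD practice: presence ≥ 65 % of individuals in ≥ 2
populations, genome-wide MAF ≥ 0.05 among called alleles, and first SNP
per RAD locus (applied after the other filters, so the retained SNP is
the first *passing* one). The filter is idempotent and can only shrink
the matrix.

## Tiled differential methylation

CpGs with < 10 total reads are dropped ("at least 10" is inclusive).
Per-individual counts are summed within 100-bp tiles; a tile enters a
comparison when ≥ 8 individuals of *each* group have ≥ 1 read in it
("covered" = any post-filter read; the occupancy rule needs an explicit
definition and this is the weakest defensible one, so it retains the most
tiles). Tiling conserves counts exactly — a property test asserts it.

The test statistic is a binomial logistic likelihood-ratio test with a
single group factor on per-individual (methylated, total) counts. With
only a group factor the group MLEs are the coverage-pooled fractions, so
the deviance has a closed form on pooled counts; the implementation is
vectorised over tiles and cross-checked against per-tile GLM fits in a
unit test. No overdispersion correction is applied (matching the default
behaviour of standard tile-testing tools); when a group has a single
member, Fisher's exact test on the pooled 2×2 table is used instead.
p-values are BH-adjusted within each pairwise comparison (one family per
comparison). A DMR requires both |pooled % difference| ≥ 15 points and
q ≤ 0.05; the effect-size gate means arbitrarily deep coverage can never
manufacture a DMR. `meth_diff` uses coverage-pooled group percentages
(not means of per-individual fractions), consistent with pooled-count
testing; the per-individual fractions remain available on the tile
matrix for anyone preferring the other convention. Pairwise comparisons
are oriented focal-group-minus-other, with the focal group recorded, so
hyper/hypo calls have an explicit sign convention.

Sample structure is summarised by Ward linkage on 1 − Pearson
correlation distances over tiles shared by all samples, and by PC scores
from the SVD of the centred fraction matrix. A constant sample vector
makes the correlation undefined and raises an error naming the sample.

## P_ST

For a region with per-individual methylation fractions,

P_ST = (Var_Total − Var_Sub) / Var_Total,

with Var_Total the pooled sample variance (denominator n−1) and Var_Sub
the **unweighted mean of per-population sample variances**. The verbal
definition circulating for this statistic ("subtract the total variance
from the variance within a single population…") contradicts its own
formula; the formula is implemented. "Within a single population" is
read as the pooled mean so a region has one P_ST; per-focal-population
values (Var_Total − Var_pop)/Var_Total are also emitted for
transparency. Negative P_ST values (sampling noise making
Var_Sub > Var_Total) are retained unclipped so means stay unbiased;
Var_Total = 0 makes P_ST undefined and the region is excluded from means
but counted. Fractions entering P_ST are the per-individual pooled tile
fractions after the coverage and occupancy filters. Tile-level P_ST is
the headline summary; gene-level means are emitted too, since "per
locus" reporting is ambiguous between the two.

P_ST is a variance ratio, hence invariant under common affine rescaling
of all fractions — verified by a property test — and is checked against
a direct-summation variance oracle to 1e−12.

## Feature annotation

From GFF3: the first mRNA per gene is used (no isoform resolution);
introns are the gene span minus merged exons; UTR features are used when
present, otherwise the sequence simply stays "exon". Promoter = 2 kb
upstream and downstream = 2 kb after the gene end, both strand-aware and
clipped to chromosome bounds (lengths come from `##sequence-region`
pragmas or an explicit argument). A tile's label is the category of
maximal overlap, ties broken 5′UTR > 3′UTR > exon > intron > promoter >
downstream — a module-level convention, since visualisation tools do not
publish one; zero overlap with any gene-linked category means intergenic
with the nearest gene by midpoint distance. Because exon intervals
contain their UTRs, the precedence makes a tile wholly inside a UTR
label as UTR without interval subtraction.

Random tile sets are uniform over positions with chromosomes weighted by
length; tiles may overlap genes and each other (the null should be the
unconstrained genome); a BED mask hook exists for real genomes with
assembly gaps — synthetic genomes have none. The KS comparison of two
category distributions treats the categories as ordered in the fixed
reporting order and uses the supremum difference of cumulative category
fractions (a two-sample KS on category ordinals, with tile counts as
sample sizes). Applying a KS test to categorical fractions is itself an
interpretation; the per-set fractions are exported so users can build
alternative nulls.

## Salinity profiles

Bins: [0, 3.5), [3.5, 6), [6, 15), [15, 20), [20, ∞) psu — internal
edges upper-exclusive, top bin lower-inclusive, which reconciles "15–20"
with ">20" labels; a day at exactly 20 psu counts as ">20" (documented
convention; whether real gauges were binned that way is unknowable from
labels alone). Same-day replicate measurements are averaged to one daily
value first. The pre-collection window mean uses the `window` calendar
days strictly before the collection date, averages whatever daily values
exist, and reports the number of missing days; an empty window is an
error, not a silent NaN.

## Synthetic-data generators

The generators define the study conditions the package is calibrated
against: 4 populations (sites LC, LF, SL, VB with the K=2 meta-grouping
LC+SL vs LF+VB) of ~20–22 diploids, 1,567 biallelic loci, 100-bp
methylation tiles.

* **Genotypes: Balding–Nichols.** Ancestral frequency p ~ U(0.1, 0.9);
  population frequency ~ Beta(p(1−F)/F, (1−p)(1−F)/F); genotypes
  ~ Binomial(2, p_pop). Chosen because its single parameter F *is* the
  expected θ, making calibration transparent. The default
  F = 1/(1 + 4·Nm) with Nm = 10.625 gives F ≈ 0.0230, the island-model
  equilibrium matching the target divergence. Default missingness is
  10 % (moderate RAD dropout); calibration runs use 0 as their design
  states no missingness. No linkage between loci is simulated.
* **Methylomes: Gaussian-on-fraction hierarchy.** Tile baseline
  μ ~ U(0.3, 0.7); population offset ~ N(0, σ_b); individual fraction
  ~ N(pop mean, σ_w) truncated to [0, 1]; per CpG, depth
  ~ Poisson(30) and methylated reads ~ Binomial(depth, fraction), CpGs
  with zero depth omitted (as in real coverage files). Gaussian noise
  (not Beta) keeps the variance algebra exact away from the boundaries;
  the default base-mean range keeps truncation negligible, and the
  generator warns when any tile's truncation mass exceeds 10 %. The
  default σ_b = 0.0383 with σ_w = 0.10 is the value solving the
  finite-sample expectation
  Var_Total ≈ σ_w² + σ_b²·n(k−1)/(N−1) (n = 20, k = 4, N = 80) for a
  design mean P_ST of 0.10. Depth is Poisson, not negative-binomial:
  overdispersion mainly widens the read-sampling layer, which the P_ST
  calibration deliberately sits below (see limitations).
* **Annotation.** Non-overlapping genes alternating strands, 1–4 exons
  (80–300 bp) with 100–500 bp introns, 5′/3′UTRs inside the terminal
  exons, ≥ 4.2 kb clear flanks so promoter/downstream windows rarely
  collide; infeasible packings are rejected.
* **Salinity.** Daily value = site mean + N(0, σ), floored at 0 psu.

Fixed seeds give byte-identical files; each generator draws from its own
seed stream so adding one does not perturb the others.

**What the generators do not emulate** — and hence what passing tests do
not show about real data: genome-scale CpG density (real RRBS yields
millions of cytosines; tiles here are dense and regular), bisulfite
conversion error, read-level sequence (no FASTQ), linkage disequilibrium,
batch effects, and covariance between methylation and genotype. The
calibration checks show the estimators recover designed parameters under
the assumed models, not that the models capture every property of field
data.

## Problem sizes and numerical choices

The calibration runs use 20 replicate genotype simulations (4 × 22 ×
1,567 loci) and one 5,000-tile methylation simulation — sizes at which
the Monte-Carlo error of the recovered means (≈ 0.0004 for θ, ≈ 0.003
for P_ST across seeds) is well inside the ±0.005 / ±0.02 recovery bands
the package tests against; each completes in seconds. The mean per-tile
P_ST computed from *latent* fractions sits ~0.005–0.01 below the
plug-in design value because the mean of ratios is slightly below the
ratio of means (Jensen effect) — this bias is part of the estimator, not
removed. Computing P_ST from read-sampled fractions instead adds
binomial noise p(1−p)/reads to both variance components and lowers mean
P_ST by a further ~0.01 at the default depth; calibration therefore
targets the fraction layer, while a test covers the read-count path at a
looser tolerance.

Degenerate inputs are errors, not warnings, wherever a silent default
would bias results: single-population θ, empty analysis windows,
constant sample vectors in clustering, overlapping tilings, negative
salinity, exons outside their gene. BH adjustment, KS p-values, exact
tests and GLM cross-checks all come from `scipy`/`statsmodels`; the
package's own statistics (WC84 components, P_ST, the closed-form LRT)
are checked against independent brute-force oracles in the test suite.

## Known limitations

* The binomial LRT without overdispersion is anticonservative for truly
  overdispersed counts; the 15-point effect-size gate absorbs most of
  this in practice (the null false-positive rate in simulation is ~0),
  but a beta-binomial test would be the principled extension.
* The KS-on-category-fractions comparison depends on the category
  ordering; it is a reporting convention, not an inference one.
* Gene bodies overlap when genes sit within 4 kb of each other; loci and
  tiles in the overlap count toward both genes.
* P_ST has no heritability-style scaling (no c/h² adjustment) and no
  mixed-model variance decomposition; it is a descriptive variance
  ratio.
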