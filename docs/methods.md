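# Methods

This note documents the models and procedures implemented in `fibronet`,
the defaults and why they were chosen, what the synthetic-data generators
emulate, and the numerical and design choices made where the problem was
genuinely open.

## Robust correlation and network construction

Pairwise gene similarity is the Tukey biweight midcorrelation. For a vector
x, deviations from the median are weighted by w_i = (1 − u_i²)² with
u_i = (x_i − median)/(9 · mad), mad including the 1.4826 normal-consistency
constant, and weights zero outside |u| < 1; the midcorrelation is the
normalized cross-product of the weighted deviations. A gene whose MAD is
zero (majority-constant expression) falls back to Pearson centering for
that gene only, so a mixed pair is a hybrid estimate; a fully constant gene
has no defined correlation and is reported as 0 with a warning. On clean
Gaussian data the biweight estimate tracks Pearson closely but not exactly
— the smooth weights still vary across points — with typical absolute
differences of order 10⁻³–10⁻² at n = 200. Tests assert closeness at that
honest scale, and the implementation is checked against a literal
transcription of the defining formula.

The network is unsigned, a_ij = |bicor_ij|^β. β is selected by the
scale-free topology criterion: among candidates whose fit R² exceeds 0.8,
the one with the highest mean connectivity wins (smallest β on ties); if
none qualifies the highest-R² candidate is used and flagged. The fit
regresses log10 of the empirical connectivity density on log10 of bin-mean
connectivity over 10 equal-count (quantile) bins. Using the density
count/(N · bin width) rather than a per-bin frequency matters: with
equal-count bins the frequency is constant by construction and carries no
information, whereas the density encodes the distribution shape in the
unequal bin widths.

Topological overlap is
TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i, k_j) + 1 − a_ij), TOM_ii = 1.

## Module detection

Genes are clustered by average linkage on 1 − TOM. A **static** cut at a
quantile of the merge heights replaces the dynamic hybrid tree cut: it is
fully specified, fast, and sufficient for the equicorrelated structures the
package's recovery tests target. The default cut quantile is **0.5**: on
factor-model data the merge-height distribution is strongly bimodal —
within-module merges sit low, background merges pile up near 1 — and the
median lands in the gap between the modes. Cutting near the top of the
height distribution (e.g. at 0.99) places the threshold above the
inter-module merges and collapses everything into one cluster, so a
near-root quantile is unsuitable for module detection even though the same
static-cut idea at 0.99 works well for outlier *sample* removal, where the
outliers are the only high merges. Clusters below `min_size` (default 30;
20 in the bundled demo, scaled to its 200-gene fixtures) join the
unassigned pool. Modules whose eigengenes (first principal component of the
gene-standardized submatrix, sign-oriented to nonnegative mean member
correlation) are closer than the merge height 0.25 in 1 − correlation are
merged iteratively, closest pair first; survivors are relabeled M1..Mk by
decreasing size.

## Trait association (pre-ranked GSEA)

Genes are ranked by the Student-t P value of their Spearman correlation
with the (inverse-normal-transformed, covariate-adjusted) trait, largest P
first, so associated genes sit at the bottom and a trait-associated module
shows a negative enrichment score. The classic (unweighted) running sum
adds 1/N_h at hits and subtracts 1/(N − N_h) at misses; ES is the signed
maximum deviation, with a positive-deviation preference on exact-magnitude
ties. Nulls come from random same-size gene sets (gene-label permutation,
the only option in pre-ranked mode); NES divides ES by the mean |null ES|
of matching sign, the nominal P is the same-sign tail fraction, and the FDR
q pools sign-normalized null NES across sets (ratio of null tail fraction
to observed tail fraction, clipped at 1, with a running minimum enforcing
monotonicity in |NES| within each sign class).

**Known limitation.** Gene-label permutations treat genes as independent. A
co-expressed module moves coherently in any ranking, so its |ES| under a
trait-null is inflated relative to the permutation null and the nominal
type-I error for such modules exceeds 5% (about 20% in our synthetic
experiments). This anti-conservativeness is inherent to pre-ranked GSEA
with correlated sets; results for strongly co-expressed modules should be
read as rankings of evidence rather than calibrated P values. Planted
signals are still separated from nulls by orders of magnitude in q.

## Conservation and differential co-expression

Conservation restricts both species' modules to the one-to-one ortholog
background expressed in both tissues, forms the 2×2 table per module pair,
and applies a one-sided (enrichment) Fisher's exact test, adjusted by
Benjamini–Yekutieli across all pairs (valid under the arbitrary dependence
created by overlapping tables).

Differential co-expression uses the dispersion statistic, the root mean
square of pairwise correlation differences between cohorts over a module's
unordered gene pairs, with biweight midcorrelations. The null resamples
gene sets of identical size from the shared post-filter universe (without
replacement within a set, independently across permutations); all pairwise
cohort correlations over the universe are computed once and cached for
universes up to a few thousand genes. Empirical P = (r + 1)/(n + 1) with r
the number of null dispersions strictly above the observed one (ties count
as non-exceeding), so P is never zero and the floor at 100,000 permutations
is ≈ 10⁻⁵; Bonferroni multiplies by the number of modules in the batch.

The permutation null is exact only when the tested set is exchangeable
with the universe draw. Because correlation estimates at large |ρ| have
smaller sampling variance, a module equally co-expressed in both cohorts
sits *below* the null of decorrelated random sets and the test is
conservative in that regime; type-I calibration is therefore assessed
under the fully exchangeable null (all correlations equal), where the
rejection rate at 0.05 is nominal.

## Network-eQTL mapping

LD blocks are pruned to one representative SNP each — the member with the
highest mean Spearman correlation to the rest of its block, input order
breaking ties — with blockless SNPs appended unchanged.

Each module gene's (standardized) expression is regressed on all pruned
SNPs with Bayesian variable selection: independent Bernoulli(π) inclusion
indicators with π = E(p_g)/p and E(p_g) = 2 expected control points per
gene; included coefficients under a Zellner g-prior with g = n, which
yields a closed-form marginal likelihood
(1+g)^(−k/2) (yᵀy − g/(1+g)·SSR_γ)^(−(n−1)/2) with coefficients and the
residual variance integrated out. The closed form serves two purposes: the
Metropolis–Hastings sampler (add/delete/swap moves chosen uniformly among
feasible ones, exact Hastings ratios, 20% burn-in, single chain) needs only
cheap k×k solves against the precomputed Gram matrix, and an **exact
enumeration over all 2^p models** (p ≤ 15) provides an independent oracle;
the sampler is held to a maximum per-predictor MPPI discrepancy of 0.02 at
50,000 iterations. Zero-variance predictors are excluded and reported at
the prior. MPPI is capped at 1 − 1/(2·n_iter) before conversion to the
Bayes factor (posterior odds over prior odds), and capped entries are
flagged. The per-SNP module summary is the median BF across module genes
plus the count of genes with BF above the call threshold (100); a locus is
called when the median exceeds 100. Replacing the original multi-response
hotspot-sharing sampler with independent per-response selection keeps the
printed prior, the BF conversion and the median-BF summary identical while
making the posterior exactly checkable; a shared-hotspot tier is out of
scope.

Syntenic translation computes the source-haplotype center
(start + (end − start)/2), walks outward from it to the nearest source gene
that has an ortholog (smaller start coordinate on distance ties), takes the
ortholog's center in the target species, and returns a window of
`window_mb` Mb (default 10, ±5) around it, clipped at position 1; all
coordinates 1-based inclusive, with BED output converted to 0-based
half-open on write. Isoform-level cis mapping reruns the sampler inside the
window (π recomputed with the windowed p), tests each isoform at its
highest-MPPI lead SNP with a tie-corrected Kruskal–Wallis across genotype
groups (groups under 2 samples dropped; fewer than 2 groups left ⇒ P = 1,
flagged) and BH-corrects across isoforms. Because the lead SNP is the best
of the window, the null of this test is mildly anti-conservative; the
planted isoform dominates by orders of magnitude in the recovery tests.

## Regulator profiling

Spearman ρ and Student-t P of the regulator against every module gene
(regulator excluded from the targets), BH FDR within cohort across the
module's genes only — matching a correction denominator equal to the module
size. The case/control shift is a two-sided Mann–Whitney U on the two ρ
distributions with the sign of the median difference as direction. The core
set keeps genes with FDR below the threshold (default 0.01) in *every*
patient cohort, by default also positively correlated in each, sorted by
mean ρ.

## Synthetic data: what it emulates, and what it does not

* **Panel** (`generate_genotypes` / `generate_panel_expression`): binary
  strain-distribution-pattern genotypes in LD blocks (identical SNPs within
  a block; block MAF uniform on [0.2, 0.5]; one chromosome per 100 blocks,
  blocks tiled every 50 kb), and expression from a single-factor model per
  module: gene = λ_g·f_m + ε with λ_g ~ U[0.4, 0.9] (co-expressed but not
  collinear), f_m ~ N(0,1) per strain, and the hotspot module's factor
  shifted by effect × dosage. Defaults: 30 strains, 100 blocks, 50-gene
  module, residual sd 0.5.
* **Hotspot effect default 3.0 SD** (factor scale). Under this
  construction the per-gene association the mapper sees is capped by the
  shared N(0,1) factor acting as correlated noise: at n = 30 the per-gene
  R² against dosage cannot support median BF > 100 for effects around
  1.5 SD even with zero residual noise. The default is calibrated so that
  the planted locus is recovered (median BF > 100, no false calls) in at
  least 9 of 10 standard seeds at 4,000 sampler iterations; it is a
  configuration of the test bed, not a claim about real effect sizes.
* **Cohorts** (`generate_case_control`): equicorrelated module via
  gene = √ρ·f + √(1−ρ)·ε, with ρ set per cohort (defaults 0.8 cases / 0.0
  controls) and independent N(0,1) background genes. Every downstream
  statistic touches only pairwise correlations, so the single-factor
  construction is the simplest structure with a tunable co-expression knob.
* **Phenotypes** (`generate_phenotype`): two fibrosis-like traits =
  loading × standardized module eigengene + confounder loading × a
  blood-pressure-like N(0,1) covariate + N(0, 0.3) noise.
* Each generator draws from its own seeded stream (seed plus a generator
  tag), so using one seed across generators never replays the same values.

Not emulated: read-level noise, isoform structure, library-size and batch
effects, LD decay within blocks (blocks are internally identical),
population structure, non-Gaussian expression margins, and correlated
background genes. Passing recovery tests therefore demonstrates the
correctness and calibration of the statistics under their stated models,
not robustness to the full messiness of real RNA-seq cohorts.

## Numerical choices and degenerate inputs

* Expression filtering keeps a gene when it exceeds the threshold in
  max(1, ceil(min_frac · n_samples)) samples (2 of 30 at the 5% default);
  zeros are replaced by the global minimum positive value before log2.
* The inverse-normal transform uses offset (rank − 0.5)/n with average
  ranks for ties at every n (a fixed-offset simplification of qqnorm's
  n-dependent offset switch; the difference is far below the resolution of
  any downstream statistic).
* Outlier-sample removal cuts the sample dendrogram at the 0.99 height
  quantile and keeps the single largest cluster; "small clusters" is
  resolved as everything outside it. By construction at least one sample
  subtree sits above an interior quantile, so the removal list is never
  empty — on homogeneous data it is a stray sample or two, never a
  majority.
* Rank-deficient residualization designs raise an error naming the
  collinear columns (pivoted QR); categorical covariates expand to
  indicator contrasts dropping one level.
* Degenerate correlation inputs (constant genes), empty gene-set
  intersections, zero-variance predictors, and sampler failures per gene
  are warned about and excluded rather than fatal; batch summaries are
  computed over the survivors.
* Module-detection problem sizes in the bundled tests (≈ 200 genes,
  30–100 samples, 100 SNPs, 4,000–50,000 sampler iterations, 500 null
  replicates at 999 permutations) were chosen so the full suite and the
  acceptance script each complete in a few minutes on a single CPU while
  leaving every statistic comfortably inside its calibration tolerance;
  all sizes scale up through function arguments.

## Known limitations

* Pre-ranked GSEA's gene-label null understates the spread for correlated
  sets (see above).
* The dispersion test is conservative for modules that are equally but
  strongly co-expressed in both cohorts relative to a decorrelated
  universe.
* The cis-isoform Kruskal–Wallis at the selected lead SNP carries
  best-of-window selection bias under the null.
* Static-cut module detection has no dynamic-cut refinement; heavily
  nested module structures may need a custom cut quantile.
* Matrices are held dense; the package targets desk-scale problems
  (≲ 20k genes), not genome-scale human panels at hundreds of thousands of
  SNPs.
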