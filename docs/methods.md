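# Methods

`laminapipe` re-implements, as tested and reusable code, the quantitative
analyses behind a mouse cortical-development phenotyping study: laminar
cell-distribution statistics with a spatially adjusted permutation two-way
ANOVA, distribution-comparison tests, gene-set overlap enrichment with a
resampling null, co-expression degree centrality, and dendritic-spine
turnover rates. Every stage runs on synthetic data that emulates the
statistical structure the analyses assume, so the whole pipeline is testable
without access to the original images or sequencing data.

## Laminar distribution statistics

A cortical column is parameterized by depth as a fraction of cortical
thickness, 0 at the ventral boundary and 1 at the pial surface. Per slice,
the column is divided into 20 equal bins; the bin distribution is the
percentage of the slice's cells per bin. Bins are 1-based and half-open,
`[(i-1)/20, i/20)`, with depth 1.0 assigned to bin 20 so that no 21st bin
exists and bins 19–20 abut the marginal zone/pia. Mean laminar position is
`100 * mean(depth)`.

The depth probability density is a Gaussian kernel estimate with boundary
reflection at 0 and 1 (mass that a plain kernel would place outside the unit
interval is folded back), so the estimate integrates to ~1 on the support.
The default bandwidth is Silverman's rule,
`h = 0.9 * min(sd, IQR/1.349) * n^(-1/5)`; an absolute bandwidth in
depth-fraction units can be passed instead. The density's argmax and maximum
are exposed as `mode` and `peak` fields rather than committing to any
particular bar rendering. The empirical CDF is the right-continuous fraction
of depths at or below a position.

Two-group depth comparisons use (a) a permutation test for the difference of
medians, statistic `|median_a - median_b|`, exhaustive over all
`C(n_a+n_b, n_a)` label assignments when that count does not exceed `n_perm`
(exact tail fraction) and random otherwise with the +1 correction
`p = (1 + hits)/(n_perm + 1)`; and (b) the Scholz–Stephens k-sample
Anderson–Darling test (midrank variant, via scipy), whose standardized
p-value is table-interpolated and therefore clipped to [0.001, 0.25]. The
median test permutes at the cell level by default; slice-level inference is
available by feeding per-slice summaries. With more than two groups,
pairwise median tests should be Bonferroni-corrected by the number of pairs.

## Spatially adjusted two-way ANOVA

Bin percentages along a column are spatially ordered, so residuals of the
classical genotype × bin factorial ANOVA can be spatially autocorrelated,
violating the independence assumption. The pipeline:

1. **Classical fit.** OLS factorial model with type-II sums of squares
   (statsmodels), chosen because slice counts per genotype are typically
   unbalanced. The replicate unit is the slice: each slice contributes one
   20-bin profile.
2. **Assumption gates** (all reported regardless of branch): Shapiro–Wilk on
   residuals, Levene across genotype × bin cells, and Moran's I of the
   residuals against chain contiguity weights — bin i adjacent to i±1 within
   each slice, blocks assembled block-diagonally across slices (bins of
   different columns are never neighbors), each row divided by its total.
   `I = (n/S0) * z'Wz / z'z` on mean-centered residuals; significance by
   permutation (999 draws by default, exhaustive when `n! <= n_perm`,
   one-sided for positive autocorrelation; a randomization-assumption normal
   approximation is available). Permutation was preferred over the normal
   approximation because per-column n is small.
3. **Spatial filtering.** If Moran's I is significant at `alpha_gate`
   (default 0.05), the spatial lag model `y = rho*W*y + X*beta + eps` is fit
   by maximum likelihood: rho maximizes the concentrated log-likelihood
   `-n/2 log(RSS(rho)/n) + sum_i log(1 - rho*lambda_i)` over
   `(1/lambda_min + 1e-6, 1 - 1e-6)`, with `lambda_i` the eigenvalues of the
   row-normalized W (computed once per chain block and tiled). The analysis
   then proceeds on the filtered response `y - rho_hat*W*y` with the original
   design — filtering rather than embedding `W*y` as a regressor, because
   the aim is to remove the autocorrelation and then run an ordinary
   factorial analysis. With rho = 0 the filtered response equals y and the
   lag likelihood equals the OLS likelihood, so the pipeline degenerates to
   the classical branch.
4. **Permutation p-values.** If residual normality fails (on real bin
   percentages it essentially always does: bin counts are multinomial, so
   residuals are heteroscedastic and skewed), F-test p-values come from
   restricted permutation. Genotype and interaction effects permute *whole
   slice profiles* across the genotype assignment; the bin main effect
   permutes bin values *within* each slice. The restriction matters: one
   slice's 20 percentages sum to 100 and are negatively correlated, and our
   own calibration showed that unrestricted (cell-level) permutation of the
   response is anti-conservative for the interaction (~0.10 at a nominal
   0.05) precisely because it destroys that compositional dependence,
   whereas slice-level permutation is exact under the slice-exchangeable
   null. With two genotypes and `C(n_slices, n_a) <= n_perm` all assignments
   are enumerated (exact tail fraction); otherwise `n_perm` random draws
   with the +1 correction. Default `n_perm` is 5000 for single analyses; the
   simulation suites use 499 per run to keep hundreds of replicate runs
   tractable.
5. **Post hoc.** Per-bin genotype contrasts (pooled t-test on the classical
   branch, Mann–Whitney when normality failed), Bonferroni-corrected by
   bins × genotype pairs (×20 for two genotypes and 20 bins), computed on
   the filtered response when filtering was applied.

The branch taken (`classical`, `permutation`, `spatial_filtered`,
`spatial_filtered_permutation`) is a deterministic function of the gate
p-values and is recorded in the result, along with rho and all gates.

Numerical conventions: permutation tail comparisons of Moran's I use a 1e-9
rounding resolution so exact ties (the identity permutation, chain
reversals) land in the tail regardless of floating-point summation order;
permutation p-values are never exactly zero (+1 correction, or exact
enumeration including the identity).

## Gene-set overlap enrichment

Identifiers are upper-cased and whitespace-stripped before matching; set
members outside the expressed-gene universe are dropped from computation and
counted in the report. For overlap k of an n-gene DEX list with a K-gene set
in an N-gene universe: the one-sided binomial tail `P(X >= k)`,
`X ~ Binomial(n, K/N)`; the hypergeometric tail `P(X >= k)`,
`X ~ Hypergeom(N, K, n)`; and a resampling null of R (default 1000) random
n-subsets of the universe with `p = (1 + hits)/(R + 1)`. The resampling null
is exactly hypergeometric, so the two converge as R grows (checked at
R = 1e5 to 0.005). One-sided enrichment alternatives only, since the
question is over-representation. Benjamini–Hochberg adjustment is applied to
the binomial p-values (the primary test) across the sets of one report.
A second randomization "way" (also resampling the disease set) adds nothing
beyond the DEX resampling under a fixed universe and is not performed.
Percentages are reported as `100*k/n`, rounded to one decimal for display
with the unrounded value retained.

## Co-expression network

Expression is transformed elementwise as `log2(RPKM + 1)`; all pairwise
Pearson correlations are computed; an edge connects genes with signed
`r >= threshold` (default 0.7 — positive co-expression only, matching
display windows that span 0.5/0.7 to 1). Zero-variance genes are dropped
with a report rather than failing the run, since RPKM matrices routinely
contain silent genes. Degree centrality is the raw neighbor count (node
sizes scale with the count, so no normalization). Display edge weights
rescale r linearly over `[w_min_r, 1]` (default 0.5), clipped to [0, 1].
Columns are treated as exchangeable samples; no within-donor averaging is
attempted.

## Spine turnover

For each dendritic segment with `n_day0` spines at the first imaging
session: formation = `100*n_gained/n_day0`, elimination =
`100*n_lost/n_day0`, net addition = formation − elimination, which holds as
an exact identity. The day-0 count is the denominator for both rates — the
only convention under which the identity is meaningful for the identified
baseline population. Rates are per interval; `interval_days` is carried for
optional per-day rescaling but not applied. Group comparisons first average
segments within animal (animals, never segments, are the replicate unit),
then use a two-tailed t-test or Mann–Whitney according to a per-group
Shapiro–Wilk gate at 0.05.

## Synthetic data

**Columns.** Depths are drawn from a mixture of truncated Gaussians
(rejection-sampled within [0, 1]), one component per laminar band. The
default bands approximate deep-to-superficial marker bands of a mature
somatosensory column — L6 (center 0.20, sd 0.07, weight 0.30), L5 (0.42,
0.06, 0.25), L4 (0.58, 0.04, 0.20), L2/3 (0.78, 0.07, 0.25); the spreads
are free parameters of the generator, not measured quantities. A genotype
shift `delta` (positive toward the pia — the over-migration direction) is
added to every band center, then clipped. The hierarchy is animals within
genotype and slices within animal, with Gaussian random intercepts on
`delta` at both levels. Defaults: 5 animals/genotype × 5 slices = 25
slices/genotype (the published column-replicate scale), 150 cells/slice,
`slice_sd = 0.01`, `animal_sd = 0.0`. Slice-level noise leaves slices iid,
so `delta = 0` data sit exactly under the null of every downstream test
while still exercising the Moran gate. Animal-level noise is deliberately
zero by default: genotype is assigned per animal, and with `animal_sd > 0`
slices are clustered within animals — a dependence the slice-replicate
analyses in scope cannot model, which makes them anti-conservative (our
calibration measured interaction type-I ~0.30 at `animal_sd = 0.01`). The
field stays available for exactly that kind of sensitivity analysis; real
data do carry between-animal variance, so passing calibrations here
demonstrate correctness of the statistics under their own assumptions, not
robustness to animal-level clustering (a mixed-model extension is out of
scope).

**Gene sets.** A universe of N labels, a disease set of K of them, and a
DEX list of n genes whose overlap count is drawn
`Binomial(n, min(1, fold*K/N))`, overlap members sampled from the set and
the rest from outside, giving expected overlap exactly `fold*n*K/N`;
`fold = 1` is the chance null.

**Expression.** Genes sharing a module load on a per-module latent factor
with loading `sqrt(r)` against `sqrt(1-r)` independent noise on the log2
scale (base 4.0, scale 1.5, plus `noise_sd = 0.1` measurement noise), and
`RPKM = max(0, 2^L - 1)`; the clip touches well under 1% of entries at the
defaults, so within-module Pearson correlation of `log2(RPKM+1)`
approximates the target r.

All generators are pure functions of their config (seed included).

What the synthetic data do not emulate: image content, per-layer depth
spreads of any particular marker, ectopic marginal-zone phenotypes,
sequencing-level read counts, donor structure in expression samples, or
animal-level clustering by default (above). Passing tests show the
statistics behave correctly under the stated generative assumptions.

## Problem sizes and defaults used in the validation suites

Calibration of the adjusted ANOVA uses 500 null runs and 200 power runs at
25 slices/genotype, 20 bins, 150 cells/slice, 499 permutations per run.
Spatial-lag recovery uses 100 simulations of 20 slices × 20 bins. The
resampling-vs-hypergeometric check uses R = 1e5 on a 100-gene toy universe.
Exhaustive-oracle checks cover all instances with at most 8 exchangeable
units. Spine power uses 200 simulations of 8 + 6 animals with a planted
+6% net-addition difference (sd 2%).

## Known limitations

- Animal-level clustering is unmodeled by the in-scope tests (see above).
- The Anderson–Darling p-value is clipped to [0.001, 0.25] by the
  standardized approximation's tables.
- The spatial lag model is the only autocorrelation filter offered (no
  spatial-error or CAR/SAR variants, no mixed-effects alternative).
- Mouse-to-human ortholog mapping is out of scope: DEX lists are inputs,
  matched purely by normalized identifier.
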