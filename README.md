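# laminapipe

Statistical pipeline for quantitative cortical-development phenotyping:
laminar cell-distribution statistics with a **spatially adjusted permutation
two-way ANOVA**, distribution-comparison tests, **gene-set overlap
enrichment** with a resampling null, **co-expression degree centrality**,
and **dendritic-spine turnover** rates — plus synthetic-data generators that
emulate the statistical structure of each input, so every stage is testable
end to end without imaging or sequencing data.

It is written for neurodevelopment labs that quantify where neurons sit in
a cortical column (e.g. migration phenotypes of knockout mice), relate
differentially expressed genes to curated disease gene sets, and track
dendritic spines longitudinally.

## The statistics at the core

**Laminar distributions.** Each cell's depth in a cortical column is a
fraction of cortical thickness (0 = ventral boundary, 1 = pia). Per slice,
the column is split into 20 equal bins and the bin distribution is the
percentage of cells per bin; mean laminar position, a boundary-reflected
kernel density, and the empirical CDF summarize the same depths. Groups are
compared with a permutation test for medians (exhaustive when feasible) and
the k-sample Anderson–Darling test.

**Spatially adjusted ANOVA.** Bin percentages are spatially ordered, so the
genotype × bin factorial ANOVA first gates its assumptions: Shapiro–Wilk
and Levene, plus Moran's I of the residuals, I = (n/S₀)·z′Wz∕z′z, against
row-normalized chain contiguity weights (bin i ↔ i±1 within a slice). If
Moran's I is significant, the spatial lag model y = ρWy + Xβ + ε is fit by
maximum likelihood (concentrated log-likelihood with log|I − ρW| from the
eigenvalues of W) and the analysis proceeds on the filtered response
y − ρ̂Wy. If residual normality fails — on multinomial bin percentages it
essentially always does — F-test p-values come from restricted permutation:
whole slice profiles are permuted across genotype assignments (a slice's 20
percentages sum to 100 and must travel together), with Bonferroni per-bin
post hoc contrasts.

**Enrichment.** Overlap k of an n-gene DEX list with a K-gene set in an
N-gene universe is tested with the one-sided binomial tail P(X ≥ k),
X ~ Binomial(n, K/N), the hypergeometric tail, and a resampling null of R
random n-subsets; p-values are Benjamini–Hochberg adjusted across sets.

**Networks.** Pairwise Pearson correlation on log2(RPKM + 1); an edge where
signed r ≥ 0.7; degree centrality is the raw neighbor count.

**Spine turnover.** Per segment: formation = 100·gained/day-0 count,
elimination = 100·lost/day-0 count, net addition = formation − elimination
(exact identity). Groups are compared at the animal level with a
normality-gated t / Mann–Whitney test.

See `docs/methods.md` for assumptions, defaults, and design decisions.

## Worked example

Simulate columns with a +0.05 depth-fraction shift planted in the KO
genotype (25 slices per genotype, 150 cells per slice), then run the laminar
and spatial-ANOVA stages:

```python
import laminapipe as lp

cfg = lp.ColumnSimConfig(genotype_shifts={"WT": 0.0, "KO": 0.05}, seed=42)
cells = lp.gen_columns(cfg)
profiles = lp.bin_profiles(cells)

wt = cells[cells.genotype == "WT"]["depth_fraction"]
ko = cells[cells.genotype == "KO"]["depth_fraction"]
print(f"mean laminar position  WT: {lp.mean_laminar_position(wt):.1f}%  "
      f"KO: {lp.mean_laminar_position(ko):.1f}%")
med = lp.median_position_test(wt, ko, n_perm=9999, seed=0)
print(f"median permutation test: |Δmedian| = {med.statistic:.4f}, p = {med.p_value:.4g}")

res = lp.adjusted_anova(profiles, n_perm=4999, seed=0)
print(f"branch: {res.branch}  (shapiro p = {res.shapiro_p:.2g}, moran p = {res.moran_p:.3g})")
print(f"interaction: F = {res.F_interaction:.2f}, p = {res.p_interaction:.4g}")
sig = res.posthoc[res.posthoc.p_bonferroni < 0.05]
print(f"bins shifted after Bonferroni: {sorted(sig['bin'])}")
```

Output:

```
mean laminar position  WT: 47.4%  KO: 51.8%
median permutation test: |Δmedian| = 0.0395, p = 0.0001
branch: permutation  (shapiro p = 4.1e-05, moran p = 0.998)
interaction: F = 21.91, p = 0.0002
bins shifted after Bonferroni: [1, 2, 3, 4, 6, 8, 10, 12, 13, 14, 15, 18, 19, 20]
```

The planted +5% pial shift is recovered by the mean positions (47.4% →
51.8%), the median test rejects at its resolution floor, residual normality
fails (multinomial percentages), so the interaction p-value comes from
slice-level permutation; the post hoc flags the bins that gained or lost
cells.

The same stages are available from the shell:

```bash
laminapipe simulate --out cells.csv --seed 42 --shift 0.05
laminapipe laminar --cells cells.csv --out profiles.tsv
laminapipe spatial-anova --profiles profiles.tsv --n-perm 4999 --seed 0 --out anova.json
laminapipe run --out-dir demo/            # full pipeline on synthetic data
```

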