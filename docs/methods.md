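# Methods

This note documents the statistical models implemented in `panelgwas`, the
assumptions behind them, what the synthetic-data generator does and does not
emulate, and the numerical choices that were genuinely open.

## Trait model and scales

The phenotype throughout is a binomial proportion: of `n` flies in a
replicate vial, `d` die within a fixed window after enteric infection, and
`p = d/n` is the proportion dead.  All parametric analyses use the angular
(variance-stabilizing) transform `y = arcsin(sqrt(p))`, under which the
binomial sampling noise of a replicate is approximately homoscedastic with
variance `1/(4n)` regardless of `p`.  The rank-based association test uses
raw proportions; being rank-based it is invariant to this (or any strictly
monotone) transform.

## Heritability (quantgen)

Replicate-level angular values follow the two-level random-effects model

    Y_ij = mu + L_i + R_ij + eps_ij,
    L ~ N(0, V_L), R ~ N(0, V_R), eps ~ N(0, V_eps).

With one measurement per replicate, `V_R` and `V_eps` are confounded; the
estimate reports their sum (flagged `residual_confounded`).  Because panel
lines are near-homozygous inbreds, the additive genetic variance among
outbred genotypes is taken as half the between-line variance, `V_A = V_L/2`,
and the heritable component is `H = V_A / (V_A + V_E)` with
`V_E = V_R + V_eps`.

The primary fit is REML (statsmodels `MixedLM`); a method-of-moments
estimator from the one-way ANOVA mean squares,
`V_L = (MS_between - MS_within)/k_bar` with `k_bar` the effective replicate
count, is the documented fallback and serves as an independent oracle (the
two agree to within 5% on balanced designs, and exactly in the interior).
Negative moment estimates are truncated at zero and flagged, keeping
`H in [0, 1]`.

On simulated data the *true* environmental variance includes the binomial
layer: `V_E = V_rep + V_res + 1/(4 n_flies)` on the angular scale.  The
generator's truth record uses this expression, so recovery tests compare
like with like.  Default recovery designs use 140 lines x 3 replicates x
100 flies, with `V_rep + V_res + 1/(4*100) = 0.02` so that `V_L = 0.04`
gives H = 0.5 exactly and `V_L = 0.0626` gives H = 0.61.

## Diallel combining abilities (diallel)

A full diallel crosses all ordered parent pairs including selfs and
reciprocals.  The fixed-effects Method-1 (Griffing-type) model for the
angular cell mean of dam i x sire j is

    y_ij = mu + g_i + g_j + s_ij + r_ij

with constraints `sum g = 0`, `s` symmetric with zero row sums, `r`
antisymmetric.  On a complete design this is the *orthogonal* decomposition
of the cell-mean matrix: the antisymmetric part is `r`, the symmetric part
splits into grand mean, additive row+column structure (`g`) and the
remainder (`s`).  Consequently estimates are closed-form, fitted values
reproduce cell means exactly, and the GCA/SCA/reciprocal sums of squares are
additive (`SS_G = 2pr * sum g^2`, `SS_S = r * sum s^2`,
`SS_R = r * sum rec^2`, df `p-1`, `p(p-1)/2`, `p(p-1)/2`).  F tests use the
within-cell replicate mean square.  Empty cells are imputed iteratively from
the additive sub-model (the saturated terms carry no information across
cells) with a logged note; replicate imbalance uses the harmonic-mean cell
count.  With `model="no_reciprocals"` the antisymmetric variation is pooled
into the residual, which equals fitting the full model to
reciprocal-averaged data.

## Rank-based permutation GWAS (gwas)

Variants whose 1-based closed intervals share at least one base on the same
chromosome are merged transitively into locus groups; a line's composite
allele is the concatenation of its member alleles.  Lines missing any member
call are excluded from that group only.  Composite alleles carried by fewer
than `min_allele_count` (default 10) lines are excluded, and groups
retaining fewer than two alleles are dropped.

Per group, replicate proportions are pooled by allele (the `line_mean` unit
is available) and compared with the tie-corrected Kruskal-Wallis statistic;
the asymptotic p-value is the upper chi-square tail on `#alleles - 1` df.
Tie correction is always applied because binomial proportions tie often.

Significance calibration permutes the line-to-phenotype assignment: whole
replicate sets move together, preserving the within-line correlation that
exists under the null of no genotype effect.  The same `B` permutations are
shared by all loci; the per-locus permutation p uses the +1 Monte-Carlo
correction, `(1 + #{p_b <= p_obs}) / (B + 1)`.  The FDR at threshold `t` is
the mean permuted hit count divided by the observed hit count, capped at 1
(NaN when nothing is observed); the threshold grid includes 1e-5 and 2e-5.

When every line is present in a group, the permutation scan uses a fast
path: pooled ranks are computed once, per-line rank sums are permuted as
vectors, and H follows from group rank sums — permutations then cost
matrix products rather than re-ranking.  Groups with excluded lines fall
back to per-permutation re-ranking.

Per-locus variance explained is the OLS R^2 of angular line means on the
allele factor (`SS_model/SS_total`) with its F test; a one-line-per-allele
design is flagged saturated.

## Multi-locus regression and the Beavis effect (multisnp)

`forward_select` is greedy forward selection of locus groups entered as
categorical factors: at each step the candidate with the smallest partial-F
p-value given the current model enters, stopping at `p_enter`, `max_k`, or
saturation.  Candidates are residualized against an orthonormal basis of
the current design, so single-column (biallelic) candidates are evaluated
for all loci at once; perfectly collinear candidates get partial p = 1.
The reported raw R^2 path equals the joint OLS refit to 1e-10.

`beavis_scan` exposes small-sample effect-size inflation: for each sample
size in a grid (default 70..140) it draws `m = 100` line subsamples without
replacement, reruns the selection, and records the selected model's raw
R^2.  For this scan the selector holds the model size fixed (`max_k = 6`,
no entry threshold) so that R^2 differences across sample sizes reflect
estimation and selection-on-noise rather than differential power; with a
stringent entry threshold the power loss at small n masks the inflation.
The resulting mean R^2 decreases with sample size and levels off as the
true jointly-explained variance is approached.

## Expression preprocessing and differential expression (expression)

RPKM per transcript is `count * 1e9 / (length * library_size)`; gene level
is the unweighted mean over the gene's transcripts.  Variance ranking and
PCA default to `log2(x + 1)` (configurable `raw`); on raw RPKM, distances
and covariances are dominated by a handful of high-abundance genes, which
is why the log scale is the default.  PCA treats samples as observations
and centres genes; unit-variance scaling is off by default.

The differential-expression stage is a deliberately simple stand-in for
moderated pipelines: library-size normalization to the mean library,
`log2(x + 1)`, per-gene (optionally line-paired) t tests,
Benjamini-Hochberg adjustment, and a pass flag requiring both adjusted
p <= `adj_p_max` and |fold change| >= `min_fold`.  It shares the contrast
and thresholding logic of moderated pipelines but not their empirical-Bayes
variance shrinkage, so per-gene power at very small n is lower.

## Co-expression modules (mmc)

Similarity is the absolute Spearman correlation with average ranks.  With
`n` samples the null distribution of `|r|` between independent genes is
approximately half-normal with mean `r0 = sqrt(2/pi)/sqrt(n-1)` (~0.21 at
n = 16) and s.d. `sqrt((1-2/pi)/(n-1))` (~0.16).  Because this background
is large at 16 samples, the clustering graph is built from the *excess*
correlation: `W = max(|r_s| - r0, 0)^s` over a sharpness grid
`s in {1..10}`, and the partition with maximal Newman modularity on its own
graph is kept.  The default optimizer is the Leiden algorithm
(leidenalg/igraph); recursive spectral bisection with Kernighan-Lin
single-node refinement is retained as `optimizer="spectral"`.  In testing,
recursive bisection systematically under-refined large matrices (planted
20-gene modules were absorbed into 100+-gene communities), which motivated
the Leiden default.

Modularity assigns *every* gene to some community, so community membership
alone is not evidence of co-expression.  Reported modules are therefore
trimmed to coherent cores: genes are removed, worst first, until every
member's mean |r| to the rest reaches `r0 + 2 sd_null`; cores smaller than
`min_size` (default 15) are pooled into the unassigned set.  On
structureless data this reports no modules.  A genuine limitation at 16
samples: among thousands of background genes, subsets with mean |r| above
the bar exist by chance, so some reported modules on large matrices are
spurious coherence — exactly why the evaluation layer below exists.
Modules with true within-correlation much below ~0.6 fall under the bar
and will be missed at this sample size.

`module_separation_test` asks whether a module's expression separates the
class x treatment groups: the observed statistic is the one-way F of the
four groups on PC1 scores of the module's genes, and the null is built by
shuffling sample labels (PCA itself is label-independent, so only F is
recomputed), with the +1-corrected permutation p over 10,000 shuffles by
default.  `module_variance_explained` summarizes a module by its eigengene
(PC1 score, sign-anchored to correlate positively with the module's mean
expression), restricted to unchallenged samples by default, averaged per
line, and regressed against angular line-mean phenotypes.  With `n` lines
the null expectation of this R^2 is `1/(n-1)` — about 0.14 at n = 8 — so
small-panel values must be read against that inflation.

## Synthetic data (simulate)

* **Panel genotypes**: homozygous lines; per-locus minor-allele frequency
  uniform on `maf_range`; linkage is block-copy (each non-anchor locus in a
  block copies the anchor's allele indicator with probability `ld_decay`,
  else redraws), which supplies correlated markers without genealogy.  A
  fraction of loci receive a low-frequency third allele (non-SNP label).
  Loci are laid out non-overlapping by default; overlap-grouping is
  exercised with purpose-built fixtures.
* **Phenotypes**: line liability = `mu` + additive QTL effects + polygenic
  `N(0, V_line_extra)`, all on the angular scale so the analysis model is
  exactly correct; replicates add `N(0, V_rep + V_res)`; death counts are
  binomial.  Liabilities are clamped to `[0, pi/2]` (logged; negligible at
  the default operating point `mu = arcsin(sqrt(0.5))`).  The truth record
  stores realized line effects, per-QTL variance, and expected components
  including the binomial term.
* **Diallel**: effects are projected onto the identifiable space (centred
  GCA, zero-row-sum symmetric SCA, antisymmetric reciprocal) and the
  projected truth is returned, so exact-recovery tests are well-posed.
* **Expression**: 2 classes x 2 treatments x `n_lines_per_class` lines, one
  sample per line x treatment (16 samples at the default 4).  Module genes
  load on a shared latent factor (`sqrt(rho)` loading gives pairwise
  correlation `rho`); class/treatment shifts displace the latent mean in
  its s.d. units; values are exponentiated (log-normal).  Not emulated:
  count noise, gene-length effects, library-size variation, batch
  structure — so passing tests demonstrate estimator correctness under the
  assumed model, not robustness to those artefacts.

## Problem sizes and runtime choices

Recovery and calibration tests run at the design points above (140 x 3
panels, 8 x 8 diallels, 2000-gene/16-sample expression, 100-500 locus
scans) with permutation counts of 200-1000 and simulation counts of
20-500 per check, chosen so the full suite completes in minutes on one
CPU while leaving Monte-Carlo error well inside the asserted margins.
Null-clustering checks use 500-gene matrices; the planted-module recovery
runs at the full 2000 genes.

## Numerical notes

* Permutation p-values never return 0 (the +1 correction); FDR estimates
  are capped at 1.
* Kruskal-Wallis with all-identical measurements returns H = 0, p = 1
  rather than erroring.
* Variance-ranking ties at the top-k boundary break lexicographically by
  gene id (logged).
* All generators and permutation routines take explicit integer seeds and
  are bit-reproducible given them; CLI subcommands with randomness require
  `--seed` and log it.
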