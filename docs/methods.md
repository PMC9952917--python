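# Methods

## Data model

A study is a long-format table of Cq measurements — one row per technical
replicate of a (sample, assay) reaction — plus per-sample metadata
(experiment E1–E9, sex, control/DSS group, DSS concentration and duration,
duration of inflammation, histology category, fixation time) and an assay
registry (mRNA vs miRNA, reference vs target). Cycle limits default to 45
cycles for mRNA assays and 40 for miRNA assays; a reaction that never
crosses threshold within the limit is *undetermined*.

Technical duplicates are merged by arithmetic mean (median by config). The
merge never drops data: a replicate pair whose SD exceeds the discordance
threshold (default 0.5 cycles — a deliberate, conservative choice; half a
cycle is a ~40% quantity discrepancy) is flagged, not removed. Undetermined
entries are excluded per (sample, assay) by default, with counts reported
per assay; censoring at the cycle limit is available but opt-in, because a
censored value fabricates a lower bound the downstream statistics would
treat as real.

## Standard-curve efficiency

Cq is regressed (OLS) on log₁₀(relative input), where a dilution series
with factor *f* puts step *s* at log₁₀ input = −s·log₁₀ f. Efficiency
`E = 10^(−1/slope) − 1`; the pass window is 90–110% and linearity requires
R² ≥ 0.98 (squared Pearson correlation of the fit). Triplicate reactions
are averaged per dilution step before fitting (fitting on raw replicates is
a config option; on symmetric replicate noise the two give the same line).
Efficiency is invariant to adding a constant to all Cq and to relabeling
which step is "undiluted" — both are translations in the regression.
Failing assays are annotated, never silently removed, since an
out-of-window assay may still be reportable with caveats.

## Descriptive stability

Per gene and stratum (e.g. control/DSS, or group × sex): geometric mean
`exp(mean(ln Cq))`, arithmetic mean, min, max, median, dispersion, and
CV% = 100·SD/mean. Genes are ranked by dispersion within each stratum
(ties: lower CV%, then name); dispersion > 1 cycle marks a gene as
inconsistently expressed. Two dispersion conventions are provided: the
sample SD (n−1 denominator; the default, matching the plain reading of
"standard deviation of the Cq values") and the mean absolute deviation
from the arithmetic mean, which is what the original BestKeeper spreadsheet
computes. Validation against published per-stratum tables should compare
both, since the two differ by ~20% on normal data. A consensus rank (mean
of per-stratum ranks) is offered as a convenience summary and labeled as
such. The pairwise-correlation / BestKeeper-index machinery of the original
tool is out of scope: only the descriptive SD ranking is used here.

## Model-based stability

Within group *g*, the Cq of gene *i* in sample *j* is modeled as

    y_igj = α_ig + β_gj + ε_igj,   ε_igj ~ N(0, σ²_ig)

— a gene-by-group mean, a sample effect shared by all genes (total RNA
amount/quality of the sample), and gene- and group-specific noise.

**Intragroup variance.** Residuals come from two-way centering (exact in
one pass on complete data; alternated to convergence under missingness).
With `S_ig` the mean squared residual of gene *i* (n_g − 1 denominator),

    E[S_ig] = σ²_ig (k − 2)/k + σ̄²_g / k

for *k* genes, because every sample effect is estimated from all genes.
Hence `σ̄²_g = Σ_i S_ig/(k − 1)` and the unbiased estimate
`σ̂²_ig = max(0, (S_ig − σ̄²_g/k) · k/(k − 2))`. This is why at least three
genes are required: at k = 2 the correction is undefined.

**Intergroup deviation.** `d_ig` is the doubly centered gene × group mean
(centered across genes within group and across groups within gene), so a
systematic group difference shared by all genes — which any normalization
would cancel — contributes nothing. Deviations are therefore measured
*relative to the panel consensus*; a panel whose genes have very
heterogeneous treatment effects has no absolute "unaffected" gene, only a
least-deviating one. The deviations are shrunken empirical-Bayes style,
`d̃ = d·γ²/(γ² + v)`, with sampling variance `v_ig = σ̂²_ig/n_g` and
between-gene deviation variance
`γ̂² = max(0, Σ d²/((k−1)(G−1)) − mean(v))`, so a noisily measured gene
cannot fake a large systematic deviation.

**Stability value.** `ρ_i = mean_g [ |d̃_ig| + √v_ig ]`, lower = more
stable. The noise penalty is deliberately the *unshrunken* intragroup
standard error: an earlier formulation penalizing with the posterior SD
`√(v·γ²/(γ²+v))` is bounded by γ and therefore *rewards* noise whenever
γ̂² is small — a very noisy or heavily censored gene could rank first,
which no sensible stability measure should allow.

**Best pair.** For a pair, deviations average, noise variances average
with halving (`(v_i + v_j)/4`, the variance of a mean of two independent
errors), and the deviation prior halves (γ²/2); the best combination is
found by exhaustive search over all pairs. Ranking ties break
lexicographically, deterministically.

**Degenerate modes.** With no grouping, stability reduces to √σ̂²_i, a
pure noise ranking. Missing entries are excluded pairwise with per-gene n
reported (complete-case by subsetting beforehand). Stability is invariant
to per-gene location shifts and to the global sign of the input, so Cq can
be used directly (lower Cq = more transcript) without converting to
log-expression.

The whole estimator is pinned in the test suite against a brute-force
oracle that fits the same two-way model by explicit least squares on a
dummy design and applies the same variance corrections through explicit
loops, to 1e−8.

## Relative expression and group comparison

Combined reference Cq is the arithmetic mean of the scheme's assay Cq
values (equivalently, the geometric mean of linear-scale quantities — the
standard multi-reference normalization factor). ΔCq = target − combined
reference; relative quantity `2^(−ΔCq)` assumes 100% efficiency;
an efficiency-corrected base (1 + E) per assay can be supplied from the QC
stage. Fold change between groups is `2^(−ΔΔCq)` with ΔΔCq the difference
of group-mean ΔCq — the ratio of group geometric means, chosen over the
mean of per-sample quantities (available by config) because it is exactly
antisymmetric under swapping the contrast. A sample missing any scheme
assay is excluded for that scheme and reported.

Group comparisons use the two-sided Mann–Whitney U test: exact by full
enumeration of the null distribution when the pooled sample is ≤ 12 and
tie-free, otherwise the normal approximation with tie and continuity
corrections. Stars follow closed thresholds (p = 0.05 earns \*). No
multiple-testing correction is applied, matching the analysis style this
pipeline reproduces; interpret star counts accordingly.

## Factor influence (PCA + PLS)

The design matrix one-hot codes every categorical factor over its full
level set (experiment ×9, sex ×2, histology ×6) and takes numeric factors
as single columns (DSS concentration, DSS duration, inflammation
duration) — 20 factor/factor-level columns for the default design — then
centers and unit-variance-scales everything. Full one-hot blocks are kept
deliberately: the redundancy is harmless to PCA/PLS and keeps each level's
loading interpretable. Constant columns are dropped with a warning.

PCA of the scaled design measures randomization: with perfectly balanced
uncorrelated factors every component explains an equal share, so the
number of components needed for 96% / 99.9% cumulative explained variance,
compared to the column count, measures design collinearity.

PLS (NIPALS, via scikit-learn) predicts the response — absolute Cq or ΔCq
under a scheme, centered and scaled — from the design. Q² = 1 − PRESS/TSS
over K-fold cross-validation (folds by seeded permutation; default 7
folds). The component count defaults to the largest number whose addition
improves Q² by more than 0.01, reported in every output. R² and Q² are
invariant to affine rescaling of the response, so scaled- and raw-space
values coincide. The permutation test (default 100 permutations, minimum
20) refits the model on scrambled responses; the model passes when both
R² and Q² exceed the 95th percentiles of their null distributions — a
concrete operationalization of "better than the scrambled pairing".

Per-factor influence is read from regression-coefficient-space loadings
(stable under component count, unlike per-component weights, which are
available in verbose output). Each cross-validation submodel contributes
one coefficient vector, sign-aligned to the full-model fit; the jackknife
mean and SD per factor are normalized so the squared means sum to 1, and a
factor is significant when SD ≤ |mean|. Near-zero full-model coefficients
make the sign alignment ambiguous; these are flagged, not errored.
Scheme comparisons ("absolute" vs one or more normalizations) are fitted
on the intersection of samples usable under every scheme, so loadings are
directly comparable.

## Synthetic-data generator

The generator draws, per sample and gene,

    Cq = baseline + dss_effect·[DSS] + sex_effect·[male]
       + shared_u_e + u_{gene,e} + histology_slope·severity + ε

with duplicates adding independent N(0, replicate_sd) noise and latent Cq
beyond the censor cycle becoming undetermined. Defaults emulate the
study's structure: 117 samples over 9 experiments (E1–E4 female-only,
E5 = 9F + 6M, E6–E9 male-only; 20 control = 10F + 10M, 97 DSS = 47F + 50M;
exact per-experiment allocation is a documented choice where the source
design is only partially known), gene baselines and dispersions on the
scale of the archived-FFPE summary statistics, male-shifted expression
(2–4 cycles), DSS effects on several references, and strongly
DSS-responsive targets (negative Cq shifts).

Two experiment-effect components exist by design: a *shared* per-experiment
shift common to all genes (block/run quality; SD 0.8 cycles by default),
which normalization can remove, and *gene-specific* per-experiment draws
(SD 0.2–0.5), which it cannot. This is what makes normalization reduce —
but never eliminate — inter-experiment influence in the PLS stage, and it
is the one place the generator deliberately couples genes.

The TBP-like assay (baseline 34.2, +4 cycles in males, noise SD 1.8,
censor at 41 cycles — above the observed maximum of expressed values,
below the 45-cycle protocol limit) yields a handful of undetermined,
almost exclusively male samples per study. The per-study count is smaller
than the archived study's 16/117 because a Gaussian latent scale cannot
produce that censoring rate while keeping the mean of *expressed* values
near 34; fidelity of the expressed-scale statistics was preferred.

Severity is coded ordinally for generation only (normal 0, mild 1,
moderate 2, severe/erosion/heterogeneous 3); the analysis side always
treats histology as categorical. Histology categories for DSS samples are
drawn (30/30/20/10/10% for mild/moderate/severe/erosion/heterogeneous);
DSS concentration (2–3%) and duration (4–6 d) are drawn once per
experiment; inflammation duration per sample from {0, 2, 7, 14, 30, 60,
90} days. Everything is reproducible bit-for-bit from (config, seed).

What the generator does *not* emulate: right-skewed/bimodal Cq
distributions (everything is conditionally Gaussian), fixation-time or
storage effects on Cq, plate/batch structure within experiments,
correlated noise between genes beyond the shared components, and
RNA-degradation chemistry. Passing recovery tests therefore show that the
estimators recover *this* model's truth at these effect sizes — not that
real FFPE data meet the model's assumptions.

## Problem sizes and numerical choices

Simulation-based tests use 100–200 seeded replicates of small instances
(3–5 genes, 20–117 samples) and the acceptance script uses 50-replicate
recovery runs — sizes chosen so the whole suite runs in a couple of
minutes while keeping Monte-Carlo error a few percent. Stochastic
procedures (CV folds, permutations, generators) take explicit integer
seeds and are deterministic given them. Variance estimates are floored at
zero; γ̂² = 0 reduces the stability to the pure noise ranking. All-equal
inputs give U = n₁n₂/2 and p = 1 in the rank test rather than an error.

## Known limitations

* The model-based stability ranking discriminates weakly at the minimum
  panel size (k = 3): every gene's deviation is estimated relative to a
  3-gene consensus, so one noisy gene perturbs all deviations. Recovery of
  a known most-stable gene at k = 3 plateaus around 90% per-replicate even
  at 20 samples/group; larger panels sharpen it quickly.
* BestKeeper-style SD ranking ignores grouping entirely; a gene with a
  clean group response can out-rank a noisier but group-neutral gene.
* The PLS loading SDs come from jackknifing cross-validation submodels —
  a reconstruction of the convention used by the commercial software
  family this stage mirrors, not a uniquely defined quantity.
* Exact Mann–Whitney p-values are only used for tie-free pooled samples
  ≤ 12; beyond that the corrected normal approximation is standard but
  approximate.
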