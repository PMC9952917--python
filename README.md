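# refstab

Reference-gene stability scoring and normalization-impact analysis for
RT-qPCR Cq data from designed animal experiments.

Relative quantification by qPCR stands or falls with the reference
("housekeeping") genes used for normalization: an unstable reference
propagates its own biological and technical variation into every ΔCq value.
`refstab` implements the full evaluation workflow for candidate reference
genes in a multi-experiment rodent study — here modeled on archived FFPE
colon samples from DSS-induced colitis experiments in mice, with mRNA and
miRNA assay panels — and quantifies how the *choice* of reference scheme
changes both the fold changes one reports and the influence that
experimental design factors retain over the normalized signal.

## What it computes

**Standard-curve efficiency QC.** Cq regressed on log₁₀(relative input)
over a serial dilution; amplification efficiency `E = 10^(−1/slope) − 1`,
pass window 90–110%, linearity pass at R² ≥ 0.98.

**Descriptive (BestKeeper-style) stability.** Per gene and stratum:
geometric/arithmetic mean, min/max/median, SD and CV% of the raw Cq; genes
ranked by SD, with SD > 1 cycle flagged as inconsistently expressed.

**Model-based (NormFinder-style) stability.** Per group, the sample × gene
Cq matrix is decomposed as `y_igj = α_ig + β_gj + ε_igj` (gene-by-group
mean, shared sample effect, gene-specific noise with variance σ²_ig). The
stability value of gene *i* averages over groups

    |d_ig · γ²/(γ² + σ̂²_ig/n_g)| + √(σ̂²_ig/n_g)

where `d_ig` is the doubly centered intergroup deviation of the gene's
group mean, shrunken by its sampling variance (γ² is the estimated
between-gene deviation variance). Lower is more stable. The best two-gene
combination is found by exhaustive pair search with averaged deviations and
halved noise.

**ΔCq relative expression.** Combined reference Cq = arithmetic mean of the
scheme's assays; `ΔCq = Cq_target − Cq_ref`, relative quantity `2^(−ΔCq)`,
group fold change `2^(−ΔΔCq)`, two-sided Mann–Whitney U tests with
significance stars (\* p ≤ 0.05, \*\* p ≤ 0.01, \*\*\* p ≤ 0.001).

**Factor-influence analysis.** Experimental metadata (experiment E1–E9,
sex, DSS concentration and duration, duration of inflammation, histology
category) are coded into a centered, unit-variance design matrix
(20 factor/factor-level columns for the default design). PCA of the design
measures randomization quality; PLS models predict absolute Cq or ΔCq from
the factors, validated by R², cross-validated Q² and a response-permutation
test. Per-factor loadings (jackknifed over cross-validation submodels,
normalized so squared means sum to 1, non-significant when SD > |mean|)
quantify each factor's influence and how normalization changes it.

**Synthetic studies.** A seeded generator reproduces the study structure —
117 samples (20 control: 10F/10M; 97 DSS: 47F/50M) across 9 experiments,
5 + 4 reference and 2 + 2 target assays, technical duplicates, and a
TBP-like high-Cq assay whose censoring ("Undetermined") is male-enriched —
with truth records for recovery testing.

## Worked example

```bash
refstab all --seed 1 --out-dir out/
```

runs simulate → replicate merge → undetermined handling → per-stratum
descriptive stability → model-based stability → per-scheme fold changes and
tests → design PCA → per-scheme PLS influence, and prints a consolidated
summary. With seed 1 the mRNA panel gives

```
stability:  RPLP0 0.116 < EEF2 0.147 < PPIA 0.261 < NONO 0.329 < TBP 0.376
best pair:  (EEF2, RPLP0), combined stability 0.100
```

so EEF2/RPLP0 is the best two-gene normalization factor — each alone is
good, and their residual intergroup deviations partially cancel. TNFR1 is
upregulated in the DSS group: fold change 10.2 under EEF2/RPLP0
normalization (U = 27, p = 8.9·10⁻¹², \*\*\*) versus 13.1 under the less
stable single reference PPIA — the reference scheme visibly moves the
reported effect size. The design PCA needs 13 of 20 components to reach
96% of factor variance (sample randomization is good but not ideal), and
the PLS stage shows what normalization buys: the absolute-Cq model
(R² 0.83, Q² 0.75) carries a summed experiment-factor loading of 1.33,
which drops to 1.00 under EEF2/RPLP0 normalization — inter-experiment
influence is reduced, but not eliminated, because each gene also has
experiment-specific variation the references cannot share.

The same analyses are available as a library, e.g.

```python
from refstab import GeneratorConfig, generate_study, NormFinderStability

table = generate_study(GeneratorConfig(), seed=1).analysis_table()
wide = table.wide()
groups = table.meta_frame().loc[wide.index, "group"]
nf = NormFinderStability().fit(wide[["EEF2", "TBP", "NONO", "PPIA", "RPLP0"]], groups)
print(nf.best_gene_, nf.best_pair_, nf.best_pair_stability_)
```

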