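"""Seeded generator of synthetic Cq studies with the archived-FFPE design.

The default configuration emulates a 117-sample, 9-experiment DSS-colitis
study: 20 control samples (10 female / 10 male) and 97 DSS samples (47 F /
50 M), with experiments E1-E4 female-only, E5 mixed (9 F + 6 M) and E6-E9
male-only. The assay panel carries 5 mRNA and 4 miRNA candidate reference
genes plus 2 + 2 target assays, with baselines and dispersions on the scale
of the archived-FFPE Cq summary statistics.

Latent model per sample s and gene g::

    Cq = baseline_g + dss_effect_g * [DSS]
       + sex_effect_g * [male]
       + shared_u_{e(s)}            (study-wide per-experiment shift,
                                     common to all genes; removable by
                                     normalization)
       + u_{g, e(s)}                (gene-specific per-experiment draw;
                                     NOT removable by normalization)
       + histology_slope_g * severity(s)
       + eps_{gs},    eps ~ N(0, noise_sd_g)

Each technical duplicate adds independent N(0, replicate_sd) noise. A
latent Cq beyond the class censor cycle (default 41 for mRNA assays, 39 for
miRNA) yields an undetermined measurement — with the default TBP-like
parameters this censoring is strongly male-enriched, because of the large
male shift of that assay.

Severity is coded ordinally for the generator only (normal=0, mild=1,
moderate=2, severe=3, erosion=3, heterogeneous=3); the analysis side always
treats histology as categorical. Regenerating with the same (config, seed)
reproduces the study bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import hashlib
import json
from typing import Sequence

import numpy as np
import pandas as pd

from .cq_data import AssayInfo, CqTable, SampleMeta, merge_replicates, handle_undetermined

__all__ = [
    "GeneParams",
    "ExperimentArm",
    "GeneratorConfig",
    "SyntheticStudy",
    "generate_study",
    "analytic_marginal_sd",
    "recovery_suite",
    "DEFAULT_GENE_PANEL",
    "DEFAULT_DESIGN",
    "SEVERITY_CODE",
]

SEVERITY_CODE = {
    "normal": 0, "mild": 1, "moderate": 2, "severe": 3, "erosion": 3, "heterogeneous": 3,
}


@dataclass(frozen=True)
class GeneParams:
    """Generating parameters for one assay (all effect units: cycles)."""

    assay_id: str
    assay_class: str  # "mRNA" | "miRNA"
    role: str  # "reference" | "target"
    baseline_cq: float  # female control intercept
    dss_effect: float = 0.0
    sex_effect: float = 0.0  # added for males
    experiment_effect_sd: float = 0.0  # gene-specific per-experiment draw
    histology_slope: float = 0.0  # cycles per severity step
    noise_sd: float = 0.5


@dataclass(frozen=True)
class ExperimentArm:
    """Sample counts for one (experiment, sex) arm."""

    experiment: str
    sex: str
    n_control: int
    n_dss: int


#: E1-E4 female-only, E5 mixed 9F/6M, E6-E9 male-only; totals 20 control
#: (10 F + 10 M) and 97 DSS (47 F + 50 M).
DEFAULT_DESIGN: tuple[ExperimentArm, ...] = (
    ExperimentArm("E1", "female", 2, 10),
    ExperimentArm("E2", "female", 2, 10),
    ExperimentArm("E3", "female", 2, 10),
    ExperimentArm("E4", "female", 2, 10),
    ExperimentArm("E5", "female", 2, 7),
    ExperimentArm("E5", "male", 2, 4),
    ExperimentArm("E6", "male", 2, 12),
    ExperimentArm("E7", "male", 2, 12),
    ExperimentArm("E8", "male", 2, 11),
    ExperimentArm("E9", "male", 2, 11),
)

DEFAULT_GENE_PANEL: tuple[GeneParams, ...] = (
    # mRNA candidate references
    GeneParams("EEF2", "mRNA", "reference", 25.8, 0.4, 2.3, 0.30, 0.05, 0.60),
    GeneParams("TBP", "mRNA", "reference", 34.2, 0.2, 4.0, 0.50, 0.20, 1.80),
    GeneParams("NONO", "mRNA", "reference", 28.6, 0.9, 1.9, 0.50, 0.15, 0.90),
    GeneParams("PPIA", "mRNA", "reference", 25.9, 0.6, 3.2, 0.50, 0.10, 1.00),
    GeneParams("RPLP0", "mRNA", "reference", 25.5, 0.2, 3.2, 0.40, 0.05, 0.80),
    # mRNA targets (upregulated in colitis: negative Cq shift)
    GeneParams("TNFR1", "mRNA", "target", 30.5, -1.8, 1.5, 0.40, -0.40, 0.80),
    GeneParams("TNFR2", "mRNA", "target", 31.0, -1.5, 1.5, 0.40, -0.35, 0.80),
    # miRNA candidate references
    GeneParams("miR-191-5p", "miRNA", "reference", 28.3, 0.05, 0.4, 0.20, 0.00, 0.45),
    GeneParams("miR-103a-3p", "miRNA", "reference", 28.4, 0.50, 0.5, 0.25, 0.05, 0.50),
    GeneParams("miR-16-5p", "miRNA", "reference", 26.3, 0.05, 0.4, 0.20, 0.00, 0.45),
    GeneParams("U6", "miRNA", "reference", 26.9, 0.60, 0.3, 0.40, 0.10, 0.90),
    # miRNA targets
    GeneParams("miR-181a-5p", "miRNA", "target", 27.5, -1.0, 0.4, 0.30, -0.25, 0.50),
    GeneParams("miR-223-3p", "miRNA", "target", 28.0, -2.0, 0.4, 0.30, -0.40, 0.50),
)


@dataclass
class GeneratorConfig:
    design: tuple[ExperimentArm, ...] = DEFAULT_DESIGN
    genes: tuple[GeneParams, ...] = DEFAULT_GENE_PANEL
    replicate_sd: float = 0.15
    n_replicates: int = 2
    #: study-wide per-experiment shift common to all genes (FFPE block /
    #: run-quality differences between experiments)
    shared_experiment_sd: float = 0.8
    censor_cycle: dict = field(default_factory=lambda: {"mRNA": 41.0, "miRNA": 39.0})
    histology_probs: dict = field(
        default_factory=lambda: {
            "mild": 0.3, "moderate": 0.3, "severe": 0.2, "erosion": 0.1, "heterogeneous": 0.1,
        }
    )
    #: DSS dose (%) and duration (days) choices, drawn once per experiment
    dss_concentrations: tuple[float, ...] = (2.0, 2.5, 3.0)
    dss_durations: tuple[float, ...] = (4.0, 5.0, 6.0)
    #: days of water after DSS, drawn per DSS sample
    inflammation_durations: tuple[float, ...] = (0.0, 2.0, 7.0, 14.0, 30.0, 60.0, 90.0)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class SyntheticStudy:
    cq_table: CqTable  # raw (unmerged) duplicates
    truth: dict
    seed: int
    config: GeneratorConfig

    def analysis_table(self, policy: str = "exclude") -> CqTable:
        """Replicate-merged table with the undetermined policy applied."""
        merged = merge_replicates(self.cq_table)
        table, _ = handle_undetermined(merged, policy)
        return table


def generate_study(config: GeneratorConfig | None = None, seed: int = 0) -> SyntheticStudy:
    """Draw one synthetic study (metadata + duplicate Cq measurements)."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    experiments = sorted({arm.experiment for arm in config.design})
    hist_cats = list(config.histology_probs)
    hist_p = np.array([config.histology_probs[c] for c in hist_cats], float)
    hist_p = hist_p / hist_p.sum()

    # per-experiment treatment settings and effects
    exp_conc = {e: float(rng.choice(config.dss_concentrations)) for e in experiments}
    exp_dur = {e: float(rng.choice(config.dss_durations)) for e in experiments}
    shared_u = {e: float(rng.normal(0, config.shared_experiment_sd)) for e in experiments}
    gene_u = {
        (g.assay_id, e): float(rng.normal(0, g.experiment_effect_sd))
        for g in config.genes
        for e in experiments
    }

    meta: dict[str, SampleMeta] = {}
    sample_rows = []
    idx = 0
    for arm in config.design:
        for group, n in (("control", arm.n_control), ("DSS", arm.n_dss)):
            for _ in range(n):
                idx += 1
                sid = f"S{idx:03d}"
                if group == "control":
                    hist, conc, dur, infl = "normal", 0.0, 0.0, 0.0
                else:
                    hist = str(rng.choice(hist_cats, p=hist_p))
                    conc = exp_conc[arm.experiment]
                    dur = exp_dur[arm.experiment]
                    infl = float(rng.choice(config.inflammation_durations))
                meta[sid] = SampleMeta(
                    sample_id=sid, experiment=arm.experiment, sex=arm.sex,
                    group=group, dss_concentration=conc, dss_duration=dur,
                    inflammation_duration=infl, histology=hist,
                    fixation_time=float(rng.integers(1, 4)),
                )
                sample_rows.append(sid)

    assays = {
        g.assay_id: AssayInfo(g.assay_id, g.assay_class, g.role) for g in config.genes
    }
    limits = {"mRNA": 45.0, "miRNA": 40.0}
    rows = []
    for sid in sample_rows:
        m = meta[sid]
        sev = SEVERITY_CODE[m.histology]
        for g in config.genes:
            latent = (
                g.baseline_cq
                + g.dss_effect * (m.group == "DSS")
                + g.sex_effect * (m.sex == "male")
                + shared_u[m.experiment]
                + gene_u[(g.assay_id, m.experiment)]
                + g.histology_slope * sev
                + rng.normal(0, g.noise_sd)
            )
            censored = latent > config.censor_cycle[g.assay_class]
            for rep in range(1, config.n_replicates + 1):
                if censored:
                    rows.append(dict(sample_id=sid, assay_id=g.assay_id,
                                     replicate=rep, cq=np.nan, undetermined=True))
                else:
                    cq = latent + rng.normal(0, config.replicate_sd)
                    cq = min(cq, limits[g.assay_class])  # protocol ceiling
                    rows.append(dict(sample_id=sid, assay_id=g.assay_id,
                                     replicate=rep, cq=float(cq), undetermined=False))
    table = CqTable(pd.DataFrame(rows), meta, assays)
    truth = dict(
        shared_experiment_effects=shared_u,
        gene_experiment_effects={f"{g}|{e}": v for (g, e), v in gene_u.items()},
        dss_effects={g.assay_id: g.dss_effect for g in config.genes},
        sex_effects={g.assay_id: g.sex_effect for g in config.genes},
        config_hash=config.config_hash(),
        seed=seed,
    )
    return SyntheticStudy(cq_table=table, truth=truth, seed=seed, config=config)


def analytic_marginal_sd(config: GeneratorConfig, gene: GeneParams) -> float:
    """Marginal SD of one gene's merged Cq implied by config + design.

    Composes the fixed-effect spread over the design (group, sex, expected
    histology severity) with the random components (shared and gene-specific
    experiment effects, sample noise, replicate noise reduced by merging).
    Censoring is ignored, so genes that censor appreciably deviate.
    """
    sev_vals = np.array([SEVERITY_CODE[c] for c in config.histology_probs])
    p = np.array(list(config.histology_probs.values()), float)
    p = p / p.sum()
    sev_mean = float(p @ sev_vals)
    sev_var = float(p @ sev_vals**2 - sev_mean**2)
    means, cond_vars = [], []
    for arm in config.design:
        for group, n in (("control", arm.n_control), ("DSS", arm.n_dss)):
            dss = group == "DSS"
            mu = (
                gene.baseline_cq
                + gene.dss_effect * dss
                + gene.sex_effect * (arm.sex == "male")
                + gene.histology_slope * (sev_mean if dss else 0.0)
            )
            cv = (gene.histology_slope**2 * sev_var) if dss else 0.0
            means.extend([mu] * n)
            cond_vars.extend([cv] * n)
    means = np.array(means)
    var = (
        float(means.var())
        + float(np.mean(cond_vars))
        + config.shared_experiment_sd**2
        + gene.experiment_effect_sd**2
        + gene.noise_sd**2
        + config.replicate_sd**2 / config.n_replicates
    )
    return float(np.sqrt(var))


def recovery_suite(
    config: GeneratorConfig | None = None,
    seeds: Sequence[int] = range(50),
    stable_gene: str | None = None,
    target: str = "TNFR1",
    reference_assays: tuple[str, ...] = ("EEF2", "RPLP0"),
    null_gene: str | None = None,
) -> dict:
    """Parameter-recovery report over seeded replicates of a study.

    Reports the fraction of replicates in which ``stable_gene`` (default:
    the reference gene with the smallest analytic stability proxy) ranks
    first under both stability algorithms, the log2 bias of the estimated
    DSS fold change of ``target`` under the given reference scheme against
    the generating truth, and — if ``null_gene`` names a reference with zero
    DSS effect — the type-I rate of the Mann-Whitney wrapper on that gene's
    raw Cq at alpha = 0.05.
    """
    from .bestkeeper import BestKeeperStability
    from .normfinder import NormFinderStability
    from .normalization import ReferenceScheme, relative_expression, fold_change, mann_whitney

    config = config or GeneratorConfig()
    target_class = next(g.assay_class for g in config.genes if g.assay_id == target)
    # stability is only comparable within one assay class (one chemistry)
    refs = [
        g for g in config.genes
        if g.role == "reference" and g.assay_class == target_class
    ]
    if stable_gene is None:
        proxy = {
            g.assay_id: np.hypot(g.noise_sd, g.experiment_effect_sd)
            + abs(g.dss_effect) / 2 + abs(g.sex_effect) / 2
            for g in refs
        }
        stable_gene = min(proxy, key=proxy.get)
    ref_ids = [g.assay_id for g in refs]
    # generating DSS-vs-control Cq shift per gene: treatment effect plus the
    # expected histology-severity contribution (controls have severity 0)
    sev_vals = np.array([SEVERITY_CODE[c] for c in config.histology_probs])
    p = np.array(list(config.histology_probs.values()), float)
    sev_mean = float((p / p.sum()) @ sev_vals)
    shift = {
        g.assay_id: g.dss_effect + g.histology_slope * sev_mean for g in config.genes
    }
    true_ddcq = shift[target] - float(np.mean([shift[a] for a in reference_assays]))
    scheme = ReferenceScheme("recovery", tuple(reference_assays))

    bk_first, nf_first, log2_err, null_rejections = [], [], [], []
    for seed in seeds:
        study = generate_study(config, seed=seed)
        table = study.analysis_table()
        wide = table.wide()
        meta = table.meta_frame().loc[wide.index]
        bk = BestKeeperStability().fit(wide[ref_ids])
        bk_first.append(bk.ranking_["all"][0] == stable_gene)
        nf = NormFinderStability().fit(wide[ref_ids], meta["group"].to_numpy())
        nf_first.append(nf.best_gene_ == stable_gene)
        rel = relative_expression(table, target, scheme)
        fc = fold_change(rel, meta["group"], ("DSS", "control"))
        log2_err.append(np.log2(fc) - (-true_ddcq))
        if null_gene is not None:
            vals = wide[null_gene]
            cmp = mann_whitney(
                vals[meta["group"] == "DSS"].dropna(),
                vals[meta["group"] == "control"].dropna(),
            )
            null_rejections.append(cmp.p_value <= 0.05)
    out = dict(
        stable_gene=stable_gene,
        bestkeeper_rank1_fraction=float(np.mean(bk_first)),
        normfinder_rank1_fraction=float(np.mean(nf_first)),
        fold_change_log2_bias=float(np.mean(log2_err)),
        n_replicates=len(list(seeds)),
    )
    if null_gene is not None:
        out["null_gene_type1_rate"] = float(np.mean(null_rejections))
    return out
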