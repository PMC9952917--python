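"""End-to-end orchestration: load/generate -> QC -> stability -> normalization
-> multivariate influence, with a consolidated JSON + TSV report bundle.

The pipeline configuration is a flat YAML mapping (unknown keys rejected).
Every stochastic stage records its seed; identical (config, seed) reruns
reproduce the bundle byte-identically.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bestkeeper import rank_by_sd
from .cq_data import CqTable, read_cq_table, AssayInfo
from .efficiency import classify_assays, fit_standard_curve, read_standard_curves
from .influence import build_design, influence_comparison, pca_randomization
from .normalization import ReferenceScheme, group_contrast
from .normfinder import normfinder_stability
from .simulate import GeneratorConfig, generate_study
from .cq_data import merge_replicates, handle_undetermined

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

_KNOWN_KEYS = {
    "cq_path", "meta_path", "curves_path", "layout", "simulate", "seed",
    "undetermined_policy", "sd_convention", "group_field", "schemes",
    "contrast", "targets", "pls_folds", "pls_permutations", "pls_components",
    "factors", "out_dir", "discordance_sd_threshold", "dilution_factors",
}


@dataclass
class PipelineConfig:
    """Validated pipeline settings (flat key/value YAML)."""

    cq_path: str | None = None
    meta_path: str | None = None
    curves_path: str | None = None
    layout: str = "long"
    simulate: bool = True
    seed: int = 0
    undetermined_policy: str = "exclude"
    sd_convention: str = "sample"
    group_field: str = "group"
    schemes: dict = field(
        default_factory=lambda: {
            "EEF2/RPLP0": ["EEF2", "RPLP0"],
            "PPIA": ["PPIA"],
            "NONO": ["NONO"],
        }
    )
    contrast: tuple[str, str] = ("DSS", "control")
    targets: tuple[str, ...] = ("TNFR1", "TNFR2")
    pls_folds: int = 7
    pls_permutations: int = 100
    pls_components: int | str = "auto"
    factors: tuple[str, ...] = (
        "experiment", "sex", "dss_concentration", "dss_duration",
        "inflammation_duration", "histology",
    )
    out_dir: str = "refstab_out"
    discordance_sd_threshold: float = 0.5
    dilution_factors: dict = field(default_factory=dict)


def load_config(path_or_mapping) -> PipelineConfig:
    """Load + schema-validate a config; unknown keys are a hard error."""
    if isinstance(path_or_mapping, (str, Path)):
        with open(path_or_mapping) as fh:
            data = yaml.safe_load(fh) or {}
    else:
        data = dict(path_or_mapping)
    unknown = set(data) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**data)
    if isinstance(cfg.contrast, list):
        cfg.contrast = tuple(cfg.contrast)
    if isinstance(cfg.targets, list):
        cfg.targets = tuple(cfg.targets)
    if isinstance(cfg.factors, list):
        cfg.factors = tuple(cfg.factors)
    return cfg


def _validate_schemes(cfg: PipelineConfig, assays: dict[str, AssayInfo]) -> dict[str, ReferenceScheme]:
    out = {}
    for name, refs in cfg.schemes.items():
        missing = [a for a in refs if a not in assays]
        if missing:
            raise ValueError(f"scheme {name!r} uses unknown assays {missing}")
        out[name] = ReferenceScheme(name, tuple(refs))
    return out


def run_pipeline(config: PipelineConfig | dict | str, out_dir: str | None = None) -> dict:
    """Execute every stage and write the report bundle; returns the summary.

    Stage order: load/generate -> replicate merge -> undetermined handling
    -> efficiency QC (if curves provided) -> per-stratum descriptive
    stability -> model-based stability (+ best pair) -> per-scheme relative
    expression and contrasts -> design PCA -> per-scheme PLS influence.
    Any stage error aborts with the stage name; completed outputs are kept.
    """
    cfg = config if isinstance(config, PipelineConfig) else load_config(config)
    out = Path(out_dir or cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "seed": cfg.seed,
        "versions": {"refstab": __version__, "python": platform.python_version()},
    }
    stage = "load"
    try:
        if cfg.simulate or cfg.cq_path is None:
            gen_cfg = GeneratorConfig()
            study = generate_study(gen_cfg, seed=cfg.seed)
            raw = study.cq_table
            summary["config_hash"] = study.truth["config_hash"]
        else:
            raw, _ = read_cq_table(
                cfg.cq_path, cfg.meta_path, _infer_assays(cfg), layout=cfg.layout
            )
        schemes = _validate_schemes(cfg, raw.assays)

        stage = "merge_replicates"
        merged = merge_replicates(raw, discordance_sd_threshold=cfg.discordance_sd_threshold)

        stage = "handle_undetermined"
        table, excl = handle_undetermined(merged, cfg.undetermined_policy)
        excl.to_csv(out / "undetermined_report.tsv", sep="\t", index=False)
        summary["n_samples"] = len(table.meta)
        summary["n_undetermined"] = int(excl["n_undetermined"].sum()) if len(excl) else 0

        stage = "efficiency_qc"
        if cfg.curves_path:
            curves = read_standard_curves(cfg.curves_path, cfg.dilution_factors)
            qc = classify_assays([fit_standard_curve(c) for c in curves])
            qc.to_csv(out / "efficiency_qc.tsv", sep="\t", index=False)
            summary["efficiency_qc"] = {
                r["assay_id"]: r["flags"] for _, r in qc.iterrows()
            }

        stage = "bestkeeper"
        refs_mrna = [a for a, i in table.assays.items()
                     if i.role == "reference" and i.assay_class == "mRNA"]
        refs_mirna = [a for a, i in table.assays.items()
                      if i.role == "reference" and i.assay_class == "miRNA"]
        bk_frames = []
        for genes, label in ((refs_mrna, "mRNA"), (refs_mirna, "miRNA")):
            if len(genes) >= 2:
                df = rank_by_sd(table, genes, ("group",), cfg.sd_convention)
                df.insert(0, "panel", label)
                bk_frames.append(df)
        bk = pd.concat(bk_frames, ignore_index=True)
        bk.to_csv(out / "bestkeeper.tsv", sep="\t", index=False)
        summary["bestkeeper_most_stable"] = {
            f"{row.panel}/{row.stratum}": row.assay_id
            for _, row in bk[bk["rank"] == 1].iterrows()
        }

        stage = "normfinder"
        nf_summary = {}
        for genes, label in ((refs_mrna, "mRNA"), (refs_mirna, "miRNA")):
            if len(genes) >= 3:
                nf = normfinder_stability(table, genes, cfg.group_field)
                nf.report().to_csv(out / f"normfinder_{label}.tsv", sep="\t")
                nf_summary[label] = {
                    "best_gene": nf.best_gene_,
                    "best_pair": list(nf.best_pair_),
                    "best_pair_stability": nf.best_pair_stability_,
                    "stability": {g: float(v) for g, v in nf.stability_.items()},
                }
        summary["normfinder"] = nf_summary

        stage = "relative_expression"
        contrasts = []
        for target in cfg.targets:
            for name, sch in schemes.items():
                cmp = group_contrast(table, target, sch, cfg.group_field, cfg.contrast)
                contrasts.append(
                    dict(target=target, scheme=name, fold_change=cmp.fold_change,
                         u=cmp.u_statistic, p=cmp.p_value, stars=cmp.stars,
                         n_a=cmp.n_a, n_b=cmp.n_b)
                )
        cdf = pd.DataFrame(contrasts)
        cdf.to_csv(out / "contrasts.tsv", sep="\t", index=False)
        summary["contrasts"] = contrasts

        stage = "pca_randomization"
        design = build_design(table.meta_frame(), cfg.factors)
        pca = pca_randomization(design)
        summary["pca"] = {
            "total_factor_count": pca.total_factor_count,
            "n_components_96pct": pca.n_components_at(0.96),
            "n_components_999pct": pca.n_components_at(0.999),
        }

        stage = "pls_influence"
        target = cfg.targets[0]
        pls_schemes: dict = {"absolute": None}
        pls_schemes.update(schemes)
        reports = influence_comparison(
            table, target, pls_schemes, cfg.factors,
            n_components=cfg.pls_components, n_folds=cfg.pls_folds,
            n_perm=cfg.pls_permutations, seed=cfg.seed,
        )
        pls_summary = {}
        loading_rows = []
        for label, rep in reports.items():
            pls_summary[label] = {
                "r2": rep.r2, "q2": rep.q2, "n_components": rep.n_components,
                "permutation_passed": rep.permutation["passed"],
                "experiment_loading_sum": rep.summed_loading("experiment="),
            }
            fl = rep.factors.reset_index(names="factor")
            fl.insert(0, "scheme", label)
            loading_rows.append(fl)
        pd.concat(loading_rows, ignore_index=True).to_csv(
            out / "pls_loadings.tsv", sep="\t", index=False
        )
        summary["pls_influence"] = {"target": target, "models": pls_summary}
    except Exception as exc:  # annotate the failing stage, keep partial outputs
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    with open(out / "run_log.txt", "w") as fh:
        fh.write(f"refstab {__version__} seed={cfg.seed}\n")
        fh.write(f"config={json.dumps(asdict(cfg), default=str, sort_keys=True)}\n")
    return summary


def _infer_assays(cfg: PipelineConfig) -> dict[str, AssayInfo]:
    # When reading external data the registry comes from the scheme/target
    # lists: scheme members are references, configured targets are targets.
    assays: dict[str, AssayInfo] = {}
    for name, refs in cfg.schemes.items():
        for a in refs:
            assays[a] = AssayInfo(a, "miRNA" if a.lower().startswith(("mir", "u6", "let")) else "mRNA", "reference")
    for t in cfg.targets:
        assays[t] = AssayInfo(t, "miRNA" if t.lower().startswith(("mir", "u6", "let")) else "mRNA", "target")
    return assays
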