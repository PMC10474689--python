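"""Pipeline orchestration: config, staged execution, report rendering.

Stages run in the order the analysis requires: read inputs, concordance QC,
INFO filtering, relatedness pruning, PRS scoring for every weight set,
PCA, residualization, weight-set evaluation, liability analyses, decile
analysis, age GLM, bootstrap.  Every stage writes its outputs before the
next begins, and the final JSON report carries a manifest (seed, config
hash, package version) so a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import flags_to_binary
from .io import (
    read_dosage_vcf,
    read_genotype_vcf,
    read_phenotype_table,
    read_weight_table,
)
from .prs import PcaConfig, compute_pcs, compute_prs, kinship_and_prune, select_pca_variants
from .qc import QCConfig, af_correlation, dosage_correlation, filter_by_info, intersect_pairs, write_concordance_report
from .stats import (
    age_glm,
    auc_with_ci,
    bootstrap_auc_removal,
    carrier_percent,
    decile_analysis,
    evaluate_weight_sets,
    fisher_2x2,
    mann_whitney,
    spearman,
)
from .synth import (
    ImputationNoiseParams,
    LiabilityParams,
    PopulationParams,
    simulate_cohort,
    write_cohort,
)

logger = logging.getLogger(__name__)

FH_TASKS = ("fh_bc_first", "fh_bc_any", "fh_anycancer_any")


@dataclass
class PipelineConfig:
    """All paths and thresholds for a pipeline run.

    Threshold defaults are the analysis defaults throughout the package:
    imputation-quality cut 0.8, PCA MAF 0.05 / HWE 1e-6 / LD r2 0.1 in 1 Mb,
    10 PCs, kinship 0.125, 10,000 bootstrap replicates.
    """

    dosage_vcf: str = ""
    truth_vcf: str = ""
    weights: list[str] = field(default_factory=list)
    phenotypes: str = ""
    panel_af: str = ""
    output_dir: str = "famprs_out"
    info_threshold: float = 0.8
    maf_min: float = 0.05
    hwe_p_min: float = 1e-6
    ld_r2_max: float = 0.1
    ld_window_bp: int = 1_000_000
    n_pcs: int = 10
    kinship_threshold: float = 0.125
    n_boot: int = 10_000
    seed: int = 0
    simulate: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**known)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not (0 <= self.info_threshold <= 1):
            raise ValueError("info_threshold must lie in [0, 1]")
        PcaConfig(
            maf_min=self.maf_min,
            hwe_p_min=self.hwe_p_min,
            ld_r2_max=self.ld_r2_max,
            ld_window_bp=self.ld_window_bp,
            n_pcs=self.n_pcs,
        )
        if self.kinship_threshold <= 0:
            raise ValueError("kinship_threshold must be positive")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")

    def pca_config(self) -> PcaConfig:
        return PcaConfig(
            maf_min=self.maf_min,
            hwe_p_min=self.hwe_p_min,
            ld_r2_max=self.ld_r2_max,
            ld_window_bp=self.ld_window_bp,
            n_pcs=self.n_pcs,
        )

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("output_dir")  # where results land does not affect them
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed: crc32 of the stage name mixed with the global seed."""
    return (zlib.crc32(stage.encode()) ^ (global_seed * 2654435761)) % (2**31 - 1)


def cmd_simulate(config: PipelineConfig) -> dict[str, Path]:
    """Generate a synthetic cohort fixture directory from config.simulate."""
    sim = dict(config.simulate)
    pop = PopulationParams(**sim.get("population", {}))
    noise = ImputationNoiseParams(**sim.get("imputation_noise", {}))
    liab = LiabilityParams(**sim.get("liability", {}))
    weight_specs = sim.get("weight_sets")
    cohort = simulate_cohort(
        pop, noise, liab, seed=stage_seed(config.seed, "simulate"),
        weight_specs=weight_specs,
    )
    out = Path(config.output_dir)
    paths = write_cohort(cohort, out)
    logger.info("simulated cohort written to %s", out)
    return paths


def _require(path: str, what: str) -> Path:
    p = Path(path)
    if not path or not p.exists():
        raise FileNotFoundError(f"{what} not found: {path!r}")
    return p


def cmd_run(config: PipelineConfig, until: str | None = None) -> dict:
    """Run the analysis battery; returns the report dict (also written).

    ``until`` stops after a checkpoint: "qc" (concordance + INFO filter),
    "score" (raw PRS per weight set), "adjust" (PC residualization),
    "analyze" (everything but the bootstrap), None (full run).  Every stage
    writes its outputs before the next begins, so later stages can be
    re-run from a completed earlier checkpoint's directory.
    """
    if until not in (None, "qc", "score", "adjust", "analyze"):
        raise ValueError(f"unknown checkpoint: {until!r}")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "manifest": {
            "famprs_version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
        }
    }

    # --- read ------------------------------------------------------------
    dosages = read_dosage_vcf(_require(config.dosage_vcf, "dosage VCF"))
    truth = read_genotype_vcf(_require(config.truth_vcf, "truth VCF"))
    pheno = read_phenotype_table(_require(config.phenotypes, "phenotype table"))
    weight_sets = [read_weight_table(_require(w, "weight table")) for w in config.weights]
    if not weight_sets:
        raise ValueError("no weight tables configured")

    # --- concordance QC ---------------------------------------------------
    qc_cfg = QCConfig(info_threshold=config.info_threshold)
    pairs = intersect_pairs(dosages, truth)
    qc = {}
    for group in (None, "info", "maf"):
        rep = dosage_correlation(pairs, group_by=group, config=qc_cfg)
        name = group or "overall"
        write_concordance_report(
            rep, out / f"concordance_{name}.tsv", out / f"concordance_{name}.json"
        )
        qc[name] = rep.summary.to_dict(orient="records")
    report["concordance"] = qc

    if config.panel_af:
        panel = pd.read_csv(config.panel_af, sep="\t")
        cohort_af = dosages.variants.copy()
        with np.errstate(invalid="ignore"):
            cohort_af["af"] = np.nanmean(dosages.dosages, axis=0) / 2
        afc = af_correlation(cohort_af, panel)
        afc.to_csv(out / "af_correlation.tsv", sep="\t", index=False)
        report["af_correlation"] = afc.to_dict(orient="records")

    # --- INFO filter ------------------------------------------------------
    filtered = filter_by_info(dosages, config.info_threshold)
    report["info_filter"] = {
        "threshold": config.info_threshold,
        "n_before": dosages.n_variants,
        "n_after": filtered.n_variants,
    }
    if until == "qc":
        _write_report(report, out)
        return report

    # --- relatedness pruning ---------------------------------------------
    kin = kinship_and_prune(truth, config.kinship_threshold)
    keep_ids = [s for s in filtered.samples if s in set(kin.kept)]
    keep_idx = [filtered.samples.index(s) for s in keep_ids]
    filtered.dosages = filtered.dosages[keep_idx]
    filtered.samples = keep_ids
    truth_kept = truth.subset_samples([truth.samples.index(s) for s in keep_ids])
    pheno = pheno.set_index("sample_id").loc[keep_ids].reset_index()
    pd.DataFrame({"sample_id": kin.kept}).to_csv(out / "kept_samples.tsv", sep="\t", index=False)
    report["relatedness"] = {
        "threshold": config.kinship_threshold,
        "n_removed": len(kin.removed),
        "removed": kin.removed,
    }

    # --- PCA --------------------------------------------------------------
    pca_vars = select_pca_variants(truth_kept, config.pca_config())
    pcs = compute_pcs(truth_kept, pca_vars, config.n_pcs)
    pc_df = pd.DataFrame(pcs, columns=[f"pc{i+1}" for i in range(config.n_pcs)])
    pc_df.insert(0, "sample_id", keep_ids)
    pc_df.to_csv(out / "pcs.tsv", sep="\t", index=False, float_format="%.6g")

    # --- score every weight set (raw, PLINK-style sum) ---------------------
    from .prs import residualize_prs, score_prs

    raw_scores: dict[str, np.ndarray] = {}
    meta: dict[str, dict] = {}
    for ws in weight_sets:
        raw, mw = score_prs(filtered, ws)
        raw_scores[ws.set_id] = raw
        meta[ws.set_id] = {
            "reported_population_auc": ws.reported_population_auc,
            "n_matched": mw.n_matched,
        }
    raw_df = pd.DataFrame({"sample_id": keep_ids})
    for sid, raw in raw_scores.items():
        raw_df[f"raw_{sid}"] = raw
    raw_df.to_csv(out / "raw_prs.tsv", sep="\t", index=False, float_format="%.6g")
    if until == "score":
        _write_report(report, out)
        return report

    # --- residualize -------------------------------------------------------
    scored: dict[str, dict] = {}
    for sid, raw in raw_scores.items():
        adjusted, _ = residualize_prs(raw, pcs, config.n_pcs)
        raw_z = (raw - raw.mean()) / raw.std(ddof=1)
        scored[sid] = {"raw": raw_z, "adjusted": adjusted, **meta[sid]}
    prs_df = pd.DataFrame({"sample_id": keep_ids})
    for sid, info in scored.items():
        prs_df[f"raw_{sid}"] = info["raw"]
        prs_df[f"adjusted_{sid}"] = info["adjusted"]
    prs_df.to_csv(out / "prs.tsv", sep="\t", index=False, float_format="%.6g")
    if until == "adjust":
        _write_report(report, out)
        return report

    # --- weight-set evaluation + best-set selection ------------------------
    label_sets = {task: flags_to_binary(pheno[task]) for task in FH_TASKS}
    eval_table, eval_summary = evaluate_weight_sets(scored, label_sets)
    eval_out = eval_table.copy()
    for c in eval_out.columns:
        if c.endswith("_ci"):
            eval_out[c] = eval_out[c].map(lambda t: f"{t[0]:.4f}-{t[1]:.4f}")
    eval_out.to_csv(out / "weight_set_evaluation.tsv", sep="\t", index=False, float_format="%.6g")
    best_id = eval_summary["best_set"]
    report["weight_set_evaluation"] = {
        "best_set": best_id,
        "spearman_reported_vs_auc_family": eval_summary["spearman_reported_vs_auc_family"],
        "spearman_reported_vs_adjustment_delta": eval_summary["spearman_reported_vs_adjustment_delta"],
    }
    best = scored[best_id]["adjusted"]
    fh1 = label_sets["fh_bc_first"]
    pv = pheno["pv_carrier"].to_numpy(dtype=bool)

    # --- liability analyses ------------------------------------------------
    known = ~np.isnan(fh1)
    auc_fam = auc_with_ci(best, fh1)
    liab_block: dict = {
        "n_analysis": int(known.sum()),
        "pv_carrier_percent": carrier_percent(pv),
        "auc_family": {
            "auc": auc_fam.auc, "ci": [auc_fam.ci_low, auc_fam.ci_high],
            "n_pos": auc_fam.n_pos, "n_neg": auc_fam.n_neg,
        },
    }
    fh_yes, fh_no = (fh1 == 1) & known, (fh1 == 0) & known
    tbl = (
        int((fh_yes & pv).sum()), int((fh_yes & ~pv).sum()),
        int((fh_no & pv).sum()), int((fh_no & ~pv).sum()),
    )
    fr = fisher_2x2(tbl)
    liab_block["pv_by_fh_table"] = {
        "table": list(tbl), "odds_ratio": fr.odds_ratio,
        "ci": [fr.ci_low, fr.ci_high], "p_minlike": fr.p_value,
    }
    comparisons = {
        "prs_fh_pos_vs_neg": (best[fh_yes], best[fh_no]),
        "prs_carrier_vs_non_in_fh_pos": (best[fh_yes & pv], best[fh_yes & ~pv]),
        "prs_carrier_vs_non_in_fh_neg": (best[fh_no & pv], best[fh_no & ~pv]),
    }
    for name, (x, y) in comparisons.items():
        if x.size and y.size:
            u, p = mann_whitney(x, y)
            liab_block[name] = {"U": u, "p": p, "n_x": int(x.size), "n_y": int(y.size)}
        else:
            liab_block[name] = {"U": None, "p": None, "n_x": int(x.size), "n_y": int(y.size)}
    report["liability"] = liab_block

    # --- decile analysis ---------------------------------------------------
    dec_block = {}
    for tag, excl in (("all", False), ("without_pv", True)):
        rep = decile_analysis(best, fh1, pv, exclude_pv=excl)
        rep.proportions.to_csv(out / f"deciles_{tag}.tsv", sep="\t", index=False, float_format="%.6g")
        dec_block[tag] = {
            "top_vs_middle_or": rep.top_vs_middle.odds_ratio,
            "top_vs_middle_p": rep.top_vs_middle.p_value,
            "bottom_vs_middle_or": rep.bottom_vs_middle.odds_ratio,
            "bottom_vs_middle_p": rep.bottom_vs_middle.p_value,
        }
    report["deciles"] = dec_block

    # --- age GLM ------------------------------------------------------------
    ages = pheno["age"].to_numpy(dtype=float)
    rho, p_rho = spearman(best, ages)
    fit = age_glm(best, ages)
    report["age"] = {
        "spearman_rho": rho, "spearman_p": p_rho,
        "glm_slope": fit.slope, "glm_slope_ci": list(fit.slope_ci),
        "glm_intercept": fit.intercept, "glm_intercept_ci": list(fit.intercept_ci),
        "n": fit.n,
    }

    if until == "analyze":
        _write_report(report, out)
        return report

    # --- bootstrap ----------------------------------------------------------
    boot = {}
    for task in FH_TASKS:
        res = bootstrap_auc_removal(
            best, label_sets[task], pv,
            n_boot=config.n_boot, seed=stage_seed(config.seed, f"bootstrap_{task}"),
        )
        boot[task] = {
            "auc_all": res.auc_all, "auc_without_pv": res.auc_without_pv,
            "delta": res.delta, "relative_delta": res.relative_delta,
            "p_boot": res.p_boot, "n_boot": res.n_boot,
        }
    report["bootstrap"] = boot

    _write_report(report, out)
    return report


def _write_report(report: dict, out: Path) -> None:
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    logger.info("report written to %s", out / "report.json")


_SECTION_ORDER = [
    ("concordance", "Imputation concordance"),
    ("af_correlation", "Allele-frequency correlation with panel groups"),
    ("info_filter", "Imputation-quality filtering"),
    ("relatedness", "Relatedness pruning"),
    ("weight_set_evaluation", "Weight-set evaluation"),
    ("liability", "PRS x pathogenic variant x family history"),
    ("deciles", "PRS decile enrichment"),
    ("age", "Age of onset"),
    ("bootstrap", "AUC after carrier removal (bootstrap)"),
]


def cmd_report(report_path: str | Path) -> str:
    """Render a report JSON as a human-readable summary (returned as text)."""
    with open(report_path) as fh:
        report = json.load(fh)
    lines = [f"famprs report ({report.get('manifest', {}).get('famprs_version', '?')})"]
    for key, title in _SECTION_ORDER:
        lines.append(f"\n== {title} ==")
        if key not in report:
            lines.append("  [not run]")
            continue
        lines.append(json.dumps(report[key], indent=2, sort_keys=True))
    return "\n".join(lines)
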