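"""Repeated-seed simulation experiments for the pipeline's headline claims.

Each experiment generates synthetic cohorts under the liability-threshold
model, runs the relevant analysis stage, and summarizes the outcome across
seeds.  These are the package's own calibration/validation studies: slope
recovery for the age model, the liability-threshold signature (carriers
have lower polygenic scores among family-history-positive patients),
bootstrap calibration and power for the carrier-removal AUC test,
monotonicity of dosage concordance in imputation quality, and the
mask-vs-amplify behaviour of ancestry adjustment for structure-confounded
weight sets.

Study conditions (cohort size, divergence, liability parameters) are fixed
here; see docs/methods.md for the rationale behind each choice.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import flags_to_binary
from .prs import PcaConfig, compute_pcs, compute_prs, select_pca_variants
from .qc import QCConfig, dosage_correlation, intersect_pairs
from .stats import age_glm, auc_rank, bootstrap_auc_removal, spearman
from .synth import (
    ImputationNoiseParams,
    LiabilityParams,
    PopulationParams,
    draw_weight_set,
    simulate_cohort,
    simulate_genotypes,
    simulate_imputed_dosages,
)

# The emulated study conditions: a case-ascertained cohort from a
# moderately structured population, with liability h2_common=0.4, a
# two-liability-SD pathogenic-variant effect at 10% population frequency,
# threshold 1.5, and onset age falling 4.5 years per score SD.
COHORT_POP = PopulationParams(
    n_samples=400, n_variants=400, n_subpops=2, fst=0.05, admixture_alpha=0.3
)
COHORT_LIAB = LiabilityParams(
    h2_common=0.4, pv_effect=2.0, threshold=1.5, pv_freq=0.1,
    age_baseline=48.0, age_slope=4.5, age_noise_sd=9.0,
)
PERFECT_IMPUTATION = ImputationNoiseParams(
    base_quality=1.0, maf_quality_slope=0.0, dosage_noise_sd=0.0
)
N_PCS = 10


def _seed_seq(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def _adjusted_prs_cohort(seed: int, pop=None, liab=None, noise=None):
    """One ascertained cohort scored and PC-residualized with its causal set."""
    coh = simulate_cohort(
        pop or COHORT_POP, noise or PERFECT_IMPUTATION, liab or COHORT_LIAB, seed=seed
    )
    variants = select_pca_variants(coh.genotypes, PcaConfig())
    pcs = compute_pcs(coh.genotypes, variants, N_PCS)
    res = compute_prs(coh.dosages, coh.weight_sets[0], pcs, N_PCS)
    return coh, res


def age_slope_recovery(n_seeds: int = 100, seed: int = 0, true_slope: float = 4.5) -> dict:
    """Recover the onset-age slope (years per PRS SD) across seeds.

    The generator writes ages with slope ``-true_slope`` on the
    standardized causal score; the analysis regresses age on the
    standardized ancestry-adjusted PRS.
    """
    liab = replace(COHORT_LIAB, age_slope=true_slope)
    slopes = []
    for s in _seed_seq(seed, n_seeds):
        coh, res = _adjusted_prs_cohort(int(s), liab=liab)
        fit = age_glm(res.adjusted, coh.phenotypes["age"].to_numpy())
        slopes.append(fit.slope)
    slopes = np.asarray(slopes)
    return {
        "mean_slope": float(slopes.mean()),
        "bias": float(slopes.mean() + true_slope),           # true fitted slope is -true_slope
        "relative_bias": float((slopes.mean() + true_slope) / true_slope),
        "mae": float(np.abs(slopes + true_slope).mean()),
        "n_seeds": n_seeds,
    }


def liability_signature(n_seeds: int = 100, seed: int = 0, n_cases: int = 4000) -> dict:
    """Carriers vs non-carriers among family-history-positive cases.

    Under the liability threshold model, family-history-positive patients
    who carry a pathogenic variant need less common-variant risk to cross
    the threshold; their median adjusted PRS should sit below that of
    non-carriers.  Returns the fraction of seeds showing that direction.
    """
    pop = replace(COHORT_POP, n_samples=n_cases)
    hits = 0
    for s in _seed_seq(seed, n_seeds):
        coh, res = _adjusted_prs_cohort(int(s), pop=pop)
        ph = coh.phenotypes
        fh = (ph["fh_bc_first"] == "yes").to_numpy()
        pv = ph["pv_carrier"].to_numpy(dtype=bool)
        med_c = np.median(res.adjusted[fh & pv])
        med_n = np.median(res.adjusted[fh & ~pv])
        hits += med_c < med_n
    return {"fraction_direction_correct": hits / n_seeds, "n_seeds": n_seeds,
            "n_cases": n_cases}


def adjustment_orthogonality(seed: int = 0) -> dict:
    """Max |corr| between the adjusted PRS and each fitted PC on one cohort."""
    coh, res = _adjusted_prs_cohort(seed)
    variants = select_pca_variants(coh.genotypes, PcaConfig())
    pcs = compute_pcs(coh.genotypes, variants, N_PCS)
    cors = [abs(np.corrcoef(res.adjusted, pcs[:, k])[0, 1]) for k in range(N_PCS)]
    return {"max_abs_corr": float(max(cors))}


def confounded_adjustment(n_seeds: int = 50, seed: int = 0) -> dict:
    """Ancestry adjustment strips a structure-confounded score harder.

    Liability includes an environmental shift along ancestry, so family
    history correlates with ancestry.  A weight set loaded on the most
    differentiated variants (weights = subpop AF difference, oriented with
    the shift) scores ancestry, not biology: its family-history AUC should
    fall under PC residualization by more than the causal set's does.
    """
    pop = replace(COHORT_POP, fst=0.15, admixture_alpha=0.15)
    liab = replace(COHORT_LIAB, ancestry_effect=1.5)
    hits = 0
    deltas_conf, deltas_causal = [], []
    for s in _seed_seq(seed, n_seeds):
        coh = simulate_cohort(pop, PERFECT_IMPUTATION, liab, seed=int(s))
        af = coh.af_table
        diff = (af["af_subpop0"] - af["af_subpop1"]).to_numpy()
        top = np.argsort(-np.abs(diff))[:100]
        conf_tab = af.iloc[np.sort(top)][["chrom", "pos", "ref", "alt"]].copy()
        conf_tab["effect_allele"] = conf_tab["alt"]
        # oriented toward subpop 0, the direction of the liability shift
        conf_tab["weight"] = diff[np.sort(top)]
        from .containers import WeightSet

        conf = WeightSet("confounded", conf_tab.reset_index(drop=True))
        variants = select_pca_variants(coh.genotypes, PcaConfig())
        pcs = compute_pcs(coh.genotypes, variants, N_PCS)
        labels = flags_to_binary(coh.phenotypes["fh_bc_first"])
        out = {}
        for name, ws in (("causal", coh.weight_sets[0]), ("confounded", conf)):
            res = compute_prs(coh.dosages, ws, pcs, N_PCS)
            raw_z = (res.raw - res.raw.mean()) / res.raw.std(ddof=1)
            pre = auc_rank(raw_z, labels).auc
            post = auc_rank(res.adjusted, labels).auc
            out[name] = post - pre
        deltas_conf.append(out["confounded"])
        deltas_causal.append(out["causal"])
        hits += out["confounded"] < out["causal"]
    return {
        "fraction_confounded_loses_more": hits / n_seeds,
        "mean_delta_confounded": float(np.mean(deltas_conf)),
        "mean_delta_causal": float(np.mean(deltas_causal)),
        "n_seeds": n_seeds,
    }


def _null_cohort(rng: np.random.Generator, n: int = 400):
    """Scores predictive of the label, carriers independent of both."""
    scores = rng.normal(0, 1, n)
    p = 1 / (1 + np.exp(-(scores - 1.2)))
    labels = (rng.random(n) < p).astype(float)
    pv = rng.random(n) < 0.15
    return scores, labels, pv


def bootstrap_null_calibration(
    n_seeds: int = 200, n_boot: int = 500, seed: int = 0, n: int = 400
) -> dict:
    """Distribution of bootstrap p-values when carrier removal is a no-op.

    With carrier status independent of score and label, the
    carrier-removal p-value should be approximately uniform; returns the
    Kolmogorov–Smirnov p against U(0,1).
    """
    pvals = []
    for s in _seed_seq(seed, n_seeds):
        rng = np.random.default_rng(int(s))
        scores, labels, pv = _null_cohort(rng, n)
        if pv.all() or (~pv).sum() < 10:
            pv = np.zeros(n, dtype=bool)
        res = bootstrap_auc_removal(
            scores, labels, pv, n_boot=n_boot, seed=int(s) + 1
        )
        pvals.append(res.p_boot)
    ks = sps.kstest(pvals, "uniform")
    return {
        "ks_statistic": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
        "mean_p": float(np.mean(pvals)),
        "n_seeds": n_seeds,
        "n_boot": n_boot,
    }


def bootstrap_power(
    n_seeds: int = 50, n_boot: int = 1000, seed: int = 0, n_cases: int = 400
) -> dict:
    """Power of the carrier-removal test under the liability generator.

    Carriers are family-history-enriched but carry little common-variant
    risk, so removing them should raise the family-history AUC (positive
    delta, small bootstrap p).
    """
    pop = replace(COHORT_POP, n_samples=n_cases)
    sig = 0
    deltas = []
    for s in _seed_seq(seed, n_seeds):
        coh, res = _adjusted_prs_cohort(int(s), pop=pop)
        labels = flags_to_binary(coh.phenotypes["fh_bc_first"])
        pv = coh.phenotypes["pv_carrier"].to_numpy(dtype=bool)
        out = bootstrap_auc_removal(
            res.adjusted, labels, pv, n_boot=n_boot, seed=int(s) + 1
        )
        sig += out.p_boot < 0.05
        deltas.append(out.delta)
    return {
        "fraction_significant": sig / n_seeds,
        "mean_delta": float(np.mean(deltas)),
        "n_seeds": n_seeds,
        "n_boot": n_boot,
    }


def concordance_monotonicity(
    n_seeds: int = 50, seed: int = 0, n_samples: int = 150, n_variants: int = 2000
) -> dict:
    """Median dosage correlation should rise with the INFO-bin midpoint.

    Generates cohorts whose latent imputation quality varies with allele
    frequency plus jitter, bins variants by the reported quality score, and
    checks the Spearman correlation between bin midpoints and per-bin median
    dosage correlations, per seed.
    """
    pop = replace(
        COHORT_POP, n_samples=n_samples, n_variants=n_variants, maf_range=(0.01, 0.5)
    )
    noise = ImputationNoiseParams(
        base_quality=0.95, maf_quality_slope=0.35, dosage_noise_sd=0.1,
        quality_noise_sd=0.1,
    )
    cfg = QCConfig()
    rhos = []
    for s in _seed_seq(seed, n_seeds):
        gm, _, afs = simulate_genotypes(pop, int(s))
        dm = simulate_imputed_dosages(gm, afs, noise, int(s) + 1)
        pairs = intersect_pairs(dm, gm)
        rep = dosage_correlation(pairs, group_by="info", config=cfg)
        summ = rep.summary.dropna(subset=["median_r"])
        summ = summ[summ["n_samples_defined"] >= max(3, n_samples // 2)]
        rho, _ = spearman(summ["bin_mid"].to_numpy(), summ["median_r"].to_numpy())
        rhos.append(rho)
    rhos = np.asarray(rhos)
    return {
        "min_spearman": float(rhos.min()),
        "fraction_nonneg": float((rhos >= 0).mean()),
        "n_seeds": n_seeds,
    }
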