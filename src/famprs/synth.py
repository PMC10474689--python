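"""Synthetic case-only cohort generator.

Emulates the statistical structure the downstream analyses assume:

* population structure — a Balding–Nichols model: subpopulation allele
  frequencies drawn around an ancestral frequency p with divergence F_ST,
  individual frequencies mixed by Dirichlet admixture proportions;
* imputation noise — each dosage is a linear blend of the true genotype and
  its Hardy–Weinberg expectation 2p, with blend fraction tied to a latent
  per-variant quality score reported as the INFO annotation;
* disease — a Gaussian liability threshold: liability is
  sqrt(h2_common) * G + b_PV * C + environment, and only individuals whose
  liability exceeds the threshold enter the (case-only) cohort;
* family history — one simulated first-degree relative (genetic share 0.5)
  drives the first-degree flag, a second relative with share 0.25 extends it
  to any degree, and independent non-breast-cancer events in relatives give
  the any-cancer flag;
* age of onset — decreases linearly with the standardized genetic score.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DosageMatrix, GenotypeMatrix, WeightSet, validate_phenotypes
from .io import (
    write_dosage_vcf,
    write_genotype_vcf,
    write_phenotype_table,
    write_weight_table,
)

_BASES = np.array(list("ACGT"))


@dataclass
class PopulationParams:
    """Balding–Nichols population-structure parameters."""

    n_samples: int = 400
    n_variants: int = 2000
    n_subpops: int = 2
    fst: float | tuple[float, ...] = 0.05
    admixture_alpha: float = 0.3
    maf_range: tuple[float, float] = (0.01, 0.5)
    variant_spacing_bp: int = 5000

    def fst_per_subpop(self) -> np.ndarray:
        f = np.broadcast_to(np.asarray(self.fst, dtype=float), (self.n_subpops,))
        return np.array(f)

    def validate(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if self.n_variants <= 0:
            raise ValueError("n_variants must be positive")
        if self.n_subpops < 1:
            raise ValueError("n_subpops must be >= 1")
        f = self.fst_per_subpop()
        if np.any(f < 0) or np.any(f >= 1):
            raise ValueError("fst must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.admixture_alpha <= 0:
            raise ValueError("admixture_alpha must be positive")
        if np.all(f == 0) and self.n_subpops > 1:
            warnings.warn(
                "fst=0 with multiple subpopulations: subpopulations will be "
                "statistically indistinguishable",
                stacklevel=3,
            )


@dataclass
class ImputationNoiseParams:
    """Imputation-noise model parameters.

    ``base_quality`` is the quality of a common variant; quality drops by
    ``maf_quality_slope * (-log10(2 * MAF))`` for rarer variants (0 at
    MAF = 0.5) plus optional Gaussian jitter, clamped to (0, 1].  The blend
    fraction pulling a dosage toward its Hardy–Weinberg mean is 1 - quality,
    so quality 1 reproduces the genotype exactly.  ``dosage_noise_sd`` adds
    within-genotype jitter on top.
    """

    base_quality: float = 0.95
    maf_quality_slope: float = 0.2
    dosage_noise_sd: float = 0.05
    quality_noise_sd: float = 0.0

    def validate(self) -> None:
        if not (0 < self.base_quality <= 1):
            raise ValueError("base_quality must lie in (0, 1]")
        if self.dosage_noise_sd < 0 or self.quality_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")


@dataclass
class LiabilityParams:
    """Liability-threshold disease model parameters.

    Liability L = sqrt(h2_common) * G + pv_effect * C + ancestry_effect * A
    + N(0, sqrt(1 - h2_common)), with G the standardized common-variant
    score, C the pathogenic-variant carrier indicator (population frequency
    ``pv_freq``), and A the centered admixture proportion of the first
    subpopulation (environmental confounding, 0 by default).  Individuals
    with L > threshold are cases.  Age of onset is
    ``age_baseline - age_slope * z(G) + N(0, age_noise_sd)`` within the
    ascertained cohort.
    """

    h2_common: float = 0.4
    pv_freq: float = 0.02
    pv_effect: float = 2.0
    threshold: float = 1.5
    age_baseline: float = 48.0
    age_slope: float = 4.5
    age_noise_sd: float = 9.0
    rel_share: float = 0.5
    rel_share_distant: float = 0.25
    other_cancer_rate: float = 0.15
    ancestry_effect: float = 0.0
    fh_unknown_frac: float = 0.0

    def validate(self) -> None:
        if not (0 <= self.h2_common <= 1):
            raise ValueError("h2_common must lie in [0, 1]")
        if not (0 <= self.pv_freq <= 1):
            raise ValueError("pv_freq must lie in [0, 1]")
        if self.age_noise_sd < 0:
            raise ValueError("age_noise_sd must be non-negative")
        for name in ("rel_share", "rel_share_distant", "fh_unknown_frac"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")


def simulate_genotypes(
    params: PopulationParams, seed: int
) -> tuple[GenotypeMatrix, np.ndarray, pd.DataFrame]:
    """Draw genotypes under the Balding–Nichols admixture model.

    Returns the genotype matrix, per-sample ancestry labels (argmax of the
    admixture proportions), and the true allele-frequency table with
    ancestral and per-subpopulation alternate-allele frequencies.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    n, m, k = params.n_samples, params.n_variants, params.n_subpops

    lo, hi = params.maf_range
    p_anc = rng.uniform(lo, hi, size=m)
    fsts = params.fst_per_subpop()
    subpop_af = np.empty((k, m))
    for s in range(k):
        f = fsts[s]
        if f == 0:
            subpop_af[s] = p_anc
        else:
            a = p_anc * (1 - f) / f
            b = (1 - p_anc) * (1 - f) / f
            subpop_af[s] = rng.beta(a, b)
    admix = rng.dirichlet(np.full(k, params.admixture_alpha), size=n)
    labels = admix.argmax(axis=1)
    indiv_af = admix @ subpop_af
    genotypes = rng.binomial(2, indiv_af).astype(float)

    ref = _BASES[rng.integers(0, 4, size=m)]
    alt = np.array([_BASES[(np.flatnonzero(_BASES != r)[rng.integers(0, 3)])] for r in ref])
    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos": 1 + np.arange(m) * params.variant_spacing_bp,
            "ref": ref,
            "alt": alt,
        }
    )
    af_table = variants.copy()
    af_table["af"] = p_anc
    for s in range(k):
        af_table[f"af_subpop{s}"] = subpop_af[s]
    gm = GenotypeMatrix(
        samples=[f"S{i:05d}" for i in range(n)], variants=variants, genotypes=genotypes
    )
    gm.admixture = admix
    return gm, labels, af_table


def _quality_scores(
    maf: np.ndarray, params: ImputationNoiseParams, rng: np.random.Generator
) -> np.ndarray:
    rarity = -np.log10(np.maximum(2.0 * maf, 1e-6))
    q = params.base_quality - params.maf_quality_slope * rarity
    if params.quality_noise_sd > 0:
        q = q + rng.normal(0, params.quality_noise_sd, size=q.shape)
    return np.clip(q, 1e-3, 1.0)


def simulate_imputed_dosages(
    genotypes: GenotypeMatrix,
    afs: pd.DataFrame,
    params: ImputationNoiseParams,
    seed: int,
) -> DosageMatrix:
    """Blend genotypes toward 2p with intensity set by a latent quality score.

    dosage = (1 - eps) * g + eps * 2p + N(0, dosage_noise_sd), clamped to
    [0, 2], with eps = 1 - quality; the quality score is reported as INFO.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    key = genotypes.key_index()
    af_idx = pd.MultiIndex.from_frame(afs[["chrom", "pos", "ref", "alt"]].astype(
        {"chrom": str, "pos": int}))
    locs = af_idx.get_indexer(key)
    if (locs < 0).any():
        miss = key[locs < 0][0]
        raise ValueError(f"allele-frequency table lacks variant {miss}")
    p = afs["af"].to_numpy(dtype=float)[locs]

    q = _quality_scores(np.minimum(p, 1 - p), params, rng)
    eps = 1.0 - q
    g = genotypes.genotypes
    d = (1 - eps)[None, :] * g + (eps * 2 * p)[None, :]
    if params.dosage_noise_sd > 0:
        d = d + rng.normal(0, params.dosage_noise_sd, size=d.shape)
    d = np.clip(d, 0.0, 2.0)
    d[np.isnan(g)] = np.nan
    with np.errstate(invalid="ignore"):
        maf = np.minimum(np.nanmean(d, axis=0) / 2, 1 - np.nanmean(d, axis=0) / 2)
    return DosageMatrix(
        samples=list(genotypes.samples),
        variants=genotypes.variants.copy(),
        dosages=d,
        info=q,
        maf=maf,
    )


def draw_weight_set(
    variants: pd.DataFrame,
    n_causal: int,
    effect_sd: float,
    label: str,
    reported_population_auc: float | None,
    seed: int,
) -> WeightSet:
    """Assign Normal(0, effect_sd) alternate-allele weights to a random subset."""
    if n_causal < 0:
        raise ValueError("n_causal must be non-negative")
    if n_causal > len(variants):
        raise ValueError("n_causal exceeds the number of variants")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(variants), size=n_causal, replace=False))
    table = variants.iloc[idx].reset_index(drop=True).copy()
    table["effect_allele"] = table["alt"]
    table["weight"] = rng.normal(0, effect_sd, size=n_causal) if n_causal else np.zeros(0)
    return WeightSet(set_id=label, table=table, reported_population_auc=reported_population_auc)


def perturb_weight_set(
    weights: WeightSet,
    noise_sd: float,
    label: str,
    reported_population_auc: float | None,
    seed: int,
) -> WeightSet:
    """A degraded copy of a weight set: weights plus Gaussian noise.

    ``noise_sd`` is relative to the SD of the source weights, so 0 clones
    the set and larger values emulate weight sets estimated with more
    error (lower population AUC).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    table = weights.table.copy()
    w = table["weight"].to_numpy(dtype=float)
    scale = w.std(ddof=1) if len(w) > 1 and w.std(ddof=1) > 0 else 1.0
    table["weight"] = w + rng.normal(0, noise_sd * scale, size=len(w))
    return WeightSet(set_id=label, table=table, reported_population_auc=reported_population_auc)


def _standardized_score(genotypes: GenotypeMatrix, weights: WeightSet) -> np.ndarray:
    """Raw weighted score, z-scored across the given samples (0-filled missing)."""
    key = genotypes.key_index()
    locs = key.get_indexer(weights.key_index())
    found = locs >= 0
    if not found.any():
        raise ValueError("weight set shares no variants with the genotype matrix")
    w = weights.table["weight"].to_numpy(dtype=float)[found]
    flip = (weights.table["effect_allele"] == weights.table["ref"]).to_numpy()[found]
    g = genotypes.genotypes[:, locs[found]]
    e = np.where(flip, 2.0 - g, g)
    e = np.nan_to_num(e)
    score = e @ w
    sd = score.std(ddof=1)
    if sd == 0:
        return np.zeros_like(score)
    return (score - score.mean()) / sd


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    weights: WeightSet,
    params: LiabilityParams,
    seed: int,
    ancestry: np.ndarray | None = None,
    ascertain: bool = True,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw liabilities and family histories; keep the case subset.

    Returns (phenotype table, integer index of retained samples into the
    input genotype matrix).  With ``ascertain=False`` every sample is kept
    and an ``is_case`` column reports affection status instead.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    n = genotypes.n_samples
    G = _standardized_score(genotypes, weights)
    C = rng.random(n) < params.pv_freq
    shift = np.zeros(n)
    if params.ancestry_effect != 0.0:
        if ancestry is None:
            raise ValueError("ancestry_effect set but no ancestry covariate given")
        a = np.asarray(ancestry, dtype=float)
        shift = params.ancestry_effect * (a - a.mean())
    h2 = params.h2_common
    env_sd = np.sqrt(1 - h2)
    L = np.sqrt(h2) * G + params.pv_effect * C + shift + rng.normal(0, env_sd, n)
    is_case = L > params.threshold

    def relative_fh(share: float) -> np.ndarray:
        G_rel = share * G + np.sqrt(1 - share**2) * rng.normal(0, 1, n)
        inherit = rng.random(n) < share
        C_rel = np.where(inherit, C, rng.random(n) < params.pv_freq)
        L_rel = (
            np.sqrt(h2) * G_rel
            + params.pv_effect * C_rel
            + shift
            + rng.normal(0, env_sd, n)
        )
        return L_rel > params.threshold

    fh_first = relative_fh(params.rel_share)
    fh_distant = relative_fh(params.rel_share_distant)
    fh_any = fh_first | fh_distant
    other = (rng.random(n) < params.other_cancer_rate) | (
        rng.random(n) < params.other_cancer_rate
    )
    fh_anycancer = fh_any | other

    keep = np.flatnonzero(is_case) if ascertain else np.arange(n)
    if ascertain and keep.size == 0:
        raise ValueError("no sample exceeded the liability threshold")

    Gk = G[keep]
    z = (Gk - Gk.mean()) / Gk.std(ddof=1) if Gk.std(ddof=1) > 0 else np.zeros_like(Gk)
    age = params.age_baseline - params.age_slope * z + rng.normal(
        0, params.age_noise_sd, keep.size
    )
    age = np.maximum(age, 18.0)

    def flag(arr: np.ndarray) -> np.ndarray:
        out = np.where(arr[keep], "yes", "no").astype(object)
        if params.fh_unknown_frac > 0:
            mask = rng.random(keep.size) < params.fh_unknown_frac
            out[mask] = "unknown"
        return out

    table = pd.DataFrame(
        {
            "sample_id": [genotypes.samples[i] for i in keep],
            "age": np.round(age, 2),
            "fh_bc_first": flag(fh_first),
            "fh_bc_any": flag(fh_any),
            "fh_anycancer_any": flag(fh_anycancer),
            "pv_carrier": C[keep],
            "true_score": G[keep],
            "liability": L[keep],
        }
    )
    if not ascertain:
        table["is_case"] = is_case
    validate_phenotypes(table)
    return table, keep


@dataclass
class SyntheticCohort:
    """A complete ascertained cohort plus its generating parameters."""

    genotypes: GenotypeMatrix
    dosages: DosageMatrix
    weight_sets: list[WeightSet]
    phenotypes: pd.DataFrame
    ancestry_labels: np.ndarray
    admixture: np.ndarray
    af_table: pd.DataFrame
    params: dict


_ASCERTAINMENT_CAP = 1000  # max draws, in multiples of the target cohort size


def simulate_cohort(
    pop: PopulationParams,
    noise: ImputationNoiseParams,
    liab: LiabilityParams,
    seed: int,
    weight_specs: list[dict] | None = None,
    batch_factor: int = 4,
) -> SyntheticCohort:
    """Generate a case-ascertained cohort of ``pop.n_samples`` cases.

    Rejection-samples genotype batches until enough liabilities exceed the
    threshold, with a hard cap of 1000x the target size; the first weight
    set listed is the causal one driving liability and age.
    """
    pop.validate()
    noise.validate()
    liab.validate()
    if weight_specs is None:
        weight_specs = [
            {"n_causal": max(1, pop.n_variants // 4), "effect_sd": 1.0,
             "label": "causal", "reported_population_auc": 0.64}
        ]
    rng = np.random.default_rng(seed)
    target = pop.n_samples

    # draw the variant scaffold (keys, ancestral and subpop AFs) once so
    # every rejection-sampling batch shares the same variants
    scaffold_seed = int(rng.integers(0, 2**31 - 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scaffold, _, af_table = simulate_genotypes(
            PopulationParams(**{**asdict(pop), "n_samples": 1}), scaffold_seed
        )
    variants = scaffold.variants
    sub_af = af_table[[c for c in af_table.columns if c.startswith("af_subpop")]].to_numpy().T
    weights0 = draw_weight_set(
        variants, seed=int(rng.integers(0, 2**31 - 1)), **weight_specs[0]
    )

    batch_n = batch_factor * target
    kept_geno: list[np.ndarray] = []
    kept_admix: list[np.ndarray] = []
    kept_labels: list[np.ndarray] = []
    kept_pheno: list[pd.DataFrame] = []
    n_drawn = 0
    n_kept = 0
    while n_kept < target:
        if n_drawn >= _ASCERTAINMENT_CAP * target:
            raise RuntimeError(
                f"ascertainment failed: {n_kept}/{target} cases after {n_drawn} draws "
                f"(threshold {liab.threshold} too extreme)"
            )
        batch_rng = np.random.default_rng(int(rng.integers(0, 2**31 - 1)))
        admix = batch_rng.dirichlet(np.full(pop.n_subpops, pop.admixture_alpha), size=batch_n)
        indiv_af = admix @ sub_af
        geno = batch_rng.binomial(2, indiv_af).astype(float)
        gm = GenotypeMatrix(
            samples=[f"B{n_drawn + i:06d}" for i in range(batch_n)],
            variants=variants,
            genotypes=geno,
        )
        labels = admix.argmax(axis=1)
        try:
            pheno, keep = simulate_phenotypes(
                gm,
                weights0,
                liab,
                seed=int(rng.integers(0, 2**31 - 1)),
                ancestry=admix[:, 0],
            )
        except ValueError:  # batch produced no cases; keep drawing until the cap
            n_drawn += batch_n
            continue
        n_drawn += batch_n
        kept_geno.append(geno[keep])
        kept_admix.append(admix[keep])
        kept_labels.append(labels[keep])
        kept_pheno.append(pheno)
        n_kept += keep.size

    genotypes = np.vstack(kept_geno)[:target]
    admixture = np.vstack(kept_admix)[:target]
    labels = np.concatenate(kept_labels)[:target]
    pheno = pd.concat(kept_pheno, ignore_index=True).iloc[:target].copy()
    sample_ids = [f"S{i:05d}" for i in range(target)]
    pheno["sample_id"] = sample_ids

    gm = GenotypeMatrix(samples=sample_ids, variants=variants.copy(), genotypes=genotypes)
    # recompute age/standardization on the final cohort so z(G) is cohort-wide
    final_rng = np.random.default_rng(int(rng.integers(0, 2**31 - 1)))
    G = pheno["true_score"].to_numpy()
    z = (G - G.mean()) / G.std(ddof=1)
    age = liab.age_baseline - liab.age_slope * z + final_rng.normal(
        0, liab.age_noise_sd, target
    )
    pheno["age"] = np.round(np.maximum(age, 18.0), 2)

    weight_sets = [weights0]
    for spec in (weight_specs or [])[1:]:
        spec = dict(spec)
        s = int(rng.integers(0, 2**31 - 1))
        if "perturb_noise_sd" in spec:
            weight_sets.append(
                perturb_weight_set(
                    weights0,
                    noise_sd=spec["perturb_noise_sd"],
                    label=spec.get("label", f"set{len(weight_sets)}"),
                    reported_population_auc=spec.get("reported_population_auc"),
                    seed=s,
                )
            )
        else:
            weight_sets.append(draw_weight_set(gm.variants, seed=s, **spec))
    dosages = simulate_imputed_dosages(
        gm, af_table, noise, seed=int(rng.integers(0, 2**31 - 1))
    )
    return SyntheticCohort(
        genotypes=gm,
        dosages=dosages,
        weight_sets=weight_sets,
        phenotypes=pheno,
        ancestry_labels=labels,
        admixture=admixture,
        af_table=af_table,
        params={
            "population": asdict(pop),
            "imputation_noise": asdict(noise),
            "liability": asdict(liab),
            "seed": seed,
            "n_drawn": n_drawn,
        },
    )


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> dict[str, Path]:
    """Write a cohort as dosage VCF, truth VCF, weight TSVs, phenotype TSV.

    A JSON sidecar echoes the generating parameters.  Files round-trip
    through the readers in :mod:`famprs.io` to 1e-4.
    """
    if cohort.genotypes.n_samples == 0 or cohort.genotypes.n_variants == 0:
        raise ValueError("refusing to write an empty cohort")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "dosage_vcf": directory / "imputed.vcf",
        "truth_vcf": directory / "truth.vcf",
        "phenotypes": directory / "phenotypes.tsv",
        "params": directory / "params.json",
        "panel_af": directory / "panel_af.tsv",
    }
    write_dosage_vcf(cohort.dosages, paths["dosage_vcf"])
    write_genotype_vcf(cohort.genotypes, paths["truth_vcf"])
    pheno_out = cohort.phenotypes.drop(columns=["true_score", "liability"], errors="ignore")
    write_phenotype_table(pheno_out, paths["phenotypes"])
    for ws in cohort.weight_sets:
        p = directory / f"weights_{ws.set_id}.tsv"
        write_weight_table(ws, p)
        paths[f"weights_{ws.set_id}"] = p
    # per-subpopulation AFs in the long panel format the QC stage consumes
    sub_cols = [c for c in cohort.af_table.columns if c.startswith("af_subpop")]
    long = cohort.af_table[["chrom", "pos", "ref", "alt", *sub_cols]].melt(
        id_vars=["chrom", "pos", "ref", "alt"],
        value_vars=sub_cols,
        var_name="group",
        value_name="af",
    )
    long["group"] = long["group"].str.replace("af_", "", regex=False)
    long.to_csv(paths["panel_af"], sep="\t", index=False, float_format="%.6g")
    with open(paths["params"], "w") as fh:
        json.dump(cohort.params, fh, indent=2, sort_keys=True)
    return paths
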