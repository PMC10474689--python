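"""PRS scoring, ancestry PCs, residualization and relatedness pruning.

Raw scores follow PLINK ``--score`` semantics with no mean imputation:
missing dosages contribute nothing (sum scoring; downstream standardization
removes the scale difference to PLINK's per-allele average).  Ancestry PCs
come from Hardy–Weinberg-normalized PCA on common, HWE-passing, LD-pruned
variants; the adjusted PRS is the z-scored residual of an OLS fit of the
raw PRS on the top K PCs.  Kinship uses half the genomic relationship
matrix with greedy pruning at the second-degree threshold 0.125.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .containers import DosageMatrix, GenotypeMatrix, WeightSet
from .io import MatchedWeights, match_weights


@dataclass
class PcaConfig:
    maf_min: float = 0.05
    hwe_p_min: float = 1e-6
    ld_r2_max: float = 0.1
    ld_window_bp: int = 1_000_000
    n_pcs: int = 10

    def __post_init__(self) -> None:
        if not (0 <= self.maf_min <= 0.5):
            raise ValueError("maf_min must lie in [0, 0.5]")
        if not (0 <= self.hwe_p_min <= 1):
            raise ValueError("hwe_p_min must lie in [0, 1]")
        if not (0 <= self.ld_r2_max <= 1):
            raise ValueError("ld_r2_max must lie in [0, 1]")
        if self.ld_window_bp < 0:
            raise ValueError("ld_window_bp must be non-negative")
        if self.n_pcs < 1:
            raise ValueError("n_pcs must be >= 1")


@dataclass
class PRSResult:
    samples: list[str]
    raw: np.ndarray
    adjusted: np.ndarray
    pc_coefficients: np.ndarray
    n_matched_variants: int


@dataclass
class KinshipResult:
    samples: list[str]
    phi: np.ndarray
    kept: list[str]
    removed: list[str]
    threshold: float


def score_prs(dosages: DosageMatrix, weights: WeightSet) -> tuple[np.ndarray, MatchedWeights]:
    """Raw PRS per sample: sum of weight x effect-allele dosage.

    Missing dosages contribute 0 ("score-no-mean-imputation").  Returns the
    score vector and the match summary.
    """
    mw = match_weights(weights, dosages)
    e = mw.effect_dosage(dosages.dosages)
    e = np.nan_to_num(e, nan=0.0)
    return e @ mw.weights, mw


def hwe_pvalue(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional Hardy–Weinberg test p-value.

    Enumerates heterozygote counts compatible with the observed allele
    counts and sums the probabilities of outcomes no more likely than the
    observed one (two-sided, no mid-p).
    """
    for v in (n_hom_ref, n_het, n_hom_alt):
        if v < 0:
            raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("total genotype count must be positive")
    n_rare = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    if n_rare == 0:
        return 1.0
    het_obs = n_het
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    # log P(het | allele counts) up to a constant:
    # n! / (hom_rare! het! hom_common!) * 2^het, with
    # hom_rare = (n_rare - het)/2, hom_common = n - het - hom_rare
    hom_rare = (n_rare - hets) // 2
    hom_common = n - hets - hom_rare
    logp = (
        hets * np.log(2.0)
        - special.gammaln(hom_rare + 1)
        - special.gammaln(hets + 1)
        - special.gammaln(hom_common + 1)
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    p_obs = p[hets == het_obs][0]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


def hwe_pvalues_for_matrix(genotypes: GenotypeMatrix) -> np.ndarray:
    g = genotypes.genotypes
    out = np.empty(genotypes.n_variants)
    for j in range(genotypes.n_variants):
        col = g[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            out[j] = np.nan
            continue
        out[j] = hwe_pvalue(
            int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
        )
    return out


def ld_prune(
    genotypes: GenotypeMatrix,
    variant_idx: np.ndarray,
    r2_max: float,
    window_bp: int,
) -> np.ndarray:
    """Greedy left-to-right LD pruning within a basepair window.

    A variant is dropped when its squared correlation with any already-kept
    variant strictly upstream within ``window_bp`` exceeds ``r2_max``.
    Missing genotypes are mean-imputed for the correlation.  Returns kept
    indices (subset of ``variant_idx``).
    """
    variant_idx = np.asarray(variant_idx)
    tab = genotypes.variants.iloc[variant_idx].reset_index(drop=True)
    g = genotypes.genotypes[:, variant_idx]
    col_mean = np.nanmean(g, axis=0)
    g = np.where(np.isnan(g), col_mean, g)
    # z-score columns once so r is a single dot product; constant columns
    # get sd 0 and are never counted as correlated
    mu = g.mean(axis=0)
    sd = g.std(axis=0)
    ok = sd > 0
    z = np.zeros_like(g)
    z[:, ok] = (g[:, ok] - mu[ok]) / sd[ok]
    n_samp = g.shape[0]

    kept_mask = np.zeros(len(variant_idx), dtype=bool)
    chroms = tab["chrom"].to_numpy()
    positions = tab["pos"].to_numpy()
    for chrom in pd.unique(chroms):
        sel = np.flatnonzero(chroms == chrom)
        order = sel[np.argsort(positions[sel], kind="stable")]
        kept_local: list[int] = []   # indices into the selected set, kept, position-sorted
        for j in order:
            pj = positions[j]
            drop = False
            in_window = []
            for k in reversed(kept_local):
                dist = pj - positions[k]
                if dist > window_bp:
                    break  # kept list is position-sorted: all earlier are farther
                if dist <= 0:
                    continue  # co-located variants are not compared
                in_window.append(k)
            if in_window and ok[j]:
                r = z[:, in_window].T @ z[:, j] / n_samp
                drop = bool(np.any(r * r > r2_max))
            if not drop:
                kept_local.append(j)
                kept_mask[j] = True
    return variant_idx[kept_mask]


def select_pca_variants(
    genotypes: GenotypeMatrix, config: PcaConfig | None = None
) -> np.ndarray:
    """Variant indices passing MAF > maf_min, HWE p > hwe_p_min, LD pruning."""
    config = config or PcaConfig()
    af = genotypes.alt_allele_frequency()
    with np.errstate(invalid="ignore"):
        maf = np.minimum(af, 1 - af)
        pass_maf = maf > config.maf_min
    hwe = hwe_pvalues_for_matrix(genotypes)
    pass_hwe = np.where(np.isnan(hwe), False, hwe > config.hwe_p_min)
    idx = np.flatnonzero(pass_maf & pass_hwe)
    if idx.size == 0:
        raise ValueError("no variants pass the PCA filters")
    kept = ld_prune(genotypes, idx, config.ld_r2_max, config.ld_window_bp)
    if kept.size == 0:
        raise ValueError("LD pruning removed every candidate PCA variant")
    return kept


def compute_pcs(
    genotypes: GenotypeMatrix, variant_idx: np.ndarray, n_pcs: int
) -> np.ndarray:
    """HWE-normalized PCA scores (samples x n_pcs).

    Columns are standardized as (g - 2p) / sqrt(2p(1-p)) with missing values
    set to 0 after centering; scores are left singular vectors scaled by
    singular values, sign-fixed so each component's largest-magnitude
    variant loading is positive.
    """
    variant_idx = np.asarray(variant_idx)
    g = genotypes.genotypes[:, variant_idx]
    n, m = g.shape
    if n < n_pcs + 1:
        raise ValueError(f"need at least {n_pcs + 1} samples for {n_pcs} PCs")
    if m < n_pcs:
        raise ValueError(f"need at least {n_pcs} variants for {n_pcs} PCs")
    p = np.nanmean(g, axis=0) / 2
    denom = np.sqrt(2 * p * (1 - p))
    usable = (p > 0) & (p < 1)
    x = (g[:, usable] - 2 * p[usable]) / denom[usable]
    x = np.where(np.isnan(x), 0.0, x)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    tol = s.max() * max(x.shape) * np.finfo(float).eps
    rank = int((s > tol).sum())
    if rank < n_pcs:
        raise ValueError(
            f"genotype matrix rank {rank} < requested {n_pcs} PCs; "
            f"at most {rank} PCs are computable"
        )
    scores = u[:, :n_pcs] * s[:n_pcs]
    # deterministic sign: largest-|loading| positive per component
    for k in range(n_pcs):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            scores[:, k] *= -1
    return scores


def residualize_prs(
    raw: np.ndarray, pcs: np.ndarray, n_pcs: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Regress the raw PRS on the top PCs; z-score the residual.

    Returns (adjusted PRS with mean 0 and SD 1 using the n-1 denominator,
    fitted coefficients [intercept, pc1..pcK]).
    """
    raw = np.asarray(raw, dtype=float)
    pcs = np.asarray(pcs, dtype=float)
    if n_pcs is not None:
        pcs = pcs[:, :n_pcs]
    n, k = pcs.shape
    if n <= k + 1:
        raise ValueError("need more samples than PCs + 1")
    if raw.std(ddof=1) == 0:
        raise ValueError("raw PRS has zero variance")
    # collinearity check with an informative pair
    if k >= 2:
        c = np.corrcoef(pcs, rowvar=False)
        iu = np.triu_indices(k, 1)
        worst = np.nanargmax(np.abs(c[iu]))
        if np.abs(c[iu][worst]) > 1 - 1e-10:
            a, b = iu[0][worst] + 1, iu[1][worst] + 1
            raise ValueError(f"collinear PCs: PC{a} and PC{b}")
    x = np.column_stack([np.ones(n), pcs])
    coef, *_ = np.linalg.lstsq(x, raw, rcond=None)
    resid = raw - x @ coef
    sd = resid.std(ddof=1)
    if sd < 1e-12 * max(1.0, np.abs(raw).max()):
        raise ValueError("residual PRS is numerically constant; cannot standardize")
    return (resid - resid.mean()) / sd, coef


def compute_prs(
    dosages: DosageMatrix,
    weights: WeightSet,
    pcs: np.ndarray,
    n_pcs: int = 10,
) -> PRSResult:
    """Raw + PC-residualized standardized PRS for one weight set."""
    raw, mw = score_prs(dosages, weights)
    adjusted, coef = residualize_prs(raw, pcs, n_pcs)
    return PRSResult(
        samples=list(dosages.samples),
        raw=raw,
        adjusted=adjusted,
        pc_coefficients=coef,
        n_matched_variants=mw.n_matched,
    )


def kinship_matrix(genotypes: GenotypeMatrix, variant_idx: np.ndarray | None = None) -> np.ndarray:
    """Kinship phi = GRM / 2 with HWE-scaled genotypes, missing mean-imputed."""
    g = genotypes.genotypes
    if variant_idx is not None:
        g = g[:, np.asarray(variant_idx)]
    p = np.nanmean(g, axis=0) / 2
    usable = (p > 0) & (p < 1)
    if not usable.any():
        raise ValueError("no polymorphic variants available for kinship")
    g = g[:, usable]
    p = p[usable]
    x = (g - 2 * p) / np.sqrt(2 * p * (1 - p))
    x = np.where(np.isnan(x), 0.0, x)
    grm = (x @ x.T) / x.shape[1]
    return grm / 2.0


def kinship_and_prune(
    genotypes: GenotypeMatrix,
    threshold: float = 0.125,
    variant_idx: np.ndarray | None = None,
) -> KinshipResult:
    """Greedy pruning until no pair exceeds the kinship threshold.

    Repeatedly removes the sample in the most violating pairs; ties broken
    by more missing genotypes, then by the lexicographically larger sample
    id.
    """
    if genotypes.n_samples < 2:
        raise ValueError("need at least 2 samples for relatedness pruning")
    phi = kinship_matrix(genotypes, variant_idx)
    n = phi.shape[0]
    miss = np.isnan(genotypes.genotypes).sum(axis=1)
    active = np.ones(n, dtype=bool)
    viol = (phi > threshold) & ~np.eye(n, dtype=bool)
    removed: list[int] = []
    while True:
        counts = (viol & active[None, :] & active[:, None]).sum(axis=1)
        counts[~active] = 0
        worst = counts.max()
        if worst == 0:
            break
        cand = np.flatnonzero(counts == worst)
        # tie-break: most missing genotypes, then larger sample id
        best = max(cand, key=lambda i: (miss[i], genotypes.samples[i]))
        active[best] = False
        removed.append(best)
    kept = [genotypes.samples[i] for i in range(n) if active[i]]
    return KinshipResult(
        samples=list(genotypes.samples),
        phi=phi,
        kept=kept,
        removed=[genotypes.samples[i] for i in removed],
        threshold=threshold,
    )
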