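"""In-memory containers for dosage/genotype matrices, weight sets and phenotypes.

Variant identity throughout is the biallelic key (chrom, pos, ref, alt) with
1-based positions and uppercase alleles, i.e. the coordinates of a
normalized, decomposed VCF record.  Dosages are expected alternate-allele
counts in [0, 2]; genotypes are hard alternate-allele counts {0, 1, 2}.
Missing entries are NaN in both matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

VARIANT_COLS = ["chrom", "pos", "ref", "alt"]

#: tri-state family-history flag values
FLAG_VALUES = ("yes", "no", "unknown")


def variant_index(table: pd.DataFrame) -> pd.MultiIndex:
    """MultiIndex of (chrom, pos, ref, alt) keys for a variant table."""
    return pd.MultiIndex.from_arrays(
        [table["chrom"].astype(str), table["pos"].astype(int),
         table["ref"].astype(str), table["alt"].astype(str)],
        names=VARIANT_COLS,
    )


def validate_variant_table(table: pd.DataFrame) -> None:
    missing = [c for c in VARIANT_COLS if c not in table.columns]
    if missing:
        raise ValueError(f"variant table lacks columns {missing}")
    if (table["pos"] < 1).any():
        raise ValueError("variant positions must be 1-based (>= 1)")
    if (table["ref"] == table["alt"]).any():
        raise ValueError("ref and alt alleles must differ")
    for col in ("ref", "alt"):
        vals = table[col].astype(str)
        if (vals != vals.str.upper()).any():
            raise ValueError(f"{col} alleles must be uppercase")


@dataclass
class DosageMatrix:
    """Imputed dosages with per-variant imputation quality (INFO) and cohort MAF.

    ``dosages`` is samples x variants, values in [0, 2] or NaN.  ``info`` is
    the imputation quality score in [0, 1] (1 = high confidence); ``maf`` is
    the cohort minor allele frequency folded to <= 0.5 (NaN when every
    dosage at the site is missing).
    """

    samples: list[str]
    variants: pd.DataFrame          # chrom, pos, ref, alt
    dosages: np.ndarray             # (n_samples, n_variants) float
    info: np.ndarray                # (n_variants,) float
    maf: np.ndarray                 # (n_variants,) float

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.info = np.asarray(self.info, dtype=float)
        self.maf = np.asarray(self.maf, dtype=float)
        validate_variant_table(self.variants)
        n_s, n_v = self.dosages.shape
        if n_s != len(self.samples) or n_v != len(self.variants):
            raise ValueError("dosage matrix shape does not match samples/variants")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosages, initial=0) < 0 or np.nanmax(self.dosages, initial=0) > 2:
                raise ValueError("dosages must lie in [0, 2]")
            ok_info = np.isnan(self.info) | ((self.info >= 0) & (self.info <= 1))
            if not ok_info.all():
                raise ValueError("INFO scores must lie in [0, 1]")
            ok_maf = np.isnan(self.maf) | ((self.maf >= 0) & (self.maf <= 0.5))
            if not ok_maf.all():
                raise ValueError("MAF must lie in [0, 0.5]")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def key_index(self) -> pd.MultiIndex:
        return variant_index(self.variants)

    def subset_variants(self, mask: np.ndarray) -> "DosageMatrix":
        mask = np.asarray(mask)
        return DosageMatrix(
            samples=list(self.samples),
            variants=self.variants.loc[mask].reset_index(drop=True)
            if mask.dtype == bool else self.variants.iloc[mask].reset_index(drop=True),
            dosages=self.dosages[:, mask],
            info=self.info[mask],
            maf=self.maf[mask],
        )


@dataclass
class GenotypeMatrix:
    """Hard-call alternate-allele counts, values in {0, 1, 2} or NaN."""

    samples: list[str]
    variants: pd.DataFrame
    genotypes: np.ndarray           # (n_samples, n_variants) float

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        validate_variant_table(self.variants)
        n_s, n_v = self.genotypes.shape
        if n_s != len(self.samples) or n_v != len(self.variants):
            raise ValueError("genotype matrix shape does not match samples/variants")
        vals = self.genotypes[~np.isnan(self.genotypes)]
        if not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("genotype values must be in {0, 1, 2} or NaN")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def key_index(self) -> pd.MultiIndex:
        return variant_index(self.variants)

    def alt_allele_frequency(self) -> np.ndarray:
        """Per-variant alternate-allele frequency from non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.genotypes, axis=0) / 2.0

    def subset_samples(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            variants=self.variants,
            genotypes=self.genotypes[idx],
        )


@dataclass
class WeightSet:
    """PRS weight table keyed by variant, with reported population AUC metadata.

    ``table`` columns: chrom, pos, ref, alt, effect_allele, weight.  The
    effect allele must equal ref or alt of its key.  ``reported_population_auc``
    is the discrimination (AUC) the weight set achieved in its source
    population, carried as metadata for cross-set comparisons.
    """

    set_id: str
    table: pd.DataFrame
    reported_population_auc: float | None = None

    def __post_init__(self) -> None:
        validate_variant_table(self.table)
        need = {"effect_allele", "weight"}
        if not need.issubset(self.table.columns):
            raise ValueError(f"weight table lacks columns {sorted(need - set(self.table.columns))}")
        bad = ~(
            (self.table["effect_allele"] == self.table["ref"])
            | (self.table["effect_allele"] == self.table["alt"])
        )
        if bad.any():
            raise ValueError("effect_allele must equal ref or alt for every weight")
        if not np.isfinite(self.table["weight"].to_numpy(dtype=float)).all():
            raise ValueError("weights must be finite")
        idx = variant_index(self.table)
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"duplicate variant key in weight set: {dup}")

    @property
    def n_variants(self) -> int:
        return len(self.table)

    def key_index(self) -> pd.MultiIndex:
        return variant_index(self.table)


PHENOTYPE_COLUMNS = [
    "sample_id", "age", "fh_bc_first", "fh_bc_any", "fh_anycancer_any", "pv_carrier",
]


def validate_phenotypes(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a phenotype table (tri-state family-history flags, ages > 0)."""
    missing = [c for c in PHENOTYPE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"phenotype table lacks columns {missing}")
    for col in ("fh_bc_first", "fh_bc_any", "fh_anycancer_any"):
        bad = ~table[col].isin(FLAG_VALUES)
        if bad.any():
            raise ValueError(
                f"{col} must be one of {FLAG_VALUES}; got {sorted(table.loc[bad, col].unique())}"
            )
    ages = table["age"].to_numpy(dtype=float)
    if np.any(ages[~np.isnan(ages)] <= 0):
        raise ValueError("ages must be positive")
    if table["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in phenotype table")
    return table


def flags_to_binary(flags: pd.Series | np.ndarray) -> np.ndarray:
    """Map tri-state flags to 1/0/NaN (yes/no/unknown)."""
    arr = np.asarray(flags, dtype=object)
    out = np.full(arr.shape, np.nan)
    out[arr == "yes"] = 1.0
    out[arr == "no"] = 0.0
    return out
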