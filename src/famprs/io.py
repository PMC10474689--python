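"""Readers and writers for the formats the pipeline touches.

Dosage VCFs carry a per-sample ``DS`` FORMAT field (expected alternate-allele
count in [0, 2]) and a per-variant imputation quality annotation (default
INFO key ``INFO``, the score emitted by low-pass imputation tools).  Truth
VCFs carry hard ``GT`` calls.  Weight tables and phenotype tables are TSV.
All readers log counts of kept/dropped records on the returned objects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .containers import (
    DosageMatrix,
    GenotypeMatrix,
    PHENOTYPE_COLUMNS,
    WeightSet,
    validate_phenotypes,
    variant_index,
)

logger = logging.getLogger(__name__)


def _fold(af: np.ndarray) -> np.ndarray:
    """Fold alternate-allele frequency to minor allele frequency (<= 0.5)."""
    return np.minimum(af, 1.0 - af)


def read_dosage_vcf(path: str | Path, info_key: str = "INFO") -> DosageMatrix:
    """Read an imputed-dosage VCF into a DosageMatrix.

    Biallelic records only; multiallelic records are skipped and counted.
    Cohort MAF is computed from the mean dosage / 2, folded to <= 0.5;
    all-missing variants get MAF = NaN.  Raises if the DS field or the
    imputation-quality annotation is absent.
    """
    path = Path(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, dos_cols, infos = [], [], []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is None:
            raise ValueError(f"{path}: record {rec.CHROM}:{rec.POS} has no DS field")
        q = rec.INFO.get(info_key)
        if q is None:
            raise ValueError(
                f"{path}: record {rec.CHROM}:{rec.POS} lacks imputation quality key '{info_key}'"
            )
        rows.append((rec.CHROM, rec.POS, rec.REF.upper(), rec.ALT[0].upper()))
        dos_cols.append(np.asarray(ds, dtype=float).reshape(-1))
        infos.append(float(q))
    if not rows:
        raise ValueError(f"{path}: no biallelic dosage records found")
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    dosages = np.column_stack(dos_cols)
    with np.errstate(invalid="ignore"):
        maf = _fold(np.nanmean(dosages, axis=0) / 2.0)
    n_allmiss = int(np.isnan(maf).sum())
    if n_multi:
        logger.info("%s: skipped %d multiallelic records", path.name, n_multi)
    if n_allmiss:
        logger.info("%s: %d variants with all dosages missing", path.name, n_allmiss)
    dm = DosageMatrix(samples, variants, dosages, np.array(infos), maf)
    dm.n_multiallelic_skipped = n_multi
    dm.n_all_missing = n_allmiss
    return dm


def read_genotype_vcf(path: str | Path) -> GenotypeMatrix:
    """Read hard GT calls into a GenotypeMatrix.

    Alternate-allele counts 0/1/2; half calls and ``./.`` become missing;
    phase is ignored; a non-diploid call with typed alleles is an error.
    Multiallelic records are skipped and counted.
    """
    path = Path(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, geno_cols = [], []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        col = np.full(len(samples), np.nan)
        for i, call in enumerate(rec.genotypes):
            alleles = call[:-1]  # last element is the phase flag
            if all(a < 0 for a in alleles):
                continue  # fully missing
            if len(alleles) != 2:
                raise ValueError(
                    f"{path}: non-diploid call for sample {samples[i]} at {rec.CHROM}:{rec.POS}"
                )
            if any(a < 0 for a in alleles):
                continue  # half call -> missing
            if any(a > 1 for a in alleles):
                raise ValueError(
                    f"{path}: allele index >1 in biallelic record at {rec.CHROM}:{rec.POS}"
                )
            col[i] = float(sum(alleles))
        rows.append((rec.CHROM, rec.POS, rec.REF.upper(), rec.ALT[0].upper()))
        geno_cols.append(col)
    if not rows:
        raise ValueError(f"{path}: no biallelic genotype records found")
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    gm = GenotypeMatrix(samples, variants, np.column_stack(geno_cols))
    gm.n_multiallelic_skipped = n_multi
    if n_multi:
        logger.info("%s: skipped %d multiallelic records", path.name, n_multi)
    return gm


def read_weight_table(path: str | Path) -> WeightSet:
    """Read a TSV weight table.

    Metadata (set id, reported population AUC) is carried on ``#key=value``
    comment lines preceding the header.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = 0
        for line in fh:
            if not line.startswith("#"):
                break
            pos += len(line)
            body = line.lstrip("#").strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
        fh.seek(pos)
        table = pd.read_csv(fh, sep="\t")
    table["ref"] = table["ref"].str.upper()
    table["alt"] = table["alt"].str.upper()
    table["effect_allele"] = table["effect_allele"].str.upper()
    auc = meta.get("reported_population_auc")
    return WeightSet(
        set_id=meta.get("set_id", path.stem),
        table=table,
        reported_population_auc=float(auc) if auc is not None else None,
    )


def write_weight_table(weights: WeightSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# set_id={weights.set_id}\n")
        if weights.reported_population_auc is not None:
            fh.write(f"# reported_population_auc={weights.reported_population_auc}\n")
        weights.table.to_csv(fh, sep="\t", index=False, float_format="%.8g")


def read_phenotype_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return validate_phenotypes(table)


def write_phenotype_table(table: pd.DataFrame, path: str | Path) -> None:
    validate_phenotypes(table)
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# VCF writing (plain-text v4.2, enough for round-tripping synthetic cohorts)

def _vcf_header(samples: list[str], chroms: list[str], fields: str) -> str:
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines.append(fields)
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    return "\n".join(lines) + "\n"


def write_dosage_vcf(dm: DosageMatrix, path: str | Path, info_key: str = "INFO") -> None:
    chroms = list(dict.fromkeys(dm.variants["chrom"].astype(str)))
    fields = (
        f'##INFO=<ID={info_key},Number=1,Type=Float,Description="Imputation quality score">\n'
        '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Imputed alternate allele dosage">'
    )
    with open(path, "w") as fh:
        fh.write(_vcf_header(dm.samples, chroms, fields))
        for j in range(dm.n_variants):
            v = dm.variants.iloc[j]
            ds = [
                "." if np.isnan(d) else f"{d:.4f}" for d in dm.dosages[:, j]
            ]
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t"
                f"{info_key}={dm.info[j]:.4f}\tDS\t" + "\t".join(ds) + "\n"
            )


def write_genotype_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    chroms = list(dict.fromkeys(gm.variants["chrom"].astype(str)))
    fields = '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">'
    with open(path, "w") as fh:
        fh.write(_vcf_header(gm.samples, chroms, fields))
        for j in range(gm.n_variants):
            v = gm.variants.iloc[j]
            gts = [
                "./." if np.isnan(g) else gt_map[g] for g in gm.genotypes[:, j]
            ]
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# Weight-to-dosage matching (PLINK --score allele semantics)

AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class MatchedWeights:
    """Alignment of a weight set onto a dosage matrix.

    ``variant_idx`` indexes columns of the dosage matrix; ``flip[i]`` is True
    where the effect allele is the reference allele, so the effect dosage is
    ``2 - d``.  Unmatched weight-set variants are dropped and counted.
    """

    variant_idx: np.ndarray
    weights: np.ndarray
    flip: np.ndarray
    n_matched: int
    n_unmatched: int
    n_ambiguous: int

    def effect_dosage(self, dosages: np.ndarray) -> np.ndarray:
        """Effect-allele dosage matrix (samples x matched variants)."""
        d = dosages[:, self.variant_idx]
        return np.where(self.flip, 2.0 - d, d)


def match_weights(
    weights: WeightSet, dosages: DosageMatrix, drop_ambiguous: bool = False
) -> MatchedWeights:
    """Align a weight set to dosage-matrix columns by (chrom,pos,ref,alt) key.

    Effect allele equal to alt keeps the dosage as-is; equal to ref flips it
    (2 - d).  Strand-ambiguous ref/alt pairs (A/T, C/G) are kept by default
    since keys carry both alleles; ``drop_ambiguous=True`` removes them.
    Raises when zero variants match.
    """
    dm_index = dosages.key_index()
    ws_index = weights.key_index()
    locs = dm_index.get_indexer(ws_index)
    found = locs >= 0
    tab = weights.table
    ambiguous = np.array(
        [(r, a) in AMBIGUOUS_PAIRS for r, a in zip(tab["ref"], tab["alt"])]
    )
    keep = found & (~ambiguous if drop_ambiguous else True)
    n_unmatched = int((~found).sum())
    if not keep.any():
        raise ValueError(
            f"no weight-set variants matched the dosage matrix "
            f"({len(tab)} weights, {n_unmatched} unmatched)"
        )
    flip = (tab["effect_allele"] == tab["ref"]).to_numpy()[keep]
    mw = MatchedWeights(
        variant_idx=locs[keep],
        weights=tab["weight"].to_numpy(dtype=float)[keep],
        flip=flip,
        n_matched=int(keep.sum()),
        n_unmatched=n_unmatched,
        n_ambiguous=int((ambiguous & found).sum()),
    )
    if n_unmatched:
        logger.info(
            "weight set %s: %d/%d variants unmatched", weights.set_id, n_unmatched, len(tab)
        )
    return mw
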