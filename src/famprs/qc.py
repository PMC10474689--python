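"""Imputation-concordance QC.

The central quantity is the *dosage correlation*: within one sample, the
Pearson correlation between imputed dosages and the truth alternate-allele
counts over the variants present in both call sets.  Correlations are
reported per sample, overall and stratified into imputation-quality (INFO)
bins or minor-allele-frequency bins, and summarized as per-bin medians and
interquartile ranges across samples.  Cohort allele frequencies can also be
correlated against external reference-panel frequency tables to rank
candidate ancestry groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import DosageMatrix, GenotypeMatrix


@dataclass
class QCConfig:
    info_bins: tuple[float, ...] = tuple(np.round(np.linspace(0.0, 1.0, 11), 2))
    maf_bins: tuple[float, ...] = (0.0, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5)
    info_threshold: float = 0.8

    def __post_init__(self) -> None:
        for edges in (self.info_bins, self.maf_bins):
            if np.any(np.diff(edges) <= 0):
                raise ValueError("bin edges must be strictly increasing")
        if not (0 <= self.info_threshold <= 1):
            raise ValueError("info_threshold must lie in [0, 1]")


@dataclass
class PairedCalls:
    """Per-sample pairing of imputed dosages with truth genotypes."""

    samples: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray     # (n_samples, n_variants)
    truth: np.ndarray       # (n_samples, n_variants)
    info: np.ndarray
    maf: np.ndarray

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of pairs where both calls are non-missing."""
        return ~(np.isnan(self.dosages) | np.isnan(self.truth))


@dataclass
class ConcordanceReport:
    """Long-format per-sample per-bin correlations plus per-bin summaries.

    ``per_sample`` columns: sample, bin_type, bin_label, n_pairs, r (NaN when
    undefined).  ``summary`` columns: bin_type, bin_label, bin_mid,
    n_samples_defined, median_r, q1_r, q3_r.  Undefined correlations (fewer
    than two pairs, or zero variance in either vector) are excluded from the
    medians rather than imputed.
    """

    per_sample: pd.DataFrame
    summary: pd.DataFrame


def intersect_pairs(dosages: DosageMatrix, truth: GenotypeMatrix) -> PairedCalls:
    """Pair imputed and truth calls on shared samples and variant keys."""
    shared_samples = [s for s in dosages.samples if s in set(truth.samples)]
    if not shared_samples:
        raise ValueError("no shared samples between dosage and truth matrices")
    d_idx = [dosages.samples.index(s) for s in shared_samples]
    t_idx = [truth.samples.index(s) for s in shared_samples]

    locs = truth.key_index().get_indexer(dosages.key_index())
    both = locs >= 0
    return PairedCalls(
        samples=shared_samples,
        variants=dosages.variants.loc[both].reset_index(drop=True),
        dosages=dosages.dosages[np.ix_(d_idx, np.flatnonzero(both))],
        truth=truth.genotypes[np.ix_(t_idx, locs[both])],
        info=dosages.info[both],
        maf=dosages.maf[both],
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r, NaN when undefined (n < 2 or zero variance)."""
    if x.size < 2:
        return np.nan
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc * xc).sum())
    sy = np.sqrt((yc * yc).sum())
    if sx == 0 or sy == 0:
        return np.nan
    return float((xc * yc).sum() / (sx * sy))


def _assign_bins(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Bin index per value: right-closed, left-open except the first bin."""
    edges = np.asarray(edges, dtype=float)
    idx = np.searchsorted(edges, values, side="left") - 1
    idx[values == edges[0]] = 0          # first bin includes its left edge
    idx[(values > edges[-1]) | (values < edges[0])] = -1
    return idx


def dosage_correlation(
    pairs: PairedCalls,
    group_by: str | None = None,
    config: QCConfig | None = None,
) -> ConcordanceReport:
    """Per-sample dosage correlations, optionally binned by INFO or MAF.

    ``group_by`` is None (one overall correlation per sample), ``"info"`` or
    ``"maf"``.
    """
    config = config or QCConfig()
    if pairs.variants.empty or not pairs.valid.any():
        raise ValueError("empty pairing: no variants with both calls present")

    if group_by is None:
        edges = None
        bin_idx = np.zeros(len(pairs.variants), dtype=int)
        labels = {0: "overall"}
        mids = {0: np.nan}
        bin_type = "overall"
    elif group_by == "info":
        edges = np.asarray(config.info_bins)
        bin_idx = _assign_bins(pairs.info, edges)
        bin_type = "info"
    elif group_by == "maf":
        edges = np.asarray(config.maf_bins)
        with np.errstate(invalid="ignore"):
            bin_idx = _assign_bins(pairs.maf, edges)
        bin_idx[np.isnan(pairs.maf)] = -1
        bin_type = "maf"
    else:
        raise ValueError(f"unknown group_by: {group_by!r}")
    if edges is not None:
        labels = {
            b: f"{edges[b]:g}-{edges[b + 1]:g}" for b in range(len(edges) - 1)
        }
        mids = {b: (edges[b] + edges[b + 1]) / 2 for b in range(len(edges) - 1)}

    valid = pairs.valid
    records = []
    for b in sorted(labels):
        in_bin = bin_idx == b
        if not in_bin.any():
            continue
        for i, sample in enumerate(pairs.samples):
            m = in_bin & valid[i]
            n = int(m.sum())
            r = _pearson(pairs.dosages[i, m], pairs.truth[i, m]) if n >= 2 else np.nan
            records.append((sample, bin_type, labels[b], mids[b], n, r))
    per_sample = pd.DataFrame(
        records, columns=["sample", "bin_type", "bin_label", "bin_mid", "n_pairs", "r"]
    )
    summary = (
        per_sample.dropna(subset=["r"])
        .groupby(["bin_type", "bin_label", "bin_mid"], dropna=False)["r"]
        .agg(
            n_samples_defined="count",
            median_r="median",
            q1_r=lambda s: s.quantile(0.25),
            q3_r=lambda s: s.quantile(0.75),
        )
        .reset_index()
        .sort_values("bin_mid", na_position="first")
        .reset_index(drop=True)
    )
    return ConcordanceReport(per_sample=per_sample, summary=summary)


def filter_by_info(dosages: DosageMatrix, threshold: float) -> DosageMatrix:
    """Keep variants with imputation quality strictly above the threshold."""
    if not (0 <= threshold <= 1):
        raise ValueError("threshold must lie in [0, 1]")
    return dosages.subset_variants(dosages.info > threshold)


def af_correlation(cohort_af: pd.DataFrame, panel_af: pd.DataFrame) -> pd.DataFrame:
    """Correlate cohort alternate-allele frequencies with panel groups.

    ``cohort_af`` columns: chrom, pos, ref, alt, af.  ``panel_af`` long
    format: chrom, pos, ref, alt, group, af.  Returns one row per group with
    the Pearson r over overlapping variants (unfolded frequencies) and the
    overlap count; groups with < 2 overlapping variants are flagged with
    r = NaN rather than dropped.
    """
    rows = []
    key_cols = ["chrom", "pos", "ref", "alt"]

    def norm(df: pd.DataFrame) -> pd.DataFrame:
        df = df.copy()
        df["chrom"] = df["chrom"].astype(str)
        df["pos"] = df["pos"].astype(int)
        return df

    cohort_af = norm(cohort_af)
    panel_af = norm(panel_af)
    for group, sub in panel_af.groupby("group"):
        merged = cohort_af.merge(sub, on=key_cols, suffixes=("_cohort", "_panel"))
        n = len(merged)
        r = (
            _pearson(
                merged["af_cohort"].to_numpy(dtype=float),
                merged["af_panel"].to_numpy(dtype=float),
            )
            if n >= 2
            else np.nan
        )
        rows.append((group, n, r))
    out = pd.DataFrame(rows, columns=["group", "n_overlap", "r"])
    return out.sort_values("r", ascending=False, na_position="last").reset_index(drop=True)


def write_concordance_report(report: ConcordanceReport, tsv_path, json_path) -> None:
    import json

    report.per_sample.to_csv(tsv_path, sep="\t", index=False, float_format="%.6g")
    payload = report.summary.to_dict(orient="records")
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2)
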