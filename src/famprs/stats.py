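"""Statistical battery for the case-only PRS analyses.

AUC here is used in a case-only sense: instead of discriminating cases from
controls (AUC_population, supplied as weight-set metadata), the score is
asked to discriminate, within a cohort of patients, those with an affected
first-degree relative (AUC_family), any-degree relative (AUC_family-any) or
any relative with any cancer.  Confidence intervals for AUC use the
Hanley–McNeil variance; 2x2 tables use the exact conditional
(hypergeometric) Fisher test with the minimum-likelihood two-sided rule;
the AUC-improvement-after-carrier-removal procedure is assessed by
whole-cohort bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats.contingency import odds_ratio as _scipy_odds_ratio
import statsmodels.api as sm


# ---------------------------------------------------------------------------
# AUC

@dataclass
class AUCResult:
    auc: float
    n_pos: int
    n_neg: int
    ci_low: float = np.nan
    ci_high: float = np.nan
    level: float = np.nan


def auc_rank(scores: np.ndarray, labels: np.ndarray) -> AUCResult:
    """Rank (Mann–Whitney) AUC with ties counted 1/2.

    ``labels`` may contain NaN (unknown); those samples are excluded first.
    Raises if only one class remains.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    known = ~np.isnan(labels)
    scores, labels = scores[known], labels[known]
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = sps.rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2
    return AUCResult(auc=float(u / (n_pos * n_neg)), n_pos=n_pos, n_neg=n_neg)


def hanley_ci(
    auc: float, n_pos: int, n_neg: int, level: float = 0.95
) -> tuple[float, float]:
    """Hanley–McNeil confidence interval for an AUC.

    SE^2 = [A(1-A) + (n_pos-1)(Q1-A^2) + (n_neg-1)(Q2-A^2)] / (n_pos n_neg)
    with Q1 = A/(2-A), Q2 = 2A^2/(1+A); the interval is A +- z SE clamped
    to [0, 1].
    """
    if not (0 <= auc <= 1):
        raise ValueError("auc must lie in [0, 1]")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need at least one sample per class")
    if not (0 < level < 1):
        raise ValueError("confidence level must lie in (0, 1)")
    a = auc
    q1 = a / (2 - a)
    q2 = 2 * a * a / (1 + a)
    se = np.sqrt(
        (a * (1 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a))
        / (n_pos * n_neg)
    )
    z = sps.norm.ppf((1 + level) / 2)
    return float(max(0.0, a - z * se)), float(min(1.0, a + z * se))


def auc_with_ci(scores, labels, level: float = 0.95) -> AUCResult:
    res = auc_rank(scores, labels)
    lo, hi = hanley_ci(res.auc, res.n_pos, res.n_neg, level)
    return AUCResult(res.auc, res.n_pos, res.n_neg, lo, hi, level)


# ---------------------------------------------------------------------------
# Fisher exact 2x2

@dataclass
class FisherResult:
    odds_ratio: float           # sample (cross-product) OR; inf/nan on zero cells
    conditional_or: float       # conditional MLE OR
    ci_low: float
    ci_high: float
    p_value: float
    method: str


def _minlike_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided minimum-likelihood exact p for a 2x2 table.

    Conditions on both margins and sums the hypergeometric probabilities of
    every table whose point probability does not exceed the observed one.
    """
    row1, col1, n = a + b, a + c, a + b + c + d
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = sps.hypergeom.pmf(support, n, row1, col1)
    p_obs = pmf[support == a][0]
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return 1.0 if p > 1 - 1e-9 else p


def fisher_2x2(
    table: np.ndarray | tuple,
    alternative: str = "two_sided_minlike",
    level: float = 0.95,
) -> FisherResult:
    """Exact conditional Fisher test on a 2x2 table (rows = exposure).

    ``two_sided_minlike`` sums all fixed-margin tables no more likely than
    the observed one; ``two_sided_central`` doubles the smaller tail.  The
    interval is the exact conditional (central) interval from inverting the
    noncentral hypergeometric tails.
    """
    t = np.asarray(table, dtype=float).reshape(2, 2)
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("table entries must be non-negative integers")
    a, b, c, d = (int(x) for x in t.ravel())
    n = a + b + c + d
    if n == 0 or min(a + b, c + d) < 0 or (a + b == 0 or c + d == 0) or (a + c == 0 or b + d == 0):
        raise ValueError("2x2 table has an empty margin")
    if b * c == 0:
        or_sample = np.inf if a * d > 0 else np.nan
    else:
        or_sample = (a * d) / (b * c)
    res = _scipy_odds_ratio([[a, b], [c, d]], kind="conditional")
    ci = res.confidence_interval(confidence_level=level)
    if alternative == "two_sided_minlike":
        p = _minlike_p(a, b, c, d)
    elif alternative in ("two_sided_central", "greater", "less"):
        row1, col1 = a + b, a + c
        lo = sps.hypergeom.cdf(a, n, row1, col1)
        hi = sps.hypergeom.sf(a - 1, n, row1, col1)
        if alternative == "greater":
            p = float(hi)
        elif alternative == "less":
            p = float(lo)
        else:
            p = float(min(1.0, 2 * min(lo, hi)))
    else:
        raise ValueError(f"unknown alternative: {alternative!r}")
    return FisherResult(
        odds_ratio=float(or_sample),
        conditional_or=float(res.statistic),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        p_value=p,
        method=alternative,
    )


# ---------------------------------------------------------------------------
# Rank tests

def mann_whitney(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann–Whitney U test.

    Exact enumeration when min(n_x, n_y) <= 8 and there are no ties; normal
    approximation with tie and continuity corrections otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative=alternative, method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with the t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return np.nan, np.nan
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Decile analysis

@dataclass
class DecileReport:
    deciles: np.ndarray             # 1..10 per analyzed sample
    sample_ids: np.ndarray
    proportions: pd.DataFrame       # decile, n, n_pos, prop
    top_vs_middle: FisherResult
    bottom_vs_middle: FisherResult
    excluded_pv: bool


def _decile_assign(values: np.ndarray) -> np.ndarray:
    """Deciles 1..10 with sizes differing by at most one, ties by stable order."""
    n = values.size
    order = np.argsort(values, kind="stable")
    deciles = np.empty(n, dtype=int)
    splits = np.array_split(np.arange(n), 10)
    for q, chunk in enumerate(splits, start=1):
        deciles[order[chunk]] = q
    return deciles


def decile_analysis(
    adjusted_prs: np.ndarray,
    fh_labels: np.ndarray,
    pv_flags: np.ndarray,
    exclude_pv: bool = False,
    sample_ids: np.ndarray | None = None,
    recompute_deciles: bool = True,
) -> DecileReport:
    """Family-history enrichment across PRS deciles.

    Unknown labels are excluded before decile assignment; with
    ``exclude_pv`` carriers are removed and (by default) deciles are
    recomputed on the remaining samples.  Odds ratios compare the top decile
    (Q10) and bottom decile (Q1) against the middle (Q2–Q9).
    """
    adjusted_prs = np.asarray(adjusted_prs, dtype=float)
    labels = np.asarray(fh_labels, dtype=float)
    pv = np.asarray(pv_flags, dtype=bool)
    if sample_ids is None:
        sample_ids = np.arange(adjusted_prs.size)
    sample_ids = np.asarray(sample_ids)

    keep = ~np.isnan(labels)
    if exclude_pv:
        keep &= ~pv
    prs, labels, ids = adjusted_prs[keep], labels[keep], sample_ids[keep]
    if prs.size < 20:
        raise ValueError("need at least 20 labelled samples for a decile analysis")
    if not recompute_deciles and exclude_pv:
        full_keep = ~np.isnan(np.asarray(fh_labels, dtype=float))
        full = _decile_assign(adjusted_prs[full_keep])
        deciles = full[(~pv[full_keep])]
    else:
        deciles = _decile_assign(prs)

    rows = []
    for q in range(1, 11):
        m = deciles == q
        rows.append((q, int(m.sum()), int(labels[m].sum()), float(labels[m].mean())))
    props = pd.DataFrame(rows, columns=["decile", "n", "n_pos", "prop"])

    def table_for(group_mask: np.ndarray) -> FisherResult:
        middle = (deciles >= 2) & (deciles <= 9)
        a = int(labels[group_mask].sum())
        b = int((1 - labels[group_mask]).sum())
        c = int(labels[middle].sum())
        d = int((1 - labels[middle]).sum())
        try:
            return fisher_2x2((a, b, c, d))
        except ValueError:
            # degenerate margin (e.g. no positives outside the group):
            # flag rather than fail, so the report can show it explicitly
            orr = np.inf if a * d > 0 and b * c == 0 else np.nan
            return FisherResult(
                odds_ratio=orr, conditional_or=np.nan,
                ci_low=np.nan, ci_high=np.nan, p_value=np.nan,
                method="degenerate",
            )

    return DecileReport(
        deciles=deciles,
        sample_ids=ids,
        proportions=props,
        top_vs_middle=table_for(deciles == 10),
        bottom_vs_middle=table_for(deciles == 1),
        excluded_pv=exclude_pv,
    )


# ---------------------------------------------------------------------------
# Age-of-onset GLM

@dataclass
class GLMAgeResult:
    slope: float
    slope_ci: tuple[float, float]
    slope_p: float
    intercept: float
    intercept_ci: tuple[float, float]
    n: int


def age_glm(adjusted_prs: np.ndarray, ages: np.ndarray, level: float = 0.95) -> GLMAgeResult:
    """Gaussian GLM of age of presentation on the standardized adjusted PRS.

    The slope is years of change in onset age per PRS standard deviation
    (negative = earlier onset for higher PRS).
    """
    prs = np.asarray(adjusted_prs, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if prs.size < 3:
        raise ValueError("need at least 3 observations")
    if prs.std(ddof=1) == 0:
        raise ValueError("PRS has zero variance")
    x = sm.add_constant(prs)
    fit = sm.GLM(ages, x, family=sm.families.Gaussian()).fit()
    ci = fit.conf_int(alpha=1 - level)
    return GLMAgeResult(
        slope=float(fit.params[1]),
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
        slope_p=float(fit.pvalues[1]),
        intercept=float(fit.params[0]),
        intercept_ci=(float(ci[0][0]), float(ci[0][1])),
        n=int(prs.size),
    )


# ---------------------------------------------------------------------------
# Bootstrap AUC after carrier removal

@dataclass
class BootstrapAUCResult:
    auc_all: float
    auc_without_pv: float
    delta: float
    relative_delta: float
    p_boot: float
    n_boot: int
    n_redraws: int
    seed: int
    comparison: str


def _auc_fast(scores: np.ndarray, pos: np.ndarray) -> float:
    n_pos = int(pos.sum())
    n_neg = pos.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return np.nan
    ranks = sps.rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2
    return u / (n_pos * n_neg)


def bootstrap_auc_removal(
    scores: np.ndarray,
    labels: np.ndarray,
    pv_flags: np.ndarray,
    n_boot: int = 10_000,
    seed: int = 0,
    comparison: str = "per_replicate",
    max_redraw_factor: int = 10,
) -> BootstrapAUCResult:
    """Does removing pathogenic-variant carriers raise the AUC?

    Point estimates: AUC on the full cohort and on non-carriers only,
    delta = after - before.  Each bootstrap replicate resamples the whole
    cohort with replacement and applies the removal within the replicate;
    the bootstrap p-value is the proportion of replicates in which the
    after-removal AUC is strictly lower than the comparator (the same
    replicate's full-cohort AUC by default, or the fixed point estimate
    with ``comparison='fixed'``).  Replicates missing a class are redrawn,
    up to ``max_redraw_factor * n_boot`` total redraws.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    pv = np.asarray(pv_flags, dtype=bool)
    known = ~np.isnan(labels)
    scores, labels, pv = scores[known], labels[known], pv[known]
    pos = labels == 1
    auc_all = _auc_fast(scores, pos)
    auc_wo = _auc_fast(scores[~pv], pos[~pv])
    if np.isnan(auc_all) or np.isnan(auc_wo):
        raise ValueError("both classes must be present with and without carriers")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if comparison not in ("per_replicate", "fixed"):
        raise ValueError(f"unknown comparison: {comparison!r}")

    rng = np.random.default_rng(seed)
    n = scores.size
    lower = 0
    redraws = 0
    b = 0
    while b < n_boot:
        idx = rng.integers(0, n, n)
        s, p_, v = scores[idx], pos[idx], pv[idx]
        a_all = _auc_fast(s, p_)
        a_after = _auc_fast(s[~v], p_[~v])
        if np.isnan(a_all) or np.isnan(a_after):
            redraws += 1
            if redraws > max_redraw_factor * n_boot:
                raise RuntimeError("too many degenerate bootstrap replicates")
            continue
        ref = a_all if comparison == "per_replicate" else auc_all
        if a_after < ref:
            lower += 1
        b += 1
    return BootstrapAUCResult(
        auc_all=float(auc_all),
        auc_without_pv=float(auc_wo),
        delta=float(auc_wo - auc_all),
        relative_delta=float((auc_wo - auc_all) / auc_all),
        p_boot=lower / n_boot,
        n_boot=n_boot,
        n_redraws=redraws,
        seed=seed,
        comparison=comparison,
    )


# ---------------------------------------------------------------------------
# Weight-set evaluation

def evaluate_weight_sets(
    scored: dict[str, dict],
    label_sets: dict[str, np.ndarray],
) -> tuple[pd.DataFrame, dict]:
    """Compare weight sets on the family-history prediction tasks.

    ``scored`` maps set_id -> {"raw": z-scored raw PRS, "adjusted": adjusted
    PRS, "reported_population_auc": float or None}; ``label_sets`` maps a
    task name (fh_bc_first, fh_bc_any, fh_anycancer_any) to binary labels
    with NaN for unknown.  Returns a per-set table of AUCs pre/post
    adjustment and a summary with the cross-set Spearman correlations of the
    reported population AUC against AUC_family and against the adjustment
    delta, plus the best set (highest first-degree AUC, ties broken by the
    any-degree AUC then set id).
    """
    rows = []
    for set_id, info in scored.items():
        row: dict = {"set_id": set_id, "reported_population_auc": info.get("reported_population_auc")}
        for task, labels in label_sets.items():
            for stage in ("raw", "adjusted"):
                res = auc_with_ci(info[stage], labels)
                row[f"auc_{task}_{stage}"] = res.auc
                row[f"auc_{task}_{stage}_ci"] = (res.ci_low, res.ci_high)
        rows.append(row)
    table = pd.DataFrame(rows)

    summary: dict = {}
    first = "fh_bc_first"
    post = table[f"auc_{first}_adjusted"]
    pre = table[f"auc_{first}_raw"]
    rep = table["reported_population_auc"].astype(float)
    if len(table) >= 3 and rep.notna().all():
        rho1, p1 = spearman(rep.to_numpy(), post.to_numpy())
        rho2, p2 = spearman(rep.to_numpy(), (post - pre).to_numpy())
        summary["spearman_reported_vs_auc_family"] = (rho1, p1)
        summary["spearman_reported_vs_adjustment_delta"] = (rho2, p2)
    else:
        summary["spearman_reported_vs_auc_family"] = (np.nan, np.nan)
        summary["spearman_reported_vs_adjustment_delta"] = (np.nan, np.nan)

    any_col = "auc_fh_bc_any_adjusted"
    by = [f"auc_{first}_adjusted"]
    ascending = [False]
    if any_col in table:
        by.append(any_col)
        ascending.append(False)
    by.append("set_id")
    ascending.append(True)
    order = table.sort_values(by=by, ascending=ascending)
    summary["best_set"] = str(order.iloc[0]["set_id"])
    return table, summary


def carrier_percent(pv_flags: np.ndarray) -> float:
    """Percentage of carriers in a cohort (printed-style, e.g. 15.81)."""
    pv = np.asarray(pv_flags, dtype=bool)
    if pv.size == 0:
        raise ValueError("empty cohort")
    return float(100.0 * pv.sum() / pv.size)
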