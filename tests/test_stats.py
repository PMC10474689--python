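"""AUC, Hanley–McNeil CI, Fisher exact, rank tests, deciles, GLM, bootstrap."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from famprs import (
    age_glm,
    auc_rank,
    bootstrap_auc_removal,
    carrier_percent,
    decile_analysis,
    evaluate_weight_sets,
    fisher_2x2,
    hanley_ci,
    mann_whitney,
    spearman,
)


class TestAucRank:
    def test_perfect_separation(self):
        res = auc_rank([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0

    def test_all_ties_half(self):
        res = auc_rank(np.ones(10), [0, 1] * 5)
        assert res.auc == 0.5

    def test_unknown_labels_excluded(self):
        res = auc_rank([1, 2, 3, 4], [0, 1, np.nan, 1])
        assert (res.n_pos, res.n_neg) == (2, 1)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            auc_rank([1, 2, 3], [1, 1, 1])

    def test_example_matches_pairwise_enumeration(self):
        pos = [0.9, 0.8, 0.4]
        neg = [0.7, 0.3, 0.2]
        res = auc_rank(pos + neg, [1, 1, 1, 0, 0, 0])
        wins = sum(
            1.0 if p > n else 0.5 if p == n else 0.0
            for p in pos for n in neg
        )
        assert res.auc == pytest.approx(wins / 9)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_exhaustive_pair_count(self, seed):
        """Rank formula equals brute-force counting over all pos x neg pairs,
        including ties (n_pos, n_neg <= 8)."""
        rng = np.random.default_rng(seed)
        n_pos, n_neg = rng.integers(1, 9, 2)
        scores = np.round(rng.normal(size=n_pos + n_neg), 1)  # force some ties
        labels = np.r_[np.ones(n_pos), np.zeros(n_neg)]
        res = auc_rank(scores, labels)
        pos, neg = scores[:n_pos], scores[n_pos:]
        wins = sum(
            1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg
        )
        assert res.auc == pytest.approx(wins / (n_pos * n_neg), abs=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_label_flip_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=20)
        labels = rng.integers(0, 2, 20).astype(float)
        if labels.sum() in (0, 20):
            labels[0] = 1 - labels[0]
        a = auc_rank(scores, labels).auc
        b = auc_rank(scores, 1 - labels).auc
        assert a == pytest.approx(1 - b, abs=1e-12)


class TestHanleyCi:
    def test_symmetric_about_half(self):
        lo, hi = hanley_ci(0.5, 20, 20)
        assert lo == pytest.approx(1 - hi, abs=1e-12)

    def test_hand_arithmetic_example(self):
        """Step-by-step evaluation of the Q1/Q2 formula at A=0.75, n=10/10."""
        a = 0.75
        q1 = a / (2 - a)                      # 0.428571...
        q2 = 2 * a * a / (1 + a)              # 0.642857...
        se = math.sqrt(
            (a * (1 - a) + 9 * (q1 - a * a) + 9 * (q2 - a * a)) / 100
        )
        z = sps.norm.ppf(0.975)
        lo, hi = hanley_ci(a, 10, 10)
        assert lo == pytest.approx(a - z * se, abs=1e-12)
        assert hi == pytest.approx(a + z * se, abs=1e-12)

    def test_clamped_to_unit_interval(self):
        lo, hi = hanley_ci(0.98, 5, 5)
        assert 0 <= lo and hi <= 1

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError, match="level"):
            hanley_ci(0.6, 10, 10, level=1.5)


def _fisher_minlike_oracle(a, b, c, d):
    """Exact-rational enumeration over all tables with the observed margins."""
    row1, col1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)

    def prob(x):
        return Fraction(
            math.comb(col1, x) * math.comb(n - col1, row1 - x), math.comb(n, row1)
        )

    probs = {x: prob(x) for x in range(lo, hi + 1)}
    p_obs = probs[a]
    return float(sum(v for v in probs.values() if v <= p_obs))


class TestFisher:
    def test_printed_pv_fh_table(self):
        """The carrier x family-history table yields the cross-product OR 2.13."""
        res = fisher_2x2((7, 18, 27, 148))
        assert round(res.odds_ratio, 2) == 2.13
        # the upper-tail exact p (one-sided) for the same table
        one_sided = fisher_2x2((7, 18, 27, 148), alternative="greater")
        assert one_sided.p_value == pytest.approx(0.1038, abs=1e-4)

    def test_modal_table(self):
        res = fisher_2x2((5, 5, 5, 5))
        assert res.odds_ratio == 1.0
        assert res.p_value == 1.0

    def test_zero_cell_or_flagged_infinite(self):
        res = fisher_2x2((5, 0, 3, 7))
        assert np.isinf(res.odds_ratio)

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_2x2((0, 0, 3, 7))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_minlike_p_matches_enumeration(self, seed):
        """Minlike p equals exact-rational fixed-margin enumeration for
        random tables with margins <= 15."""
        rng = np.random.default_rng(seed)
        a, b, c, d = (int(x) for x in rng.integers(0, 11, 4))
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            a, b, c, d = a + 1, b + 1, c + 1, d + 1
        res = fisher_2x2((a, b, c, d))
        assert res.p_value == pytest.approx(
            _fisher_minlike_oracle(a, b, c, d), rel=1e-9
        )

    def test_agrees_with_scipy_two_sided(self):
        """Independent cross-check: scipy's two-sided Fisher uses the same
        minimum-likelihood rule."""
        for tbl in [(7, 18, 27, 148), (2, 9, 8, 3), (10, 2, 3, 11)]:
            res = fisher_2x2(tbl)
            a, b, c, d = tbl
            assert res.p_value == pytest.approx(
                sps.fisher_exact([[a, b], [c, d]])[1], rel=1e-9
            )


class TestRankTests:
    def test_mwu_separated_exact(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 of C(6,3)=20 orderings

    def test_mwu_identical_samples(self):
        _, p = mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
        assert p == pytest.approx(1.0, abs=0.05)

    def test_mwu_power_on_shifted_normals(self):
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(s)
            x = rng.normal(0, 1, 200)
            y = rng.normal(1, 1, 200)
            hits += mann_whitney(x, y)[1] < 0.001
        assert hits >= 19

    def test_mwu_empty_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_spearman_monotone_and_reversed(self):
        x = np.arange(10.0)
        assert spearman(x, x**3)[0] == pytest.approx(1.0)
        assert spearman(x, -x)[0] == pytest.approx(-1.0)

    def test_spearman_tied_toy_matches_midrank_pearson(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0])
        y = np.array([5.0, 7.0, 6.0, 6.0, 9.0])
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y)[0] == pytest.approx(oracle, abs=1e-12)

    def test_spearman_constant_flagged(self):
        rho, p = spearman(np.ones(5), np.arange(5.0))
        assert np.isnan(rho) and np.isnan(p)


class TestDeciles:
    def test_sizes_exact_when_divisible(self):
        rng = np.random.default_rng(0)
        prs = rng.normal(size=40)
        labels = rng.integers(0, 2, 40).astype(float)
        rep = decile_analysis(prs, labels, np.zeros(40, dtype=bool))
        assert list(rep.proportions["n"]) == [4] * 10

    def test_null_or_near_one(self):
        """Labels independent of PRS: median top-vs-middle OR across seeds
        sits near 1."""
        ors = []
        for s in range(40):
            rng = np.random.default_rng(s)
            prs = rng.normal(size=200)
            labels = (rng.random(200) < 0.3).astype(float)
            rep = decile_analysis(prs, labels, np.zeros(200, dtype=bool))
            if np.isfinite(rep.top_vs_middle.odds_ratio):
                ors.append(rep.top_vs_middle.odds_ratio)
        assert 0.5 <= np.median(ors) <= 2.0

    def test_degenerate_top_decile_flagged(self):
        """All positives forced into Q10 with an empty middle-positive cell:
        the OR is infinity-flagged rather than raising."""
        prs = np.arange(40.0)
        labels = np.zeros(40)
        labels[-4:] = 1  # exactly the top decile
        rep = decile_analysis(prs, labels, np.zeros(40, dtype=bool))
        assert np.isinf(rep.top_vs_middle.odds_ratio)

    def test_exclude_pv_recomputes_membership(self):
        rng = np.random.default_rng(1)
        prs = rng.normal(size=60)
        labels = rng.integers(0, 2, 60).astype(float)
        pv = np.zeros(60, dtype=bool)
        pv[:20] = True
        rep = decile_analysis(prs, labels, pv, exclude_pv=True)
        assert rep.deciles.size == 40
        assert list(rep.proportions["n"]) == [4] * 10

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 20"):
            decile_analysis(np.arange(10.0), np.ones(10), np.zeros(10, dtype=bool))


class TestAgeGlm:
    def test_noiseless_line_recovered_exactly(self):
        prs = np.random.default_rng(0).normal(size=50)
        ages = 50.0 - 4.0 * prs
        res = age_glm(prs, ages)
        assert res.slope == pytest.approx(-4.0, abs=1e-8)
        assert res.intercept == pytest.approx(50.0, abs=1e-8)
        assert res.slope_ci[1] - res.slope_ci[0] < 1e-6

    def test_null_slope_ci_coverage(self):
        """With ages independent of PRS the 95% CI covers zero at ~the
        nominal rate."""
        covered = 0
        n_seeds = 60
        for s in range(n_seeds):
            rng = np.random.default_rng(s)
            prs = rng.normal(size=200)
            ages = rng.normal(48, 10, 200)
            res = age_glm(prs, ages)
            covered += res.slope_ci[0] <= 0 <= res.slope_ci[1]
        assert covered >= int(0.85 * n_seeds)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            age_glm(np.ones(10), np.arange(10.0) + 30)


class TestBootstrap:
    def test_noop_removal_boundary(self):
        """No carriers: delta is exactly 0 and, under the strict 'lower'
        rule, no replicate counts, so p_boot = 0."""
        rng = np.random.default_rng(0)
        scores = rng.normal(size=100)
        labels = (rng.random(100) < 0.4).astype(float)
        res = bootstrap_auc_removal(
            scores, labels, np.zeros(100, dtype=bool), n_boot=200, seed=1
        )
        assert res.delta == 0.0
        assert res.p_boot == 0.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=80)
        labels = (rng.random(80) < 0.5).astype(float)
        pv = rng.random(80) < 0.2
        a = bootstrap_auc_removal(scores, labels, pv, n_boot=300, seed=9)
        b = bootstrap_auc_removal(scores, labels, pv, n_boot=300, seed=9)
        assert a.p_boot == b.p_boot and a.delta == b.delta

    def test_fixed_comparison_variant(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=80)
        labels = (rng.random(80) < 0.5).astype(float)
        pv = rng.random(80) < 0.2
        res = bootstrap_auc_removal(
            scores, labels, pv, n_boot=200, seed=4, comparison="fixed"
        )
        assert 0 <= res.p_boot <= 1


class TestEvaluateWeightSets:
    def test_identical_sets_flag_undefined_spearman(self):
        rng = np.random.default_rng(0)
        adj = rng.normal(size=100)
        scored = {
            f"s{i}": {"raw": adj, "adjusted": adj, "reported_population_auc": 0.6}
            for i in range(3)
        }
        labels = {"fh_bc_first": (rng.random(100) < 0.3).astype(float)}
        table, summary = evaluate_weight_sets(scored, labels)
        rho, _ = summary["spearman_reported_vs_auc_family"]
        assert np.isnan(rho)
        assert table["auc_fh_bc_first_adjusted"].nunique() == 1

    def test_fewer_than_three_sets_flagged(self):
        rng = np.random.default_rng(1)
        scored = {
            "a": {"raw": rng.normal(size=50), "adjusted": rng.normal(size=50),
                  "reported_population_auc": 0.6},
        }
        labels = {"fh_bc_first": (rng.random(50) < 0.5).astype(float)}
        _, summary = evaluate_weight_sets(scored, labels)
        assert np.isnan(summary["spearman_reported_vs_auc_family"][0])
        assert summary["best_set"] == "a"


def test_weight_set_quality_ordering_recovered():
    """Graded-noise copies of the causal weight set rank by quality on the
    family-history AUC task (Spearman > 0 across seeds)."""
    from scipy.stats import spearmanr

    from famprs import (
        ImputationNoiseParams,
        LiabilityParams,
        PcaConfig,
        PopulationParams,
        compute_pcs,
        compute_prs,
        flags_to_binary,
        select_pca_variants,
        simulate_cohort,
    )

    ok = 0
    n_seeds = 8
    for s in range(n_seeds):
        coh = simulate_cohort(
            PopulationParams(n_samples=2000, n_variants=400, n_subpops=2, fst=0.05),
            ImputationNoiseParams(base_quality=1.0, maf_quality_slope=0.0,
                                  dosage_noise_sd=0.0),
            LiabilityParams(h2_common=0.6),
            seed=s,
            weight_specs=[
                {"n_causal": 100, "effect_sd": 1.0, "label": "causal",
                 "reported_population_auc": 0.64},
                {"perturb_noise_sd": 1.0, "label": "noisy",
                 "reported_population_auc": 0.60},
                {"perturb_noise_sd": 3.0, "label": "noisier",
                 "reported_population_auc": 0.56},
            ],
        )
        pcs = compute_pcs(
            coh.genotypes, select_pca_variants(coh.genotypes, PcaConfig()), 10
        )
        labels = flags_to_binary(coh.phenotypes["fh_bc_first"])
        aucs = [
            auc_rank(compute_prs(coh.dosages, ws, pcs, 10).adjusted, labels).auc
            for ws in coh.weight_sets
        ]
        ok += spearmanr([3, 2, 1], aucs).statistic > 0
    assert ok >= int(0.75 * n_seeds)


def test_carrier_percent_printed_convention():
    flags = np.r_[np.ones(34), np.zeros(181)].astype(bool)
    assert round(carrier_percent(flags), 2) == 15.81
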