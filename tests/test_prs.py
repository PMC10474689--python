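"""PRS scoring, HWE test, LD pruning, PCA, residualization, kinship."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import special

from famprs import (
    DosageMatrix,
    GenotypeMatrix,
    PcaConfig,
    PopulationParams,
    compute_pcs,
    hwe_pvalue,
    kinship_and_prune,
    ld_prune,
    residualize_prs,
    score_prs,
    select_pca_variants,
    simulate_genotypes,
)

from conftest import make_variants, weight_set_from


def _dosage_matrix(d, variants=None, info=None):
    d = np.asarray(d, dtype=float)
    m = d.shape[1]
    variants = variants if variants is not None else make_variants(m)
    return DosageMatrix(
        samples=[f"S{i}" for i in range(d.shape[0])],
        variants=variants,
        dosages=d,
        info=info if info is not None else np.full(m, 0.9),
        maf=np.full(m, 0.25),
    )


class TestScorePrs:
    def test_zero_weights_zero_scores(self):
        dm = _dosage_matrix(np.random.default_rng(0).uniform(0, 2, (5, 4)))
        ws = weight_set_from(dm.variants, np.zeros(4))
        scores, _ = score_prs(dm, ws)
        np.testing.assert_array_equal(scores, np.zeros(5))

    def test_two_variant_arithmetic(self):
        dm = _dosage_matrix([[2.0, 1.0]])
        ws = weight_set_from(dm.variants, [0.5, -1.0])
        scores, _ = score_prs(dm, ws)
        assert scores[0] == pytest.approx(0.5 * 2 - 1.0 * 1)

    def test_matches_naive_double_loop(self):
        """Vectorized scoring equals an index-by-index oracle to 1e-12,
        including ref-oriented effect alleles and missing dosages."""
        rng = np.random.default_rng(7)
        d = rng.uniform(0, 2, (20, 50))
        d[rng.random((20, 50)) < 0.1] = np.nan
        dm = _dosage_matrix(d)
        eff = np.where(rng.random(50) < 0.5, dm.variants["ref"], dm.variants["alt"])
        w = rng.normal(size=50)
        ws = weight_set_from(dm.variants, w, effect_alleles=eff)
        scores, _ = score_prs(dm, ws)

        oracle = np.zeros(20)
        for i in range(20):
            for j in range(50):
                dij = d[i, j]
                if np.isnan(dij):
                    continue
                e = dij if eff[j] == dm.variants["alt"].iloc[j] else 2 - dij
                oracle[i] += w[j] * e
        np.testing.assert_allclose(scores, oracle, atol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_linearity_in_weights(self, seed):
        """score(w1 + w2) = score(w1) + score(w2) on identical matching."""
        rng = np.random.default_rng(seed)
        d = rng.uniform(0, 2, (8, 12))
        dm = _dosage_matrix(d)
        w1, w2 = rng.normal(size=12), rng.normal(size=12)
        s1, _ = score_prs(dm, weight_set_from(dm.variants, w1))
        s2, _ = score_prs(dm, weight_set_from(dm.variants, w2))
        s12, _ = score_prs(dm, weight_set_from(dm.variants, w1 + w2))
        np.testing.assert_allclose(s12, s1 + s2, atol=1e-9)


class TestHwe:
    def test_equilibrium_table_p_one(self):
        assert hwe_pvalue(25, 50, 25) == pytest.approx(1.0)

    def test_extreme_het_deficit_tiny_p(self):
        assert hwe_pvalue(50, 0, 50) < 1e-6

    def test_monomorphic_p_one(self):
        assert hwe_pvalue(100, 0, 0) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_pvalue(-1, 2, 3)

    @pytest.mark.parametrize("table", [(5, 10, 5), (12, 2, 6), (3, 9, 1), (30, 10, 0)])
    def test_matches_exhaustive_enumeration(self, table):
        """p equals a direct enumeration over all heterozygote counts using
        exact rational probabilities."""
        import math
        from fractions import Fraction

        n_aa, n_ab, n_bb = table
        n = sum(table)
        n_rare = min(2 * n_aa + n_ab, 2 * n_bb + n_ab)

        def prob(het):
            hom_r = (n_rare - het) // 2
            hom_c = n - het - hom_r
            return Fraction(
                math.factorial(n) * 2**het,
                math.factorial(hom_r) * math.factorial(het) * math.factorial(hom_c),
            )

        hets = range(n_rare % 2, n_rare + 1, 2)
        probs = {h: prob(h) for h in hets}
        total = sum(probs.values())
        p_obs = probs[n_ab]
        oracle = float(sum(v for v in probs.values() if v <= p_obs) / total)
        assert hwe_pvalue(*table) == pytest.approx(oracle, rel=1e-9)


class TestLdPrune:
    def test_identical_adjacent_columns_second_dropped(self):
        rng = np.random.default_rng(0)
        g = rng.binomial(2, 0.3, size=(50, 3)).astype(float)
        g[:, 1] = g[:, 0]
        gm = GenotypeMatrix([f"S{i}" for i in range(50)], make_variants(3, spacing=500), g)
        kept = ld_prune(gm, np.arange(3), r2_max=0.1, window_bp=1_000_000)
        np.testing.assert_array_equal(kept, [0, 2])

    def test_window_zero_drops_nothing(self):
        rng = np.random.default_rng(0)
        g = np.tile(rng.binomial(2, 0.3, size=(50, 1)), (1, 4)).astype(float)
        gm = GenotypeMatrix([f"S{i}" for i in range(50)], make_variants(4, spacing=100), g)
        kept = ld_prune(gm, np.arange(4), r2_max=0.1, window_bp=0)
        np.testing.assert_array_equal(kept, np.arange(4))

    def test_independent_drop_rate_matches_null_r2_tail(self):
        """With independent variants, the drop rate tracks the tail mass of
        the null r^2 distribution estimated by simulation."""
        n, m = 100, 300
        rng = np.random.default_rng(3)
        g = rng.binomial(2, 0.4, size=(n, m)).astype(float)
        gm = GenotypeMatrix([f"S{i}" for i in range(n)], make_variants(m, spacing=1), g)
        kept = ld_prune(gm, np.arange(m), r2_max=0.1, window_bp=10)
        drop_rate = 1 - len(kept) / m

        # oracle: null r^2 between independent binomial columns at this n
        sims = []
        for _ in range(2000):
            a = rng.binomial(2, 0.4, n)
            b = rng.binomial(2, 0.4, n)
            if a.std() == 0 or b.std() == 0:
                continue
            sims.append(np.corrcoef(a, b)[0, 1] ** 2)
        tail = np.mean(np.array(sims) > 0.1)
        # each variant is compared against ~10 kept predecessors
        upper = 1 - (1 - tail) ** 10
        assert drop_rate <= upper * 3 + 0.02


class TestSelectPcaVariants:
    def test_maf_boundary_strict(self):
        # build genotype columns with known allele frequencies
        n = 200
        rng = np.random.default_rng(1)
        cols, mafs = [], [0.04, 0.05, 0.3]
        for maf in mafs:
            k = int(round(2 * n * maf))
            col = np.zeros(2 * n)
            col[:k] = 1
            rng.shuffle(col)
            cols.append(col[:n] + col[n:])
        g = np.column_stack(cols)
        gm = GenotypeMatrix([f"S{i}" for i in range(n)], make_variants(3), g)
        kept = select_pca_variants(gm, PcaConfig(maf_min=0.05, hwe_p_min=0.0))
        assert list(kept) == [2]  # exactly-0.05 excluded by strict >


class TestComputePcs:
    def test_rank_one_toy(self):
        """K=1 scores on a rank-1 pattern are proportional to the pattern."""
        v = np.array([0.0, 1.0, 2.0, 1.0, 0.0, 2.0])
        g = np.tile(v[:, None], (1, 5))
        gm = GenotypeMatrix([f"S{i}" for i in range(6)], make_variants(5), g)
        scores = compute_pcs(gm, np.arange(5), 1)
        r = np.corrcoef(scores[:, 0], v)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-10)

    def test_requested_k_exceeding_rank_errors(self):
        v = np.array([0.0, 1.0, 2.0, 1.0])
        g = np.tile(v[:, None], (1, 6))
        gm = GenotypeMatrix([f"S{i}" for i in range(4)], make_variants(6), g)
        with pytest.raises(ValueError, match="rank"):
            compute_pcs(gm, np.arange(6), 3)

    def test_pc1_separates_diverged_subpops(self):
        """Point-biserial |r| between PC1 and the ancestry label is high for
        F_ST 0.1 cohorts, and near zero without structure."""
        hi, lo = [], []
        for s in range(20):
            pop = PopulationParams(
                n_samples=120, n_variants=300, n_subpops=2, fst=0.1,
                admixture_alpha=0.05,
            )
            gm, labels, _ = simulate_genotypes(pop, seed=s)
            scores = compute_pcs(gm, np.arange(300), 2)
            hi.append(abs(np.corrcoef(scores[:, 0], labels)[0, 1]))

            pop0 = PopulationParams(
                n_samples=120, n_variants=300, n_subpops=1, fst=0.0
            )
            gm0, _, _ = simulate_genotypes(pop0, seed=s)
            fake_labels = np.arange(120) % 2
            s0 = compute_pcs(gm0, np.arange(300), 2)
            lo.append(abs(np.corrcoef(s0[:, 0], fake_labels)[0, 1]))
        assert np.mean(np.array(hi) > 0.8) >= 0.9
        assert np.median(lo) < 0.3

    def test_invariant_under_sample_reordering(self):
        pop = PopulationParams(n_samples=50, n_variants=100, n_subpops=2, fst=0.1)
        gm, _, _ = simulate_genotypes(pop, seed=2)
        scores = compute_pcs(gm, np.arange(100), 3)
        perm = np.random.default_rng(0).permutation(50)
        gm2 = gm.subset_samples(perm)
        scores2 = compute_pcs(gm2, np.arange(100), 3)
        for k in range(3):
            diff = np.abs(scores2[:, k] - scores[perm, k]).max()
            flip = np.abs(scores2[:, k] + scores[perm, k]).max()
            assert min(diff, flip) < 1e-8


class TestResidualize:
    def test_orthogonal_prs_reduces_to_zscore(self):
        rng = np.random.default_rng(0)
        pcs = rng.normal(size=(200, 3))
        raw = rng.normal(size=200)
        x = np.column_stack([np.ones(200), pcs])
        raw -= x @ np.linalg.lstsq(x, raw, rcond=None)[0]  # orthogonalize
        raw += 0.7  # a pure mean offset must not matter
        adj, _ = residualize_prs(raw, pcs)
        z = (raw - raw.mean()) / raw.std(ddof=1)
        np.testing.assert_allclose(adj, z, atol=1e-10)

    def test_exact_linear_function_of_pc_errors(self):
        pcs = np.random.default_rng(1).normal(size=(50, 2))
        raw = 3.0 * pcs[:, 0] + 1.0
        with pytest.raises(ValueError, match="constant"):
            residualize_prs(raw, pcs)

    def test_six_sample_normal_equation_oracle(self):
        """K=1 fit matches the closed-form 2x2 normal-equation solution."""
        pc1 = np.array([-2.0, -1.0, 0.0, 1.0, 2.0, 3.0])
        raw = np.array([0.5, 0.1, 0.4, 0.9, 0.7, 1.5])
        n = 6
        sx, sy = pc1.sum(), raw.sum()
        sxx, sxy = (pc1 * pc1).sum(), (pc1 * raw).sum()
        beta = (n * sxy - sx * sy) / (n * sxx - sx * sx)
        alpha = (sy - beta * sx) / n
        resid = raw - alpha - beta * pc1
        expected = (resid - resid.mean()) / resid.std(ddof=1)
        adj, coef = residualize_prs(raw, pc1[:, None])
        np.testing.assert_allclose(adj, expected, atol=1e-10)
        np.testing.assert_allclose(coef, [alpha, beta], atol=1e-10)

    def test_adjusted_orthogonal_to_all_pcs(self):
        rng = np.random.default_rng(3)
        pcs = rng.normal(size=(300, 10))
        raw = pcs @ rng.normal(size=10) + rng.normal(size=300)
        adj, _ = residualize_prs(raw, pcs)
        assert adj.mean() == pytest.approx(0.0, abs=1e-10)
        assert adj.std(ddof=1) == pytest.approx(1.0, abs=1e-8)
        for k in range(10):
            assert abs(np.corrcoef(adj, pcs[:, k])[0, 1]) < 1e-8

    def test_zero_variance_prs_rejected(self):
        pcs = np.random.default_rng(1).normal(size=(30, 2))
        with pytest.raises(ValueError, match="zero variance"):
            residualize_prs(np.ones(30), pcs)


class TestKinship:
    def test_clone_pair_one_removed(self):
        pop = PopulationParams(n_samples=40, n_variants=500, n_subpops=1)
        gm, _, _ = simulate_genotypes(pop, seed=0)
        g = gm.genotypes.copy()
        g[1] = g[0]  # duplicate sample
        gm2 = GenotypeMatrix(gm.samples, gm.variants, g)
        res = kinship_and_prune(gm2, 0.125)
        assert len(res.removed) == 1
        assert res.removed[0] in (gm.samples[0], gm.samples[1])
        # no violating pair remains among kept samples
        kept_idx = [gm.samples.index(s) for s in res.kept]
        sub = res.phi[np.ix_(kept_idx, kept_idx)]
        np.testing.assert_array_less(sub - np.diag(np.diag(sub)), 0.125)

    def test_unrelated_cohort_rarely_pruned(self):
        """With enough markers the null kinship distribution stays below the
        second-degree threshold."""
        removed = []
        for s in range(10):
            pop = PopulationParams(n_samples=100, n_variants=2000, n_subpops=1)
            gm, _, _ = simulate_genotypes(pop, seed=s)
            removed.append(len(kinship_and_prune(gm, 0.125).removed))
        assert np.mean(np.array(removed) == 0) >= 0.9

    def test_parent_offspring_trio_prunes_shared_parent(self):
        """Gamete-constructed trio: each parent-child pair has phi ~ 0.25;
        the child (in two violating pairs) is removed first, keeping 2 of 3."""
        rng = np.random.default_rng(5)
        m = 3000
        p = rng.uniform(0.2, 0.5, m)
        unrelated = rng.binomial(2, p, size=(60, m)).astype(float)

        def gametes(geno):
            return np.where(geno == 1, rng.integers(0, 2, m), geno / 2)

        mother = rng.binomial(2, p, m).astype(float)
        father = rng.binomial(2, p, m).astype(float)
        child = gametes(mother) + gametes(father)
        g = np.vstack([unrelated, mother, father, child])
        samples = [f"U{i}" for i in range(60)] + ["mother", "father", "child"]
        gm = GenotypeMatrix(samples, make_variants(m), g)
        res = kinship_and_prune(gm, 0.125)
        i_m, i_f, i_c = 60, 61, 62
        assert res.phi[i_m, i_c] == pytest.approx(0.25, abs=0.06)
        assert res.phi[i_f, i_c] == pytest.approx(0.25, abs=0.06)
        assert res.phi[i_m, i_f] == pytest.approx(0.0, abs=0.06)
        assert res.removed == ["child"]
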