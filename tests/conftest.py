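import numpy as np
import pandas as pd
import pytest

from famprs import (
    DosageMatrix,
    GenotypeMatrix,
    ImputationNoiseParams,
    LiabilityParams,
    PopulationParams,
    WeightSet,
)
from famprs.synth import simulate_cohort


def make_variants(n, spacing=1000, chrom="1"):
    rng = np.random.default_rng(123 + n)
    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, n)]
    alt = np.array([bases[(np.flatnonzero(bases != r))[rng.integers(0, 3)]] for r in ref])
    return pd.DataFrame(
        {"chrom": chrom, "pos": 1 + np.arange(n) * spacing, "ref": ref, "alt": alt}
    )


@pytest.fixture
def tiny_dosage_matrix():
    variants = pd.DataFrame(
        {
            "chrom": ["1", "1"],
            "pos": [100, 200],
            "ref": ["A", "C"],
            "alt": ["G", "T"],
        }
    )
    dosages = np.array([[0.1, 1.0], [1.9, 0.0], [np.nan, 2.0]])
    return DosageMatrix(
        samples=["S1", "S2", "S3"],
        variants=variants,
        dosages=dosages,
        info=np.array([0.95, 0.5]),
        maf=np.array([0.5, 0.5]),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """One ascertained cohort reused by read-only tests."""
    pop = PopulationParams(n_samples=200, n_variants=300, n_subpops=2, fst=0.05)
    return simulate_cohort(
        pop, ImputationNoiseParams(), LiabilityParams(), seed=11,
        weight_specs=[
            {"n_causal": 80, "effect_sd": 1.0, "label": "causal",
             "reported_population_auc": 0.64},
        ],
    )


@pytest.fixture
def random_genotypes():
    rng = np.random.default_rng(5)
    n, m = 60, 120
    variants = make_variants(m)
    p = rng.uniform(0.1, 0.5, m)
    g = rng.binomial(2, p, size=(n, m)).astype(float)
    return GenotypeMatrix([f"S{i}" for i in range(n)], variants, g)


def weight_set_from(variants, weights, effect_alleles=None, set_id="w", auc=None):
    tab = variants.copy().reset_index(drop=True)
    tab["effect_allele"] = effect_alleles if effect_alleles is not None else tab["alt"]
    tab["weight"] = weights
    return WeightSet(set_id=set_id, table=tab, reported_population_auc=auc)
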