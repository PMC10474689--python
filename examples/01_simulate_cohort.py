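"""Generate a case-only synthetic cohort and inspect its structure.

The generator draws a structured population (Balding–Nichols with
admixture), gives every individual a liability combining a polygenic score
and a rare pathogenic-variant effect, keeps only those above the disease
threshold (case ascertainment), and simulates first-degree relatives to
produce family-history flags.
"""

from famprs import (
    ImputationNoiseParams,
    LiabilityParams,
    PopulationParams,
    simulate_cohort,
)

cohort = simulate_cohort(
    PopulationParams(n_samples=300, n_variants=500, n_subpops=2, fst=0.05),
    ImputationNoiseParams(base_quality=0.95, dosage_noise_sd=0.05),
    LiabilityParams(),  # h2=0.4, pv_effect=2 SD, threshold=1.5, pv_freq=0.02
    seed=7,
)

ph = cohort.phenotypes
print(f"cases retained: {len(ph)} (drawn {cohort.params['n_drawn']} candidates)")
print(f"pathogenic-variant carriers: {100 * ph.pv_carrier.mean():.1f}% of cases")
print(f"first-degree breast-cancer family history: {(ph.fh_bc_first == 'yes').mean():.2%}")
print(f"mean liability of cases: {ph.liability.mean():.2f} (threshold 1.5)")
print(f"mean age at presentation: {ph.age.mean():.1f} y")
# Carriers need less polygenic risk to cross the threshold, so their mean
# standardized causal score should sit below the non-carriers' even before
# any analysis:
print(
    "mean causal score, carriers vs non-carriers: "
    f"{ph.true_score[ph.pv_carrier].mean():+.2f} vs "
    f"{ph.true_score[~ph.pv_carrier].mean():+.2f}"
)
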