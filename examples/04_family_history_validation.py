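"""Validate weight sets by family-history prediction within a case cohort.

Without controls, a PRS can still be validated by asking whether it
identifies the patients with an affected first-degree relative
(AUC_family).  Several candidate weight sets of graded quality are
compared; the confidence interval is Hanley–McNeil.
"""

from famprs import (
    ImputationNoiseParams,
    LiabilityParams,
    PcaConfig,
    PopulationParams,
    auc_with_ci,
    compute_pcs,
    compute_prs,
    evaluate_weight_sets,
    flags_to_binary,
    select_pca_variants,
    simulate_cohort,
)

cohort = simulate_cohort(
    PopulationParams(n_samples=2000, n_variants=500, n_subpops=2, fst=0.05),
    ImputationNoiseParams(base_quality=1.0, maf_quality_slope=0.0, dosage_noise_sd=0.0),
    LiabilityParams(h2_common=0.7),
    seed=3,
    weight_specs=[
        {"n_causal": 125, "effect_sd": 1.0, "label": "causal",
         "reported_population_auc": 0.64},
        {"perturb_noise_sd": 1.0, "label": "noisy", "reported_population_auc": 0.60},
        {"perturb_noise_sd": 3.0, "label": "noisier", "reported_population_auc": 0.56},
    ],
)

pcs = compute_pcs(cohort.genotypes, select_pca_variants(cohort.genotypes, PcaConfig()), 10)
scored = {}
for ws in cohort.weight_sets:
    res = compute_prs(cohort.dosages, ws, pcs, 10)
    raw_z = (res.raw - res.raw.mean()) / res.raw.std(ddof=1)
    scored[ws.set_id] = {
        "raw": raw_z, "adjusted": res.adjusted,
        "reported_population_auc": ws.reported_population_auc,
    }
labels = {
    task: flags_to_binary(cohort.phenotypes[task])
    for task in ("fh_bc_first", "fh_bc_any", "fh_anycancer_any")
}
table, summary = evaluate_weight_sets(scored, labels)
print(table[["set_id", "reported_population_auc",
             "auc_fh_bc_first_adjusted", "auc_fh_bc_any_adjusted"]]
      .to_string(index=False))
print(f"\nbest set by first-degree AUC: {summary['best_set']}")

print("\nbest set across widening family-history definitions:")
for task, desc in (
    ("fh_bc_first", "breast cancer, first-degree relative"),
    ("fh_bc_any", "breast cancer, any relative"),
    ("fh_anycancer_any", "any cancer, any relative"),
):
    res = auc_with_ci(scored[summary["best_set"]]["adjusted"], labels[task])
    print(
        f"  {desc:40s} AUC {res.auc:.3f} "
        f"(95% CI {res.ci_low:.3f}-{res.ci_high:.3f})"
    )
print("the AUC falls as the definition widens: the score is most informative "
      "about the most heritable, most closely related outcome")
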