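# Methods

`famprs` analyses case-only cohorts: every individual is a patient, and the
question is not case/control discrimination but whether a polygenic risk
score (PRS), computed from imputed low-pass sequencing dosages, carries the
familial and rare-variant structure that a liability-threshold model of a
common disease predicts.  This note describes the models implemented, the
synthetic data generator used to exercise them, the parameter choices, and
the known limitations.

## The analysis model

**Dosage-correlation QC.**  Imputed genotypes are continuous dosages
`d ∈ [0, 2]` with a per-variant imputation quality score (the `INFO`
annotation, in [0, 1]).  Against truth hard calls `g ∈ {0, 1, 2}` from a
higher-coverage assay, accuracy is summarized per sample as the Pearson
correlation of `d` against `g` over the variants present in both call sets
("dosage correlation"), stratified into INFO bins and into cohort-MAF bins
and reported as per-bin medians and IQRs across samples.  Bins are
right-closed and left-open except the first, which keeps its left edge;
correlations that are undefined (fewer than two pairs, or zero variance in
either vector) are flagged and excluded from medians rather than imputed as
zero.  Downstream analyses keep variants with INFO strictly greater than
0.8.  Cohort alternate-allele frequencies can also be correlated (unfolded)
against external reference-panel frequency tables to rank candidate
ancestry groups; folding to MAF is used only for binning.

**PRS scoring.**  `PRS_i = Σ_j w_j e_ij` where `e_ij` is the effect-allele
dosage (`d` when the effect allele is the alternate allele, `2 − d` when it
is the reference).  Missing dosages contribute nothing and are counted
(no mean imputation).  The sum is reported rather than PLINK's per-allele
average: the two differ by an affine map per sample, and the downstream
standardization removes scale, so raw values differ from PLINK's by a
constant factor.

**Ancestry adjustment.**  PCs come from HWE-normalized PCA: genotype
columns standardized as `(g − 2p̂)/sqrt(2p̂(1−p̂))` with missing values set
to zero after centering, on variants with folded MAF > 0.05, exact-test HWE
p > 1e−6, and greedy LD pruning at r² > 0.1 within 1 Mb.  Scores are left
singular vectors scaled by singular values, sign-fixed so each component's
largest-magnitude loading is positive (reproducible regressions).  The
adjusted PRS is the ordinary-least-squares residual of the raw PRS on the
top 10 PCs, z-scored with the n−1 denominator (the choice of denominator is
immaterial at cohort sizes of interest but is fixed here for exactness).
PCA is computed on the analysis cohort itself (optionally augmented by a
user-supplied external genotype file); no reference-panel anchoring is
required.

**Relatedness.**  Kinship is half the genomic relationship matrix on
HWE-scaled genotypes.  Pruning is greedy at threshold 0.125 (the
second-degree boundary): while any pair exceeds the threshold, remove the
sample in the most violating pairs, ties broken by more missing genotypes
and then by the lexicographically larger sample id.  This replaces
weighted-kinship formulations (e.g. LDAK-Thin) with the plain GRM; the
threshold semantics are unchanged.

**Statistics.**
* AUC is the rank (Mann–Whitney) statistic with ties counted ½; samples
  with unknown labels are dropped first.  Its confidence interval is
  Hanley–McNeil: `SE² = [A(1−A) + (n₊−1)(Q₁−A²) + (n₋−1)(Q₂−A²)]/(n₊n₋)`
  with `Q₁ = A/(2−A)`, `Q₂ = 2A²/(1+A)`.
* 2×2 tables use the exact conditional (hypergeometric) test.  The default
  two-sided rule is *minimum likelihood*: sum the probabilities of all
  fixed-margin tables no more likely than the observed one.  Central
  (doubled-tail) and one-sided alternatives are available, as is the
  conditional-MLE odds ratio next to the reported cross-product OR; the
  interval is the exact conditional central interval.
* Mann–Whitney U is exact by enumeration when `min(n) ≤ 8` with no ties,
  otherwise a tie- and continuity-corrected normal approximation.  Spearman
  uses mid-ranks with the t-approximation p-value (adequate at cohort n;
  exact permutation p-values are out of scope).
* Decile analysis assigns deciles by adjusted PRS with stable-order tie
  breaking (sizes differ by at most one) and compares the top (Q10) and
  bottom (Q1) deciles against the middle (Q2–Q9) by Fisher OR.  When
  carriers are excluded, deciles are recomputed on the remaining samples by
  default (freezing the original membership is an option).  Degenerate
  tables (an empty margin) are flagged, not raised.
* Age of onset is a Gaussian identity-link GLM of age on the standardized
  adjusted PRS; the slope is years per PRS SD with Wald 95% intervals.
* The carrier-removal bootstrap resamples the whole cohort with
  replacement `B` times (default 10,000); within each replicate both the
  full-cohort AUC and the AUC after removing pathogenic-variant carriers
  are computed, and the p-value is the fraction of replicates in which the
  after-removal AUC is *strictly lower* (ties count as not-lower; with no
  carriers the two AUCs are identical in every replicate, so p = 0 — a
  documented boundary, not a bug).  Comparing against the fixed point
  estimate instead of the per-replicate AUC is available
  (`comparison="fixed"`); per-replicate is the default because it reflects
  the joint resampling uncertainty.  Replicates that lose a class are
  redrawn, counted, and capped.

**Weight-set evaluation.**  Each candidate weight set is scored and
adjusted identically, then evaluated as a predictor of family history at
three widening definitions (breast cancer in a first-degree relative,
breast cancer in any relative, any cancer in any relative), before and
after adjustment.  Across sets, the reported source-population AUC is
Spearman-correlated with the family-history AUC and with the adjustment
delta; the best set is the highest first-degree AUC, ties broken by the
any-degree AUC then set id.

## The synthetic cohort generator

The generator is the test bed: it produces the smallest data-generating
process under which every analysis above has a known right answer.

* **Population structure** is Balding–Nichols: ancestral frequencies
  uniform on a MAF range, subpopulation frequencies Beta-distributed
  around them with divergence F_ST, individual frequencies mixed by
  Dirichlet admixture proportions, genotypes binomial.  Variants are
  independent (no LD); LD-dependent code paths are exercised with
  duplicated-column fixtures instead.
* **Imputation noise** blends each genotype toward its Hardy–Weinberg mean:
  `d = (1−ε)g + ε·2p + N(0, σ_d)` clipped to [0, 2], with `ε = 1 − q` and
  the latent quality `q = base − slope·(−log10 2·MAF) + jitter` clipped to
  (0, 1].  `q` is reported directly as the INFO score: only the monotone
  quality→concordance link matters downstream, so no attempt is made to
  re-estimate INFO from posteriors.
* **Disease** is a liability threshold:
  `L = √h² · G + b_PV · C + c_A · A + N(0, √(1−h²))`, with `G` the
  standardized causal score, `C` a carrier indicator of population
  frequency `pv_freq`, and `A` an optional centered ancestry covariate
  (environmental confounding, default off).  Only individuals with `L > T`
  are retained; the cohort-level generator rejection-samples genotype
  batches until the target size is reached, with a hard cap of 1000× the
  target (explicit failure beats an endless loop).
* **Family history**: one simulated first-degree relative (genetic share
  0.5, carrier status inherited with probability 0.5) determines the
  first-degree flag; a second relative with share 0.25 extends it to any
  degree; independent other-cancer events (rate 0.15 per relative) give the
  any-cancer flag.  This ordering makes the first-degree flag the cleanest
  readout of `G` and the any-cancer flag the noisiest — the degree-ordered
  AUC pattern the evaluation stage looks for.  A configurable fraction of
  flags can be masked to "unknown" (how unknowns were handled in real
  cohorts is typically unstated; here they are always excluded
  per-analysis, never imputed).
* **Age of onset**: `age = baseline − slope · z(G) + N(0, σ_age)`, floored
  at 18, with `z(G)` standardized within the ascertained cohort.

Default liability parameters: `h² = 0.4`, `b_PV = 2` (two liability SDs),
`T = 1.5`, `pv_freq = 0.02`, baseline 48 y, slope 4.5 y/SD, residual age SD
9 y.  With `b_PV = 2` and `T = 1.5` a population carrier frequency of 0.02
yields roughly 16–18% carriers among ascertained cases, matching the
carrier share reported in hereditary breast-cancer case series; the age
residual SD makes the slope standard error at n ≈ 400 about 0.45 y.

## Validation experiments and their conditions

All experiments live in `famprs.experiments` with fixed study conditions;
`scripts/acceptance.py` reruns them (at reduced seed counts) and
`tests/test_acceptance.py` runs them at full scale.

* **Cohort scale**: n = 400 cases, 400 variants (100 causal), two
  subpopulations at F_ST 0.05 — within-region substructure, the regime the
  adjustment is meant for.  An a-priori calculation (between-population
  share of score variance ≈ 0.6·F under the Dirichlet used) puts the
  PC-residualization attenuation of the age slope around 3–6%, inside the
  10% recovery band; the measured bias is ~6%.
* **Liability signature** uses `h² = 0.4, b_PV = 2, T = 1.5, pv_freq = 0.1`
  and n = 4000 cases so that the family-history-positive carrier and
  non-carrier groups are large enough for stable medians.
* **Slope recovery and the signature run on perfect-imputation dosages**:
  these experiments test the regression and adjustment machinery, not
  imputation attenuation (which is studied separately by the concordance
  experiments).
* **Confounded-set experiment**: liability includes an ancestry shift
  (`c_A = 1.5`, admixture concentration 0.15, F_ST 0.15), making family
  history partly an ancestry readout.  The confounded weight set loads the
  100 most differentiated variants with weights equal to the subpopulation
  AF difference, oriented toward the ancestry shift.  Without an
  ancestry–phenotype link a pure-structure score has family AUC ≈ 0.5 and
  adjustment has nothing to strip; the shift is what makes "adjustment
  masks confounded signal, spares causal signal" observable.
* **Bootstrap calibration** uses a null with scores predictive of the label
  (logistic link) but carriers independent of both, n = 400, B = 500,
  200 seeds; **power** uses the liability generator above, B = 1000.
* **Weight-set ordering** compares the causal set against graded-noise
  perturbations of itself (relative noise SD 1 and 3) at n = 2000 with
  h² = 0.6: the per-seed family-history signal is weak (the true
  AUC(G, first-degree FH) under the default conditions is only ≈ 0.54, an
  inherent property of one-relative family history at h² = 0.4), so the
  ordering is only reliably visible with larger cohorts or a larger
  heritable share.  The family-history-validation example raises h² to 0.7
  for the same reason.
* **Concordance monotonicity** uses 150 samples × 2000 variants with
  quality spread over bins (`base 0.95, slope 0.35, jitter 0.1,
  dosage noise 0.1`), 50 seeds.

## Numerical choices and degenerate inputs

* Exact HWE test (heterozygote-count enumeration in log space), not
  chi-square: stable at the small per-variant counts used in tests.
* PCA rank is checked against the requested K; a deficient matrix raises
  with the achievable K.  Collinear PCs are detected and named before the
  OLS fit; a residual that is numerically constant (raw PRS an exact linear
  function of the PCs) raises rather than standardizing noise.
* Strict inequalities follow stated thresholds: INFO > 0.8, MAF > 0.05,
  HWE p > 1e−6, r² > 0.1, kinship > 0.125.
* Multiallelic VCF records are skipped and counted; half-calls and `./.`
  are missing; a non-diploid call with typed alleles is an error.
  Strand-ambiguous (A/T, C/G) weight-set entries are kept by default since
  variant keys carry both alleles; dropping them is an option.
* Seeds: the pipeline derives per-stage seeds from the global seed by
  hashing the stage name, so stages are independently reproducible.

## What passing these tests does and does not show

The generator omits LD, X-chromosome inheritance, genotyping batch
effects, subtype heterogeneity, non-Gaussian environmental risk and real
pedigree structure; family history is self-contained (simulated relatives)
rather than self-reported with recall error.  Passing therefore shows the
*machinery* is correct under the stated model — scores, PCs, residuals,
exact tests, bootstrap — and that the analysis recovers known generative
parameters; it does not certify effect sizes on real cohorts, where
imputation error, LD between weight variants, and misreported family
history all attenuate signals in ways the generator does not emulate.
The case-only design also means all AUCs here are within-case contrasts:
nothing in this package estimates absolute disease risk.
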