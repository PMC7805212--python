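# Methods

## Problem and model

The package implements a volumetric-MRI analysis for separating
frontotemporal dementia (FTD) from Alzheimer's disease (AD).  Starting from a
per-subject volumetric report (absolute structure volumes, per-lobe CSF and
parenchyma volumes, total intracranial volume ICV, and an exogenous AD-RAI
score), it derives head-size-corrected measures

- relative volume = 100 · absolute volume / ICV (percent of ICV),
- lobar atrophy = 100 · CSF / parenchyma within a lobe,
- QMTA = inferior lateral ventricle volume / hippocampus volume,

identifies the measures that differ between FTD and AD at the group level,
and combines them into a single subject-level score, the frontotemporal
dementia index (FTDI).

With R_i(j) the i-th measure of subject j, training extrema min(R_i),
max(R_i) taken over *all* training subjects (NC included), the normalized
value is

    R'_i(j) = (R_i(j) − min(R_i)) / (max(R_i) − min(R_i)),

each dominant measure receives the weight

    w_i = |Σ_{j∈FTD} R_i(j) − Σ_{j∈AD} R_i(j)| / (Σ_{j∈FTD} R_i(j) + Σ_{j∈AD} R_i(j)),

computed on raw (unnormalized) values of the FTD and AD training subjects,
and the index is the weighted-sum ratio

    FTDI(j) = Σ_{i∈FTD-dominant} w_i R'_i(j) / Σ_{i∈AD-dominant} w_i R'_i(j).

"FTD dominant" measures are those with statistically larger values in FTD
(frontal atrophy ratios; parietal, right-occipital and hippocampal relative
volumes — larger *relative to AD*), "AD dominant" those larger in AD
(right-occipital atrophy; left-frontal, insular and left-caudate volumes).
FTDI > 1.08 calls FTD, otherwise AD.  A two-stage rule first gates on the
exogenous AD-RAI score (≤ 0.75 → NC) and only then applies the FTDI split.

## Dominant-set identification

Each of the 11 panel measures is compared across the three matched groups
with the Friedman rank test over NC/AD/FTD triplets; when the omnibus p is
below α = 0.05, Wilcoxon signed-rank post hoc tests are run with Bonferroni
correction over the three pairwise comparisons (k = 3; the correction family
is per measure, not across measures).  Measures with corrected AD-vs-FTD
p < α are assigned to a dominant set by comparing group medians.

Numerical choices:

- **Friedman p-values are exact.**  Under the null each triplet's ranks are
  exchangeable, and a triplet's tie pattern is invariant under within-triplet
  permutation, so the null distribution of the rank-sum statistic is computed
  exactly by dynamic programming over the (doubled, hence integer) rank sums
  — O(n²) states for three groups, fast up to hundreds of triplets.  The
  chi-square approximation is available as `method="asymptotic"`.
- **Wilcoxon**: zero differences dropped; average ranks for tied magnitudes;
  exact tie-aware distribution (subset-sum DP over signed ranks) up to 25
  non-zero pairs, normal approximation with tie and continuity correction
  beyond; two-sided p = min(1, 2·min(P(W ≤ w), P(W ≥ w))).
- Unmatched cohorts (no triplet ids) fall back to Kruskal–Wallis plus
  Mann–Whitney, off by default.

## Model fitting, scoring, thresholds

- Extrema use all three training groups; `include_nc_extrema=False` restricts
  them to AD+FTD for sensitivity analysis.
- Weights default to the literal sum form (`weight_mode="sum"`); with unequal
  FTD/AD group sizes this conflates size with effect, so a warning is emitted
  and a size-balanced `weight_mode="mean"` is available.
- External-cohort scoring reuses the frozen training extrema and clamps
  normalized values below zero to zero; values above one deliberately pass
  through (only the lower clamp is part of the method).
- A zero denominator (all AD-dominant values clamped to zero) produces an
  explicitly flagged missing score, never ±∞; the decision rule treats a
  missing FTDI at stage 2 as an error.
- Classification is strict: FTDI > threshold → FTD, equality → AD; the AD-RAI
  gate is ≤ threshold → NC.  Default thresholds are 1.08 (FTDI) and 0.75
  (AD-RAI); `evaluate_pipeline` refits the FTDI threshold on the training
  cohort by the Youden index (ties broken toward higher sensitivity, since a
  missed FTD case is the costlier error) and carries it frozen to validation.

## ROC conventions

The classification rule is score > t with candidate thresholds midway between
consecutive distinct scores plus ±∞ sentinels.  AUC is the Mann–Whitney
concordance probability with ties counted ½ (delegated to
scikit-learn's `roc_auc_score`); the test suite pins it against a brute-force
pairwise count.  No confidence intervals or AUC comparisons are computed.

## Synthetic cohort generator

The real cohorts are access-restricted, so the generator emulates them from
the published summary statistics alone:

- Each measure × group is drawn as a zero-truncated normal centered at the
  published group median with σ = IQR/1.349 (the normal IQR→σ factor);
  truncation is by re-drawing the independent noise term, and is mild for
  every panel measure (median/σ ≥ 2.5), so sample medians and IQRs match the
  printed values.  For strongly truncated quantities (the NC row of AD-RAI)
  the marginal is shifted upward by construction; this is inherent to
  enforcing non-negativity.
- Dependence: a per-subject latent severity factor (loading λ = 0.3 by
  default) couples all of a subject's measures, with the loading sign aligned
  to disease direction (atrophy ratios, QMTA and AD-RAI load +, tissue
  volumes −); a per-triplet frailty factor (loading ρ = 0.2) is shared by the
  matched NC/AD/FTD triple and is what makes the paired tests genuinely
  paired.  Independent noise is scaled by √(1 − λ² − ρ²) so the marginal SD
  stays σ.  Both loadings are configurable; the defaults are a deliberately
  modest dependence, chosen once as plausible for within-subject
  neurodegeneration severity, not estimated from data.
- Matched training cohorts (default 47 triplets) share demographic draws
  (age 64.6 ± 10.2 y, education 15.5 ± 3.0 y, 53% male) within a triplet;
  ICV is drawn per group from the published means/SDs.  Validation cohorts
  (default 50 AD + 50 FTD, unmatched) reuse the training measure rows with
  their own ICV/demographics, because no per-measure validation summaries are
  published — they are stand-ins, not estimates of the validation databases.
- Raw volumetry is back-computed (absolute = rel/100 × ICV; lobar CSF =
  atrophy/100 × parenchyma; inferior lateral ventricle = QMTA × hippocampus)
  so the volumetry module round-trips exactly.  Lobes and structures without
  a published row get fixed nominal relative volumes; they never enter the
  analysis panel.
- Reproducibility: every stream (per group × measure, latents, demographics,
  ICV) is seeded from the master seed plus a CRC-hashed label, so generation
  is a pure function of the seed and adding a measure never perturbs existing
  columns.  The visual MTA rating is simulated only as carried metadata
  (rounded to 0.5, clipped to [0, 4]).

### What the generator does and does not emulate

It reproduces per-group marginals, matched-triplet structure and a generic
positive dependence among atrophy measures.  It does not model scanner/site
effects, left–right structural correlations, FTD subtypes, non-Gaussian skew,
or the true covariance of the source data.  Consequently, passing tests show
the *pipeline* behaves correctly under cohorts with the published summary
statistics — not that the real-data accuracies would be reproduced.  One
concrete consequence: with only median/IQR information at n = 47, the weakest
published AD-vs-FTD effects (hippocampus: median gap 0.03 against
within-group σ ≈ 0.06) have limited power under Bonferroni-corrected paired
testing, so full recovery of all 11 significant measures in a single
replicate is uncommon even though wrong-side assignments essentially never
occur and the aggregate FTDI discrimination remains high.  The real data
evidently carry paired correlation structure that summary statistics cannot
convey.

## Problem sizes and defaults

Replicated experiments in the test suite and the acceptance script use the
cohort sizes of the study design (47 per training group, 50 per validation
group), 200 replicates for mean-AUC estimates and 100 for recovery-rate
estimates; marginal-recovery checks use n = 2000 per group with dependence
switched off.  All replicate streams derive from a single master seed via
`numpy.random.SeedSequence`.

## Known limitations

- The weight formula is sensitive to measure scale through the raw sums (a
  pure rescaling of one measure changes its weight but not its normalized
  values); this is a property of the method itself, preserved deliberately.
- The exact Friedman DP is specific to three groups; more groups would need a
  different accumulation.
- AD-RAI is treated as an exogenous non-negative score with no upper bound;
  its internal construction is out of scope.
- Validation-cohort simulation reuses training distributions; measured
  "validation" performance is therefore optimistic relative to a genuinely
  shifted external cohort.
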