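# Methods

This note documents the models, parameter choices and numerical decisions
behind methmark, and what the synthetic study can and cannot show.

## Beta values and gene-level methylation

A probe's beta value is β = M/(M+U), the methylated signal fraction, in
[0, 1]; β(M, U) + β(U, M) = 1 and M = U = 0 yields a missing value. Probes
are aggregated to genes by the unweighted mean of non-missing probe betas,
optionally restricted to a region class (the synthetic annotation tags
probes as `promoter` or `exon1`, matching assays that target the
promoter/exon-1 junction). The gene-level tumor–normal contrast is the
difference of unpaired group means, ΔAvg_β = mean β(tumor) − mean β(normal);
a per-pair contrast is available through the paired qPCR path instead.
Whether a published gene-level contrast used the probe mean or the maximal
probe is generally not recoverable from a methods section; the mean is the
default here and the region filter is configurable.

All threshold comparisons on betas and plasma levels are **strict** (">"),
matching "higher than" phrasing: a tumor beta of exactly 0.25 is not
hypermethylated, a plasma ratio of exactly 0.002 is not abnormal. The two
fold-change rules are **inclusive** ("at least twofold" ≥ 2; "0.5-fold
lower" ≤ 0.5).

## The screening funnel

Five criteria, intersected; defaults: ΔAvg_β cutoff 0.4 in both the
discovery and replication cohorts; top-k = 20 for the response contrast;
normal-panel rule "mean beta < 0.1 in *every* tissue type separately"
("close to 0" is not a number, so 0.1 is this package's quantification,
configurable); expression ratio ≤ 0.5, inclusive. The response criterion
ranks genes by mean(PD) − mean(CR) of gene-level betas — a contrast, since
the selection is of genes *most methylated in poor responders compared
with* complete responders — with ties broken lexicographically by gene
identifier so results are deterministic. The final list is ordered by
response rank. Each criterion is evaluated independently; a failing
criterion yields a partial report with the error recorded rather than an
exception, and relaxing any cutoff can only grow its criterion set
(monotonicity, enforced by tests).

## Relative quantification (comparative Cq)

With amplification efficiency E per cycle (fixed at 2.0 by default,
configurable per assay), the target/reference ratio of a sample is
E^(Cq_ref − Cq_target). Replicates are averaged on the Cq scale before
exponentiation, matching instrument relative-quantification software; a
mean-of-levels alternative is available by flag. Cq 50 is the
no-amplification sentinel (QMSP protocols here run 50 cycles): a target at
the sentinel is undetected (level 0), a reference at the sentinel
invalidates the sample. Calibrating a tumor level against a paired-normal
level of 0 with detected tumor signal returns an infinite fold, which the
≥ 2-fold rule counts as hypermethylated — methylation over an unmethylated
background — and is logged distinctly. Treated-vs-control effects are
reported as percent-of-control and fold change (100·mean(treated)/
mean(control)), with the treated-group SD propagated onto the percent
scale.

## Diagnostics

Sensitivity tp/(tp+fn), specificity tn/(tn+fp), accuracy (tp+tn)/n;
percentages are rounded to 0.1% when reported. ROC curves step over all
score thresholds with ties handled simultaneously and AUC by trapezoid
(delegated to scikit-learn's `roc_curve`; tests verify AUC against an
all-pairs concordance oracle and the U/(n₁n₂) identity with the
Mann–Whitney statistic). Fisher's exact test is two-sided by the
minimum-likelihood convention — the sum of hypergeometric probabilities of
all margin-fixed tables no more likely than the observed one (scipy's
convention, cross-checked against an exact-rational enumeration oracle); a
mid-p variant (half weight on the observed table) is available by flag.
Pearson's chi-squared uses no continuity correction. The Mann–Whitney test
enumerates exactly for tie-free samples of at most 20 per group and
otherwise uses the tie-corrected normal approximation.

## Survival

Kaplan–Meier, log-rank and Cox regression are delegated to lifelines
behind this module's surface; Cox uses the Efron approximation for tied
event times (the modern default). Hand-computed product-limit and
partial-likelihood grid-search oracles back the tests. Follow-up is
administratively truncated at 120 months for 10-year overall survival
analyses (events beyond the horizon become censorings). Published
multivariate hazard ratios from restricted patient-level data are not
reproducible without the original covariate codings; the pipeline's
survival claims are therefore calibration claims (log-rank holds its
nominal size; Cox recovers a planted hazard ratio), verified by
simulation.

## Plasma surveillance

A timepoint is abnormal when the methylated-target/ACTB ratio strictly
exceeds 0.002. Patients retain circulating signal for a short period after
treatment even when therapy succeeds, so the first `clearance_window`
post-baseline draws (default 1, i.e. timepoint indices ≤ 1) are not
scored; the patient-level rule is "any abnormal timepoint after the
window" → predicted progression. This rule is monotone: raising the cutoff
or inserting sub-cutoff draws can never create a positive call. For ROC
benchmarking each patient's score is the maximum post-window level — the
continuous counterpart of the any-abnormal rule — and the same scoring is
applied to serum CEA (clinical cutoff 5 ng/mL) and CA15-3 (25 U/mL).

## The synthetic study

The generator's defaults are the study conditions used throughout the
tests and the acceptance script:

- **Tissue cohorts**: 20 tumor/normal pairs per cohort, 1000 genes × 2
  probes, background β 0.05, 20 planted genes at Δβ = 0.5, beta noise sd
  0.05; a response cohort of 8 PD vs 21 CR tumors with the planted genes
  elevated by 0.4 in PD; a normal panel of 10 tissue types × 32 samples
  (≈ 320 normals, the scale of a multi-tissue reference panel). Noise is
  Beta-distributed with exact mean and standard deviation `noise_sd`:
  values stay in [0, 1] with no atom at the bounds, planted group means
  are exact (a logit-normal draw would bias low-background means upward
  by nearly a factor of two at these settings), and background genes get
  the J-shaped near-zero distribution typical of unmethylated probes.
  `noise_sd = 0` reproduces the true means exactly, which the trivial
  test cases rely on.
- **Expression**: baseline 100 units, mean-one lognormal noise with CV
  0.2, planted genes reduced `expression_coupling`-fold in tumors. The
  default coupling is 4, not 2: the screening criterion is ratio ≤ 0.5
  inclusive, so a planted fold of exactly 2 would sit on the decision
  boundary and noise would drop planted genes at random; strong (4-fold)
  reduction models near-complete promoter silencing and keeps the planted
  truth identifiable.
- **qPCR**: reference Cq 28, replicate noise N(0, cq_sd) on both assays;
  the noiseless path is an exact inverse of `relative_level` (tested over
  ratios 10⁻⁴–10²).
- **Plasma**: 200 patients, baseline ratio 0.016, geometric clearance with
  half-life 0.5 draws (a successful treatment clears below the 0.002
  detection floor by the second post-treatment draw; levels below the
  floor are reported as 0), progression fraction 0.5 (the monitored-cohort
  proportion), regrowth ×2 per draw from the floor after a random onset,
  multiplicative lognormal assay noise with CV 0.3, 9 draws on the
  3-monthly-then-6-monthly schedule (months 0–24). Serum CEA/CA15-3 sit at
  normal baselines (1.5 ng/mL, 12 U/mL, CV 0.3) and become abnormal only
  at the last two draws of a random subset of progressors (40% / 20%) —
  the late, insensitive behaviour these markers show in surveillance.
  The published record does not state the assay's variance or detection
  limit; the CV and floor here are package choices, stated as such.
- **Survival**: exponential event times, reference median 60 months,
  planted hazard ratio on the exposed group, administrative censoring at
  120 months.

What passing tests show: the pipeline's rules and statistics are
implemented correctly, are calibrated under their own assumptions, and
recover planted effects of the stated sizes. What they do not show:
performance on real arrays (no normalization artefacts, batch effects,
probe cross-reactivity or tumor-purity dilution are simulated), real cfDNA
kinetics (clearance is geometric with patient-independent rates), or real
survival data (no covariate confounding; the published multivariate hazard
ratios are context, not targets).

## Problem sizes

The default sizes above were chosen so a full test run and the acceptance
script each complete in well under a minute on a single core while leaving
every statistical check comfortably powered (50 funnel seeds × 1000 genes;
500 log-rank replicates at n = 200; 100 Cox replicates at n = 500; 200
monitored patients).
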