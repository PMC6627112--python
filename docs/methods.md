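# Methods

This note documents the statistical models behind `crcmark`, the defaults
and why they were chosen, what the synthetic cohort generator does and does
not emulate, and the numerical conventions that matter for reproducing its
output.

## Study design being modelled

A cohort of colorectal-cancer patients undergoes surgery — *radical*
(complete tumor removal) or *palliative* (residual disease remains). Each
patient gives a preoperative plasma/serum sample (one day before surgery), a
postoperative sample (5–10 days after), and between 0 and 7 follow-up
samples at irregular times. Measured markers are plasma miRNAs (relative
2^−ΔCt units against an exogenous cel-miR-39 spike-in) and serum CEA
(ng/mL) and CA19-9 (U/mL). Three questions are asked of these data:

1. Do levels drop after surgery, and does the drop depend on surgery type?
2. Do high preoperative levels predict shorter overall survival?
3. Can rising follow-up trajectories detect disease recurrence early?

## qPCR processing

Processing order is **reconcile → calibrate → filter → normalize**; the
reliability filter is applied to the *calibrated* Ct so that plate shifts
cannot push a sample across the threshold.

- *Duplicate reconciliation.* Technical duplicates agreeing within
  `tolerance` (default 0.5 cycles) are averaged; a single present replicate
  is used as-is; disagreement flags `repeat_required`. The original study
  protocol re-assayed such samples; a reanalysis cannot, so these rows are
  excluded and counted in the processing log. The 0.5-cycle default is a
  conventional repeatability criterion; it is configurable.
- *Inter-run calibration.* Calibrator samples (measured on the reference run
  and re-measured on every later run) estimate a per-run, per-marker Ct
  offset as the mean Ct difference against the reference run. Calibration is
  done in Ct space (a shift) rather than on levels (a ratio) because plate
  effects act additively on Ct. A run sharing no calibrator with the
  reference is a hard error naming the run.
- *Reliability filter.* Quantification with calibrated Ct above 35 cycles is
  excluded (`excluded_high_ct`); the threshold is strict, so Ct = 35.0 is
  kept. Absent amplification in both duplicates is `excluded_no_amplification`.
  A panel-level report (`marker_qc_summary`) flags whole assays whose ok
  fraction falls below 50%, for panels where some markers amplify too late
  across the board.
- *Normalization.* `level = 2^−(Ct_target − Ct_spike-in)` with the same
  sample's spike-in Ct. Adding any constant to both Cts leaves the level
  unchanged (extraction-efficiency equivariance), and the level is strictly
  decreasing in target Ct — both are property-tested.

CEA and CA19-9 are immunoassay concentrations; they enter the level table
directly with `qc_flag = ok`.

## Paired pre/post testing

The Wilcoxon signed-rank test is built in-house because its exact behaviour
is contractual: zero differences dropped, average ranks for tied absolute
differences, W = sum of positive-difference ranks. For n ≤ 25 the two-sided
p is exact — the null distribution of W over all 2^n sign assignments is
computed by convolution on the lattice of doubled ranks, so ties are handled
exactly; the two-sided p is the symmetric tail
P(|W − S/2| ≥ |w − S/2|), where S is the total rank sum. For larger n a
Gaussian approximation with tie-corrected variance Σrᵢ²/4 and a 0.5
continuity correction is used. Both regimes are cross-checked against
independent enumeration and `scipy.stats.wilcoxon` in the test suite.

**Scale.** The test is applied to log(post) − log(pre) — equivalently to
paired ΔCt differences. Marker levels are close to lognormal and the
signed-rank test assumes null differences are symmetric about zero; that
holds on the log scale but not on the raw level scale, where multiplicative
noise skews the differences (simulations under a no-change null show the
raw-scale test rejecting at ≈7.5% instead of the nominal 5%). Medians are
always reported on the raw level scale (3 decimals for miRNAs, 1 for serum
markers). `log_scale=False` restores raw-scale testing.

The "all patients" stratum is an independent re-test on the union of the
two surgery groups, not a pooled statistic.

## Survival analysis

Kaplan–Meier estimation and the two-group logrank test follow the standard
constructions (censoring at an event time counted at risk; hypergeometric
variance summed over distinct event times); both are verified against
hand-worked tables and `lifelines`.

The *optimal cutoff* for a marker is the candidate split minimizing the
logrank p-value. Candidates are midpoints between consecutive distinct
values; splits leaving either group below `min_group_fraction` (default
0.1) of patients are inadmissible — the floor prevents degenerate 1-vs-rest
splits and is configurable since the admissibility rule of the original
analysis is unknown. Ties on p are broken toward larger χ², then the
smaller cutoff; the high/unfavorable side is strict (`value > cutoff`).

**Multiple-look caveat.** The reported p is the *unadjusted minimum* over
the scan, matching the conventional presentation of such analyses. It is
systematically optimistic: on null simulations the scan rejects at far more
than 5% (this optimism is itself asserted in the test suite).
`permutation_adjusted_p` re-runs the full scan on label-permuted marker
values and is the honest alternative.

Survival analysis defaults to the palliative stratum: radically resected
patients rarely die within a three-year window, so overall survival carries
information mainly where residual disease remains. The OR-combination rule
uses the per-marker optimal cutoffs (the assumption that the combined
classifier reuses the single-marker cutoffs is a design choice); a patient
missing any panel value is reported non-evaluable rather than classified.

## Recurrence detection

Per marker, the postoperative level is the patient's individual baseline.
The rule is positive if any follow-up level is ≥ `fold` × baseline (default
1.5, inclusive — "a 1.5-fold increase" is read as *reaching* 1.5×), or if
`consecutive_k` (default 2) consecutive follow-up samples are each strictly
above baseline. Consecutiveness is in sample order, not calendar time,
because sampling is irregular. `rule_fired` records whichever rule triggers
earlier in time, the fold rule winning same-time ties; the trigger time of
the consecutive rule is the k-th sample of the run. The rule is invariant
under uniform rescaling of baseline and trajectory, and raising `fold` can
only lose positives — both property-tested.

CEA and CA19-9 are evaluated under the same individual-baseline rule by
default so all markers are compared on one footing; fixed clinical
thresholds can be emulated by passing absolute cutoffs through the
trajectory API. No cross-marker recurrence vote is computed.

Evaluation is restricted to radically resected patients (palliative
patients are never recurrence-labelled). Patients with no usable
postoperative baseline or no follow-up samples are reported separately as
non-evaluable — their recurrence status cannot be observed biochemically —
mirroring how only a subset of a real cohort is evaluable. Percentages
recompute exactly from the confusion counts; undefined ratios (zero
denominator) are reported absent rather than as 0 or 100.

The ROC score is the maximum follow-up fold change over baseline — a
natural continuous analogue of the fold rule; the score underlying the
original curves is not documented, so this is an implementation decision.
Thresholds sweep the distinct scores; the trapezoidal AUC equals the
tie-corrected Mann–Whitney probability (asserted against an exhaustive
pairwise oracle and scikit-learn).

## Synthetic cohort generator

The generator reproduces the *structure* the analysis assumes, with every
parameter explicit in `CohortConfig`:

- **Cohort.** `n_patients = 85`, `fraction_radical = 57/85` (the radical
  count is rounded). TNM stage, grade and clinical stage are drawn from the
  marginal frequencies of a typical mixed resection cohort; they are
  descriptive covariates only and are sampled independently of each other
  and of outcome.
- **Marker levels.** Log levels are Gaussian: marker m of patient i has
  log level μₘ + σₘ·(ρ·bᵢ + √(1−ρ²)·εᵢₘ), where bᵢ ~ N(0,1) is a shared
  standardized "tumor burden" factor and ρ (`marker_correlation`, default
  0.6) its loading. Default locations are ln(median) of typical preoperative
  values for the six-marker panel (miR-20a 0.247, miR-21 1.050, miR-23a
  0.705, miR-223 1.275 relative units; CEA 3.1 ng/mL; CA19-9 11 U/mL) with
  log-sd 1.2 (1.5 for the serum markers, whose clinical dynamic range is
  wider). Palliative patients carry residual disease, so their burden is
  shifted by `palliative_burden_shift` (default +0.5).
- **Postoperative drop.** Post and follow-up samples scatter around
  pre × drop with multiplicative lognormal noise (`level_noise_sd`, default
  0.3 on the natural-log scale). Drop defaults: 0.5 after radical surgery,
  0.9 after palliative (residual tumor keeps producing marker).
- **Survival.** Exponential with hazard
  `hazard_baseline · exp(coef · bᵢ)`, times a palliative multiplier
  (default 8): proportional hazards on the same burden factor that raises
  marker levels, which is what makes every panel marker prognostic.
  Defaults (baseline 0.001/week, coefficient 0.7, administrative censoring
  at 156 weeks ≈ the three-year median follow-up) give ≈10% mortality among
  radical and ≈70% among palliative patients — a cohort in which survival
  analysis is only informative in the palliative stratum, as in the
  motivating study. Exponential times keep closed-form checks possible.
- **Recurrence.** A fixed fraction (default 9/31 ≈ 0.29) of radical
  patients relapse; all follow-up samples at or after the recurrence time
  are multiplied by `recurrence_fold_signal` (default 3). The recurrence
  time is drawn uniformly within (2 weeks, last follow-up time) for
  patients who have follow-ups: clinically detected recurrences occur under
  surveillance, and a recurrence after the last sample is biochemically
  unobservable by construction.
- **Raw Ct rendering.** Per replicate,
  `Ct = ct_baseline + (spikein_ct − spikein_ct_mean) − log2(level) +
  run_shift + N(0, ct_noise_sd)`; the per-sample spike-in Ct
  (N(26, 0.5)) shifts the target Ct with it, so spike-in normalization
  cancels extraction efficiency exactly. Sample events are assigned to
  `n_runs` plate-sized blocks; non-reference runs carry per-marker shifts
  N(0, `run_shift_sd` = 0.3 cycles) expressed relative to the first run,
  and the first three sample events of the first run are re-measured on
  every later run as inter-run calibrators. With the default
  `ct_baseline = spikein_ct_mean = 26`, the processing chain inverts the
  generator exactly at zero noise — the round-trip identity the test suite
  asserts. Replicates past 40 cycles are reported as absent (no Cq call).

All randomness flows from a single integer seed; a fixed seed yields
bit-identical tables.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: assay-specific amplification efficiencies and
standard curves; correlation between stage covariates and outcome;
non-exponential (e.g. frailty or cure-fraction) survival; marker-specific
recurrence signatures (all markers share one burden factor and one
recurrence elevation); hemolysis and other pre-analytical artefacts; and
informative censoring or visit schedules. Results on synthetic cohorts
demonstrate correctness of the machinery, not clinical performance.

## Numerical conventions and degenerate inputs

- Exact Wilcoxon enumeration up to n = 25 (configurable); all-zero
  differences give p = 1 with a warning.
- Logrank with no events (or zero variance) returns χ² = 0, p = 1; a group
  with no subjects is an error.
- Cutoff search with fewer than two distinct values, or no admissible
  candidate, is an error rather than a silent fallback.
- ROC requires both truth classes; undefined diagnostic ratios are absent.
- Ties at a survival cutoff fall into the low group; ties at the ROC
  threshold are called positive (score ≥ threshold).
- The problem sizes used by the simulation-based tests (cohorts of 40–600
  patients, 200–1000 replicates for power and type-I error studies, single-
  or two-marker panels where the marker identity is irrelevant) were chosen
  to make Monte-Carlo bands tight enough to be informative while keeping
  the suite quick to run.

## Known limitations

- The minimal-p cutoff's unadjusted p-value is anti-conservative by
  construction; use the permutation adjustment for inference.
- The individual-cutoff recurrence rule has low specificity when follow-up
  noise is comparable to the baseline (two mildly elevated consecutive
  samples suffice); the synthetic defaults reproduce this behaviour
  (specificity ≈ 40–60% with high sensitivity), so specificity figures from
  synthetic runs should be read as properties of the rule, not of any
  marker.
- Clinical covariates in the generator are marginally realistic but jointly
  independent; analyses stratifying on stage would need a richer model.
- `repeat_required` rows are excluded rather than re-measured, which a
  wet-lab re-run could rescue; the exclusion rate is reported in the
  processing log.
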