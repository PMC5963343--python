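# Methods

## Quantification model

The pipeline implements the comparative-Ct method in its
equal-efficiency form. A Ct value is the PCR cycle at which fluorescence
crosses the detection threshold; under near-perfect doubling, one cycle
corresponds to a two-fold difference in starting template, so all
arithmetic is base 2 throughout (2^-ddCt for relative expression, 2^n
for isoform abundance ratios, log2 amounts in the degradation fits).

**Replicate aggregation.** Technical replicates are averaged within each
run first and the run means are then averaged, so each independent run
carries equal weight even when wells drop out. The SD attached to a
sample x assay aggregate is the sample standard deviation over all
detected wells pooled across runs: run-to-run shifts therefore widen the
dispersion estimate alongside pipetting noise. Undetected wells
("Undetermined") are a first-class flag, excluded from means and counts;
capping them at a numeric Ct would bias group means downward, so no cap
is applied. A sample whose wells are all undetected simply lacks that
assay and is skipped (with a warning) by dataset-level analyses.

**Group estimates.** ddCt is the mean case dCt minus the mean control
dCt. The SD propagated into the fold-change interval is the sample SD of
the per-sample case dCt values — the control group enters through its
mean only. This spans biological scatter plus any residual technical
variation in the per-sample dCts; with a single case sample the SD is
defined as 0 (the interval collapses to the point). The interval is
obtained by evaluating 2^-x at ddCt +/- SD, which makes the bounds
geometrically symmetric around the point estimate for a single
reference. With two housekeeping references the per-reference point,
low and high are averaged *arithmetically*, which is how the final
expression change is defined here; geometric symmetry then holds only
approximately, which is accepted deliberately.

**Significance rule.** A decrease is called only when the point estimate
is below 0.5 *and* the upper bound does not exceed 0.5; an increase only
when the point is above 1.5 and the lower bound is at least 1.5. Point
comparisons are strict, bound comparisons inclusive: an interval
touching the threshold exactly still supports the call. The rule is
intentionally conservative — it demands that the entire variance
interval clear the threshold — and the thresholds (0.5, 1.5) are
configurable but default to the conventional two-fold/1.5-fold bands.
Note the rule is a fixed decision band, not a hypothesis test; no
multiple-testing correction is applied across the profile rows.

**Efficiency.** Standard curves are ordinary least-squares fits of Ct on
log10 dilution of a common calibrator, per assay per run;
E = 10^(-1/slope) - 1, so slope -3.321928 corresponds to E = 1. The
equal-efficiency assumption behind 2^-ddCt is checked by
|E_target - E_reference| <= 0.1 (configurable); a failure logs a warning
and flags the estimate rather than aborting, since the analyst may still
want the number with the caveat attached. Efficiency-corrected
(Pfaffl-type) quantification is deliberately out of scope.

## Stability QC

Samples enter the analysis only with RIN strictly greater than 6;
missing RIN excludes with a warning. The degradation assay incubates
RNA at 50 °C and measures each transcript at 0/15/30/60/120/240 min;
the relative amount at time t is 2^(Ct_0 - Ct_t). Decay is modelled
log-linear: the per-minute log2 rate is the OLS slope of log2(amount) on
time, exact on noiseless series. Two transcripts are "comparable" when
neither absolute rate exceeds twice the other (max_ratio = 2,
configurable) — a declared operationalisation of "similar stability";
the criterion is symmetric, zero-vs-zero is trivially comparable, and
zero-vs-nonzero is not. No formal test is attached to the verdict.

## Cohort analyses

Per-patient expression uses the patient's own dCt against the *mean*
control dCt, per reference, then reference-averaged; consequently the
geometric mean of control-vs-control expression is exactly 1 for a
single reference. Stratification cuts are 65 years for age at onset
(onset at 65 or earlier is "early") and 6 years for duration (under 6 is
"short") — note the boundary belongs to the early stratum for onset but
to the long stratum for duration. Between-stratum contrasts reuse the
ddCt machinery with one stratum as the baseline; by default the
larger-expression stratum (smaller mean dCt) is the baseline so the
contrast reads as a fold <= 1, with `baseline="first"/"second"`
available when a fixed orientation is wanted. Clinical variables are
compared between strata with Welch's two-sided t-test (robust to the
unequal stratum sizes typical here, e.g. 6 vs 14); both groups constant
and equal yields p = 1 by convention. Expression-covariate association
is OLS of log2(rq) on the covariate — expression acts multiplicatively,
so the log scale is the default response (switchable). Patients missing
a covariate are excluded per analysis, never imputed.

## Synthetic cohorts

The generator emulates the measurement process, not the biology: Ct is
additive on the cycle scale,

    Ct = baseline[assay] - log2(fold) + run_offset + N(0, replicate_sd)

with Gaussian cycle-scale noise (the standard qPCR assumption),
per-assay-per-run offsets N(0, run_sd), references and controls fixed at
fold 1. Defaults: duplicate wells, two independent runs,
replicate_sd = 0.25 cycles, run_sd = 0.15 cycles — magnitudes typical of
SYBR-green assays on a rotary instrument. Group sizes default to the
emulated study's shape (brain 8/12/12/13 cases + 17 controls over
temporal cortex and caudate nucleus; blood 20 DLB / 26 PD / 17
controls), and the default true folds plant the suppressions the study
design targets (e.g. blood GBAtv1 at 0.41 in DLB and 0.35 in PD).
Covariate links are log-linear: fold multiplied by
2^(slope x (covariate - center) + noise), so the regression stage should
recover `slope` exactly on noiseless data. Clinical covariates come from
truncated normals (onset ~68 y for DLB, ~65 y for PD, durations ~6 y),
rounded to 0.1 y; age is onset + duration. Everything flows from one
`numpy.random.Generator`, so a config (including its seed) fixes the
outputs byte-for-byte.

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: amplification-efficiency mismatch between
assays (cohort Ct uses the ideal base-2 model; efficiency deviations
enter only the dilution-series generator), primer-level artefacts such
as GBA/GBAP1 cross-amplification, non-Gaussian outliers, undetected-well
censoring correlated with expression, and reference-gene instability
across disease groups.

## Numerical and design choices

- All fold arithmetic goes through exact base-2 exponentials;
  log2(point) = -ddCt to machine precision, which the property suite
  asserts, along with bound ordering and the Ct-shift invariance
  (adding a constant to every Ct changes nothing downstream).
- OLS fits and t-tests delegate to `scipy.stats` (`linregress`,
  `ttest_ind(equal_var=False)`).
- Dilution series need >= 3 distinct points; degradation series >= 3
  timepoints including 0; regressions >= 3 patients and a non-constant
  covariate; t-tests n >= 2 per group.
- Monte-Carlo scales: the recovery experiments use 200 cohorts of
  20 + 20 subjects (tests) and 100 cohorts in the acceptance script,
  with duplicate wells in two runs — ample for a +/-0.05 band on a mean
  fold of 0.4 at these noise levels.
- CSV dialect: comma-separated UTF-8 with a required header and "."
  decimal mark (tab-separated via `sep="\t"`); parsing is
  locale-independent and comma decimals are rejected loudly.

## Known limitations

Single-threaded, in-memory tables (fine up to ~10^6 wells). No
instrument-native file formats. The significance band is not a
calibrated error rate; users wanting inferential guarantees should
bootstrap or model dCt directly. Stratified analyses assume the two
strata share the control group. The degradation comparability criterion
is a heuristic ratio, not a test.
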