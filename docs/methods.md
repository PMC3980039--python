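# Methods

## The measurement problem

A frequently sampled mixed-meal tolerance test (FS-MMTT) gives a standard
liquid meal (~100 g carbohydrate, ~2930 kJ, eaten within 15 min) to a
fasted subject and samples plasma glucose, insulin and C-peptide at −15, 0,
30, 60, 90, 120 and 180 min relative to the meal start; urine is collected
from −15 to +180 min for urinary glucose excretion (UGE). From these seven
timed samples per visit the pipeline estimates beta cell function and
insulin sensitivity, and compares baseline→endpoint changes between
treatment arms. The UGE correction matters for SGLT2-inhibitor trials:
the drug lowers the renal glucose threshold, so part of glucose disposal is
renal and insulin-independent, and an uncorrected oral sensitivity index
mistakes it for an insulin-sensitivity improvement.

## Secretion model

Insulin secretion per unit body surface area (pmol min⁻¹ m⁻²) is modelled

    ISR(t) = P(t) · f(G(t)) + k_d · max(dG/dt, 0)

* `f(G)` — dose-response, piecewise linear in glucose on six evenly spaced
  knots spanning the fitted glucose range. Derived indices:
  **beta cell glucose sensitivity** = chord (mean) slope of `f` over the
  observed glucose range, and **ISR@9** = `f(9 mmol/l)` (linearly
  extrapolated, and flagged, when 9 mmol/l lies outside the observed
  range — common when fasting glucose exceeds 9).
* `P(t)` — potentiation factor, piecewise linear in time with nodes every
  30 min on [0, 180], constrained to unit time-average by exact
  renormalisation (the scale moves into `f`, leaving the ISR unchanged).
* `k_d` — rate sensitivity (pmol m⁻² (mmol/l)⁻¹), active only while
  glucose rises; a proxy for early insulin release.

C-peptide links the model to data: it is co-secreted equimolarly with
insulin but not hepatically extracted, so plasma C-peptide is the ISR
passed through two-compartment kinetics. Kinetic constants are not fitted;
they come from the standard population regression on age, sex, body
surface area (DuBois) and diabetes status. Forward simulation uses the
exact matrix-exponential update for piecewise-linear forcing on a 1-min
grid, which is bit-reproducible and matches a fine-step ODE oracle to
better than 0.1 %.

### Glucose signal

G(t) is the fasting level (mean of the −15 and 0 min samples) for t ≤ 0
and a cubic smoothing spline through the post-meal samples for t > 0. The
spline is fitted to mirror-symmetrised samples around t = 0, which anchors
G(0) at the fasting value with zero slope; the curve is then C¹ at the
meal start. The derivative of the spline supplies dG/dt for the rate
component (zero pre-meal). A single spline across the whole window cannot
represent the flat-then-rise shape and was found to bias the early ISR and
the rate sensitivity.

### Fitting

For fixed smoothing weights the model is bilinear, and is solved by
alternating bounded linear least squares (dose-response values and rate
sensitivity given P; potentiation nodes given the rest; renormalise P;
iterate to 1e−6 relative change, 200-iteration cap), followed by a joint
bounded Gauss-Newton polish — the alternation alone crawls along the
weakly identified trade-off between the rate component and a potentiation
tilt. Residuals are relative (percent of signal). Penalties are squared
second differences of the dose-response values (scaled by the basal ISR)
and of the potentiation nodes, sharing one weight. Non-negativity of `f`,
`P ≥ 0.01` and `k_d ≥ 0` are hard bounds. Optimiser stalls set
`converged=False` instead of raising.

### Smoothing selection

Weights are selected so the model residual SDs approach the expected
measurement error: ~1 % for glucose, ~4 % for C-peptide (band ±30 %).
Numerical choices that matter:

* **Dof-corrected residual SDs.** The criterion uses
  `sqrt(Σr² / (n − df))`, with `df` the smoother/hat-matrix trace — an
  unbiased noise estimate. Matching a plain RMS would force the fit to
  *manufacture* ~1 % distortion even on noise-free data, which was
  measured to corrupt the recovered indices by several percent.
* **Grid scan, not bisection.** The corrected SD is not monotone in the
  weight (residual dof collapse toward the interpolation end), so the
  target is located by a 9-point log-grid scan plus local refinement.
  Admissible ranges: glucose spline penalty 1e−4…3e2, secretion penalty
  1e−7…3e−1. Noise-free data never reach the target and return the
  largest admissible weight with a boundary flag, as intended.
* **Residual accounting.** The glucose criterion uses the post-meal
  samples; the −15/0 pair is a duplicate that informs the fasting level,
  and its within-pair scatter is a one-degree-of-freedom noise estimate
  whose variance would otherwise dominate per-subject selection.

The ISR is reported every 5 min on [0, 180] (37 nodes). Total insulin
secretion is its trapezoid integral (nmol/m²; the printed magnitudes of
this literature, ~40–60, are only dimensionally consistent with nmol/m²).
Insulin clearance = total secretion / insulin AUC (l min⁻¹ m⁻²), computed
only when at least five insulin measurements exist. AUCs and the 3-h mean
glucose integrate the trapezoid rule over [0, 180]; the −15 min sample
informs the baseline, not the AUC.

## Insulin sensitivity

OGIS (2-h variant; the schedule provides the required 0/90/120 min
samples) is evaluated from its published closed form with the published
constants, kept in a versioned constants module and locked by a
dual-transcription test. Units are converted to the formula's originals
(glucose ×18.016 mg/dl per mmol/l; insulin ÷6.945 pmol/l per mU/l); the
glucose dose is the meal's 100 g carbohydrate per body surface area.
Renal glucose clearance = UGE (g → mmol at 180.16 g/mol) / plasma glucose
AUC / BSA, and OGIS_c = OGIS − renal clearance. Whether the source
analyses used the 2-h or 3-h variant, and what dose value they supplied
for a mixed meal, is not published; 2-h with the 100-g carbohydrate dose
is this package's documented choice.

## Trial statistics

Endpoint ANCOVA per parameter: response = endpoint value, covariates =
baseline value and the binary baseline glycaemic-control stratum
(HbA1c ≥ 9.0 %), factor = treatment arm. LSMs are predictions at
grand-mean covariates; "change LSM" subtracts the pooled baseline mean;
contrasts vs the comparator arm use residual-df t intervals. Reading the
model statement as an ANCOVA on endpoints (not on raw changes) is a
documented choice. Covariate columns that are constant in a dataset are
dropped rather than raised as errors. Glucose sensitivity and the OGIS
indices are log-normal across subjects: estimates are reported on the
original scale while significance testing uses the log-transformed model.
Rate sensitivity, highly non-normal, is compared by a tie-corrected
Kruskal-Wallis test on the changes. Complete-case per parameter; no
multiplicity adjustment; p < 0.05 two-sided.

## Synthetic trial generator

Because no patient-level data are deposited, a forward simulator defines
the study conditions:

* **Glucose**: fasting level (9.5 ± 1.2 mmol/l, winsorised to 7–13) plus a
  gamma-like pulse peaking at 45 min, amplitude 4 ± 0.8 mmol/l per 100 g
  carbohydrate, back near baseline by 180 min.
* **Secretion truth**: piecewise-linear dose-response with knots at 4, 7,
  17, 21 mmol/l (slope multipliers 0.6/1.0/1.4 around the 9 mmol/l
  anchor — the observed range of a diabetic MMTT sits on the linear
  central segment); glucose sensitivity log-normal, median
  35 pmol min⁻¹ m⁻² (mmol/l)⁻¹; ISR@9 proportional to it (×4.0,
  log-normal); unit-mean linear potentiation ramp with end/start ratio
  ~1.5; rate sensitivity log-normal, median 350. These place the truth
  inside the fitted model class, so the noise-free closed loop measures
  estimation error, not representation error.
* **C-peptide** via the same population kinetics; **insulin** via a
  single compartment (7 l/m²) with hepatic extraction folded into the
  truth clearance (1.2 ± 0.2 l min⁻¹ m⁻²), so pipeline clearance ≈ truth.
* **UGE**: excretion rate = ρ · max(G − threshold, 0) with
  ρ ≈ 0.1 l/min and threshold 10 ± 0.8 mmol/l; the treated arm lowers the
  threshold by 5.5 mmol/l and glucose by 12 %, yielding ~15 g/3 h.
* **Noise**: multiplicative log-normal on the measured samples — 1 %
  glucose, 4 % C-peptide (the assay errors the smoothing targets), 6 %
  insulin (not assay-characterised in the source studies; a default).
* **Seeding**: one global seed expands through
  `SeedSequence(seed, spawn_key=(arm, subject, stream))`, so growing a
  trial never reshuffles existing subjects.

What the generator does *not* emulate: gastric-emptying variability and
multi-phase glucose excursions, insulin-dependent glucose dynamics (the
glucose curve is exogenous, so treatment effects on sensitivity do not
feed back into glucose), C-peptide kinetic misspecification, assay drift,
dropout and rescue-therapy censoring. Passing tests therefore demonstrate
the estimation machinery under the stated noise model, not robustness to
those real-data features.

## Problem sizes

Validation uses 100 profiles for the residual-SD calibration, 10 noise-free
subjects for closed-loop recovery, 50 replicates for noisy-recovery bias,
50 simulated trials for the UGE-correction direction, a 2 × 40-subject
two-visit trial for the end-to-end ANCOVA check, and 2000 replicates for
the Kruskal-Wallis null calibration. A single fit takes ~0.3 s, so the
full suite runs in a few minutes.

## Known limitations

* Rate sensitivity is weakly identified from seven samples; noise-free
  recovery is within ~15 %, noisy estimates scatter widely (the trial
  comparison treats it non-parametrically for the same reason).
* ISR@9 is an extrapolation whenever fasting glucose exceeds 9 mmol/l.
* The first two ISR grid nodes (0, 5 min) interpolate between the 0 and
  30 min samples; different smoothness priors can move them by a few
  percent (see the deconvolution-oracle test).
* The OGIS constants are transcribed from the original publication and
  locked by a dual-transcription test; an upstream transcription error
  would shift all OGIS values by the same deterministic map.
* Per-subject residual-SD targeting on seven points estimates noise on
  2–4 residual dof; individual achieved SDs scatter and only the pooled
  calibration is tight.
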