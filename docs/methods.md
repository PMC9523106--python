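# Methods

This note documents the models, algorithms and design choices behind
`hemoqol`: what is computed, under which assumptions, and what the synthetic
data do and do not establish.

## Setting

Transcatheter aortic valve implantation (TAVI) removes a left-ventricular
outflow obstruction within seconds. The package reconstructs, on synthetic
data with known ground truth, an analysis of that moment: beat-by-beat
hemodynamics from a continuous non-invasive arterial pressure waveform
(200 Hz finger-cuff recording), the immediate pre- vs post-implantation
change in ten variables, EQ-5D-5L quality-of-life (HRQoL) scoring before and
12 weeks after the procedure, and the association between the immediate
change in left ventricular ejection time (LVET) and the change in the HRQoL
index.

## Waveform analytics (`beats`, `hemo`)

**Filtering.** All fiducial decisions are made on a zero-phase 4th-order
Butterworth low-pass at 15 Hz. Derivatives are Savitzky–Golay local
polynomials (order 3): a 25 ms window for dP/dt and a 45 ms window for the
second derivative used in notch timing. Finite differences at 200 Hz are
noise-dominated; measured dP/dt max on noisy records carries an upward noise
bias and is treated as a comparative, not absolute, quantity.

**Beat onset (foot).** Candidate upstrokes are maxima of the smoothed
derivative (height: 25 % of the 95th percentile of positive slopes; minimum
spacing from a 220 bpm ceiling). For each candidate the classic
intersecting-tangent construction (tangent through the max-slope point
intersected with the preceding diastolic minimum level) brackets the onset;
the foot itself is the average of two refinements with opposite
smoothing-induced biases — the last negative-derivative sample before the
upstroke (runs a few ms early on a zero-phase-filtered corner) and the
curvature maximum around the diastolic minimum (runs a few ms late). On
generated records this average recovers onsets to within ~2 ms in the mean.

**Dicrotic notch / LVET.** The notch is searched between 0.15·IBI + 100 ms
and min(0.5 s, 0.6·IBI) after the foot, after the systolic peak. Valve
closure interrupts the late-systolic decline, so the notch is taken as the
maximum of the smoothed second derivative immediately (≤ 80 ms) after the
steepest post-peak decline; this coincides with the incisura's
negative-to-positive derivative crossing whenever the incisura is strong
enough to produce one. The candidate is accepted only when the curvature
peak exceeds 0.3 × (decline rate / 50 ms); a smooth, notch-free decay fails
this test and the beat is flagged and excluded from LVET and stroke-volume
averaging. LVET = (notch − foot)/fs. Validated recovery at the generator's
default 1 mmHg sample noise: per-record mean error within ±8 ms across 100
records spanning HR 60–90 bpm, LVET 280–380 ms. At 2 mmHg noise the
steepest-decline anchor begins to mislocate and errors can exceed the 10 ms
budget; that regime is a known limitation.

**Per-beat variables.** SBP = beat maximum; DBP = pressure at the foot;
MAP = true time average over the beat; HR = 60/IBI; dP/dt max = maximum
smoothed derivative over the upstroke.

**Stroke volume.** The pulse-contour rule: SV = ∫ foot→notch (P − P_foot) dt
/ Z_ao. Integrating pressure above the beat's foot pressure makes the
rectangular-pulse oracle exact and removes the diastolic offset; an
absolute-pressure variant is available (`offset="absolute"`). Z_ao is
supplied (the synthetic truth carries the impedance that makes the clean
curve's systolic integral match the true SV — this is what "truth recovery"
means) or estimated from a calibration beat against a nominal 70 ml. The
commercial pulse-contour algorithm used in the original recordings is
proprietary; this documented Windkessel-consistent rule replaces it, and no
absolute-accuracy claim against thermodilution is made.

**Derived indices.** CO = SV·HR/1000 (L/min, averaged per beat);
SVR = 80·(MAP − CVP)/CO with CVP defaulting to 0 mmHg (configurable);
SW = SV·MAP per beat; BSA by Du Bois (0.007184·h^0.725·w^0.425, Mosteller
available); CPI = (MAP·CO/451)/BSA in W·m⁻², classified low below
0.44 W·m⁻² with 0.44 itself normal.

**Windows.** Three analysis time frames: a 600 s baseline from the
`baseline_start` event; a 20 s pre-implantation window chosen inside the
180 s before valvuloplasty (when performed, else before implantation); a
20 s post window inside the 180 s after implantation. Candidates step by
1 s and the minimum-artifact-score window wins; if none scores below 0.2 the
patient is excluded (`no_artifact_free_window`). The score is an automated
surrogate for the original study's manual selection: the larger of the
clipped-sample fraction (outside 20–250 mmHg) and a capped weighted
fraction of violating beats (out-of-range SBP/DBP, >20 % beat-to-beat SBP
jumps, missing notch at half weight, implausible rate). The rhythm flag is a
screening surrogate, never diagnostic: `irregular_suspect` requires both an
IBI coefficient of variation above 0.15 and sign alternation of successive
IBI differences in more than 60 % of beats; `annotated_paced` comes only
from an explicit event label.

## EQ-5D-5L scoring (`hrqol`)

A health state is five levels (1–5) on mobility, self-care, usual
activities, pain/discomfort and anxiety/depression. Scoring is
tariff-agnostic over an additive decrement table loaded from CSV; the
vendored Dutch value set (Versteegh et al. 2016) has no constant term and
its level-5 decrements sum to 1.446, so the worst state 55555 scores
−0.446 — the published range endpoint, which pins down the value-set
version. Monotonicity (worsening any dimension never raises the index) and
the exact range over all 3125 states are enforced by tests. A missing state
yields a missing index; imputation happens downstream in the statistics.

## Statistics (`stats`)

* **Change table.** Per variable: pre/post mean and SD, mean within-patient
  change with t-based 95 % CI and paired-t p-value, and the mean of
  *per-patient* percent changes (computed per patient before averaging —
  with skewed baselines this deliberately differs from the percent change
  of the means). Zero-variance differences return p = 1 rather than NaN.
* **Rank and exact tests.** Wilcoxon signed-rank / rank-sum with exact null
  for n ≤ 25 without ties (normal approximation with continuity correction
  otherwise); Fisher's exact test by hypergeometric computation. All via
  scipy, cross-checked in tests against full enumeration oracles.
* **Association model.** The outcomes analyzed (HRQoL index, hemodynamic
  deltas) are continuous and reported on additive scales, so the
  "generalized" mixed models are Gaussian with identity link: outcome
  stacked over (pre, post), random intercept per patient, fixed effects
  timepoint + timepoint×predictor. The interaction coefficient rescaled by
  −10 gives "index points per 10 ms LVET decrease". The exact design matrix
  of the original analysis is not published; this structure is our
  reconstruction, and a simpler Δoutcome ~ Δpredictor OLS form is available
  (`model_form="delta"`).
* **Missing data.** Little's MCAR test is implemented directly (no
  installed package provides it): EM for the multivariate-normal ML mean
  and covariance under arbitrary missingness patterns, then the summed
  pattern-wise Mahalanobis distance d² on Σ pattern variable-counts − p
  degrees of freedom; complete data return statistic 0, df 0, p = 1 by
  convention. Imputation is chained equations with predictive mean matching
  (k = 5 donors, m = 5 imputations, 10 iterations) via statsmodels'
  `MICEData`; PMM respects the bounded index support. Downstream estimates
  are pooled by Rubin's rules (within + (1 + 1/m)·between variance,
  Barnard–Rubin df); with zero missingness pooling returns the
  complete-data result exactly.
* **Power.** Exact noncentral-F: power = P(F'(u, n−u−1, λ = f²·n) >
  F_crit). At f² = 0.2, 10 predictors, α = 0.05 the achieved power at n = 91
  is 0.8015 and 91 is also the smallest n reaching 80 % — consistent with
  the published planning, asserted as a bound since the original
  table-lookup method is ambiguous.

## Synthetic data (`synthgen`)

**Waveforms.** Per beat, a half-sine aortic inflow of duration LVET and
area SV drives a three-element Windkessel (defaults: Zc 0.06 mmHg·s/ml,
C 1.3 ml/mmHg, Rp 0.75 mmHg·s/ml, outflow offset 25 mmHg — chosen to give
physiologic pressures near the cohort's pre-implantation means at
SV 70 ml / HR 75 / LVET 332 ms). The compliance ODE is integrated by exact
first-order discretisation; a damped 8 Hz sinusoid of 3 mmHg starting at
flow cessation creates the dicrotic notch; Gaussian sample noise (default
1 mmHg) is added last. The truth object carries per-beat SV/LVET/IBI, the
Windkessel parameters, the clean trace's mean pressure, and the matched
aortic impedance. Procedure records concatenate a ≥10 min baseline and
pre-implantation epoch with a post epoch at changed hemodynamics, with
events and a configurable extra 336 s between measurements for
valvuloplasty patients. The generator emulates timing, morphology and
event structure — not arrhythmia, pulse-wave reflection changes, drift or
movement artifact — so passing truth-recovery tests demonstrates correctness
of the analytics on well-formed beats, not robustness to every clinical
artifact.

**Cohorts.** n = 97 by default. The directly simulated variables (SBP, DBP,
MAP, HR, SV, LVET) are drawn at the published pre-implantation means/SDs
(correlated pressures; truncated at wide physiologic bounds) with additive
within-patient changes whose SDs are reconstructed from the printed 95 %
CIs of the mean change (SD = halfwidth/1.96·√97 — the only consistent
reconstruction, since change SDs are not published). ΔLVET and ΔHR are
negatively correlated (−0.3 by default); other delta correlations default
to 0. The additive construction automatically yields a within-patient
pre/post correlation near 0.7 for the published SDs. CO, SVR and SW are
derived per patient, so their cohort moments follow rather than being set.
dP/dt is lognormal at mean 724 / SD 368 with a multiplicative change: the
per-patient fractional change has mean 0.67 and is negatively coupled to
the pre value with coefficient 0.38, chosen analytically from the two
published numbers (mean change 414 = 724·(0.67 − 0.38·CV²)); this
reproduces both the +67 % per-patient mean and the 414/724 ≈ 57 %
asymmetry between the two percent conventions.

The latent pre-procedural utility is a Beta(5.79, 1.13) scaled to
[−0.446, 1], calibrated once to the published median 0.810 and IQR
[0.662, 0.914] (the family itself is a convention; only quantiles are
published), then snapped to the nearest attainable EQ-5D-5L state and
scored, so every index in the cohort is a real tariff value. The post
index is pre + β·ΔLVET + N(0, 0.15), clipped to the tariff range and
snapped likewise, with β = −0.002 per ms (+0.02 per 10 ms decrease).
Because the index is bounded and the pre distribution sits near the
ceiling, a naive hard clip would censor roughly a quarter of post draws
and attenuate the realized slope by ~20–30 %; the applied latent shift is
therefore inflated by the mean in-range probability (a censoring-aware
calibration analogous to the dP/dt one) so that the population slope of
the *observed* index equals the configured coefficient. Missingness is
completely at random at fixed counts (9 pre, 1 post at n = 97). Baseline
CPI and its class emerge from the drawn MAP, CO and Du Bois BSA rather
than being targeted; the CPI-class contrasts are computed by the pipeline
but deliberately left unanchored in the generator.

## Pipeline (`pipeline`, `cli`)

`run_study` consumes either a directory of waveform CSVs plus a patient
table, or a synthetic-cohort block; applies the exclusion rules (no clean
window, suspected arrhythmia, annotated pacing); builds the cohort table;
and produces the change table, HRQoL medians with rank-test p, pooled
mixed-model associations per change variable, CPI-class and valvuloplasty
contrasts, and a provenance block (config hash, seed, version). All
randomness flows from the config seed, so reruns are byte-identical. The
CLI (`hemoqol simulate|analyze|report`) is a thin wrapper.

## Problem sizes used in validation

Truth recovery uses 100 records of 30 s (≈30–45 beats each, enough for
stable within-record averages). Mixed-model recovery uses 500 cohorts of
n = 97; calibration echoes 100–200 cohorts; Little's-test size 1000
replicates of n = 150 with 20 % missingness on two of three variables;
moment convergence n = 10⁴. These sizes keep Monte-Carlo error well below
the corresponding acceptance tolerances.

## Known limitations

* Notch detection degrades above ~2 mmHg sample noise and is tuned for
  200 Hz; at lower sampling rates the fixed-width smoothing windows shrink
  to their minimum sizes.
* Measured dP/dt max inherits an upward noise bias (max of a noisy
  derivative); only changes and comparisons are meaningful.
* EDF I/O requires the optional `pyedflib` backend; CSV is the reference
  dialect.
* The generator draws deltas mostly independent of pre values; real
  hemodynamic responses are more strongly coupled, and the CPI-response
  correlations reported in the original cohort are intentionally not built
  in.
* The mixed model assumes homoscedastic residuals across timepoints,
  whereas the generator gives the pre index no residual of its own; with
  two timepoints the interaction estimate is unaffected.
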