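# Methods

This note documents the models, algorithms and numerical choices behind
`fqrs`, in the order the pipeline runs them.

## Synthetic 12-lead ECG

Beats are sums of Gaussian waves (P, Q, R, S, T).  Each wave carries a
3-vector dipole moment; each lead is a fixed projection row of that dipole
(limb leads at their conventional frontal-plane angles, precordial rows
rotating from right-anterior V1 to left-lateral V6).  Leads are therefore
coherent — III = II − I holds exactly — which is what multi-lead
segmentation needs to be tested against.  Default wave parameters give a
~120 ms QRS with a dominant R in II and an S-dominant V1–V2, i.e. a
plausible cardiomyopathy-range complex at 250 Hz, the conventional
acquisition rate for resting 12-lead ECG.

Records tile beats at RR intervals of mean 1.0 s with 3% Gaussian jitter,
and add baseline wander (sinusoid < 0.5 Hz, default 0.05 mV at 0.3 Hz),
powerline hum (50 Hz, 0.01 mV) and white noise (0.01 mV SD).  All
generators are pure functions of their parameters and a seed.

**Fragmentation model.**  Fragmentation is extra intra-QRS deflections:
`n_notches` narrow Gaussians (default width sigma = 2.5 ms) with
alternating sign, amplitude `0.15 × severity × QRS peak-to-peak`, at
stratified-random positions strictly inside the QRS support (the 3-sigma
span of the Q/R/S waves).  Notches are windowed to that support, so
samples outside the QRS are bit-identical to the clean template.  The
width default matters: a notch on the steep R flank only creates a
visible extremum when its peak slope (amplitude / width) exceeds the local
flank slope, and sigma = 2.5 ms achieves that at moderate severities while
remaining representable at 250 Hz.  Severity 0 means no notches and vice
versa; severity only scales amplitude.

**Annotator panel.**  Five independent binary annotators vote
"fragmented" with probability interpolating linearly on the logit scale
from their false-positive rate at severity 0 to their sensitivity at
severity 1 (exact at the endpoints, so perfect annotators are
deterministic there).  Default operating points (sensitivity ~0.72–0.85,
specificity ~0.90–0.94) bracket the published performance range of
trained human readers of QRS fragmentation.  The vote sum 0–5 is the
agreement score; only full-agreement leads (0 or 5) become classifier
ground truth, and the intermediate scores are generated but excluded, as
in the annotation study the pipeline emulates.

## Segmentation

* **R detection** runs on the RMS envelope of per-lead z-scored signals
  (gain-invariant), with a 200 ms refractory distance and an amplitude
  floor of 60% of the 90th-percentile peak height — robust to isolated
  outsized beats while rejecting P/T envelope bumps.
* **Abnormal-beat rejection** compares every beat's R±100 ms window with
  the beat-wise median template per lead; Pearson correlation below 0.90
  in any lead rejects the beat.  At least one beat must survive.
* **Delineation** walks outward from R per lead until the absolute
  derivative stays below `max(0.03 × max|d|, 4 × median|d|)` for 12 ms;
  the median term is a noise floor (the median derivative magnitude over
  the ±150 ms span estimates the derivative of the noise).  The fused
  per-beat window is the earliest per-lead onset to the latest per-lead
  offset.  The onset is then padded left by a fixed 8 ms guard: near the
  Q onset the opposing Q and R flank slopes partially cancel, so a
  derivative criterion systematically fires late there, while near the
  offset the S and T slopes add and the criterion is already
  conservative.  This deliberate asymmetry makes an isolated symmetric R
  wave's window asymmetric by exactly the guard — accepted and tested as
  such.  Window width is clamped to [40, 200] ms about R.
* **Representative segment**: kept beats aligned on R, per-beat baseline
  (mean of the 20 ms before onset) subtracted, averaged pointwise, and
  resampled to 128 samples by band-limited (FFT) interpolation — ~1 kHz
  equivalent for a 128 ms window, giving PRSA and VMD enough support when
  the source is 250 Hz.

All indices are 0-based with half-open windows.

## The ten features

1–3. **PRSA**: anchors are samples with `x[i] > x[i−1]`, at least L = 16
samples from either edge; the curve is the anchor-aligned mean of 2L
windows.  Features: mean first difference of the curve, and slope and
k = 0 intercept of its least-squares line (closed form).  The
implementation is tested to be exactly (1e-12) the literal anchored
average.

4–9. **VMD**: ADMM variational mode decomposition, K = 5, bandwidth
penalty alpha = 2000, tau = 0 (no exact-reconstruction constraint, which
tolerates noise), tolerance 1e-7, at most 500 iterations.  The signal is
mirror-extended, modes are Wiener-filter updates on the half spectrum,
center frequencies are spectral centroids.  Center frequencies start at
the K strongest spectral peaks; uniform initialisation can leave two
modes sharing one tone, a degenerate fixed point of the ADMM iteration
(and for a spectrally leaky tone even the peak initialisation converges
toward a split, which is why the tone unit tests use grid-aligned
frequencies).  Features: relative energies and strict sign-change counts
of the three highest-frequency modes — fragmentation adds high-frequency
structure, so these rise with severity.  The exact six VMD-derived
quantities are an interpretation and are isolated behind `vmd_features`
so they can be swapped.

10. **Peak count**: local maxima plus minima of the 5-point
moving-average-smoothed segment with prominence at least 5% of its
peak-to-peak amplitude.

PRSA features scale linearly with amplitude; energies, sign changes and
peak counts are scale-invariant — tested properties.

## Classifier and operating point

`FqrsClassifier` is a scikit-learn estimator: feature standardisation,
RBF-kernel SVM (C = 1, bandwidth heuristic gamma = "scale"), and Platt
scaling `p = 1/(1 + exp(A·f + B))` fitted by logistic regression on
out-of-fold decision values (3-fold, seeded) to avoid calibrating on
resubstitution scores.  Training uses only full-agreement leads (20+
per class required); intermediate-score leads are scored at prediction
time.  One generic model serves all leads.  The decision function is
evaluated from stored support vectors, so a model serialised to JSON
reproduces probabilities exactly.

Per-lead probabilities are averaged into anterior (V1–V5), lateral
(I, aVL, V6) and inferior (II, III, aVF) regions; aVR belongs to no
region.  A region is positive when its mean is strictly greater than the
cutoff; a patient is fQRS(+) when any region is positive.  The operating
cutoff is recomputed per trained model as the threshold maximising
Youden's J = sensitivity + specificity − 1 subject to specificity ≥ 0.95,
over midpoints of consecutive sorted unique probabilities plus sentinels;
ties break towards higher specificity, then the lower cutoff.  The value
0.642 (J = 0.651) reported for the original clinical training registry is
shipped as a documented constant, not a default.

## Cohort simulator

Covariates follow documented marginals of a registry-like ICD population
(age ~ N(62.6, 11.5), LVEF ~ N(31, 12) truncated to [5, 70], creatinine
~ N(1.26, 0.48), 18.3% female, 64.3% ischemic, NYHA multinomial, device
and medication prevalences as tabulated in `cohort_sim`).  Age, LVEF and
creatinine share a small Gaussian copula (age–creatinine +0.30,
age–LVEF −0.15, LVEF–creatinine −0.15); truncation is by clipping, whose
distortion of the stated means is well below the simulator's own Monte
Carlo noise at the tested sizes.  Everything else is independent —
marginals, not joint structure, are what the downstream statistics are
tested against.

Death and first appropriate therapy are Weibull proportional-hazards
processes (death: shape 1.1, scale 4600 d; therapy: shape 0.9, scale
4200 d — front-loaded, ~35% ever-appropriate and ~30% mortality over the
simulated follow-up).  Log-hazard coefficients apply to z-scored
continuous covariates and raw binaries; the fragmentation coefficient
defaults to 0 — the null-association scenario.  The first appropriate
therapy is a shock with probability 0.5, otherwise ATP with a later
first shock (exponential delay, mean 700 d).  Inappropriate shock is a
separate process (AF raises it, age lowers it).  Transplant
(exponential) and administrative end of follow-up (uniform 1–10 years)
censor independently; transplantation is the last day of follow-up.

Endpoints per patient: overall / 1-year / 3-year mortality and
appropriate therapy (day granularity, horizons 365 and 1095 d, a death
at exactly day 365 counts as within the first year), first appropriate
shock, ever inappropriate shock, and ICD-resistant mortality — death
within the first year after implantation, or within 30 days after the
first appropriate shock (as written: the *first* shock, even if later
shocks precede death), or death without any documented appropriate
intervention (ATP or shock) during follow-up.  Survivors and
transplant-censored patients are 0.

## Outcome statistics

* Pearson chi-square **without** continuity correction for 2×2 tables —
  validated against the two printed baseline contrasts (device type
  p = 0.004, etiology p = 0.019); with Yates correction the device-type
  fixture rounds to 0.005 instead.
* Mann-Whitney U, two-sided: exact null when the combined sample is
  below 20 and tie-free, otherwise the tie-corrected normal
  approximation (scipy).
* Cox proportional hazards via lifelines, Efron tie handling
  (day-granular simulated data produces ties), Wald CIs and p-values.
  Candidates with univariable p < 0.100 enter one joint model
  simultaneously (ENTER; no stepwise).  NYHA is screened by a
  likelihood-ratio block test and expanded against class I.  The
  exposure of interest can be force-included so its CI is always
  reported.  A non-convergent unpenalised joint fit (sparse indicator
  separation at small n) retries once with a weak ridge
  (penalizer 0.1); a non-convergent univariable fit is reported as
  inestimable.
* VIF per covariate from regressing it on the others with intercept;
  R² within 1e-10 of 1 is flagged as infinite rather than raised.
* Baseline table: mean ± SD with Mann-Whitney p for continuous, n (%)
  with chi-square p for categorical, complete-case per variable with
  per-variable denominators reported.

## What the synthetic data does and does not show

The generator reproduces the *structure* the methods need: coherent
leads, controllable intra-QRS deflections, graded annotator agreement,
registry-like covariate marginals and proportional-hazards event
processes with a switchable fragmentation effect.  It does not model
conduction physiology, AF rhythms (the simulator is sinus-only with RR
jitter), pathology beyond fragmentation, inter-patient morphology
variability beyond amplitude/jitter, or non-proportional hazards.
Passing tests therefore demonstrate algorithmic correctness and
statistical calibration under the stated generative assumptions — not
clinical performance on recorded ECGs, which requires annotated data the
package does not ship.

## Problem sizes and determinism

Default verification sizes: 100 records (1200 leads) for classifier
recovery; 200 replicates of 300-patient cohorts for the null-effect
coverage; 200/500 replicates of 150-patient survival samples for CI
coverage and type-I error; 3000 patients for point recovery.  One global
seed fans out to per-stage child seeds via `numpy.random.SeedSequence`
spawning in a fixed stage order, so every stage is independently
reproducible and two runs of the pipeline under one seed produce
byte-identical artifacts.

## Known limitations

* The per-wave "3-sigma support" is an analytic convention; near the Q
  onset the composite waveform is already below 0.5% of peak-to-peak,
  so any finite-threshold delineator needs the documented onset guard.
* VMD mode identity (which mode is "highest-frequency") can swap under
  near-equal center frequencies; features depend only on the sorted
  order.
* The Youden cutoff of a model trained on synthetic data is a property
  of that synthetic distribution; it is not comparable to the clinical
  reference constant.
* Wald CIs are first-order; at very low event counts their coverage
  degrades, which the simulator sizes avoid.
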