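# Methods

## The paradigm and its measures

The pipeline analyses a cued free-viewing task: a 1 s central fixation
cross, then a face for 1.5 s placed so that gaze starts inside either the
eye region (eyes-cued) or the mouth region (mouth-cued).  Sessions have 60
trials, 30 per condition; 10 actor identities × 3 emotions (angry, happy,
neutral) are fully crossed with condition, so each actor appears 6 times
and each emotion 20 times.  The dependent variables are, per participant ×
condition: the proportion of valid trials whose first gaze shift leaves the
cued region for the other region; the latency of that shift (saccade onset
minus stimulus onset, ms); and the arousal index V_p/A — peak saccadic
velocity divided by amplitude, in 1/s — over all saccades with A > 4°
regardless of direction.  First shifts landing outside both regions are
excluded from both the numerator and denominator of the proportion and from
latencies (they are rare by design; the latency-agreement QC below verifies
this).  A condition with fewer than five valid trials drops that
participant from that condition.

## Synthetic gaze generation

The generator is first-class: it defines the conditions under which every
downstream stage is validated, and emits exact ground truth per trial
(shift indicator, target, latency, amplitude, duration, peak velocity).

**Saccade kinematics.**  Saccades follow a raised-cosine velocity profile
v(t) = (V_p/2)(1 − cos 2πt/D), chosen because its closed forms — peak
velocity V_p = 2A/D and displacement x(s) = A(s − sin 2πs / 2π) — give
exact oracles for every velocity-estimation and event-detection test.
Durations follow a linear main sequence D = D₀ + kA with D₀ = 21 ms and
k = 2.2 ms/deg, which puts V_p in the physiological 100–500 deg/s range for
the 4–10° amplitudes the paradigm produces and makes V_p/A decrease with A,
as the main sequence requires.  Tonic hypo-arousal is modelled as a
multiplicative scaling s < 1 of peak velocity at fixed amplitude,
implemented by inflating D to D/s; the WS-like default is s = 0.75, the
ratio of the reported group means of the arousal index (22.45 / 29.67).

**Trial composition.**  Gaze rests at the cross (the angular origin) for
1 s; the cued AOI is centred on the cross and the other AOI sits 5° away
vertically (eyes above mouth).  AOI extents are fixtures — eyes 8° × 3°,
mouth 6° × 2.5° — not reconstructions of any stimulus set.  With the
condition's shift probability, one saccade is made to the other AOI's
centre at a latency drawn from a shifted log-normal (shift 100 ms,
σ = 0.35, median ≈ 280–380 ms by direction and group), the standard
right-skewed shape of saccadic latency distributions; draws are capped at
1.3 s so the movement completes within the stimulus epoch.

**Noise.**  Isotropic Gaussian position noise per sample (default SD 0.3°),
independent per-sample dropout (default 2%) and optional contiguous blink
gaps.  The generator does not emulate temporally correlated drift or
tremor, smooth pursuit, microsaccades, corrective saccades, head movement,
or eccentricity-dependent precision loss; passing recovery tests therefore
demonstrates correctness of the algorithms under the stated noise model,
not performance on any particular eye tracker.

**Reproducibility.**  A cohort is a pure function of its config and seed;
each participant receives an independent child RNG spawned from the cohort
seed.

## Event detection (I-VT)

Angular speed is the central difference of position over time (the distance
between samples i−1 and i+1 over their time span, one-sided at ends).
Samples with speed strictly above 30 deg/s are saccadic; equality counts as
fixation, a fixed convention that makes the boundary testable.  Runs of
same-label samples become events; saccade runs shorter than 10 ms are
relabelled fixational and fixation runs shorter than 60 ms are dropped as
unclassified.  Gaps shorter than 75 ms are bridged by linear interpolation;
longer gaps leave velocity undefined.  All of these are config.

**Noisy data.**  With 0.3° iid position noise at 120 Hz, the plain central
difference has ≈ 25 deg/s velocity noise per axis, and a 3-sample median
pre-filter still leaves ≈ 17 deg/s — both make a 30 deg/s threshold
meaningless (large fractions of fixation samples cross it).  The package
therefore provides `IVTConfig.noise_robust()`: a Savitzky–Golay derivative
(order 2, window 7 samples ≈ 58 ms at 120 Hz) with a 15 ms minimum saccade
duration (3 samples at 120 Hz).  Measured under the generator's defaults
this yields ≥ 95% detection of ≥ 4° saccades, mean onset error under 1
sample, mean amplitude error ≈ 5%, and ≈ 2% false alarms.  Saccade
amplitude is the straight-line start→end angular displacement (not path
length), measured between the smoothed positions flanking the
supra-threshold run.

Raising the threshold always shrinks the set of saccade-labelled samples,
but can split one run into two events that both survive the
minimum-duration rule, so event counts are only guaranteed monotone on
clean data; the suite asserts the sample-level (total saccadic time)
monotonicity on noisy data.

## Peak velocity and the arousal index

At 120 Hz the sampling grid usually straddles the velocity peak, biasing
raw peaks low by 15–25% for 30–50 ms saccades.  Recordings are therefore
up-sampled tenfold with an interpolating cubic spline (not-a-knot ends,
fitted per contiguous valid block so gaps are never bridged), and velocity
is recomputed on the dense stream with the same central-difference
operator; each saccade's peak is the dense-stream maximum within its
window.  Phase-averaged recovery error is ≈ 1.4% at A = 5° and below 1% at
A ≥ 6° (the criterion grid starts at 5° because only saccades exceeding 4°
qualify for the index); at 60 Hz the error is ≈ 40–55% and cannot be
repaired by interpolation, so 60 Hz recordings are refused with an explicit
error and the pipeline skips the arousal stage for them.  The
per-participant mean pools qualifying saccades across trials within a
condition (not trial means first) — the choice is logged because either
reading is defensible.

## Mixed-model inference

Outcomes are modelled with linear (Gaussian) mixed models with a random
intercept per participant, fitted by maximum likelihood — never REML, since
likelihood-ratio and BIC comparisons across fixed-effect specifications
require comparable likelihoods.  Proportions are modelled linearly rather
than with a logistic link, trading statistical taste for fidelity to the
analysis this pipeline mirrors.  A hypothesis is tested by comparing the
model with the effect against the nested model without it:
χ² = 2(ℓ₁ − ℓ₀), p from the χ² distribution on the parameter-count
difference, and BF₁₀ = exp((BIC₀ − BIC₁)/2) with BIC = k ln n − 2ℓ, where
n is the number of observations (rows) and k counts fixed effects plus the
two variance components; n and k conventions change the BF and are fixed
here deliberately.  Effect sizes are marginal f² =
(R²m₁ − R²m₀)/(1 − R²m₁), with marginal R² = var(Xβ)/(var(Xβ) + σ²_b +
σ²_e).  Follow-up families carry Benjamini–Hochberg FDR flags at q = 0.05;
uncorrected p-values are reported alongside.

When the random-intercept variance collapses to its boundary (typical for
one-observation-per-participant subsets) the optimizer's Hessian is
singular there; the fit then falls back to ordinary least squares, which is
exactly the ML solution at σ²_b = 0, keeping the parameter count unchanged
so comparisons remain valid.

**Power.**  For a binary group indicator with observation-level variance
p(1−p), a fixed effect β has generating marginal f² = β²p(1−p)/(σ²_b +
σ²_e); the power simulation inverts this analytically (no iterative
calibration) and measures the LRT rejection rate over simulated datasets
with two groups of participants and two observations each.  At the study's
group sizes (37 vs 50) and f² = 0.15 the measured power is far above the
80% design claim; with f² = 0 the same machinery measures the type-I error,
which sits at the nominal 5% within Monte-Carlo error.

## Problem sizes and numerical choices

The test suite uses 500-replicate simulations for the power and type-I
checks, 8 sessions (480 trials) for detection recovery, and 28 participants
for the end-to-end group-signature check; these sizes give Monte-Carlo
standard errors comfortably below the margins being asserted.  Tolerances
follow the oracles: closed-form kinematic identities at 1e-6–1e-9,
interpolation-limited recovery at 1–2%, stochastic recovery at 2–3 SE.
Velocity equality at the I-VT threshold counts as fixation; BF exponents
are clipped at ±700 before exponentiation; χ² is floored at 0 against
round-off; empty event lists, all-invalid recordings, < 3 QC pairs and
zero-qualifying-saccade summaries all return flagged/empty results rather
than raising.

## Known limitations

Monocular (or eye-averaged) gaze only; no I-DT or adaptive thresholds; no
glissade or corrective-saccade handling; AOIs are abstract rectangles; the
latency model is stationary within a session (no fatigue or learning); the
Bayes factor is the BIC approximation, not a posterior model comparison;
and group means from real cohorts are not reproducible from synthetic data
— only the method's operating characteristics are.
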