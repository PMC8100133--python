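# Methods

## Arterial-wall impedance estimation

The vessel wall is modelled as a Voigt element: a spring (stiffness K,
mmHg per PPG a.u.) and a damper (viscosity B, mmHg·s per PPG a.u.) in
parallel across the vessel diameter, driven by intraluminal pressure
and observed through the fingertip photoplethysmogram. Within one
heartbeat, with Pb the ABP wave height, Pl the PPG wave height and all
series re-zeroed at the beat onset t₀,

    dPb(t) = K·dPl(t) + B·dṖl(t).

Beats are delimited by ECG R waves (annotations take precedence over
detection; detection is a half-maximum peak picker with a 200 ms
refractory period, sufficient for impulse-marker or QRS-dominated
ECGs). Beat windows are half-open [Rᵢ, Rᵢ₊₁): the sample at Rᵢ₊₁ opens
the next beat, so windows tile the record exactly. t₀ is the R time
opening the beat — the only per-beat landmark the protocol defines.

Ṗl is computed per beat by second-order central differences at the
native sampling rate (one-sided second-order stencils at the window
edges); computing it per window rather than over the whole record keeps
beat-boundary discontinuities out of the difference series. Because
Eqs. above zero all three series at t₀, the regression is constrained
through the origin: (K, B) minimise Σ(dPb − K·dPl − B·dṖl)² with no
intercept, and r² = 1 − SSE/Σ dPb² (the no-intercept convention, which
can be negative). Rank-deficient designs (flat PPG, collinear
regressors) yield an invalid estimate with a reason code, never an
exception.

Quality control retains a beat iff r² ≥ 0.95 and K > 0 and B > 0.
Removed beats leave gaps in the K trace (no interpolation); windowed
statistics downstream simply use the remaining beats.

Per-beat features: hr = 60/RR (beats/min), sbp = max ABP in the window
(mmHg), ppg_amp = PPG peak-to-peak excursion in the window (a.u.).

## Evoked responses and the MEC

For a stimulus at time s and each parameter p ∈ {K, HR, BP, PPG}:
pre = median of p over beats in [s − 10 s, s); post = max over
(s, s + 20 s] for K/HR/BP and min for PPG amplitude, whose response
direction is downward (vasoconstriction). The direction-adjusted
percent change is 100·(post/pre − 1), or 100·(1 − post/pre) for PPG, so
a single 5% threshold applies to all four parameters.

The MEC rule is stated once: let c* be the largest current on the
10–80 mA ladder with change ≤ 5%. MEC = c* + 10 mA if c* < 80 mA;
out of range if c* = 80 mA; 10 mA if every rung exceeded 5%. This
subsumes noise rejection — an early supra-threshold rung followed by a
sub-threshold one is discarded automatically — and the sequential-scan
reading of the protocol (candidate at first crossing, reset on any
later sub-threshold rung) is kept in the test suite as an independent
oracle, verified equivalent on all 2⁸ sub/supra patterns. "More than
5%" is read strictly: a change of exactly 5.0% does not trigger.

K_R80 = 100·(post/pre) of K at the 80 mA rung (ratio scale, 100% = no
change), whereas ROC_BP = 100·(post/pre − 1) — percent excess — with
pre-BP the median systolic pressure of the 10 s before skin incision
and post-BP the maximum between incision and the start of
electrocautery. The two conventions differ deliberately: K_R80 is
reported as a raw ratio percentage while ROC_BP can be negative.

## Cohort statistics

Regression of ROC_BP on MEC (or K_R80) uses only subjects where both
are measurable. Outlier treatment is iterative: fit by OLS,
Grubbs-test the raw residuals (two-sided, α = 0.05), remove the single
flagged pair, refit; stop when nothing is flagged or removal would
leave fewer than 3 pairs. The Grubbs statistic is G = max|r − r̄|/s
(sample SD) with critical value ((n−1)/√n)·√(t²/(n−2+t²)), t the upper
α/(2n) t-quantile at n−2 df; the implementation reproduces the
published two-sided 5% table (1.715 at n = 5, 2.290 at n = 10, 2.709 at
n = 20). Pearson p-values across the four MEC parameters are
Bonferroni-corrected by multiply-and-cap with m = 4.

Out-of-range subjects re-enter prediction with a provisional MEC
obtained by inverting the final line at the mean ROC_BP of the
out-of-range group; subjects removed as outliers still receive
predictions. Bland–Altman agreement uses differences d = measured −
predicted: fixed bias = mean(d), limits of agreement = bias ±
1.96·SD(d) (sample SD), proportional bias = Pearson test of d against
the pairwise means (reported as not applicable when either side is
constant). On a cohort with no removed outliers the fixed bias is
exactly zero — residuals of an OLS fit with intercept sum to zero, and
each out-of-range subject's prediction equals the group mean — so any
nonzero bias traces to the outlier-removal step.

The power analysis uses the Fisher-z approximation
n = ((z₁₋α/2 + z₁₋β)/arctanh r)², rounded to the nearest integer,
giving n = 26 at r = 0.5, α = 0.05, power = 0.8. The small-sample
"+3" variant (n = 29) is deliberately not used; only the plain form
reproduces the protocol's stated sample size.

## Synthetic-physiology generator

The generator is the measurement model run forward, so every pipeline
stage has an exact oracle.

**Pulse and PPG.** ABP per beat is diastolic baseline + pulse pressure
× a smooth template: raised-cosine systolic upstroke (0.12 s) followed
by exponential diastolic decay (τ = 0.25 s). The PPG channel solves
the wall ODE dṖl = (dPb − K·dPl)/B per beat via the exact
integrating-factor kernel evaluated by trapezoidal quadrature on an
8× oversampled grid, then decimated to the 250 samples/s monitor rate.
The record therefore satisfies the impedance relation at the scheduled
per-beat (K, B) up to quadrature error. The refit residual is floored
not by the generator but by the estimator's central-difference
derivative, at ≈5×10⁻⁴ of pulse pressure at 250 samples/s; parameter
recovery is correspondingly ≈0.2% for both K and B (the tests assert
< 1%). The ECG channel carries unit impulses at the R times, which are
also annotated on the record.

**Evoked-response dynamics.** Each rung at current c evokes a
fractional response r(t): triangular rise to its peak 10 s
post-stimulus (matching the observed 9.8–10.0 s peak latencies) and
linear return to baseline by 30 s, before the next pre-stimulus window
opens (inter-stimulus interval ≥ 40 s, protocol minimum 30 s). Peak
magnitude is gain·(c − threshold + 10 mA) percent at or above the
subject's sympathetic threshold (default gain 1.2%/mA, so the
threshold rung itself already moves 12% ≫ 5%) and a 2% perturbation
below it, comfortably under the 5% detection threshold even after beat
quantisation. Scheduled per beat: K and B scale by (1 + r) — viscosity
co-varies with stiffness under vasoconstriction, which by linearity of
the wall ODE makes the PPG amplitude scale exactly by 1/(1 + r), i.e.
the PPG response is the exact reciprocal of the K response and all
four thresholds are identifiable end-to-end. Systolic BP responds via
a diastolic baseline shift at constant pulse pressure; a within-beat
constant offset cancels in the difference series, so the BP response
leaves the impedance fit untouched. Heart rate defaults to a
sub-threshold gain (its MEC is then out of range, as clinically
observed for HR); pass an explicit `hr_response_gain` to make it
respond.

**Incision segment.** Systolic pressure steps to baseline × (1 +
ROC_BP/100) for the whole incision-to-cautery interval and back after.
A step (rather than a ramp) makes the programmed ratio exact for
negative as well as positive ROC_BP, since the post-window statistic is
a maximum.

**Cohorts.** Measurable subjects draw MEC_K uniformly on the 10–80 mA
ladder and ROC_BP = −0.28·MEC_K + 31.26 + N(0, 5²) percent by default
(the scale of the clinical regression); an out-of-range fraction
(default 10%, i.e. 3 of 30) gets low ROC_BP centred on 0.7%. The other
MEC columns are jittered copies of MEC_K with realistic out-of-range
rates (HR mostly unmeasurable); K_R80 is the linear inverse of the
K_R80→ROC_BP relation plus noise. All generators are pure functions
of their arguments and the seed.

**What the generator does not emulate:** real pulse morphology
(dicrotic notch, respiratory modulation), arrhythmia, measurement
drift, probe artefacts, baroreflex coupling between the channels, or
pharmacokinetics of the opioid itself. Passing round trips therefore
demonstrate correctness of the estimators under the stated model, not
robustness to clinical signal pathology.

## Problem sizes and numerical choices

Default simulations: 250 samples/s, 70 beats/min, 320 s stimulation
sessions (8 rungs, 40 s apart), 90 s records for the 100-beat recovery
suite, 200 replicate cohorts of n = 30 for the regression recovery
study. Tolerances: 1% relative error for noiseless (K, B) recovery;
0.5% absolute for the incision ROC_BP round trip (beat quantisation);
exact equality for MEC recovery at zero noise. Ties in the Grubbs
argmax resolve to the first index (numpy argmax); degenerate inputs
(flat channels, zero residual variance, constant Bland–Altman means)
return flagged results or not-applicable fields rather than raising
where the contract allows.

## Known limitations

The clinical headline numbers (r = −0.723 for MEC_K vs ROC_BP, fixed
bias −0.17%, the 27/8/21/25 measurable-MEC counts) depend on the
30-patient dataset, which was never released; they are not
reproducible and are not asserted anywhere. The provisional-MEC value
computed from the published rounded coefficients is 109.1 mA (the
original analysis, presumably using unrounded coefficients, printed
107 mA); this package exposes full-precision coefficients so either
pathway is available. PPG is in arbitrary units, so K is
record-relative: rescaling the PPG channel by c rescales K and B by
1/c (a tested covariance), and absolute K values are not comparable
across devices.
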