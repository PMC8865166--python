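# Methods

This note documents the models, numerical choices and known limitations of
`drivestress`: a pipeline for event-locked cardiac and speed analysis of
simulated driving sessions, together with the synthetic-session generator
used to validate it.

## The measurement model

A session is two ~2-minute trips on the same route. Trip 1 is the control
pass; Trip 2 carries three hazard conditions at fixed route positions:

| condition | cue | event | post-window end |
|---|---|---|---|
| U (unpredictable) | invisible (marker only), 2.0 s | deer-type event, 1.83 s | 4.5 s |
| P (predictable) | visible alert, 4.41 s | oncoming-car-type event, 3.01 s | 4.5 s |
| PF (predictable + familiar) | visible sign, 7.24 s | merging-traffic event, 3.73 s | 7.5 s |

The PF cue and event also run in Trip 1 — that first exposure is what makes
the Trip-2 pass "familiar" — and its Trip-1 response is injected at 60%
amplitude by default, so the "control" PF pass itself carries a (weaker)
anticipatory pattern. Cue→event gaps default to 5 s (U, P) and 8 s (PF) so
the post-cue analysis window closes before the event begins; the gap is a
free parameter because study descriptions of this design constrain it only
loosely. Perceived stress is rated 1–5 per condition for U and P only (PF
has no matched safe condition to rate against).

## Synthetic cardiac signal

**Beat trains.** R-peak times follow an instantaneous-rate model:
`rate(t) = baseline + ecr(t) + rsa(t) + noise`, with the evoked cardiac
response `ecr` a sum of event-locked templates, `rsa` a single sinusoid
(0.25 Hz, random phase per trip — breathing is not locked to the route) and
`noise` drawn once per beat on the bpm scale. Each RR interval solves the
implicit inversion `RRI = 60 / rate(t + RRI)` (a 4-step fixed point,
clamped to 0.3–2.0 s). Evaluating the rate at the interval's *closing* time
rather than its opening time matters: it makes the derived instantaneous
heart rate `HR_n = 60/RRI_n`, attributed to beat n, equal the target rate
at that beat exactly (verified to 3·10⁻⁴ bpm), so injected templates are
recoverable without a one-interval lag. The scheme is exact for constant
rates (60 bpm ⇒ beats at 0, 1, 2, … s).

**ECR templates.** A template is two compactly supported raised-cosine
lobes: a deceleration (ECR1, amplitude ≤ 0 bpm) and a later acceleration
(ECR2, ≥ 0 bpm). It is continuous, identically zero for t ≤ 0 (enforced by
requiring the decel peak time ≥ the lobe width) and vanishes after the
acceleration lobe. Defaults: P post-cue −5 bpm @ 1 s / +6 bpm @ 3 s (lobe
width 1 s); PF post-cue −5 @ 2 s / +6 @ 4.5 s (width 1.5 s); all post-event
responses are acceleration-only (+8 bpm @ 3 s), scaled ×1.5 for
high-perceived-stress and ×0.5 for low-perceived-stress drivers so the
stress-group contrast on post-event AUC is a real generated effect. U gets
no post-cue template (nothing to anticipate).

**ECG rendering.** Each beat is a fixed sum of Gaussian P/Q/R/S/T bumps
(R amplitude 1, at least 3× every other wave) with the R apex on the sample
nearest the beat time, at 500 Hz, plus broadband Gaussian noise (default
3% of R). Participants flagged as bad-ECG exclusions get R-like spikes
injected mid-interval in ~35% of intervals, so the exclusion is *earned*
downstream by the artifact-correction stage rather than read off a label.

**Speed.** 10 Hz, constant base speed (90 km/h ± per-driver jitter) with an
event-locked deceleration (lag 0.5 s, −30 km/h over 2 s, 2 s hold, 6 s
recovery) plus white noise (0.5 km/h).

**Noise calibration.** Beat-to-beat noise SD (1.8 bpm) and RSA amplitude
(1.2 bpm) were calibrated so that a simulated 27-driver cohort's post-cue
quadratic-trend statistic matches the magnitude reported for cued hazards
in the driving-simulator literature this design emulates (|t| ≈ 4.8 at
n = 27); with these values the simulated effect-to-noise ratio of the
anticipation signature matches the published scale rather than drowning it.

**Cohorts and reproducibility.** One global seed fans out to
per-participant substreams (`default_rng([seed, participant_index])`), so a
cohort is reproducible participant-by-participant and byte-identical on
disk across runs. Per-driver jitter: baseline HR ~ N(70, 7²) clipped to
50–95 bpm, base speed ~ N(90, 8²). Exclusion flags (motion-sickness n=5,
bad-ECG n=2 of 34 by default) and exact high/low stress-group counts among
the non-excluded drivers (11/16 by default) are assigned at the cohort
level.

## Preprocessing choices

- **Filter.** 4th-order Butterworth, 2–40 Hz, applied forward–backward:
  the zero-phase pass preserves R-peak timing (an IIR single pass would
  shift it). Cutoffs must satisfy high < Nyquist, enforced with fs in the
  message.
- **Detector.** Derivative → squaring → 150 ms moving-window integration →
  adaptive threshold (a candidate must clear 30% of a running level that
  tracks accepted integrated peaks with weight 0.125) → 250 ms refractory
  (caps detectable HR at 240 bpm, beyond any plausible driver) → apex
  refinement to the local filtered-signal maximum within ±50 ms. A flat
  signal yields an empty result with a warning, not an exception. The first
  beat of a record, whose QRS template is truncated by the recording edge,
  can be missed or mistimed; epochs never use the first seconds of a trip.
- **Artifact correction.** Intervals > 1.8× the local median (9-interval
  window) are treated as missed beats and filled by evenly spaced
  insertion; intervals < 0.4× the local median are false triggers and the
  weaker apex is removed. More than 20% edited intervals flags the record
  `bad_ecg`, mirroring exclusion for unusable recordings. Thresholds are
  deliberately conservative and exposed as arguments.
- **HR attribution.** `HR_n = 60/RRI_n` is placed at the interval's
  *closing* beat (the interval is only known once its second beat occurs).
  The identity `hr · rri = 60` holds to 10⁻⁹.
- **Resampling.** Natural cubic spline through (beat time, HR) knots,
  evaluated every 0.5 s; no extrapolation beyond the knot support, ever —
  a grid outside it is an error, and an epoch whose window is not covered
  is dropped (complete-case) and logged, never imputed.

## Epoching and summaries

The baseline is the single interpolated sample 0.5 s before onset (not a
mean over [−0.5, 0)), consistent with defining HR(t₀) as the value at the
window's start; every epoch therefore has change ≡ 0 at −0.5 s exactly,
and adding a constant to a series changes nothing downstream (shift
invariance). Post-window ends follow from the factor levels (10 ⇒ 4.5 s,
16 ⇒ 7.5 s). Speed is linearly interpolated — at 10 Hz the trace is already
dense relative to the 0.5 s grid and a spline would add nothing. AUC is the
signed trapezoid over 0…end, excluding the forced-zero baseline point so it
does not dilute the summary. The U condition's invisible cue still has a
positional marker, and its epochs are built identically. The 2.5-of-5
median split assigns strictly-greater ratings to the high group, per
condition.

## Statistics

The 2 × k fully within-subject ANOVA uses the complete sums-of-squares
decomposition with each effect tested against its own subject-interaction
error term; partial η² = SS_effect / (SS_effect + SS_error). Sphericity is
assessed per within effect on the appropriately collapsed per-subject data
(mean over condition types for the time effect; their difference for the
interaction): Mauchly's W via orthonormal contrasts with the standard
second-order chi-square approximation, and Greenhouse–Geisser
ε = tr(CSC′)² / ((k−1)·tr((CSC′)²)), clipped to [1/(k−1), 1]. Corrected and
uncorrected p-values are both always stored; the reported p switches to the
GG-corrected one when Mauchly's p < .05. Huynh–Feldt is deliberately not
implemented. All tests are two-sided at α = .05; the Bonferroni family is
the set of time points within one condition/window/channel (matching how
such studies annotate per-figure significance), with no correction across
conditions or windows. Polynomial contrast weights are built by
Gram–Schmidt on {t, t², t³} over the post-baseline grid only (the baseline
point is identically zero and would distort orthogonality); each weight
vector sums to zero, has unit norm and a positive leading coefficient, so a
positive quadratic score means a U-shaped time course. Cohen's d for paired
comparisons uses the difference-score SD (so t = d·√n); degenerate
zero-variance differences are reported explicitly (d = 0, p = 1 when the
difference is identically zero; d = ±∞, p = 0 otherwise) rather than as
NaN. Everything is cross-checked in the test suite against explicit
brute-force recomputations and, where available, against pingouin.

Measured calibration (recomputed by `scripts/acceptance.py`): the
GG-corrected interaction test on 1000 null simulated cohorts (n = 27,
2 × 10) rejects at ≈ 4% — slightly conservative, as expected for the GG
correction under the strong temporal autocorrelation that spline-resampled
heart rate carries.

## Problem sizes and the fast simulation path

Trips default to 120 s rather than a full 10-minute drive: the analysis
consumes only ±8 s around six markers per trip, and the shorter route keeps
a 34-participant full-ECG cohort (render → filter → detect → correct →
epoch → infer) under half a minute. Monte-Carlo studies (type-I error over
1000 cohorts, template recovery at n = 200, contrast power over 100
cohorts) use the simulator's beat-level path — the same beat trains,
spline and epoching, skipping only ECG rendering and re-detection, which
the end-to-end tests cover separately (detector sensitivity and positive
predictivity ≥ 99% at ±50 ms under 10%-of-R broadband noise, and RMSE < 1
bpm between detected and generated instantaneous HR).

## Known limitations

- **Pointwise template recovery is biased by beat sampling.** HR is only
  observed at beats (~0.86 s apart at 70 bpm); a cubic spline through those
  knots smooths the 1 s-wide template lobes by up to ~0.9 bpm near the
  peaks. This bias does not shrink with the number of participants, so the
  grand-mean recovered curve tracks the injected template to correlation
  ≈ 0.98 but its pointwise error is not within pure Monte-Carlo error at
  n = 200 — a 3-SE band test on it fails, and honestly so. Any analysis of
  real beat-sampled data inherits the same resolution limit.
- The simulator is not a physiological model: single-lead caricature ECG,
  one sinusoidal RSA component (never removed in analysis — respiration
  removal is out of scope), no arrhythmias, no driving dynamics beyond a
  deterministic speed profile. Passing tests demonstrate the *analysis
  chain* is correct and calibrated, not that it has been validated against
  real driver recordings.
- Control passes precede experimental passes by design (as in the emulated
  protocol), so learning/acclimatization confounds are not modeled.
- The stress-group gain on post-event responses is a simulator construct
  to make group comparisons testable; its magnitude (×1.5 / ×0.5) is not
  empirically derived.
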