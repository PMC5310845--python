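# Methods

This note records the model as implemented, the parameter conventions,
the numerical choices, and the places where the design was genuinely
open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Vocal-fold model and integration

The fold oscillator is the cubic normal form

    ẋ = y,   ẏ = −αγ² − βγ²x + γ²x² − γxy − γ²x³ − γx²y,

integrated with fixed-step forward Euler. Internal time is in
milliseconds so that γ = 45 /ms and dt = 0.005 ms (5 μs) are used
directly; audio export converts to seconds. The default initial state is
(x, y) = (0.01, 0): a small perturbation off the α = 0 equilibrium that
reaches the attractor quickly. Integration aborts with `BlowupError` when
|x| > 10³ (forward-Euler instability guard). Simulations are 1 s by
default, and the first 100 ms are discarded from every amplitude,
frequency, and gain measurement as limit-cycle transient.

Fixed points are the real roots of x³ − x² + βx + α (Newton-polished to
|residual| < 1e−9, deduplicated at 1e−6); the Jacobian at (x*, 0) has
trace −γx*(1+x*) and determinant γ²(3x*² − 2x* + β). Saddle-node curves
are the zero set of the cubic discriminant
−18αβ + 4α + β² − 4β³ − 27α², traced as the two α-branches of its
quadratic-in-α form; Hopf branches are α = 0 (β > 0, the fixed point
x* = 0) and α = β + 2 (x* = −1). The Takens–Bogdanov point — zero trace
*and* zero determinant at the same fixed point — is the origin, which is
also where the θ diagonal starts; θ is implemented as α = β = θ on
[0, 1.1] with no additional offset. Region classification is analytic
(fixed-point count and eigenvalues), with a short simulation only to
separate regions II and III (presence of the small stable cycle around
the source) and for ambiguous sink cases; points within discriminant
tolerance 1e−8 of a bifurcation curve are flagged `boundary` and given
the larger adjacent region's label.

**A property of the integrator worth knowing.** Forward Euler adds
numerical negative damping: a spiral sink with decay rate |Re λ| below
≈ dt·ω²/2 (≈ 2–4 /ms at dt = 5 μs for this system) is integrated as a
sustained oscillation. This creates an artifact band of width ≈ 0.05 in
α just left of the Hopf curve where simulations oscillate although the
true dynamics is a damped spiral. The calling region and the gain
landscape are unaffected (the band lies at α < 0, outside the synthesis
range), but any simulation-based attractor oracle must either refine the
step (the tests use dt = 0.2 μs, which shrinks the band inside their
0.01 boundary buffer) or use an adaptive integrator (RK45 spot checks).

## Tract filter

The tract is a uniform cylinder parameterised by the one-way travel time
`half_T` (default 50 μs; `L = c_sound · half_T` gives 17.5 mm at
c_sound = 350 m/s). The implemented recursion is

    P_in(t) = c·x(t) − r·P_in(t − half_T),
    P_sound(t) = (1 − r)·P_in(t − half_T),

with r = 0.8, c = 1, delays in whole samples (half_T/dt must be an
integer; `TractParams.from_length` refines dt to satisfy this), and the
delay line initialised empty (pure source term for the first delay
worth of samples, zero-padded output head). With a one-way delay the
frequency response (1−r)/|1 + r·e^{−iω·half_T}| peaks at odd multiples
of f0 = 1/(2·half_T) = 10 kHz, which is both the closed-closed tube
fundamental c_sound/2L and the frequency band where the model's gains
are highest; a round-trip delay instead would put the response maxima at
5, 15, 25 kHz, inconsistent with that resonance structure, which is why
the one-way form is used. The optional cubic source term of the
third-order tract approximation is exposed (`c3`) but off by default.

Gain is `g = max|P_sound| / max|P_glottal|` over the post-transient
window; it errors on silent input.

## Call classification

A simulated call is `none` unless the post-transient displacement is a
sustained oscillation (peak-to-peak > 1e−3 and last-quarter amplitude
≥ 0.9 × second-quarter amplitude — the non-decay rule). Cries are
detected from the amplitude modulation of the emitted sound: the Hilbert
envelope, lowpassed at 4 kHz, must have modulation depth (std/mean)
above 0.1. This criterion replaces a spectral peak-to-median rule that
is degenerate in practice (the median of a near-line envelope spectrum
is numerically ~0, so the ratio is astronomically large for every call);
the modulation threshold separates the cry and phee anchor parameter
pairs — (0.09364, 0.088) and (0.151, 0.895) — by two orders of
magnitude and is exposed in `ClassifierConfig`. Voiced, unmodulated
calls are `phee` if the first (lowest-frequency) peak of the call power
spectrum is also its largest, else `subharmonic_phee`; peaks are local
maxima above 1% of the global maximum separated by ≥ 200 Hz.

The θ grid default is 221 points (step 0.005), fine enough to resolve
the narrow cry band just above the saddle-node onset near θ ≈ 0.09.

## Landscape, softmax, development

Costs: C = −log g (+λθ), with +∞ on unvoiced cells. Probabilities use a
right Riemann sum in which every grid point is the right endpoint of a
cell of width h, so densities satisfy h·Σp = 1 and region probabilities
are h·Σ over labelled cells; unvoiced cells carry zero mass. η defaults:
300 for the full-concentration landscape analysis, 5 for fitting daily
λ to ratio curves (at large η the λ→ratio map is a near-step and the
inverse problem is ill-conditioned).

λ_z is found by bisection of the monotone λ → ratio map on [0, λ0] to
|ratio| < 1e−6. Daily λ fitting clamps targets outside the attainable
ratio range to the nearest endpoint with a warning. λ_t = λ0 − (κF+δ)t
is clipped at 0 (negative muscular cost is meaningless) with a warning.
(κ, δ) are fitted to (F, z0) pairs by bounded nonlinear least squares on
z0 = (λ0−λ_z)/(κF+δ), started from the exact linearisation
(λ0−λ_z)/z0 = κF + δ; all-zero F makes κ structurally unidentifiable
and is reported as such.

The diffusion uses drift **−∂C/∂θ** and noise scale √(2/η), so its
stationary law is the softmax density exp(−ηC)/Z. (A gradient-ascent
drift would concentrate the walk on cost *maxima*, contradicting that
equilibrium, so the descent sign is the implemented one.) Gradients are
central differences (one-sided at edges); the walk reflects at the
edges of the contiguous finite-cost support; a step size that throws
more than half the moves out of the domain raises.

## Synthetic cohort

`CohortConfig` encodes the study conditions: 10 infants, days 0–60, one
5-minute undirected session per day with Poisson(300) calls
(≈ 1 call/s), λ0 = 3, κ = 0.2126 /day, δ = 0.0654 /day, per-infant F ~
Uniform(0.05, 0.3), and a tract whose one-way delay grows in three
stages 40 → 45 → 50 μs (the values used for the landscape-shift
analyses; piecewise-constant because the sampled delay must be a whole
number of 5-μs samples). Call types are drawn multinomially from the
day's softmax probabilities; dominant frequencies are the day's
resonance f0 plus Gaussian noise (σ = 0.2 kHz); parental contingent
responses are Bernoulli(F) per phee with Uniform(0, 5) s latency;
weights grow at 1 g/day from 30 g with σ = 0.5 g, measured every 3
days. Everything derives from a master seed via spawned per-infant
seeds, and per-infant truth records (λ(t), F, per-day probabilities,
stage λ_z, predicted z0) close the loop for recovery tests.

The generation-side concentration defaults to η = 5, not 300: at
η = 300 the subharmonic trough holds essentially all probability mass
through mid-development, so phees and cries are unobservably rare in
finite sessions and the empirical ratio curve cannot express the
transition it exists to measure. At η = 5 all three call types stay
observable and the empirical crossing tracks the predicted
(λ0 − λ_z)/(κF + δ) to within ~1 day. Because the tract delay changes
in stages and λ_z is stage-specific, the predicted crossing walks the
stages in order: it is either interior to a stage (λ_t hits that
stage's λ_z) or pinned to a stage boundary.

What the generator does *not* emulate: twitter/trill call types and the
phee-cry intermediate (excluded from ratio counts by convention),
session-to-session rate trends, parental call content beyond onset
times, vocal-fold growth (frequency changes come from the tract only),
and any deviation from the model's own softmax statistics. Passing
recovery tests therefore demonstrates internal consistency of the
pipeline, not correctness of the model for real recordings.

Audio fixtures place model-synthesized anchor calls (cry and phee) at
scheduled onsets over 1/f-spectrum pink noise at a configurable SNR
(default 20 dB), resampled to 96 kHz.

## Acoustic measurement

Detection: bandpass 6–10 kHz (4th-order Butterworth, zero-phase), then
|Hilbert| at the full rate, then decimation of the envelope to 1 kHz,
then a 50 Hz lowpass; the threshold is the 99th percentile of the
envelope over a caller-supplied silent baseline segment, and
supra-threshold runs shorter than 20 ms are discarded (click
suppression standing in for the study's manual verification step).
Taking the envelope *before* decimation is a deliberate reordering: the
nominal sequence (resample the 6–10 kHz band to 1 kHz, then Hilbert)
destroys the signal, since anti-alias filtering at 500 Hz removes the
entire band. Dominant frequency is the frame-averaged argmax-power
spectrogram frequency (1024-sample Hann, 50% overlap). Whole calls are
greedy merges of same-type syllables with gaps strictly under 500 ms; a
type change always breaks. A parental response is contingent when its
onset falls within 5 s after an infant call's offset with no other call
onset in between; F is the contingent fraction of phees in the supplied
period.

## Developmental statistics

Smoothing splines use the penalised-least-squares family with parameter
s ∈ [0, 1] (1 = interpolation, 0 = the least-squares line, internally
λ = (1−s)/s for scipy's `make_smoothing_spline`); s = None selects λ by
generalised cross-validation. Duplicate abscissae are aggregated to
weighted means; exactly four distinct sites fall back to the natural
cubic interpolant (the penalised solver needs five). The zero-crossing
day is the first negative-to-positive crossing, located by a 0.01-day
scan plus bisection.

Tract lengths are estimated by measuring the model resonance for each
grid length from the filter's impulse response (dt refined to ≈ 1 μs),
cubic-splining the L↔f0 map, smoothing-splining the
dominant-frequency-vs-day data, inverting day by day, and bootstrapping
over sessions (1000 resamples, percentile 95% band). Note the length
convention L = c_sound·T/2 applied to the reference 50 μs delay gives
17.5 mm, while the estimation grid spans 7.9–10 mm; the two scales
coexist in the source material and are deliberately not reconciled —
everything is parameterised by the travel time, and the L-grid is
mapped through the same L↔T relation. Percentile bootstrap bands
around smoothing splines undercover somewhat (the smoothing bias is not
resampled); the test suite pins the measured coverage (~87% for a
nominal 95% band at σ = 0.2 kHz).

The feedback regression is ordinary least squares of F on (W, N) with
intercept and classical two-sided t-tests, plus plain Pearson
correlations of F with each predictor. Correlation-test power is
computed from the exact (hypergeometric-function) sampling density of
the Pearson correlation under a bivariate normal, integrated beyond the
two-sided critical value r_c = t_c/√(n−2+t_c²); a vectorised Monte
Carlo route is provided as a cross-check and agrees to a few parts in a
thousand at 10⁶ replicates.

## Problem sizes used by tests and the acceptance script

The acceptance script synthesizes the full 221-point, 1-s landscape.
Unit tests share session-scoped fixtures: the same full landscape once
per run, plus a reduced configuration (111 θ points, 0.4-s calls,
3 infants) whose landscape structure is identical at coarser
resolution. The diffusion equilibrium check runs 3×10⁷ steps at
dt = 5×10⁻⁴ with every 10th position recorded; the region-agreement
sample uses 200 points at the fine-step oracle. These sizes were chosen
so the whole suite completes in a few minutes while keeping every
statistical margin comfortable.

## Known limitations

* The normal form is a local reduction; α, β outside [0, 1.1] are
  analysed dynamically but never synthesized.
* The classifier is calibrated on the two anchor morphologies; its
  thresholds are config, not biology.
* The subharmonic-mass concentration at η = 300 (see above) means the
  full-concentration model's crossing is a statement about two
  vanishing probabilities; it is exactly computable but not observable
  from finite counts.
* Euler integration at the reference step is faithful to the original
  scheme, including its spurious-oscillation band at weakly damped
  sinks (documented above).
* Real-recording behaviour of the detection front-end (e.g. cry energy
  below the 6–10 kHz band) is untested by construction: all fixtures
  are model-generated.
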