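# Methods

## Problem setting

A prosthetic-hand controller driven by two piezoelectric (PVDF) tactile
sensors must map forearm-surface deformation transients to one of six
trained wrist–hand motions (grasp, open, pronation, supination, palmar
flexion, dorsiflexion) — and, critically, must *withhold* its output when
the input is an ambiguous execution of a trained motion, an untrained
wrist deviation (radial/ulnar flexion), or an unrelated body movement
(elbow flexion).  The package implements the classification pipeline,
three reject-option mechanisms, and the session-wise evaluation framework,
together with a simulator that stands in for the unavailable human
recordings.

## Signal model of the simulator

Each motion is a deterministic two-channel template: a biphasic damped
sinusoid `A · exp(−λ t) · sin(2π f t)` per channel, delayed by a
channel-specific onset latency and truncated at the template duration.
This family reproduces the qualitative character of averaged PVDF
waveforms — transient biphasic deflections whose amplitude and polarity
differ between the flexor- and extensor-side channels.  Class signatures
are fixed so that flexion-dominant motions load the FCR channel,
extension-dominant motions the ECRL channel, pro-/supination produce
opposite-polarity pairs, the two unknown motions sit *between* trained
signatures (making them plausibly confusable), and elbow flexion is a
slower (2 Hz, λ = 2 s⁻¹, 1.5 s) both-channel deflection.

A session is: `rest_duration` (default 10 s) of motion-free baseline, then
one cued trial every `cue_interval` (2 s) in seeded randomized interleaved
order, `trials_per_motion` (50) trials per listed motion.  The recorded
signal is the sum of the trial templates plus

- white Gaussian sensor noise, `noise_sd` = 0.1 V,
- slow drift: one sinusoid per channel with frequency drawn from
  [0.05, 0.3) Hz, amplitude 0.1 V,
- power-line interference: 50 Hz sinusoid, amplitude 0.05 V,

clipped to the ±5 V acquisition range (never active under defaults).

**Parameter rationale (chosen once, a priori).**  Template peak amplitudes
(0.5–2.5 V) sit comfortably inside the ±5 V range as a gain-adjusted
charge amplifier would place them.  `noise_sd` = 0.1 V makes the
within-class scatter of the 40-dimensional feature a modest fraction of
the 1–2.5 V between-class template separation — mirroring real averaged
waveforms whose across-trial standard-deviation bands are visible but do
not swamp the class structure.  `ambiguous_fraction` = 0.15 of target
trials reflects the mid-80s% baseline accuracy regime reported for this
kind of data.  The default ambiguity mode is `blend` (convex mix of two
target templates, weight in [0.35, 0.65]); `attenuate` (scale by
[0.2, 0.5]) models weak executions.  None of these values were revisited
after observing test outcomes.

**What the generator does not emulate** — and hence what a green test does
not establish: biomechanical coupling between motions, electrode/sensor
placement drift, perspiration and fatigue effects, heavy-tailed artifact
noise, and trial-to-trial waveform variability beyond additive noise and
the explicit ambiguity mechanisms.  Synthetic unknown motions are
*geometrically* intermediate templates; real untrained motions can be far
more heterogeneous, so absolute unknown-rejection rates here do not
predict human-data rates (they are indeed lower for OCSVM than observed
on humans, whose unknown motions lie further off the trained manifold).

## Preprocessing

Filters are designed by bilinear transform at 1000 Hz (first-order
Butterworth high-pass at 0.5 Hz; `iirnotch` 50 Hz, Q = 25) and applied
causally (`lfilter`, forward only) to emulate the real-time system; no
zero-phase filtering.  Downsampling to 100 Hz averages blocks of 10,
truncating a trailing partial block.

Detection operates on the 100 Hz series (the window index n_d of the
feature construction indexes the 100 Hz series; applying the threshold
rule at 1000 Hz would be the other defensible reading).  The threshold
rule — unspecified in the source protocol beyond "determined from resting
segments" — is the conventional amplitude rule θ_i = mean(|x_i|) +
k·sd(|x_i|) with k = 5 (configurable); an identically zero resting channel
receives a floor of 10⁻⁶ V so θ_i > 0 always.  After a detection, further
crossings are suppressed for a 1 s refractory window (motions complete
within ~1 s; cues are 2 s apart).  Detections too close to the series
edges for a full 20-sample window are discarded.  Detected events are
matched to the annotation whose cue window contains them; annotated trials
with no detection are logged and skipped (≥ 95% recall under default
noise is enforced by test).

No amplitude normalization precedes classification; the raw voltage
window is the feature, as in the real-time system this emulates.

## Models

The OvR SVM is six explicit binary RBF machines (class vs rest, C = 16,
γ = 0.0625, sklearn `SVC`), *not* sklearn's OvO-derived "ovr" decision
shape, so the decision values f_k(z) are genuine one-vs-rest outputs whose
signs carry meaning.  Raw solver decision values are used (only signs and
the argmax matter); argmax ties resolve to the lowest class index, classes
ordered alphabetically.

The one-class SVM uses ν = 0.1 and the scale heuristic
γ = 1/(d·Var(Z)) with Var over the flattened training matrix (d = 40).

The BPNN is a hand-written numpy 40–25–6 network (tanh hidden, softmax
output) trained full-batch for exactly 1000 epochs with Adam (β₁ = 0.9,
β₂ = 0.999, ε = 10⁻⁸, α = 10⁻³), no early stopping.  The initial weights
*and biases* are drawn from U[0, 1) — asymmetric, but implemented
literally as specified for the reference configuration; a conventional
symmetric initialisation is available via `BpnnConfig(init="symmetric")`.
In practice Adam's per-parameter step normalisation escapes the initial
tanh saturation within a few hundred epochs on this problem size.

Training partitions: stratified 50/50 per target class (configurable
fraction, seeded); unknown and non-target trials are never eligible for
training and are routed to the test side unconditionally.  All three
models share one identical partition.

## Rejection rules and numerical choices

- Entropy uses the natural log (τ = 0.7 is then a meaningful fraction of
  the 6-class maximum ln 6 ≈ 1.79); the base is configurable.  A
  probability vector must sum to 1 within 10⁻⁶; zero components contribute
  0 by convention.
- The OCSVM gate and the sign-consistency rule both use strict
  inequalities: Δ = 0 rejects, f_k = 0 counts as non-positive.
- `decide_ovr_ro(f)` takes the decision values and nothing else — the
  parameter-free property is part of its signature.
- Undefined ratios (accuracy with zero accepted trials, precision with
  zero rejections, rates of empty categories) propagate as NaN and are
  dropped pairwise by the paired t-tests; they are never coerced to 0
  or 1.  Identical paired columns yield t = 0, p = 1 by definition rather
  than scipy's degenerate NaN.
- Operating-point selection minimizes the Euclidean distance to the ideal
  (RR_target, RR_unintended) = (0, 1), ties toward the smaller parameter;
  the unintended pool is ambiguous + unknown + non-target trials.

## Study design

The default study simulates twelve sessions with derived sub-seeds; all
twelve run the target protocol, seven additionally the unknown-motion
protocol and four the non-target protocol, matching the session
allocation of the reference study design.  Accuracy comparisons span the
four systems (N_comp = 6 Bonferroni pairs); rejection metrics compare the
three rejection mechanisms (N_comp = 3).

## Known limitations

- The OCSVM-vs-baseline accuracy difference is a statistical tie by
  construction (OCSVM rejections are barely correlated with
  misclassification, here and in the human data), so its sign at any
  single seed is noise; the test suite asserts the full ordering anyway
  and this sub-assertion can legitimately fail at a given seed.
- BPNN rejection of the non-target elbow flexion is weaker than on human
  data: the overfit network is confidently wrong on far-off-manifold
  inputs, a known behaviour of softmax confidence.
- The simulator's determinism makes session-to-session variability purely
  seed-driven; real inter-participant variability (musculature,
  subcutaneous fat, task familiarity) is not modelled.
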