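# Methods

`skerp` re-creates, end to end and on fully synthetic data, an EEG study of
error prediction in a ballistic motor task: performers throw a tethered
virtual ball around a central post at a target, and erroneous throws are
accompanied by two fronto-central negative EEG deflections — a sharp error
negativity (Ne/ERN) peaking 250 ms after ball release and a broader
negativity lasting until the moment of knowledge of results (KR).  This note
documents the models, the defaults and why they were chosen, and what the
synthetic data can and cannot establish.

## Task physics

The ball flight is a two-dimensional isotropic harmonic oscillator about the
post centre: per axis, `u(t) = u0 cos(ωt) + (v0/ω) sin(ωt)`.  This is the
standard flight model for the skittles task and produces exactly the centred
elliptic orbits the task displays.  Release is parameterized by the lever
angle θ (degrees, counter-clockwise from +x) and angular velocity θ̇; the
ball starts at the lever tip `pivot + L(cos θ, sin θ)` with tangential
velocity `L θ̇ (-sin θ, cos θ)`.

Work-space constants follow the published layout: post radius 0.25 m at the
origin, target of radius 0.05 m centred at (0.35, 1.00) m, ball radius
0.05 m, lever length 0.40 m.  A throw is a *hit* when the minimal distance
between the ball path and the target centre stays below 0.10 m (target plus
ball radius).  The lever pivot is not published; the default (0, −0.90) m
places the lever below the post with the target up-right, matching the
displayed geometry.  A ball whose centre enters the post disc is stopped
there (`post_hit`), and such throws count as errors downstream; whether the
ball radius should widen the post collision is left configurable.

The minimal distance and its time (the KR moment, `t_kr`) are found by
sampling the closed form at 1 ms, then refining the discrete argmin by
golden-section search on the analytic squared distance inside the one-sample
bracket.  The refinement is exact to machine precision for untruncated
flights; ties break to the earliest time, and the search is restricted to
the first orbital period (orbits repeat; KR is the first approach).

The angular frequency ω is not published.  The default geometry calibrates ω
by a bracketed root search so that the median KR latency of a representative
set of successful throws equals 0.85 s, the centre of the 817–910 ms range
reported across real performers.

## Synthetic cohort

**Behaviour.**  Each performer aims at a point on the solution manifold
(release angles drawn from 264–282°, where misses fly past the target rather
than striking the post) and throws with normal dispersion in θ and θ̇.  A
skill parameter in [0, 1] maps geometrically to an angle dispersion between
9.5° and 2.6° (angular-velocity dispersion 12 deg/s per degree); this span
was calibrated once, via the solution-map integral, so that expected hit
rates cover roughly 48–96 % — the published cross-performer range.  Sessions
end at the first non-hit at or after trial 400 (hard cap 600), trials are
paced 2.2 s apart on average (minimum 1.9 s), and throws at or below
50 deg/s lever velocity are redrawn as invalid.

**KR latency.**  Real performers differed in KR latency (817–910 ms)
"dependent on throwing strategy".  The generator realizes each performer's
latency centre (drawn uniformly from 0.820–0.905 s) by alternating two
steps: snap the aiming angular velocity onto the solution manifold, and
rescale that performer's ω so the aim's KR latency equals the centre (a
fixed-point iteration exploiting the near-reciprocal latency–ω relation).
Trial-to-trial KR jitter then emerges from release dispersion — a few
milliseconds for skilled performers, ~30 ms for unskilled ones.

**EEG.**  500 Hz, ten 10–20 scalp channels (F3 Fz F4 FCz C3 Cz C4 P3 Pz P4)
plus the right mastoid and four EOG channels, all referenced to the left
mastoid as recorded.  Error (and post-hit) trials add at FCz: a negative
Gaussian pulse peaking 250 ms after release (σ = 25 ms, magnitude `a1`) and
a negative smoothed boxcar from 325 ms until the trial's KR moment
(Gaussian-CDF edges, τ = 10 ms, magnitude `a2`).  Hit trials add only a
small pulse (`a1_hit = 0.3 a1`; the source data show a small hit-trial
deflection but do not quantify it).  The shapes themselves are a modelling
choice — only the peak latency and extent are constrained by the data — and
were chosen for closed-form readouts.  The 325 ms onset splits the
inconsistent 300 vs 350 ms statements in the source.  Components spread to
neighbours with a fixed fronto-central attenuation map (FCz 1.0; Fz, Cz 0.8;
F3, F4, C3, C4 0.5; parietals 0.2), arbitrary but fixed values expressing
the Ne/ERN topography.

Amplitudes: `a1 = 3.0 + 0.12 × expected hit % + N(0, 1.2²)` µV (clipped at
1), so better performers carry larger error pulses — the coupling behind the
negative performance–amplitude correlation.  The injected coupling
(corr(`a1`, hit %) ≈ 0.8) is deliberately stronger than the r ≈ −0.5 the
analysis is meant to recover, because window-amplitude measurement noise at
10 µV background attenuates correlations by a factor ≈ 0.6; the *measured*
hit-percentage–amplitude correlation across default cohorts is ≈ −0.5, the
calibration target.  `a2 = N(6.0, 0.8²)` µV: smaller than
the mean pulse difference (≈ 8 µV) so the two deflections stay separable by
the data-driven window rule; the second deflection's much larger t statistic
in the source is carried by its low cross-performer variance, not by a
larger amplitude.  A mean `a1` near 12 µV is in the range of published
fronto-central error negativities.

Background noise per channel is 1/f-power noise (flattened below 0.5 Hz)
plus a narrowband 10 Hz rhythm (0.5 Hz bandwidth, 25 % of the power),
normalized to `noise_sd` (default 10 µV).  The rhythm is narrowband noise
rather than a sinusoid so its phase drifts over seconds and averages out of
event-locked means, as real ongoing alpha does.  Blinks are a Poisson train
(15/min) of Gaussian templates (σ = 55 ms, ~160 µV on the upper vertical EOG
channel) propagated to frontal channels with fixed coefficients.  No line
noise is generated; filter tests inject 50 Hz explicitly.

**Seeding.**  One master seed fans out through `numpy` `SeedSequence`
counters: participant *i* draws its parameters from
`[master_seed, i+1, 7]` and stores `seed_i = [master_seed, i+1]`; behaviour
uses stream `[seed_i, 1]`, continuous EEG `[seed_i, 2]`, direct epoch
synthesis `[seed_i, 3]`, ICA `[seed_i, 4]`.  Identical configuration and
seed give byte-identical outputs.

## Preprocessing

Order-2 Butterworth band-pass 0.2–30 Hz, applied forward and backward
(zero net phase, doubled effective order) with reflected edge padding; the
order is a configurable default since the source states only the band.  The
amplifier's online 0.01 Hz high-pass is not re-simulated; the 0.2 Hz offline
high-pass dominates.  Re-referencing to averaged mastoids uses the algebra
of the recorded right-mastoid channel: every scalp channel gets `M2/2`
subtracted, the mastoid channel becomes `M2/2`, EOG channels are untouched.

Ocular artifacts are removed from the **continuous** signal.  The default is
natural-gradient Infomax ICA (logistic nonlinearity) on PCA-whitened data:
block updates (block 1024) on at most 50 000 evenly decimated samples,
learning-rate annealing (×0.9 on a >60° change of update direction, plus a
steady ×0.99 decay after 32 passes so the stochastic noise floor keeps
shrinking), convergence when the squared per-pass weight change falls below
1e-6, at most 512 passes.  Components whose time courses correlate with
either bipolar EOG derivation at |r| > 0.8 are zeroed and the data remixed;
non-convergence falls back, with a warning, to least-squares regression of
each channel on the bipolar EOG pair.  Logistic Infomax separates
super-Gaussian sources (which ocular artifacts are); it is not expected to
isolate sub-Gaussian ones.

Epochs: (−0.6, +1.0) s around release (800 samples) and (−1.0, +0.8) s
around feedback (900 samples).  Baseline correction subtracts each
epoch/channel's own whole-window mean — deliberately not a pre-stimulus
mean.  Manual artifact inspection is replaced by automatic thresholds:
epochs with any scalp sample beyond ±100 µV or any one-sample step beyond
50 µV are dropped and logged.

## Classification and exclusions

Within each performer, trials are sorted by minimal distance; up to 50
trials below 5 cm (from the lower end) become the hit category and up to 50
trials above 12 cm become the error category.  "Up to 50 above 12 cm" is
read as the 50 *largest* distances, symmetric to the hits; the
nearest-above-threshold reading is available as a config option.  Post-hit
trials are eligible for the error category through their truncated-path
distance.  Performers with fewer than 20 surviving trials in either category
(counted after artifact rejection of the release-locked epochs) are
excluded; a single-pass ±2 SD screen on hit percentage and release-angle
dispersion (computed over the performers surviving the first rule, without
re-iteration) removes outliers.  Hit percentage counts all session trials of
the experimental session only.

## ERP statistics

Per performer: category averages, then the error-minus-hit difference wave;
all inference is at FCz.  Analysis windows are defined from the grand
average of the difference waves, since no prior window exists for a
ballistic task: window 1 is the maximal contiguous run, within the search
range 0.10–0.35 s (release-locked), around the deepest *local* minimum there
where the amplitude stays below half that minimum; window 2 applies the same
rule between the end of window 1 and the earliest typical KR latency across
performers.  Preferring a local minimum over the range's global one matters
for feedback-locked data, where the smeared first deflection and the second
deflection adjoin: the trace can still be falling at the search-range edge,
and an edge argmin would park window 1 on the flank of the second
deflection.  Bounding the run by the search range likewise keeps a merged
first window from swallowing the second deflection.  Feedback-locked data use the analogous ranges shifted
by the KR latency, with window 2 ending at the KR moment.  The 50 %
fractional-peak rule and the search ranges are configurable, and manual
windows can be supplied.  Mean window amplitudes are tested against zero
with a two-tailed one-sample t-test (`t = mean/(sd/√n)`, df = n−1) and
correlated with hit percentage (Pearson r, two-tailed t-based p).  The sign
convention is throughout: more negative amplitude = larger error signal.

Two estimators beyond window means support parameter-recovery analyses:
`deflection_magnitude` (trough depth below the mean of flanking segments —
offset-invariant, the scale on which a "visible deflection" lives) and
`fit_component_amplitudes` (template regression of a waveform on the pulse
and boxcar shapes; with a noise power spectrum estimated from trial-to-trial
epoch residuals it is generalized least squares in the frequency domain,
otherwise least squares on first-differenced data).

## Numerical choices and degenerate inputs

Filter bands must lie inside the Nyquist range; epochs that would cross the
record bounds are dropped and logged; a zero-variance EOG makes ocular
removal the identity; zero cohort variance skips screening with a warning;
an all-identical sample makes the t-test undefined (reported as such); a
cohort too small for statistics completes the run with the statistics
flagged not computable.  Categorization tie-breaks are by trial index.
Writers emit floats at repr precision, so tables round-trip bitwise; EEG is
stored as multiplexed IEEE float32 in µV (round trips exact to float32).

## Problem sizes used in the shipped analyses

The acceptance script runs the full default study (29 performers, ~400–440
trials each, ~15 min of 500 Hz EEG per performer).  The test suite uses the
same code paths at reduced sizes chosen for quick iteration: physics oracles
at 100–1000 throws, signal-chain exactness on a 3-performer noise-free
cohort, statistical calibration with 10 000 null cohorts, recovery and
correlation studies with 50–100 seeded replicates synthesized through the
direct epoch path (identical injected signal and background model as the
continuous route, without blinks).

## What the synthetic data do and do not show

Passing tests establish that the pipeline's machinery is correct: physics to
oracle precision, classification identical to brute force, a signal chain
that is exact in the noise-free limit, calibrated inference, and recovery of
injected structure under realistic noise.  They cannot validate the
neuroscience: components are injected with fixed shapes and latencies, real
scalp topography, trial-to-trial ERP latency jitter, learning across the
session, non-stationary noise, muscle and cardiac artifacts are all absent,
and the hit-trial deflection magnitude is an assumption.  Inferential
numbers from the original recordings (t = −2.5 and −7.5 at df = 20,
r = −0.54, 75.1 % mean hit rate) are reproduced *in kind* — same pipeline,
same statistics, matching signs and data-driven windows — not in value,
since they depend on unreleased human data; the synthetic cohort is
deliberately constructed so its values land in qualitatively the same
regime (hit rates, KR latencies, window placement, negative t and r).

Two published phenomena constrain the generator only qualitatively.  The
feedback-locked smearing of the hit-trial deflection is reproduced in
direction (the deflection always shrinks once KR latency centres span
≥ 40 ms) but its magnitude is bounded: with a σ = 25 ms pulse and latency
spread capped by the published 93 ms range, averaging can reduce the peak to
at best ~55–75 % of the release-locked value, not make it vanish; in the
source data, trial counts and noise contributed to the visual
disappearance.  And at 10 µV of 1/f-plus-alpha background, single-session
amplitude estimates carry an irreducible ~1.2 µV standard error (the
Cramér–Rao bound for the pulse template in that noise), so per-session
recovery is accurate to ~10–15 %, not the few percent white-noise intuition
would suggest.
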