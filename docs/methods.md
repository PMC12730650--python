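# Methods

This note documents the models, parameter choices, and numerical
conventions behind `vibrotrace`, and what its synthetic experiments do
and do not demonstrate.

## Synthetic EEG generator

Each channel is an independent mixture of band-pass-filtered Gaussian
noise components — delta 0.5–4 Hz, theta 4–8 Hz, alpha centered on a
configurable peak (±1.5 Hz), beta 13–30 Hz, gamma 30–45 Hz — plus a 1/f
"aperiodic" floor band-limited to 0.5–45 Hz, mirroring the band-pass
applied to clinical resting-state recordings. Components are normalized
to unit variance and weighted by the square root of the profile's
relative band powers, so the weights are power shares. The channel
matrix is scaled to an RMS of 20 µV (physiological tens-of-µV range).
All randomness flows from the profile's single seed.

The two stock profiles encode the group-level pattern reported for
eyes-closed resting EEG in Alzheimer's disease versus healthy elderly
controls:

| band  | AD-like | NC-like |
|-------|--------:|--------:|
| delta | 0.37    | 0.10    |
| theta | 0.32    | 0.10    |
| alpha | 0.13    | 0.50    |
| beta  | 0.06    | 0.16    |
| gamma | 0.02    | 0.02    |
| 1/f floor | 0.10 | 0.10   |

The AD profile's alpha center sits at 9 Hz (alpha slowing), the NC
profile's at 10 Hz. Gamma is deliberately small: after 0.5–45 Hz
band-passing and automated muscle-artifact removal, residual scalp
gamma is on the order of a few percent, and — because the projected
trace's velocity weights band power by frequency squared — an inflated
gamma share would mask the slow-versus-alpha contrast the profiles are
meant to express.

What the generator does **not** emulate: inter-channel coherence
(channels are independent; real posterior alpha is spatially coherent),
non-stationarities such as drowsiness, artifacts, volume-conduction
topography, or inter-subject variability structure. Passing tests
therefore show that the *pipeline* transmits group-level spectral
differences into image descriptors — not that real patients would be
classified at the same rates.

## Group averaging

Channel-wise time-domain mean across subjects, aligned by channel label
and truncated to the shortest common length; no filtering. Unequal
record lengths are truncated rather than imputed. Subjects are summed
in a canonical order (sorted by a content digest) so the result is
exactly invariant to the order in which recordings are supplied.

## Sonification

Direct mapping: channels are mixed (mean by default), resampled with a
polyphase band-limited filter onto the 44.1 kHz grid, level-normalized,
and quantized to 16-bit PCM. The `time_scale` factor compresses the
time base; its default of 2.7 maps a ~13.5 min recording onto ~5 min of
audio. No dithering is applied at quantization (the error bound is one
LSB and the downstream consumer is a simulator, not a listener).

Two level conventions are provided. `normalize_amplitude` scales the
peak to a headroom (0.99 by default). The chain default, however, is
RMS normalization to 0.25 with a hard limiter at 0.99: the sample
maximum of a stochastic signal fluctuates between realizations, so
peak normalization imprints a realization-specific amplitude scale on
every downstream frame. In a two-group frame-level classification
protocol that scale acts as a *run fingerprint*: with identical
spectral profiles driving both groups, a classifier fed peak-normalized
runs reached test accuracies up to ~0.9 purely by memorizing which run
a frame came from. RMS normalization pins the typical level of every
run and restores chance-level behavior under the null. This is the one
deliberate departure from the simplest reading of the published chain,
and it matters only because the synthetic study re-runs the chain many
times; a single physical recording session has no second run to be
confused with.

## Membrane–mirror–laser simulator

Closed-form physics: A = πa², σ = m/A, f₀₁ = (c₀₁/2πa)√(T/σ) with
c₀₁ the first zero of J₀ computed by bracketed root finding on (2, 3).
Defaults a = 0.04 m, m = 2 g, f₀₁ = 187 Hz give A = 5.03×10⁻³ m²,
σ = 0.398 kg/m², T ≈ 152 N/m.

Dynamics: only mode (0,1) is simulated. The modal displacement obeys
ü + (ω₀₁/Q)u̇ + ω₀₁²u = κ·p(t) with ω₀₁ = 2πf₀₁, Q = 50 by default and
p(t) the audio samples, integrated by exact zero-order-hold
discretization of the transfer function at the audio rate (at 44.1 kHz
the staircase approximation of a 187 Hz drive is accurate to ~10⁻⁵ in
amplitude, well inside the 1% tolerance of the steady-state check).
Audio content (≤ ~120 Hz after time-scaling) sits far below the 187 Hz
resonance, so the response is quasi-static and the spot essentially
tracks the waveform.

Optics: mirror tilt θ = gain·u about two axes; the second axis is
driven by a 2.5 ms-delayed copy of the audio so oscillatory drives
draw Lissajous-like figures rather than a line (the physical mechanism
by which the real rig produces 2-D patterns is not modeled; this is
the smallest device that does). A tilt θ deflects the beam by 2θ; the
screen offset is L·tan(2θ) per axis with the horizontal axis stretched
by 1/cos(incidence) for the 30° oblique screen. The default gain
(5.5×10⁵ rad per unit modal displacement) puts the RMS spot excursion
near one third of the screen half-extent — large patterns with little
boundary clipping. Excursions beyond the 0.40 × 0.60 m screen are
clamped and flagged.

Camera: frames integrate the trajectory samples inside each exposure
window (default: full-frame, 1/fps at 10 fps) onto a 180×120 px grid
(isotropic ~3.3 mm pixels), convolve with a Gaussian point-spread
function (σ = 1.2 px), and apply a **fixed** intensity response:
black-level pedestal 8 plus 40 intensity counts per accumulated
sample, saturating at 255 — a sensor at fixed exposure/ISO. Slow,
dwelling traces render bright and saturated; fast sweeps render
dimmer. The response is identical for every sequence; per-run
normalization was rejected for the same fingerprint reason as peak
audio normalization. Optional Gaussian sensor noise (σ = 1 by default)
and a static screen-texture term (off by default) are added last.

## Frame processing

Adaptive threshold: foreground iff value > μ(x,y) − C, μ the local
mean over a 31×31 window, C = 2, replicate padding, strict comparison
(ties → background). Both Gaussian-weighted (default; σ = (w−1)/6) and
uniform means are implemented; the uniform variant uses an exact
integer integral image so that brute-force oracle comparisons are
bit-exact — sliding-window float accumulation could flip pixels that
tie with the threshold. Note the formula's fixed point: a perfectly
flat region is always foreground (v > v − 2), so on these rendered
scenes the *background* binarizes white and the trace appears as a
bright core outlined by a dark halo where the local mean is elevated.

Opening: erosion then dilation with the 3×3 discrete-ellipse (plus)
element; outside-image pixels count as background for both operations
(plain set morphology; the brute-force oracle uses the same
definition).

Envelope mask: candidate regions are the 8-connected components of one
phase of the cleaned frame; the component with the largest hole-filled
area becomes the mask (ties to the first component in a row-major
scan), and only pixels inside it are kept. The text this step derives
from is ambiguous about whether the contour search runs on the bright
or the inverted (dark) phase; both are implemented. The default is the
bright phase: on desk-scale frames the dark phase fragments into halo
arcs and speckle and selects an unstable sub-region (a quarter to a
half of frames end with no white pixel inside the mask), while the
bright phase yields a stable envelope. The dark variant is available
as `phase="dark"`.

Noise injection: additive N(0, σ²) per pixel, σ = 5 on the 0–255
scale, rounded and clamped, seeded per frame. By default the perturbed
frame feeds the binarization that produces the descriptors while the
envelope mask is computed from the unperturbed frame
(`mask_on_clean=True`): with C = 2 and σ ≈ 5 the injected noise turns
flat regions into near-critical salt-and-pepper speckle whose clusters
can out-compete the trace envelope, so masking on the clean frame
keeps the perturbation a robustness test of the *descriptors* rather
than of the envelope search. `mask_on_clean=False` restores the
single-path literal order.

## Descriptors

Active area = count of 255-pixels. Spatial entropy = binary Shannon
entropy of the intensity distribution (identically h₂ of the white
fraction; ≤ 1 bit). Box-counting dimension: grids of side ε anchored
at the origin, ε running over powers of two from min(H, W)/2 down to
2 px, D = the least-squares slope of log N(ε) against log(1/ε) over
all sizes (no scaling-region pruning — pruning choices change D, so
the reproducible convention is "use everything"), clamped to [0, 2];
undefined (NaN, flagged) for empty frames. Centroid = mean (x, y) of
white pixels. The per-frame classification vector is
[active_area, entropy, fractal_dim, centroid_x, centroid_y,
step_disp], where step_disp is the Euclidean centroid displacement
from the previous valid frame (0 for the first). Displacements are in
pixels; no physical calibration is implied.

## Classification protocol

Frame-level stratified 80/20 holdout; stratified 5-fold CV on the
training split (mean, population SD, and both interval conventions:
mean ± 1.96·SD/√k and mean ± SD); final fit and evaluation on the
untouched test split. Random forest: 100 trees, gini, unbounded
depth, √p features per split, bootstrap, random_state 42. ROC scores
are ensemble vote fractions for the Alzheimer class; AUC by the
trapezoidal rule. Every reported metric is recomputable from the
confusion matrix, and per-class precision is also exposed under the
alias "accuracy" as some summaries label that column.

Frame-level splitting is pseudo-replication — frames from one
recording are correlated, and a warning is logged. The `grouped` mode
keeps all frames of one source on one side of the split.

## Study conditions and problem sizes

The `run_all` defaults keep the published processing settings
(31/2, 3×3 ellipse, 10 fps, 275 s analysis window with 12 s/0 s start
offsets, σ = 5 injection, the full random-forest configuration) with
36 + 29 synthetic subjects. The package's own synthetic experiments
(acceptance tests) run desk-scale: 2 subjects per group, 100 s of
audio/video per group (1000 frames each, 2000 balanced frames per
run), 180×120 px frames. Under those conditions, across seeds 1–10:
the null configuration (both groups driven by the NC profile) gives
test accuracies 0.47–0.53, and the AD-vs-NC contrast gives AUC
0.81–0.84. Published headline figures obtained from physical
apparatus recordings are not expected to be reproduced by the
simulator, and the package makes no such claim.

## Known limitations

* One vibrational mode; no membrane nonlinearity, no speaker or room
  acoustics, no optical diffraction or camera distortion.
* Synthetic EEG lacks spatial structure and non-stationarity.
* The frame-level protocol's figures quantify group-level pattern
  separability, not diagnostic performance on individuals.
* The envelope mask's phase convention is a modeling decision made
  under ambiguity; both conventions are exposed and tested against
  brute-force oracles.
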