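# vibrotrace

EEG → sound → vibration → image → classifier: a tested, fully software
implementation of a biomimetic pipeline that turns group-averaged
resting-state EEG into laser-projection imagery and asks whether the
projected dynamics separate Alzheimer's-disease (AD) patients from
healthy controls (NC).

The pipeline has five stages, each a module:

1. **`eeg_core`** — read (EDF or plain matrix) or synthesize 19-channel,
   500 Hz resting-state EEG; average a group of recordings channel by
   channel in the time domain to one representative signal per group.
   The synthetic generator produces two spectral phenotypes: an AD-like
   signal (elevated delta/theta, attenuated alpha/beta) and an NC-like
   signal with a dominant ~10 Hz alpha peak.
2. **`sonify`** — direct-mapping sonification: EEG amplitude maps
   linearly to sound pressure; band-limited resampling onto the
   44.1 kHz grid, level normalization, 16-bit PCM WAV output.
3. **`membrane_optics`** — physics of the speaker–membrane–mirror–laser
   apparatus. A circular membrane of radius *a* and mass *m* (surface
   density σ = m/πa²) under tension *T* has fundamental mode (0,1) at
   f₀₁ = (c₀₁/2πa)·√(T/σ), c₀₁ ≈ 2.4048 the first zero of Bessel J₀ —
   so a measured resonance yields T = σ(2πa·f₀₁/c₀₁)². The audio drives
   that mode as a damped harmonic oscillator, the mirror tilt deflects
   the laser, and a camera model integrates the moving spot into
   grayscale frames.
4. **`frameproc` / `descriptors`** — adaptive binarization
   (T(x,y) = μ(x,y) − C, 31 px window, C = 2), morphological opening
   (3×3 elliptical element), largest-contour envelope masking, optional
   Gaussian noise injection (σ = 5); then per-frame active area,
   Shannon spatial entropy, box-counting fractal dimension, centroid,
   and centroid-trajectory displacements.
5. **`classify`** — 80/20 stratified holdout, stratified 5-fold CV on
   the training split, a 100-tree gini random forest (seed 42, √p
   features per split), confusion-matrix metrics, ROC/AUC from ensemble
   vote fractions.

`pipeline.run_all` wires the whole chain (two synthetic groups →
average → sonify → simulate → process → features → classify) with one
global seed; identical configs reproduce byte-identical outputs.

## Worked example

```python
from vibrotrace.membrane_optics import MembraneSpec

spec = MembraneSpec.from_resonance(a=0.04, m=0.002, f01=187.0)
print(f"area A = {spec.area:.3e} m^2")   # area A = 5.027e-03 m^2
print(f"sigma  = {spec.sigma:.3f} kg/m^2")  # sigma  = 0.398 kg/m^2
print(f"T      = {spec.T:.1f} N/m")      # T      = 152.0 N/m
```

A 4 cm membrane carrying 2 g and resonating at 187 Hz is therefore
under ≈152 N/m of tension — the quantity the acoustic method measures.

A desk-scale end-to-end run (60 s per group, two synthetic subjects per
group, all processing defaults):

```python
from vibrotrace.pipeline import PipelineConfig, EEGBlock, run_all

cfg = PipelineConfig(seed=7, duration=60.0,
                     eeg=EEGBlock(n_subjects_ad=2, n_subjects_nc=2))
report, manifest, features = run_all(cfg)
print(report.confusion.tolist())          # [[83, 37], [28, 92]]
print(f"{report.overall_accuracy:.3f}")   # 0.729
print(f"{report.auc:.3f}")                # 0.770
print(f"{report.cv_mean:.3f} +/- {report.cv_sd:.3f}")  # 0.703 +/- 0.019
```

Each group contributes 600 frames. The AD-like group's slow trace
dwells, rendering broad, brightly saturated regions (larger active
area and entropy per frame), while the faster alpha-driven NC trace
sweeps thinner, dimmer paths; the random forest separates the two
groups' frames well above chance.
Longer runs (100 s per group) reach AUC ≈ 0.81–0.84. Frame-level
splitting treats correlated frames as independent samples, so these
figures describe group-level pattern separability, not subject-level
diagnosis — `classify.run_protocol(mode="grouped")` provides the
leakage-free variant.

The same chain is scriptable from the shell:

```bash
vibrotrace run-all --duration 60 --seed 7 --out runs/demo/
vibrotrace synth-eeg --profile nc --duration 60 --seed 1 --out nc.txt
vibrotrace sonify --in nc.txt --format matrix --time-scale 2.7 --out nc.wav
```

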