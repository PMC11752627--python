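# afwave

Single-lead ECG time–frequency analysis and atrial-fibrillation
classification: duration-based segmentation, short-time Fourier and
generalized Morse continuous wavelet transforms, scalogram-image
rendering, a transfer-learning-style CNN classifier, and a full
one-vs-rest evaluation battery — plus a synthetic four-class ECG
generator so the whole pipeline is testable without any data download.

## The problem

Atrial fibrillation (AF) shows up in a single-lead ECG as irregularly
irregular RR intervals, absent P waves, and a fibrillatory baseline
oscillation in roughly the 4–10 Hz band. Rather than detecting beats
and classifying them one by one, the approach here analyses the signal
*as a continuum*: a 30 s segment is mapped to a time–frequency image
whose texture a convolutional network can classify into four rhythm
classes — normal (N), AF (A), other rhythm (O), and noisy (~).

## The method

**Segmentation.** Records are cut to a fixed 30 s window
(`round(30 · fs)` samples); shorter records are excluded. Segments are
resampled from the 300 Hz acquisition rate to a 128 Hz analysis rate by
polyphase rational-ratio filtering (32/75).

**Time–frequency analysis.** Two decompositions are provided:

- STFT with a symmetric Hamming window (256-point window, 128-point
  overlap):
  `X(τ, ω) = ∫ x(t) w(t − τ) e^{−jωt} dt`.
- A continuous wavelet transform
  `Z(a, b) = a^{−1} ∫ x(t) ψ*((t − b)/a) dt`
  (or the `1/√a` convention) on a generalized Morse wavelet filter
  bank. The Morse family is analytic, defined in the frequency domain
  as `Ψ(ω) = U(ω) · c · ω^β e^{−ω^γ}`, here with `(γ, P²) = (3, 60)`
  hence `β = 20`; the response peaks at `ω_p = (β/γ)^{1/γ} ≈ 1.8821`.
  Scales are geometric at `2^{1/10}` (10 voices per octave) from the
  Nyquist-peaked scale down to the longest scale whose wavelet still
  fits the segment. The scalogram is `|Z(a, b)|`.

**Rendering.** Scalogram magnitudes are log-compressed, min–max
normalized per image, mapped through a perceptual colormap with a
yellow high end, and resampled to a fixed image size (224 × 224 RGB by
default; the bundled pipeline uses 64 × 256 so beat-level time
structure survives at desk scale).

**Classification.** Images are split 64:16:20 (stratified, seeded)
into train/validation/test, and a CNN is trained with rmsprop
(learning rate 1e-4, batch 64, at most 105 epochs) with early stopping
after 10 validation checks without an accuracy improvement, returning
the best-check weights. The backbone is pluggable: a bundled small CNN
(two conv/pool blocks) trains end to end on a CPU; a frozen pretrained
backbone can be substituted, in which case only the fresh
fully-connected + softmax head trains.

**Evaluation.** The K-class confusion matrix is reduced per class to
(Tp, Fn, Tn, Fp) and six statistics are computed — accuracy,
sensitivity, specificity, precision, F1, and Matthews correlation
coefficient — with unweighted macro averages, plus per-class ROC and
precision–recall curves with trapezoidal AUCs.

## Worked example

```python
import numpy as np
from afwave import synth_ecg, cwt, scalogram
from afwave.synth import preset_config
from afwave.preprocess import Segment, resample_segment

rec = synth_ecg(preset_config("A", duration_s=30.0, seed=7))
print(f"record {rec.record_id}: {rec.duration_s:.0f} s at {rec.fs:.0f} Hz, label {rec.label}")

seg = resample_segment(Segment(rec.record_id, rec.signal, rec.fs, rec.label), 128.0)
coeffs = cwt(seg.samples, seg.fs)
mag = scalogram(coeffs)
print(f"scalogram: {mag.shape[0]} scales x {mag.shape[1]} samples, "
      f"center frequencies {coeffs.center_freqs[-1]:.3f}-{coeffs.center_freqs[0]:.1f} Hz")

band = (coeffs.center_freqs >= 4) & (coeffs.center_freqs <= 10)
print(f"mean 4-10 Hz scalogram power: {np.mean(mag[band]**2):.4f} mV^2")
```

prints

```
record S000007: 30 s at 300 Hz, label A
scalogram: 102 scales x 3840 samples, center frequencies 0.058-64.0 Hz
mean 4-10 Hz scalogram power: 0.0267 mV^2
```

The same computation on the matched normal-sinus record gives
0.0082 mV² — the fibrillatory 4–10 Hz band carries about three times
more energy under AF, which is exactly the texture difference the
image classifier learns.

The command line covers the same ground end to end:

```bash
afwave synth --counts A=50,N=50,O=50,~=50 --seed 1 --out data/
afwave run --in data/ --out results/ --seed 1
```

`run` reports the kept/excluded segment counts, the early-stopping
epoch, and the test-set macro-F1, and writes `metrics.json`,
`history.csv`, and the rendered scalogram images.

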