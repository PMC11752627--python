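# Methods

This note documents the models, conventions, and numerical choices
behind afwave, and what the synthetic-data tests do and do not
demonstrate.

## Segmentation and resampling

A record is kept iff it holds at least `round(30 s · fs)` samples; the
cut is the half-open window `[0, round(30 · fs))`. Taking the *first*
30 s is a deliberate, deterministic choice (an offset parameter exists
for other cut positions). Sample indexing is 0-based throughout.

Resampling to the 128 Hz analysis rate uses polyphase rational-ratio
filtering (`scipy.signal.resample_poly`; 300→128 Hz is exactly 32/75)
with its built-in anti-aliasing low-pass. The output is trimmed or
edge-padded to exactly `round(duration · fs_target)` samples so
downstream shapes are deterministic. Both the CWT and the STFT branch
operate on the 128 Hz segment by default, keeping the two image types
on identical time axes; the original rate can be kept by skipping the
resample step.

## STFT

Symmetric Hamming window `w[n] = 0.54 − 0.46 cos(2πn/(L−1))`,
`L = 256`, hop 128 (i.e. 128-point overlap), frames fully contained in
the signal (no padding), one-sided spectrum of `L/2 + 1` bins, no
zero-padding beyond the window. Frame count is
`floor((N − L)/(L − overlap)) + 1`.

## Generalized Morse wavelets

Frequency-domain definition `Ψ(ω) = U(ω) · c · ω^β e^{−ω^γ}` with
`γ = 3`, time-bandwidth `P² = βγ = 60`, so `β = 20`. The "(3, 60)"
pairing is read as (γ, P²) — the convention used by the major
wavelet toolboxes — rather than (γ, β); with β = 60 the wavelet would
be far narrower than the published scalograms show. Peak angular
frequency: `ω_p = (β/γ)^{1/γ}`.

Two normalizations are available:

- **l1** (default): `c` fixed so the peak response is 2. With an
  analytic transform of a real signal this makes a unit-amplitude
  sinusoid produce unit scalogram magnitude at its center frequency,
  which is the natural convention for rendering.
- **l2**: `c = sqrt(2πγ·2^{r}/Γ(r))`, `r = (2β+1)/γ`, giving unit
  time-domain energy, and the scaled filter carries the `√a` factor so
  the transform matches the `1/√a` integral convention literally.

**Filter bank.** Scales are geometric with ratio `2^{1/v}`, `v = 10`
voices per octave by default (a common filter-bank density; denser
banks only refine ridge resolution). The smallest scale places the
response peak at Nyquist, `s_min = ω_p/π`; the largest is capped so two
time-domain standard deviations of the wavelet fit in the signal,
`s_max = N/(2σ_t)`, with `σ_t ≈ 2.92` unit-scale samples for (3, 60)
computed numerically from the wavelet's energy-weighted second moment.
Filters are sampled on the signal's FFT grid, zero at DC and at
negative frequencies (analyticity/admissibility).

**Transform.** The signal is extended by reflection (half its length
per side) to soften FFT wrap-around; coefficients are the inverse FFT
of the padded spectrum times each filter, cropped back to the original
support. The transform is exactly linear in the input.

**Cone of influence.** Each time sample is annotated with the boundary
frequency below which coefficients are edge-affected. The boundary is
placed at **three** e-folding times of the wavelet envelope
(`t_e ≈ 5.86` unit-scale samples for (3, 60)): at one e-folding the
envelope tail still carries ~15% of the wavelet's mass, whereas beyond
three e-foldings it carries ~1e-5, so coefficients outside the cone
agree with an edge-free computation to well below 1e-3. The cone is
reported, not masked.

**Validation against the transform integral.** `cwt_direct` evaluates
the CWT integral directly: the time-domain wavelet is obtained by
trapezoid quadrature of its inverse Fourier integral on a dense grid,
clipped beyond 30 unit-scale times (envelope < 1e-12 of peak), and the
integral is computed as an explicit sum treating the signal as zero
outside its support. The FFT path agrees with it to ~1e-5 relative
(normalized by the largest coefficient) outside the cone of influence,
on scales whose response lies below Nyquist. Near-Nyquist scales are
excluded from the comparison by construction: any discrete
implementation truncates the response at Nyquist, so those scales
cannot match a continuum integral.

## Image rendering

`log(1 + m/ε)` compression with `ε = 1e-8`, after dividing by the
image's peak magnitude — which makes rendering exactly invariant to
positive rescaling of the input. The compressed matrix is bilinearly
resized, min–max normalized, and mapped through viridis (perceptually
uniform, yellow high end). Because CWT center frequencies are already
geometrically spaced, row-wise resampling yields a log frequency axis
for scalograms and a linear one for spectrograms without explicit axis
handling. No axes, ticks, or colorbars are rendered — classifier input
is the data panel only. An all-zero or constant matrix maps to the
colormap's low end uniformly.

The image contract's default size is 224 × 224 (the input size imposed
by standard pretrained backbones). The bundled end-to-end pipeline
instead defaults to 64 × 256 (frequency × time): squeezing a 30 s
segment into 224 columns leaves 0.13 s per pixel, and into 64 columns
0.47 s per pixel — the latter erases beat-level time structure, which
at desk scale is precisely what separates ectopic rhythms from AF. At
64 × 256 each pixel spans ~0.12 s and individual beats survive.

## Classifier and training

The split is stratified by class with largest-remainder rounding, so
100 items at 64:16:20 give exactly 64/16/20 and every class appears in
every subset. The same seed always reproduces the same assignment.

The model is a backbone plus a replaced head (fully connected layer →
softmax → argmax decision, ties to the lowest class index). The
bundled small reference CNN is two 3×3 conv + ReLU + 2×2 max-pool
blocks (8 and 16 channels), implemented in NumPy with im2col
convolutions; with a pretrained backbone only the head's parameters
are trainable.

Training uses rmsprop (ρ = 0.9, ε = 1e-7) with learning rate 1e-4,
batch 64, at most 105 epochs. Validation accuracy is checked once per
epoch; "no improvement for 10 checks" is interpreted as validation
patience (10 consecutive validation evaluations), not 10 optimizer
steps — step-level patience would stop almost immediately. The weights
from the best check are restored on return. A gradient-threshold
option (global-norm clipping) exists but defaults to off. No class
re-weighting is applied by default; a class-weight hook is out of
scope for the bundled trainer.

## Evaluation

Per-class one-vs-rest counts come straight from the confusion matrix
(Tp = diagonal, Fn = row remainder, Fp = column remainder, Tn = rest).
Any metric with a zero denominator is reported as 0 and flagged
`degenerate` rather than NaN, keeping batch evaluation total. Note
that per-class accuracy here is the standard one-vs-rest
`(Tp+Tn)/N`; published per-class tables sometimes place recall under
an "Acc" column, and both values are emitted so either reading can be
checked. ROC and PR curves enumerate the empirical threshold set with
tied scores grouped; areas are trapezoidal (PR area over recall,
anchored at recall 0 with the strictest threshold's precision).
`recall_at_precision(p)` returns the maximal recall among thresholds
whose precision is at least p.

## Synthetic ECG generator

Each beat is a sum of five Gaussian bumps (P, Q, R, S, T) at fixed
offsets from the R peak with amplitudes (0.15, −0.10, 1.0, −0.25,
0.35) mV. RR intervals are gamma-distributed (shape `1/CV²`, so
intervals stay positive) with mean 60/HR. Presets:

| class | RR CV | P wave | extras |
|---|---|---|---|
| N | 0.02 | yes | — |
| A | 0.25 | no | 4–10 Hz band-limited oscillation, 0.20 mV RMS |
| O | 0.05 | yes | 15% ectopic beats: preceding RR × 0.6, widened P-less QRS |
| ~ | 0.05 | yes | beats × 0.3, 0.40 mV broadband noise, 0.50 mV baseline wander |

The fibrillatory amplitude (0.20 mV RMS, within the physiological
range of coarse AF f-waves) is set so the AF scalogram's 4–10 Hz band
energy exceeds the normal rhythm's by a factor ≥ 2 at matched seeds —
the separability that makes the end-to-end classifier test meaningful.
Dataset generation draws durations uniformly in 9–60 s (so the 30 s
filter is exercised in both directions) and heart rates in 60–90 bpm,
with per-record seeds derived from a base seed.

**What this does not show.** The morphology is stylized: no real
P/QRS/T shape variability, electrode artefacts, muscle noise, atrial
flutter waves, or inter-patient variation. Passing the end-to-end test
demonstrates that the pipeline's stages compose correctly and that the
classifier can exploit genuine time–frequency structure; it says
nothing about clinical performance on real recordings, which requires
the public single-lead arrhythmia corpus and a full-scale pretrained
backbone.

## Problem sizes and degenerate inputs

The end-to-end check uses 200 records (50 per class), of which ~60%
survive the duration filter, with the small CNN at 64 × 256 — chosen
as the smallest configuration at which all four classes remain
learnable; results on it are stochastic and therefore assessed as a
median over three seeds. Degenerate inputs are handled explicitly:
empty containers, non-finite samples, labels outside {N, A, O, ~},
signals shorter than one STFT window or four CWT samples, all-zero
render matrices, single-class training sets, and single-valued truth
in curve computation all raise typed errors (or flags) rather than
propagating NaNs.
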