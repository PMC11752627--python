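"""Time-frequency analysis: STFT and the generalized Morse CWT.

Two complementary decompositions of a single-lead ECG segment:

* A short-time Fourier transform with a symmetric Hamming window
  (default 256-point window, 128-point overlap), producing a one-sided
  complex spectrogram X(tau, omega).

* A continuous wavelet transform built on a generalized Morse wavelet
  filter bank. The Morse family is analytic, defined in the frequency
  domain as

      Psi(omega) = U(omega) * a * omega**beta * exp(-omega**gamma),

  where U is the unit step, gamma controls symmetry and beta bandwidth;
  the family is conventionally parameterized by (gamma, P^2) with the
  time-bandwidth product P^2 = beta*gamma. The "(3, 60)" bank used here
  therefore has gamma = 3, beta = 20. The frequency response peaks at
  omega_p = (beta/gamma)**(1/gamma), which maps scale a to the physical
  center frequency f = omega_p * fs / (2*pi*a).

The transform is evaluated per scale by frequency-domain multiplication
of the (reflection-extended) signal spectrum with the scaled wavelet
response followed by an inverse FFT; a scalogram is the elementwise
modulus of the resulting coefficient matrix Z(a, b).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gamma as gamma_fn

from afwave.errors import InputError, ParameterError

__all__ = [
    "MorseParams",
    "FilterBank",
    "SpectrogramMatrix",
    "CoefficientMatrix",
    "hamming_window",
    "stft",
    "morse_wavelet_freq",
    "morse_wavelet_time",
    "design_filter_bank",
    "cwt",
    "scalogram",
]


# ---------------------------------------------------------------------------
# STFT
# ---------------------------------------------------------------------------

@dataclass
class SpectrogramMatrix:
    """One-sided complex STFT coefficients, frequency bins x frames."""

    values: np.ndarray
    frame_times: np.ndarray  # seconds, frame centers
    bin_freqs: np.ndarray  # Hz, ascending in [0, fs/2]


def hamming_window(length: int) -> np.ndarray:
    """Symmetric Hamming weights w[n] = 0.54 - 0.46*cos(2*pi*n/(L-1)).

    ``length == 1`` returns ``[1.0]`` by convention.
    """
    if length < 1:
        raise ParameterError(f"window length must be >= 1, got {length}")
    if length == 1:
        return np.ones(1)
    n = np.arange(length)
    return 0.54 - 0.46 * np.cos(2.0 * np.pi * n / (length - 1))


def stft(
    signal: np.ndarray,
    fs: float,
    window_length: int = 256,
    overlap: int = 128,
) -> SpectrogramMatrix:
    """Short-time Fourier transform with a Hamming window.

    Frames are fully contained in the signal (no padding); the frame
    count is ``floor((N - L) / (L - overlap)) + 1`` and the one-sided
    spectrum holds ``L/2 + 1`` bins.
    """
    x = np.asarray(signal, dtype=float).ravel()
    if not (0 <= overlap < window_length):
        raise ParameterError(f"need 0 <= overlap < window_length, got {overlap} / {window_length}")
    if x.size < window_length:
        raise InputError(f"signal of {x.size} samples shorter than window ({window_length})")
    hop = window_length - overlap
    n_frames = (x.size - window_length) // hop + 1
    starts = hop * np.arange(n_frames)
    frames = np.lib.stride_tricks.sliding_window_view(x, window_length)[starts]
    w = hamming_window(window_length)
    values = np.fft.rfft(frames * w, axis=1).T  # bins x frames
    bin_freqs = np.fft.rfftfreq(window_length, d=1.0 / fs)
    frame_times = (starts + window_length / 2.0) / fs
    return SpectrogramMatrix(values=values, frame_times=frame_times, bin_freqs=bin_freqs)


# ---------------------------------------------------------------------------
# Generalized Morse wavelets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MorseParams:
    """Generalized Morse wavelet family parameters.

    Parameters
    ----------
    gamma : float
        Shape exponent (> 0); 3 gives the symmetric "Airy" branch.
    time_bandwidth : float
        P^2 = beta * gamma (> 0). The default (3, 60) bank has beta = 20.
    voices_per_octave : int
        Number of geometrically spaced scales per frequency doubling.
    normalization : str
        'l1' (unit-amplitude response: a unit sinusoid yields unit
        scalogram magnitude at its center frequency) or 'l2' (the
        1/sqrt(a) convention, unit wavelet energy).
    """

    gamma: float = 3.0
    time_bandwidth: float = 60.0
    voices_per_octave: int = 10
    normalization: str = "l1"

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.time_bandwidth <= 0:
            raise ParameterError("gamma and time_bandwidth must be positive")
        if self.voices_per_octave < 1:
            raise ParameterError("voices_per_octave must be >= 1")
        if self.normalization not in ("l1", "l2"):
            raise ParameterError(f"normalization must be 'l1' or 'l2', got {self.normalization!r}")

    @property
    def beta(self) -> float:
        return self.time_bandwidth / self.gamma

    @property
    def peak_omega(self) -> float:
        """Angular frequency of the response maximum, (beta/gamma)**(1/gamma)."""
        return (self.beta / self.gamma) ** (1.0 / self.gamma)


def _morse_l2_amplitude(b: float, g: float) -> float:
    """Amplitude giving unit time-domain energy, from the closed form
    int_0^inf w**(2b) exp(-2 w**g) dw = Gamma((2b+1)/g) / (g * 2**((2b+1)/g))."""
    r = (2.0 * b + 1.0) / g
    return float(np.sqrt(2.0 * np.pi * g * 2.0**r / gamma_fn(r)))


def morse_wavelet_freq(omega: np.ndarray | float, params: MorseParams) -> np.ndarray | float:
    """Frequency response of the unit-scale Morse wavelet.

    Zero for omega <= 0 (analytic, admissible); positive for omega > 0.
    The amplitude constant depends on the normalization mode but is
    fixed across scales.
    """
    b, g = params.beta, params.gamma
    if params.normalization == "l1":
        wp = params.peak_omega
        amp = 2.0 / (wp**b * np.exp(-(wp**g)))
    else:
        amp = _morse_l2_amplitude(b, g)
    omega_arr = np.atleast_1d(np.asarray(omega, dtype=float))
    out = np.zeros_like(omega_arr)
    pos = omega_arr > 0
    w = omega_arr[pos]
    out[pos] = amp * w**b * np.exp(-(w**g))
    return out if np.ndim(omega) else float(out[0])


def morse_wavelet_time(t: np.ndarray, params: MorseParams, n_omega: int = 4096, omega_max: float | None = None) -> np.ndarray:
    """Time-domain Morse wavelet psi(t) by quadrature of the inverse transform.

    psi(t) = (1/2pi) int_0^inf Psi(omega) exp(i omega t) d omega, with t in
    unit-scale time (samples at scale 1). Used for time-spread statistics
    and as an independent slow path in validation.
    """
    b, g = params.beta, params.gamma
    if omega_max is None:
        # response decays like omega**b * exp(-omega**g); 6x the peak is ample
        omega_max = 6.0 * params.peak_omega
    om = np.linspace(0.0, omega_max, n_omega)
    resp = morse_wavelet_freq(om, params)
    t = np.asarray(t, dtype=float)
    kernel = np.exp(1j * np.outer(t, om))
    return np.trapezoid(kernel * resp, om, axis=1) / (2.0 * np.pi)


@functools.lru_cache(maxsize=8)
def _time_spread(gamma: float, beta: float) -> tuple[float, float]:
    """(sigma_t, e-folding time) of the unit-scale wavelet envelope.

    sigma_t is the energy-weighted time standard deviation; the e-folding
    time is where |psi(t)| first stays below |psi(0)|/e. Both are in
    unit-scale sample units and scale linearly with a.
    """
    params = MorseParams(gamma=gamma, time_bandwidth=beta * gamma, normalization="l1")
    t = np.linspace(0.0, 60.0, 3001)
    psi = morse_wavelet_time(t, params)
    env = np.abs(psi)
    w = env**2
    # |psi(t)|^2 is even in t for a real-valued frequency response
    sigma = float(np.sqrt(np.sum(t**2 * w) / np.sum(w)))
    below = env < env[0] / np.e
    efold = float(t[np.argmax(below)]) if below.any() else float(t[-1])
    return sigma, efold


@dataclass
class FilterBank:
    """Frequency-domain Morse wavelet filters over an FFT grid.

    Row j of ``filters`` is the response of the wavelet at ``scales[j]``
    sampled on the length-n FFT grid (zero at DC and at negative
    frequencies); ``center_freqs[j] = peak_omega * fs / (2*pi*scales[j])``.
    """

    params: MorseParams
    fs: float
    n_samples: int
    scales: np.ndarray  # ascending
    center_freqs: np.ndarray  # Hz, descending
    filters: np.ndarray  # n_scales x n_samples, real


def design_filter_bank(
    n_samples: int,
    fs: float,
    params: MorseParams | None = None,
    max_scale_samples: int | None = None,
) -> FilterBank:
    """Build a Morse CWT filter bank for a length-n signal.

    Scales are geometric with ratio 2**(1/voices_per_octave). The
    smallest scale puts the wavelet peak at the Nyquist frequency; the
    largest is capped so two time-domain standard deviations of the
    wavelet fit inside ``max_scale_samples`` (the signal length by
    default).
    """
    if params is None:
        params = MorseParams()
    if fs <= 0:
        raise ParameterError(f"fs must be positive, got {fs}")
    if n_samples < 4:
        raise InputError(f"need at least 4 samples, got {n_samples}")
    if max_scale_samples is None:
        max_scale_samples = n_samples
    wp = params.peak_omega
    sigma_t, _ = _time_spread(params.gamma, params.beta)
    s_min = wp / np.pi  # peak response at omega = pi rad/sample
    s_max = max_scale_samples / (2.0 * sigma_t)
    n_octaves = np.log2(s_max / s_min)
    if n_octaves < 1.0:
        raise InputError(
            f"signal too short for one octave of scales ({max_scale_samples} samples, "
            f"wavelet spread {sigma_t:.1f})"
        )
    v = params.voices_per_octave
    n_scales = int(np.floor(n_octaves * v)) + 1
    scales = s_min * 2.0 ** (np.arange(n_scales) / v)
    center_freqs = wp * fs / (2.0 * np.pi * scales)
    omega = 2.0 * np.pi * np.fft.fftfreq(n_samples)  # rad/sample, signed
    filters = np.zeros((n_scales, n_samples))
    pos = omega > 0
    for j, s in enumerate(scales):
        filters[j, pos] = morse_wavelet_freq(s * omega[pos], params)
        if params.normalization == "l2":
            filters[j, pos] *= np.sqrt(s)
    return FilterBank(
        params=params,
        fs=fs,
        n_samples=n_samples,
        scales=scales,
        center_freqs=center_freqs,
        filters=filters,
    )


@dataclass
class CoefficientMatrix:
    """Complex CWT coefficients Z(a, b): scales x time.

    ``coi`` holds, per time sample, the frequency (Hz) at the cone of
    influence: coefficients at center frequencies *below* coi[t] are
    within one wavelet e-folding time of the nearer signal edge and
    should be treated as edge-affected.
    """

    values: np.ndarray
    scales: np.ndarray
    center_freqs: np.ndarray
    times: np.ndarray  # seconds
    coi: np.ndarray  # Hz
    params: MorseParams = field(default_factory=MorseParams)

    @property
    def fs(self) -> float:
        if self.times.size > 1:
            return 1.0 / (self.times[1] - self.times[0])
        return 1.0


def cwt(
    signal: np.ndarray,
    fs: float,
    params: MorseParams | None = None,
    reflect_pad: bool = True,
) -> CoefficientMatrix:
    """Morse continuous wavelet transform of a real signal.

    The signal is extended by reflection (half its length on each side)
    to soften FFT wrap-around; coefficients are computed per scale as
    the inverse FFT of the signal spectrum times the scaled wavelet
    response, then cropped back to the original support. The transform
    is linear in the input.
    """
    if params is None:
        params = MorseParams()
    x = np.asarray(signal, dtype=float).ravel()
    if x.size < 4:
        raise InputError(f"signal too short for CWT ({x.size} samples)")
    if not np.all(np.isfinite(x)):
        raise InputError("signal contains non-finite samples")
    n = x.size
    pad = min(n - 1, n // 2) if reflect_pad else 0
    xe = np.pad(x, pad, mode="reflect") if pad else x
    bank = design_filter_bank(xe.size, fs, params, max_scale_samples=n)
    spectrum = np.fft.fft(xe)
    z = np.fft.ifft(spectrum[None, :] * bank.filters, axis=1)[:, pad : pad + n]
    times = np.arange(n) / fs
    wp = params.peak_omega
    _, efold = _time_spread(params.gamma, params.beta)
    # boundary at three e-folding times: the envelope tail mass beyond
    # that distance is ~1e-5 of the wavelet, so coefficients outside the
    # cone are clean of edge effects to well below 1e-3
    edge = np.minimum(np.arange(n), n - 1 - np.arange(n)).astype(float)
    with np.errstate(divide="ignore"):
        coi = np.minimum(wp * fs * (3.0 * efold) / (2.0 * np.pi * edge), fs / 2.0)
    return CoefficientMatrix(
        values=z,
        scales=bank.scales,
        center_freqs=bank.center_freqs,
        times=times,
        coi=coi,
        params=params,
    )


def cwt_direct(
    signal: np.ndarray,
    fs: float,
    scales: np.ndarray,
    params: MorseParams | None = None,
    support: float = 30.0,
) -> np.ndarray:
    """Slow reference CWT by direct numerical integration.

    Evaluates Z(a, b) = (1/a) * sum_t x[t] psi*((t - b)/a) (or the
    1/sqrt(a) variant for 'l2') with the time-domain wavelet obtained by
    trapezoid quadrature of its inverse Fourier integral, treating the
    signal as zero outside its support. Quadratic in the signal length;
    intended for validating the FFT path on short signals, not for use.
    ``support`` clips the wavelet beyond that many unit-scale times,
    where its envelope is below ~1e-12 of the peak.
    """
    if params is None:
        params = MorseParams()
    x = np.asarray(signal, dtype=float).ravel()
    n = x.size
    diffs = np.arange(-(n - 1), n)
    samp = np.arange(n)
    out = np.zeros((len(scales), n), dtype=complex)
    for j, s in enumerate(scales):
        rel = diffs / s
        psi = morse_wavelet_time(rel, params, n_omega=8192)
        psi[np.abs(rel) > support] = 0.0
        kernel = np.conj(psi[(samp[None, :] - samp[:, None]) + (n - 1)])
        norm = s if params.normalization == "l1" else np.sqrt(s)
        out[j] = (kernel @ x) / norm
    return out


def alias_free_scales(params: MorseParams, rel_tol: float = 1e-6) -> float:
    """Smallest scale whose wavelet response is below ``rel_tol`` of its
    peak at the Nyquist frequency (i.e. effectively band-limited)."""
    from scipy.optimize import brentq

    wp = params.peak_omega
    peak = morse_wavelet_freq(wp, params)
    cut = brentq(lambda w: morse_wavelet_freq(w, params) - rel_tol * peak, wp, 50.0 * wp)
    return cut / np.pi


def scalogram(coeffs: CoefficientMatrix) -> np.ndarray:
    """Elementwise modulus |Z(a, b)| of the coefficient matrix."""
    return np.abs(coeffs.values)


def ridge_frequency(coeffs: CoefficientMatrix) -> float:
    """Center frequency (Hz) of the scale with the largest time-averaged energy."""
    power = np.mean(np.abs(coeffs.values) ** 2, axis=1)
    return float(coeffs.center_freqs[int(np.argmax(power))])
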