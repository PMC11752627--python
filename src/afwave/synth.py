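"""Synthetic four-class single-lead ECG generator.

Generates stylized 300 Hz ECG in the four rhythm classes used
throughout the toolkit:

* ``N`` (normal sinus): regular RR intervals (CV <= 0.03), full PQRST
  morphology.
* ``A`` (AF-like): irregularly irregular RR intervals (CV >= 0.2),
  absent P waves, and a band-limited 4-10 Hz fibrillatory baseline
  oscillation.
* ``O`` (other rhythm): sinus rhythm with premature ectopic beats
  (shortened preceding RR, widened P-less QRS).
* ``~`` (noisy): broadband noise plus baseline wander dominating an
  attenuated ECG.

Morphology is intentionally stylized -- each beat is a sum of five
Gaussian bumps (P, Q, R, S, T) -- sufficient to exercise the transforms
and the classifier; no claim of clinical realism is made.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.signal

from afwave.errors import ParameterError
from afwave.records import CLASS_LABELS, EcgRecord

#: (offset s, width s, amplitude mV) of the P, Q, R, S, T bumps.
BEAT_BUMPS = {
    "P": (-0.18, 0.030, 0.15),
    "Q": (-0.045, 0.012, -0.10),
    "R": (0.0, 0.015, 1.0),
    "S": (0.045, 0.012, -0.25),
    "T": (0.28, 0.070, 0.35),
}
#: half-open beat support around the R peak, seconds
BEAT_SPAN = (-0.30, 0.50)


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters for one record; presets per class below."""

    label: str = "N"
    duration_s: float = 30.0
    fs: float = 300.0
    heart_rate_bpm: float = 70.0
    rr_cv: float = 0.02
    p_wave: bool = True
    fib_wave_amp: float = 0.0  # mV RMS of the fibrillatory band oscillation
    fib_wave_band: tuple[float, float] = (4.0, 10.0)
    ectopic_rate: float = 0.0  # per-beat probability
    noise_sd: float = 0.03  # mV, broadband
    wander_amp: float = 0.0  # mV, baseline wander
    beat_amp: float = 1.0  # scale on the beat train
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.fs <= 0 or self.heart_rate_bpm <= 0:
            raise ParameterError("duration, fs and heart rate must be positive")
        if self.rr_cv < 0:
            raise ParameterError("rr_cv must be >= 0")
        if not 0.0 <= self.ectopic_rate <= 1.0:
            raise ParameterError("ectopic_rate must be a probability")


#: per-class preset overrides; fibrillatory amplitude chosen so the AF
#: 4-10 Hz band energy clearly exceeds the normal rhythm's QRS harmonics
PRESETS: dict[str, dict] = {
    "N": dict(rr_cv=0.02, p_wave=True),
    "A": dict(rr_cv=0.25, p_wave=False, fib_wave_amp=0.20),
    "O": dict(rr_cv=0.05, p_wave=True, ectopic_rate=0.15),
    "~": dict(rr_cv=0.05, p_wave=True, noise_sd=0.40, wander_amp=0.50, beat_amp=0.30),
}


def preset_config(label: str, **overrides) -> SynthConfig:
    """Build the preset SynthConfig for a class symbol."""
    if label not in PRESETS:
        raise ParameterError(f"unknown preset symbol {label!r}; expected one of {CLASS_LABELS}")
    kwargs = dict(PRESETS[label])
    kwargs.update(overrides)
    return SynthConfig(label=label, **kwargs)


def synth_beat_template(fs: float, p_wave: bool = True, ectopic: bool = False) -> np.ndarray:
    """One PQRST beat as a sum of Gaussian bumps; R is the global maximum.

    The template spans ``BEAT_SPAN`` seconds around the R peak. With
    ``p_wave`` off the P bump is omitted; an ectopic beat additionally
    widens Q/R/S and drops the P wave.
    """
    if fs <= 0:
        raise ParameterError("fs must be positive")
    t = np.arange(round(BEAT_SPAN[0] * fs), round(BEAT_SPAN[1] * fs)) / fs
    wave = np.zeros_like(t)
    for name, (mu, sigma, amp) in BEAT_BUMPS.items():
        if name == "P" and (not p_wave or ectopic):
            continue
        width = sigma * (1.8 if ectopic and name in ("Q", "R", "S") else 1.0)
        wave += amp * np.exp(-0.5 * ((t - mu) / width) ** 2)
    return wave


def _rr_intervals(rng: np.random.Generator, mean_rr: float, cv: float, total_s: float) -> np.ndarray:
    n_max = int(np.ceil(total_s / mean_rr * 2)) + 4
    if cv == 0:
        rr = np.full(n_max, mean_rr)
    else:
        shape = 1.0 / cv**2
        rr = rng.gamma(shape, mean_rr / shape, size=n_max)
    return rr


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float, band: tuple[float, float], rms: float) -> np.ndarray:
    white = rng.standard_normal(n)
    lo, hi = band
    sos = scipy.signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    shaped = scipy.signal.sosfiltfilt(sos, white)
    current = np.sqrt(np.mean(shaped**2))
    return shaped * (rms / current) if current > 0 else shaped


def synth_ecg(config: SynthConfig) -> EcgRecord:
    """Generate one labelled record; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    n = int(round(config.duration_s * fs))
    signal = np.zeros(n)
    mean_rr = 60.0 / config.heart_rate_bpm
    rr = _rr_intervals(rng, mean_rr, config.rr_cv, config.duration_s)
    ectopic = rng.random(rr.size) < config.ectopic_rate
    rr = np.where(ectopic, rr * 0.6, rr)  # premature: shortened preceding interval
    r_times = np.cumsum(rr)
    for r_t, ect in zip(r_times, ectopic):
        if r_t >= config.duration_s + abs(BEAT_SPAN[0]):
            break
        beat = synth_beat_template(fs, p_wave=config.p_wave, ectopic=bool(ect))
        start = int(round((r_t + BEAT_SPAN[0]) * fs))
        lo, hi = max(start, 0), min(start + beat.size, n)
        if lo < hi:
            signal[lo:hi] += beat[lo - start : hi - start]
    signal *= config.beat_amp
    if config.fib_wave_amp > 0:
        signal += _bandlimited_noise(rng, n, fs, config.fib_wave_band, config.fib_wave_amp)
    if config.wander_amp > 0:
        for f_w in (0.15, 0.33):
            phase = rng.uniform(0, 2 * np.pi)
            signal += (config.wander_amp / 2) * np.sin(2 * np.pi * f_w * np.arange(n) / fs + phase)
    if config.noise_sd > 0:
        signal += rng.normal(0.0, config.noise_sd, size=n)
    return EcgRecord(record_id=f"S{config.seed:06d}", signal=signal, fs=fs, label=config.label)


def synth_dataset(
    per_class_counts: dict[str, int],
    base_seed: int = 0,
    duration_range_s: tuple[float, float] = (9.0, 60.0),
    fs: float = 300.0,
) -> list[EcgRecord]:
    """Generate a labelled dataset with per-class counts.

    Seeds derive from ``base_seed + index`` so records are mutually
    distinct yet reproducible. Durations are drawn uniformly in
    ``duration_range_s`` (9-60 s by default, so a 30 s duration filter
    has both kept and excluded records) and heart rate varies in
    60-90 bpm across records.
    """
    records: list[EcgRecord] = []
    index = 0
    for label in sorted(per_class_counts, key=str):
        count = per_class_counts[label]
        if count < 0:
            raise ParameterError("counts must be >= 0")
        for _ in range(count):
            seed = base_seed + index
            meta_rng = np.random.default_rng(seed + 987654321)
            duration = float(meta_rng.uniform(*duration_range_s))
            hr = float(meta_rng.uniform(60.0, 90.0))
            config = preset_config(
                label, duration_s=duration, fs=fs, heart_rate_bpm=hr, seed=seed
            )
            rec = synth_ecg(config)
            rec.record_id = f"R{index:05d}"
            records.append(rec)
            index += 1
    return records
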