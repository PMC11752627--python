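"""Fixed-duration segmentation and resampling of ECG records.

Records shorter than the target duration (30 s by default) are excluded;
longer records are cut to exactly ``round(duration * fs)`` samples starting
at a configurable offset (the start of the record by default). Kept
segments are typically resampled from the 300 Hz acquisition rate down to
the 128 Hz analysis rate before time-frequency analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import scipy.signal

from afwave.errors import ParameterError
from afwave.records import EcgRecord

DEFAULT_DURATION_S = 30.0
DEFAULT_ANALYSIS_FS = 128.0


@dataclass
class Segment:
    """A fixed-duration cut of a record: samples (mV), fs, label, origin index."""

    record_id: str
    samples: np.ndarray
    fs: float
    label: str
    source_start: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass
class FilterSummary:
    """Bookkeeping for a dataset-wide duration filter pass."""

    kept: int = 0
    excluded: int = 0
    per_class_kept: dict[str, int] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"kept": self.kept, "excluded": self.excluded, "per_class_kept": dict(self.per_class_kept)}


def segment_record(
    record: EcgRecord,
    target_duration_s: float = DEFAULT_DURATION_S,
    source_start: int = 0,
) -> Segment | None:
    """Cut one record to the target duration, or return None (excluded).

    A record is kept iff it holds at least ``round(target_duration_s * fs)``
    samples from ``source_start`` onward; the cut is the half-open window
    ``[source_start, source_start + n_target)``.
    """
    if target_duration_s <= 0:
        raise ParameterError(f"target_duration_s must be positive, got {target_duration_s}")
    if source_start < 0:
        raise ParameterError(f"source_start must be >= 0, got {source_start}")
    n_target = int(round(target_duration_s * record.fs))
    if record.signal.size - source_start < n_target:
        return None
    return Segment(
        record_id=record.record_id,
        samples=record.signal[source_start : source_start + n_target].copy(),
        fs=record.fs,
        label=record.label,
        source_start=source_start,
    )


def filter_dataset(
    records: list[EcgRecord],
    target_duration_s: float = DEFAULT_DURATION_S,
    source_start: int = 0,
) -> tuple[list[Segment], FilterSummary]:
    """Apply :func:`segment_record` to every record, with count bookkeeping."""
    summary = FilterSummary()
    segments: list[Segment] = []
    for rec in records:
        seg = segment_record(rec, target_duration_s, source_start)
        if seg is None:
            summary.excluded += 1
        else:
            summary.kept += 1
            summary.per_class_kept[seg.label] = summary.per_class_kept.get(seg.label, 0) + 1
            segments.append(seg)
    return segments, summary


def resample_segment(segment: Segment, fs_target: float = DEFAULT_ANALYSIS_FS) -> Segment:
    """Resample a segment by polyphase rational-ratio filtering.

    The 300 -> 128 Hz case reduces to the exact ratio 32/75. The output is
    trimmed or edge-padded to exactly ``round(duration * fs_target)``
    samples so downstream shapes are deterministic. Identity when
    ``fs_target == fs``.
    """
    if fs_target <= 0:
        raise ParameterError(f"fs_target must be positive, got {fs_target}")
    if fs_target == segment.fs:
        return segment
    ratio = Fraction(fs_target / segment.fs).limit_denominator(10000)
    up, down = ratio.numerator, ratio.denominator
    resampled = scipy.signal.resample_poly(segment.samples, up, down)
    n_out = int(round(segment.samples.size / segment.fs * fs_target))
    if resampled.size > n_out:
        resampled = resampled[:n_out]
    elif resampled.size < n_out:
        resampled = np.pad(resampled, (0, n_out - resampled.size), mode="edge")
    return Segment(
        record_id=segment.record_id,
        samples=resampled,
        fs=fs_target,
        label=segment.label,
        source_start=segment.source_start,
    )
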