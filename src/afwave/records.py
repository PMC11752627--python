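"""Reading and writing single-lead ECG records in the CinC-2017 layout.

A record is a MATLAB v5 ``.mat`` container holding one integer row vector
named ``val``, with a WFDB-style ``.hea`` text header alongside that
declares the sampling rate and the ADC gain (units per millivolt).
Labels live in a headerless ``REFERENCE.csv`` with rows ``record_id,label``
and the closed label set {N, A, O, ~} (normal, AF, other rhythm, noisy).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import scipy.io

from afwave.errors import FormatError, InputError

logger = logging.getLogger(__name__)

#: Closed set of class symbols: normal, atrial fibrillation, other rhythm, noisy.
CLASS_LABELS = ("N", "A", "O", "~")
UNKNOWN_LABEL = "unknown"

DEFAULT_FS = 300.0
#: CinC-2017 convention: ADC units per millivolt when the header omits gain.
DEFAULT_GAIN = 1000.0


@dataclass
class EcgRecord:
    """A labelled single-lead ECG signal.

    Attributes
    ----------
    record_id : str
        Identifier, e.g. ``"A00001"``.
    signal : np.ndarray
        Samples in millivolts, 1-D float array.
    fs : float
        Sampling rate in Hz.
    label : str
        One of ``N``, ``A``, ``O``, ``~`` or ``"unknown"``.
    """

    record_id: str
    signal: np.ndarray
    fs: float
    label: str = UNKNOWN_LABEL

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float).ravel()
        if self.fs <= 0:
            raise InputError(f"{self.record_id}: sampling rate must be positive, got {self.fs}")
        if self.signal.size < 1:
            raise InputError(f"{self.record_id}: signal is empty")
        if not np.all(np.isfinite(self.signal)):
            raise InputError(f"{self.record_id}: signal contains non-finite samples")
        if self.label not in CLASS_LABELS and self.label != UNKNOWN_LABEL:
            raise InputError(f"{self.record_id}: unknown label {self.label!r}")

    @property
    def duration_s(self) -> float:
        return self.signal.size / self.fs


@dataclass
class LabelTable:
    """Mapping record_id -> class label, from a REFERENCE.csv file."""

    mapping: dict[str, str] = field(default_factory=dict)

    def get(self, record_id: str) -> str:
        return self.mapping.get(record_id, UNKNOWN_LABEL)

    def __len__(self) -> int:
        return len(self.mapping)


def _parse_header(header_path: Path) -> tuple[float, float]:
    """Parse fs and ADC gain from a WFDB-style .hea header.

    Only the two fields the CinC layout uses are read: field 3 of the
    record line (sampling frequency) and field 3 of the first signal
    line (gain, possibly in ``gain(baseline)/units`` form). Missing
    fields fall back to 300 Hz and 1000 units/mV.
    """
    fs, gain = DEFAULT_FS, DEFAULT_GAIN
    if not header_path.exists():
        return fs, gain
    lines = [
        ln.strip()
        for ln in header_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if lines:
        rec_fields = lines[0].split()
        if len(rec_fields) >= 3:
            try:
                fs = float(rec_fields[2])
            except ValueError as exc:
                raise FormatError(f"{header_path}: bad sampling rate field {rec_fields[2]!r}") from exc
    if len(lines) >= 2:
        sig_fields = lines[1].split()
        if len(sig_fields) >= 3:
            token = sig_fields[2]
            # gain field may look like "1000", "1000/mV" or "1000(0)/mV"
            token = token.split("/")[0].split("(")[0]
            try:
                gain = float(token)
            except ValueError as exc:
                raise FormatError(f"{header_path}: bad gain field {sig_fields[2]!r}") from exc
    if fs <= 0 or gain <= 0:
        raise FormatError(f"{header_path}: non-positive fs or gain")
    return fs, gain


def read_record(record_path: str | Path, header_path: str | Path | None = None) -> EcgRecord:
    """Read one MAT + header record pair into an :class:`EcgRecord`.

    Integer ADC samples are converted to millivolts by dividing by the
    header's gain; fs defaults to 300 Hz when the header is absent.
    """
    record_path = Path(record_path)
    if header_path is None:
        header_path = record_path.with_suffix(".hea")
    header_path = Path(header_path)
    if not record_path.exists():
        raise InputError(f"record container not found: {record_path}")
    try:
        container = scipy.io.loadmat(record_path)
    except Exception as exc:
        raise FormatError(f"{record_path}: not a readable MAT container ({exc})") from exc
    if "val" not in container:
        raise FormatError(f"{record_path}: MAT container has no 'val' variable")
    raw = np.asarray(container["val"]).ravel()
    if raw.size == 0:
        raise InputError(f"{record_path}: empty sample vector")
    if not np.issubdtype(raw.dtype, np.number):
        raise FormatError(f"{record_path}: non-numeric samples (dtype {raw.dtype})")
    fs, gain = _parse_header(header_path)
    return EcgRecord(record_id=record_path.stem, signal=raw.astype(float) / gain, fs=fs)


def write_record(record: EcgRecord, out_dir: str | Path, gain: float = DEFAULT_GAIN) -> Path:
    """Write a record in the same MAT + .hea layout :func:`read_record` reads.

    Millivolt samples are quantized to 16-bit ADC units with the given
    gain; the round trip is exact when samples are multiples of 1/gain.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    adc = np.round(record.signal * gain)
    if np.any(np.abs(adc) > np.iinfo(np.int16).max):
        raise InputError(f"{record.record_id}: amplitude exceeds 16-bit ADC range at gain {gain}")
    mat_path = out_dir / f"{record.record_id}.mat"
    scipy.io.savemat(mat_path, {"val": adc.astype(np.int16)[None, :]})
    hea_path = out_dir / f"{record.record_id}.hea"
    n = record.signal.size
    hea_path.write_text(
        f"{record.record_id} 1 {record.fs:g} {n}\n"
        f"{record.record_id}.mat 16 {gain:g}/mV 16 0 0 0 0 ECG\n"
    )
    return mat_path


def read_labels(csv_path: str | Path) -> LabelTable:
    """Read a headerless ``record_id,label`` REFERENCE.csv into a LabelTable."""
    csv_path = Path(csv_path)
    if not csv_path.exists():
        raise InputError(f"labels file not found: {csv_path}")
    mapping: dict[str, str] = {}
    with open(csv_path, newline="") as fh:
        for i, row in enumerate(csv.reader(fh)):
            if not row:
                continue
            if len(row) != 2:
                raise FormatError(f"{csv_path}:{i + 1}: expected 'record_id,label', got {row!r}")
            rid, label = row[0].strip(), row[1].strip()
            if label not in CLASS_LABELS:
                raise FormatError(f"{csv_path}:{i + 1}: label {label!r} outside {{N,A,O,~}}")
            if rid in mapping:
                raise FormatError(f"{csv_path}:{i + 1}: duplicate record_id {rid!r}")
            mapping[rid] = label
    return LabelTable(mapping)


def write_labels(records: Iterable[EcgRecord], csv_path: str | Path) -> Path:
    csv_path = Path(csv_path)
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for rec in records:
            writer.writerow([rec.record_id, rec.label])
    return csv_path


def load_dataset(
    records_dir: str | Path,
    labels_path: str | Path | None = None,
    strict: bool = False,
) -> tuple[list[EcgRecord], int]:
    """Load every ``*.mat`` record in a directory, labels attached.

    Records are returned in ascending record_id order. Unreadable records
    are skipped with a logged warning (counted in the second return value)
    unless ``strict`` is set, in which case the first failure raises.
    """
    records_dir = Path(records_dir)
    if not records_dir.is_dir():
        raise InputError(f"records directory not found: {records_dir}")
    labels = LabelTable()
    if labels_path is None:
        default = records_dir / "REFERENCE.csv"
        if default.exists():
            labels = read_labels(default)
    else:
        labels = read_labels(labels_path)
    out: list[EcgRecord] = []
    skipped = 0
    for mat_path in sorted(records_dir.glob("*.mat"), key=lambda p: p.stem):
        try:
            rec = read_record(mat_path)
        except Exception as exc:
            if strict:
                raise
            logger.warning("skipping unreadable record %s: %s", mat_path.name, exc)
            skipped += 1
            continue
        rec.label = labels.get(rec.record_id)
        out.append(rec)
    return out, skipped


def read_plain_signal(path: str | Path, fs: float, record_id: str | None = None) -> EcgRecord:
    """Read a one-column delimited text signal (values already in mV)."""
    path = Path(path)
    if fs <= 0:
        raise InputError("fs must be positive")
    try:
        values = np.loadtxt(path, ndmin=1)
    except Exception as exc:
        raise FormatError(f"{path}: not a one-column numeric file ({exc})") from exc
    return EcgRecord(record_id=record_id or path.stem, signal=values, fs=fs)
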