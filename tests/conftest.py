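import numpy as np
import pytest

from afwave.records import EcgRecord, write_labels, write_record


@pytest.fixture
def record_dir(tmp_path):
    """Three quantized records (60 s, 30 s, 9 s at 300 Hz) with labels."""
    rng = np.random.default_rng(42)
    specs = [("A00001", 60.0, "N"), ("A00002", 30.0, "A"), ("A00003", 9.0, "O")]
    records = []
    for rid, dur, label in specs:
        sig = np.round(rng.normal(0.0, 0.3, size=int(dur * 300)) * 1000) / 1000
        records.append(EcgRecord(record_id=rid, signal=sig, fs=300.0, label=label))
    d = tmp_path / "records"
    for rec in records:
        write_record(rec, d)
    write_labels(records, d / "REFERENCE.csv")
    return d, records
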