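"""EDF reading and writing.

Reading goes through MNE's native EDF reader.  Writing uses a small plain-EDF
writer (16-bit samples, 1 s data records, physical units uV) implemented here;
its round trip is validated against the MNE reader in the test suite.  Event
markers are carried in the trial-log CSV alongside each recording rather than
as EDF+ annotations.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np

from .synth import EegRecording

__all__ = ["write_edf", "read_edf"]

_HDR_DATE = "01.01.24"
_HDR_TIME = "00.00.00"


def _field(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field too long: {text!r} (> {width})")
    return b.ljust(width)


def write_edf(rec: EegRecording, path) -> None:
    """Write a plain EDF file: one signal per channel, 1 s records, 16-bit.

    Physical range is set symmetrically per channel from the data; the last
    record is zero-padded (EDF stores whole records only).
    """
    fs = rec.sample_rate_hz
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sample rate")
    fs = int(round(fs))
    n_ch = len(rec.channel_labels)
    n_records = int(np.ceil(rec.n_samples / fs))
    header_bytes = 256 * (1 + n_ch)

    phys_max = np.maximum(np.abs(rec.data).max(axis=1), 1e-6)
    phys_max = np.ceil(phys_max * 1.01)  # headroom so extremes stay in range
    phys_min = -phys_max
    dig_max, dig_min = 32767, -32768

    with open(Path(path), "wb") as fh:
        fh.write(_field("0", 8))
        fh.write(_field("X X X X", 80))  # local patient id (anonymous)
        fh.write(_field("Startdate X X X X", 80))
        fh.write(_field(_HDR_DATE, 8))
        fh.write(_field(_HDR_TIME, 8))
        fh.write(_field(str(header_bytes), 8))
        fh.write(_field("", 44))
        fh.write(_field(str(n_records), 8))
        fh.write(_field("1", 8))  # record duration, seconds
        fh.write(_field(str(n_ch), 4))
        for lab in rec.channel_labels:
            fh.write(_field(f"EEG {lab}", 16))
        for _ in range(n_ch):
            fh.write(_field("AgAgCl electrode", 80))
        for _ in range(n_ch):
            fh.write(_field("uV", 8))
        for v in phys_min:
            fh.write(_field(f"{v:g}", 8))
        for v in phys_max:
            fh.write(_field(f"{v:g}", 8))
        for _ in range(n_ch):
            fh.write(_field(str(dig_min), 8))
        for _ in range(n_ch):
            fh.write(_field(str(dig_max), 8))
        for _ in range(n_ch):
            fh.write(_field("BP:1-36Hz", 80))
        for _ in range(n_ch):
            fh.write(_field(str(fs), 8))
        for _ in range(n_ch):
            fh.write(_field("", 32))

        total = n_records * fs
        padded = np.zeros((n_ch, total))
        padded[:, : rec.n_samples] = rec.data
        scale = (dig_max - dig_min) / (phys_max - phys_min)
        digital = np.rint((padded - phys_min[:, None]) * scale[:, None] + dig_min)
        digital = np.clip(digital, dig_min, dig_max).astype("<i2")
        for r in range(n_records):
            fh.write(digital[:, r * fs:(r + 1) * fs].tobytes())


def read_edf(path, required_channels: tuple[str, ...] = ("F8", "Fp1", "M1", "M2"),
             reference_label: str = "CPz") -> EegRecording:
    """Load an EDF recording via MNE; amplitudes converted to uV.

    Raises if any of ``required_channels`` is absent (named in the error).
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    labels = [ch.removeprefix("EEG ").strip() for ch in raw.ch_names]
    missing = [c for c in required_channels if c not in labels]
    if missing:
        raise ValueError(f"EDF file {path} missing required channel(s): {missing}")
    data = raw.get_data() * 1e6  # MNE loads EEG in volts
    return EegRecording(labels, float(raw.info["sfreq"]), data, [],
                        reference_label=reference_label)
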