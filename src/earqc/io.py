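"""EDF import/export and report serialization.

Reading goes through MNE's EDF/BDF reader.  Writing uses a compact EDF
writer (16-bit EDF, one-second data records) sufficient for round-tripping
simulated sessions and exporting aligned data; it is round-trip tested
against MNE's independent reader.
"""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

from .recording import Recording

__all__ = ["write_edf", "read_edf", "write_json"]

TRIGGER_LABEL = "TRIG"


def _ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _phys_str(v: float) -> str:
    """Physical min/max in positional notation fitting the 8-char field."""
    return np.format_float_positional(v, precision=7, unique=False)[:8].rstrip(".")


def write_edf(path: str | Path, rec: Recording) -> Path:
    """Write a recording (plus its trigger channel, if any) as 16-bit EDF.

    Requires an integer sampling rate; uses 1-s data records and pads the
    final partial second with zeros.  Physical units are microvolts.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    fs = int(round(fs))
    labels = list(rec.labels)
    data = [rec.data[i] for i in range(rec.n_channels)]
    if rec.trigger is not None:
        labels.append(TRIGGER_LABEL)
        data.append(rec.trigger)
    ns = len(labels)
    n_samples = max(x.size for x in data)
    n_records = int(np.ceil(n_samples / fs))

    phys_min, phys_max, scaled = [], [], []
    for x in data:
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi <= lo:
            lo, hi = lo - 1.0, lo + 1.0
        span = hi - lo
        lo, hi = lo - 0.01 * span, hi + 0.01 * span
        # digitize against the values as printed in the 8-char header field,
        # otherwise readers reconstruct with a slightly different scale
        lo = float(_phys_str(lo))
        hi = float(_phys_str(hi))
        phys_min.append(lo)
        phys_max.append(hi)
        pad = np.zeros(n_records * fs)
        pad[: x.size] = x
        dig = np.round(
            (pad - lo) / (hi - lo) * (32767 - (-32768)) + (-32768)
        ).astype("<i2")
        scaled.append(dig)

    start = datetime(2024, 1, 1, 12, 0, 0, tzinfo=timezone.utc)
    header = b""
    header += _ascii("0", 8)  # version
    header += _ascii("X X X X", 80)  # patient id (anonymous)
    header += _ascii(f"Startdate 01-JAN-2024 X X {rec.meta.get('device', 'X')}", 80)
    header += _ascii(start.strftime("%d.%m.%y"), 8)
    header += _ascii(start.strftime("%H.%M.%S"), 8)
    header += _ascii(256 * (ns + 1), 8)  # header bytes
    header += _ascii("", 44)  # reserved
    header += _ascii(n_records, 8)
    header += _ascii(1, 8)  # record duration, s
    header += _ascii(ns, 4)
    for lb in labels:
        header += _ascii(lb, 16)
    for _ in labels:
        header += _ascii("Simulated" if rec.meta.get("device") else "", 80)
    for _ in labels:
        header += _ascii("uV", 8)
    for v in phys_min:
        header += _ascii(_phys_str(v), 8)
    for v in phys_max:
        header += _ascii(_phys_str(v), 8)
    for _ in labels:
        header += _ascii(-32768, 8)
    for _ in labels:
        header += _ascii(32767, 8)
    for _ in labels:
        header += _ascii("", 80)  # prefiltering
    for _ in labels:
        header += _ascii(fs, 8)  # samples per record
    for _ in labels:
        header += _ascii("", 32)  # reserved

    path = Path(path)
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            for dig in scaled:
                fh.write(dig[r * fs : (r + 1) * fs].tobytes())
    return path


def read_edf(path: str | Path, trigger_label: str = TRIGGER_LABEL) -> Recording:
    """Read an EDF/BDF file into a :class:`Recording` (microvolts).

    A channel named ``TRIG`` (if present) is moved to the trigger slot.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose=False)
    data = raw.get_data() * 1e6  # MNE returns volts for uV-dimensioned EEG
    labels = list(raw.ch_names)
    trigger = None
    if trigger_label in labels:
        idx = labels.index(trigger_label)
        trigger = data[idx]
        keep = [i for i in range(len(labels)) if i != idx]
        data = data[keep]
        labels = [labels[i] for i in keep]
    return Recording(
        labels=labels,
        data=data,
        fs=float(raw.info["sfreq"]),
        trigger=trigger,
        meta={"source": str(path)},
    )


def write_json(path: str | Path, payload: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        return str(o)

    path.write_text(json.dumps(payload, indent=2, default=_default))
    return path
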