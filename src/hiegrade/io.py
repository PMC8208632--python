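"""EDF input/output and TFD caching.

Reading goes through MNE's EDF reader.  Writing uses a small built-in
16-bit EDF encoder (plain ASCII header plus little-endian int16 data
records) sufficient for the synthetic recordings this package generates:
one fixed sampling rate, physical range +/-800 uV.
"""

from __future__ import annotations

import datetime as _dt
import json
from pathlib import Path

import numpy as np

from .preprocess import EegRecording
from .tfd import TfdMatrix

__all__ = ["read_edf", "write_edf", "save_tfd", "load_tfd"]

PHYS_MIN, PHYS_MAX = -800.0, 800.0
DIG_MIN, DIG_MAX = -32768, 32767


def read_edf(path) -> EegRecording:
    """Load an EDF/EDF+ recording as microvolt samples."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    return EegRecording(
        samples=data,
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
    )


def _field(text: str, width: int) -> bytes:
    s = str(text)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: EegRecording, path) -> Path:
    """Write a recording as 16-bit EDF (physical range +/-800 uV).

    The sampling rate must be an integer; data are chunked into 1-second
    records and zero-padded to a whole number of seconds.
    """
    fs = int(round(rec.fs))
    if abs(fs - rec.fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    if np.max(np.abs(rec.samples)) > PHYS_MAX:
        raise ValueError(f"samples exceed the physical range +/-{PHYS_MAX} uV")
    path = Path(path)
    ns = rec.n_channels
    n_records = int(np.ceil(rec.n_times / fs))
    padded = np.zeros((ns, n_records * fs))
    padded[:, : rec.n_times] = rec.samples

    scale = (DIG_MAX - DIG_MIN) / (PHYS_MAX - PHYS_MIN)
    digital = np.round((padded - PHYS_MIN) * scale + DIG_MIN).astype("<i2")

    now = _dt.datetime(2000, 1, 1)
    header = b"".join(
        [
            _field("0", 8),
            _field("X X X X", 80),  # patient id
            _field("Startdate X X X X", 80),  # recording id
            _field(now.strftime("%d.%m.%y"), 8),
            _field(now.strftime("%H.%M.%S"), 8),
            _field(str(256 + ns * 256), 8),
            _field("", 44),
            _field(str(n_records), 8),
            _field("1", 8),  # record duration, seconds
            _field(str(ns), 4),
        ]
    )
    labels = b"".join(_field(lbl, 16) for lbl in rec.channel_labels)
    transducer = b"".join(_field("", 80) for _ in range(ns))
    dim = b"".join(_field("uV", 8) for _ in range(ns))
    pmin = b"".join(_field(f"{PHYS_MIN:g}", 8) for _ in range(ns))
    pmax = b"".join(_field(f"{PHYS_MAX:g}", 8) for _ in range(ns))
    dmin = b"".join(_field(str(DIG_MIN), 8) for _ in range(ns))
    dmax = b"".join(_field(str(DIG_MAX), 8) for _ in range(ns))
    prefilter = b"".join(_field("", 80) for _ in range(ns))
    nsamp = b"".join(_field(str(fs), 8) for _ in range(ns))
    reserved = b"".join(_field("", 32) for _ in range(ns))

    with open(path, "wb") as fh:
        fh.write(header + labels + transducer + dim + pmin + pmax + dmin
                 + dmax + prefilter + nsamp + reserved)
        for r in range(n_records):
            fh.write(digital[:, r * fs : (r + 1) * fs].tobytes())
    return path


def save_tfd(tfd: TfdMatrix, path) -> Path:
    """Cache a TFD image as .npy with a JSON metadata sidecar."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), tfd.values)
    sidecar = {
        "time_step_s": tfd.time_step_s,
        "freq_step_hz": tfd.freq_step_hz,
        "freq_offset_hz": tfd.freq_offset_hz,
        "meta": {k: (v.item() if isinstance(v, np.generic) else v)
                 for k, v in tfd.meta.items()},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path.with_suffix(".npy")


def load_tfd(path) -> TfdMatrix:
    path = Path(path)
    values = np.load(path.with_suffix(".npy"))
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return TfdMatrix(values=values, **{k: sidecar[k] for k in
                                       ("time_step_s", "freq_step_hz",
                                        "freq_offset_hz", "meta")})
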