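"""Synthetic neonatal EEG for the four HIE background grades.

No clinical data ship with this package.  The generator emulates the
grading scheme's defining features so that every downstream module is
testable end to end:

* grade 1 - continuous background activity (coloured 1/f^alpha noise);
* grade 2 - discontinuous: bursts alternating with interburst intervals
  (IBIs) shorter than 10 s;
* grade 3 - discontinuous with IBIs of 10-60 s;
* grade 4 - either continuous activity below 10 uV, or severe
  discontinuity with IBIs above 60 s.

Because a hypoxic-ischaemic injury is global, burst timing is shared
across channels while the noise itself is independent per channel.  Burst
edges use raised-cosine ramps.  Sleep-wake cycling and inter-hemispheric
asynchrony are deliberately not modelled: the aim is label-faithful,
separable classes, not clinical realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import STANDARD_ELECTRODES, EegRecording

__all__ = [
    "GradeModelParams",
    "generate_epoch",
    "inject_artifacts",
    "make_dataset",
]


@dataclass(frozen=True)
class GradeModelParams:
    """Generative parameters for one background grade.

    Amplitudes are RMS scales in uV; interburst and burst durations are
    drawn uniformly from their (min, max) ranges in seconds;
    ``spectral_slope`` is the 1/f^alpha exponent of the background noise.
    Grade 4 has two modes: ``ibi_range_s=None`` selects the low-amplitude
    (< 10 uV throughout) mode, otherwise IBIs must exceed 60 s.
    """

    grade: int
    background_amp_uv: float = 25.0
    burst_amp_uv: float = 50.0
    suppressed_amp_uv: float = 3.0
    ibi_range_s: tuple[float, float] | None = None
    burst_range_s: tuple[float, float] = (3.0, 8.0)
    spectral_slope: float = 1.5
    ramp_s: float = 0.5

    def __post_init__(self) -> None:
        if self.grade not in (1, 2, 3, 4):
            raise ValueError("grade must be 1-4")
        r = self.ibi_range_s
        if self.grade == 1 and r is not None:
            raise ValueError("grade 1 is continuous: no interburst intervals")
        if self.grade == 2 and not (r and 0 < r[0] <= r[1] < 10):
            raise ValueError("grade 2 requires IBIs within (0, 10) s")
        if self.grade == 3 and not (r and 10 <= r[0] <= r[1] <= 60):
            raise ValueError("grade 3 requires IBIs within [10, 60] s")
        if self.grade == 4 and r is not None and r[0] <= 60:
            raise ValueError(
                "grade 4 requires IBIs > 60 s (or ibi_range_s=None for the "
                "low-amplitude mode)"
            )

    @classmethod
    def for_grade(cls, grade: int) -> "GradeModelParams":
        """Default study conditions per grade."""
        if grade == 1:
            return cls(grade=1, background_amp_uv=25.0)
        if grade == 2:
            return cls(grade=2, ibi_range_s=(2.0, 8.0), burst_range_s=(3.0, 8.0))
        if grade == 3:
            return cls(grade=3, ibi_range_s=(10.0, 60.0), burst_range_s=(2.0, 6.0))
        if grade == 4:
            return cls(grade=4, background_amp_uv=5.0, ibi_range_s=None)
        raise ValueError("grade must be 1-4")


def _coloured_noise(
    rng: np.random.Generator,
    n: int,
    fs: float,
    alpha: float,
    band: tuple[float, float] = (0.5, 30.0),
) -> np.ndarray:
    """Unit-RMS noise with power ~ 1/f^alpha inside ``band``, rolled off outside."""
    freqs = np.fft.rfftfreq(n, 1 / fs)
    shape = np.zeros_like(freqs)
    inside = (freqs >= band[0]) & (freqs <= band[1])
    shape[inside] = freqs[inside] ** (-alpha / 2)
    # gentle roll-off below the band keeps a little slow activity
    below = (freqs > 0) & (freqs < band[0])
    shape[below] = band[0] ** (-alpha / 2) * (freqs[below] / band[0]) ** 2
    spec = shape * (rng.normal(size=freqs.size) + 1j * rng.normal(size=freqs.size))
    x = np.fft.irfft(spec, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _burst_schedule(
    rng: np.random.Generator, params: GradeModelParams, duration_s: float
) -> list[tuple[str, float, float]]:
    """Alternating (kind, start, end) annotation covering the epoch."""
    events = []
    t = 0.0
    kind = "burst"
    while t < duration_s:
        if kind == "burst":
            dur = rng.uniform(*params.burst_range_s)
        else:
            dur = rng.uniform(*params.ibi_range_s)
        end = min(t + dur, duration_s)
        events.append((kind, t, end))
        t = end
        kind = "ibi" if kind == "burst" else "burst"
    return events


def _amplitude_profile(
    events, params: GradeModelParams, n: int, fs: float
) -> np.ndarray:
    """Raised-cosine envelope switching between burst and suppressed RMS."""
    hi, lo = params.burst_amp_uv, params.suppressed_amp_uv
    t = np.arange(n) / fs
    env = np.full(n, lo)
    ramp = max(params.ramp_s, 1.0 / fs)
    for kind, start, end in events:
        if kind != "burst":
            continue
        rise = np.clip((t - start) / ramp, 0, 1)
        fall = np.clip((end - t) / ramp, 0, 1)
        w = 0.5 * (1 - np.cos(np.pi * rise)) * 0.5 * (1 - np.cos(np.pi * fall))
        env = np.maximum(env, lo + (hi - lo) * w)
    return env


def generate_epoch(
    params: GradeModelParams,
    duration_s: float = 3600.0,
    n_channels: int = 9,
    fs: float = 64.0,
    seed: int | None = None,
    channel_labels: list[str] | None = None,
) -> tuple[EegRecording, pd.DataFrame]:
    """Generate one labelled multichannel epoch plus its annotation.

    Returns the recording and a data frame of (kind, start_s, end_s) rows
    listing every burst and interburst interval ("background" for the
    continuous grades).  Burst timing is shared across channels.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    if channel_labels is None:
        if n_channels == len(STANDARD_ELECTRODES):
            channel_labels = list(STANDARD_ELECTRODES)
        else:
            channel_labels = [f"CH{i + 1}" for i in range(n_channels)]

    discontinuous = params.ibi_range_s is not None
    if discontinuous:
        events = _burst_schedule(rng, params, duration_s)
        env = _amplitude_profile(events, params, n, fs)
    else:
        events = [("background", 0.0, duration_s)]
        env = np.full(n, params.background_amp_uv)

    chans = np.empty((n_channels, n))
    for ci in range(n_channels):
        noise = _coloured_noise(rng, n, fs, params.spectral_slope)
        x = noise * env
        if params.grade == 4 and not discontinuous:
            # hard guarantee of the sub-10 uV amplitude bound
            peak = np.max(np.abs(x))
            if peak >= 9.5:
                x *= 9.5 / peak
        chans[ci] = x

    rec = EegRecording(samples=chans, fs=fs, channel_labels=channel_labels)
    ann = pd.DataFrame(events, columns=["kind", "start_s", "end_s"])
    return rec, ann


def inject_artifacts(
    rec: EegRecording,
    spike_rate_per_min: float = 1.0,
    amp_range_uv: tuple[float, float] = (320.0, 600.0),
    seed: int | None = None,
) -> tuple[EegRecording, pd.DataFrame]:
    """Add short high-amplitude movement-like transients at Poisson times.

    Each transient is a Hann-windowed 4-8 Hz oscillation of 0.2-2 s on one
    randomly chosen channel.  Ground-truth intervals are returned so the
    detector can be validated round-trip.
    """
    lo, hi = amp_range_uv
    if not (100.0 < lo <= hi < 1000.0):
        raise ValueError("artefact amplitudes must lie within (100, 1000) uV")
    rng = np.random.default_rng(seed)
    out = rec.samples.copy()
    n = rec.n_times
    n_events = rng.poisson(spike_rate_per_min * rec.duration_s / 60.0)
    rows = []
    for _ in range(n_events):
        dur = rng.uniform(0.2, 2.0)
        width = max(int(round(dur * rec.fs)), 3)
        start = int(rng.integers(0, max(n - width, 1)))
        ci = int(rng.integers(0, rec.n_channels))
        amp = rng.uniform(lo, hi)
        f0 = rng.uniform(4.0, 8.0)
        t = np.arange(width) / rec.fs
        burst = amp * np.hanning(width) * np.sin(2 * np.pi * f0 * t)
        out[ci, start : start + width] += burst
        rows.append(
            {"channel": rec.channel_labels[ci], "start_s": start / rec.fs,
             "end_s": (start + width) / rec.fs, "amp_uv": amp}
        )
    noisy = EegRecording(out, rec.fs, list(rec.channel_labels), rec.start_time)
    return noisy, pd.DataFrame(
        rows, columns=["channel", "start_s", "end_s", "amp_uv"]
    )


def make_dataset(
    n_subjects: int,
    grade_mix: tuple[int, int, int, int],
    duration_s: float = 3600.0,
    seed: int = 0,
    out_dir: str | Path = "synthetic_dataset",
    fs: float = 64.0,
) -> pd.DataFrame:
    """Write one EDF per synthetic subject plus a manifest CSV.

    ``grade_mix`` gives subject counts per grade (must sum to
    ``n_subjects``).  Returns the manifest (path, subject_id, grade).
    """
    from .io import write_edf

    if sum(grade_mix) != n_subjects or n_subjects <= 0:
        raise ValueError("grade_mix must sum to a positive n_subjects")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    subject = 0
    for grade, count in zip((1, 2, 3, 4), grade_mix):
        for _ in range(count):
            subject += 1
            sid = f"S{subject:03d}"
            rec, ann = generate_epoch(
                GradeModelParams.for_grade(grade),
                duration_s=duration_s,
                fs=fs,
                seed=seed * 10_000 + subject,
            )
            path = out_dir / f"{sid}_grade{grade}.edf"
            write_edf(rec, path)
            ann.to_csv(out_dir / f"{sid}_annotation.csv", index=False)
            rows.append({"path": str(path), "subject_id": sid, "grade": grade})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
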