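"""Front-end conditioning of multichannel neonatal EEG.

Derives the 8-channel bipolar montage from the standard 9-electrode NICU
set, low-pass filters with a zero-phase FIR, resamples to 64 Hz, and cuts
overlapping 5-minute single-channel segments for the time-frequency
transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import signal

__all__ = [
    "EegRecording",
    "MontageSpec",
    "EegSegment",
    "STANDARD_ELECTRODES",
    "derive_montage",
    "lowpass_and_resample",
    "segment_epoch",
]

#: referential electrodes of the standard NICU recording protocol
STANDARD_ELECTRODES = ("F4", "C4", "O2", "F3", "C3", "O1", "T4", "T3", "Cz")

#: bipolar pairs of the 8-channel analysis montage, in canonical order
DEFAULT_PAIRS = (
    ("F4", "C4"),
    ("C4", "O2"),
    ("F3", "C3"),
    ("C3", "O1"),
    ("T4", "C4"),
    ("C4", "Cz"),
    ("Cz", "C3"),
    ("C3", "T3"),
)

#: occipital electrodes may be replaced by parietal ones at some sites
DEFAULT_FALLBACKS = {"O1": "P3", "O2": "P4"}


class MissingElectrodeError(KeyError):
    """An electrode required by the montage cannot be resolved."""


@dataclass
class EegRecording:
    """Multichannel EEG time series in microvolts.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_times)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_labels : sequence of str
        Unique channel names (electrodes or bipolar pairs such as "F4-C4").
    start_time : float or None
        Optional recording onset in seconds since an arbitrary origin.
    """

    samples: np.ndarray
    fs: float
    channel_labels: Sequence[str]
    start_time: float | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (channels x time) matrix")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.channel_labels = list(self.channel_labels)
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(lbl.upper() for lbl in self.channel_labels)) != len(
            self.channel_labels
        ):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_times / self.fs

    def channel(self, label: str) -> np.ndarray:
        idx = _label_index(self.channel_labels)
        try:
            return self.samples[idx[label.upper()]]
        except KeyError:
            raise MissingElectrodeError(label) from None


@dataclass
class MontageSpec:
    """Ordered bipolar derivation with per-electrode fallbacks."""

    pairs: Sequence[tuple[str, str]] = DEFAULT_PAIRS
    fallbacks: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_FALLBACKS))

    def __post_init__(self) -> None:
        self.pairs = [tuple(p) for p in self.pairs]
        if len(self.pairs) == 0:
            raise ValueError("montage needs at least one pair")

    @property
    def labels(self) -> list[str]:
        return [f"{a}-{c}" for a, c in self.pairs]


@dataclass
class EegSegment:
    """A single-channel analysis window (default 300 s at 64 Hz)."""

    samples: np.ndarray
    channel: str
    fs: float = 64.0
    epoch_id: str | int | None = None
    segment_index: int = 0
    channel_index: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("segment contains non-finite values")

    @property
    def n_times(self) -> int:
        return self.samples.size


def _label_index(labels: Sequence[str]) -> dict[str, int]:
    return {lbl.upper(): i for i, lbl in enumerate(labels)}


def _resolve(label: str, idx: dict[str, int], fallbacks: dict[str, str]) -> int:
    key = label.upper()
    if key in idx:
        return idx[key]
    fb = fallbacks.get(label) or fallbacks.get(key)
    if fb is not None and fb.upper() in idx:
        return idx[fb.upper()]
    raise MissingElectrodeError(
        f"electrode {label!r} (fallback {fb!r}) not present in recording"
    )


def derive_montage(rec: EegRecording, spec: MontageSpec | None = None) -> EegRecording:
    """Form bipolar channels as anode minus cathode, in spec order.

    Label matching is case-insensitive; occipital electrodes fall back to
    their parietal replacements (O1->P3, O2->P4) when absent.
    """
    if spec is None:
        spec = MontageSpec()
    idx = _label_index(rec.channel_labels)
    rows = []
    for anode, cathode in spec.pairs:
        ia = _resolve(anode, idx, spec.fallbacks)
        ic = _resolve(cathode, idx, spec.fallbacks)
        rows.append(rec.samples[ia] - rec.samples[ic])
    return EegRecording(
        samples=np.vstack(rows),
        fs=rec.fs,
        channel_labels=spec.labels,
        start_time=rec.start_time,
    )


def lowpass_and_resample(
    rec: EegRecording,
    cutoff_hz: float = 30.0,
    target_fs: float = 64.0,
    taps: int = 4001,
) -> EegRecording:
    """Zero-phase Hamming-window FIR low-pass, then resample to 64 Hz.

    The linear-phase FIR is designed at the input rate and applied with its
    constant group delay (taps-1)/2 compensated, giving net zero phase.
    Resampling is polyphase over the rational ratio target_fs/fs.
    """
    if rec.fs < target_fs:
        raise ValueError(
            f"input rate {rec.fs} Hz below target {target_fs} Hz; upsampling "
            "is not supported"
        )
    if taps % 2 == 0:
        raise ValueError("taps must be odd for a symmetric zero-phase FIR")
    h = signal.firwin(taps, cutoff_hz, window="hamming", fs=rec.fs)
    # 'same' centres the symmetric kernel on each sample: group delay removed
    filtered = np.stack(
        [signal.fftconvolve(ch, h, mode="same") for ch in rec.samples]
    )
    if rec.fs == target_fs:
        out = filtered
    else:
        ratio = Fraction(target_fs / rec.fs).limit_denominator(10_000)
        out = signal.resample_poly(filtered, ratio.numerator, ratio.denominator, axis=1)
    return EegRecording(
        samples=out,
        fs=target_fs,
        channel_labels=list(rec.channel_labels),
        start_time=rec.start_time,
    )


def segment_epoch(
    rec: EegRecording,
    win_s: float = 300.0,
    overlap: float = 0.5,
    epoch_id: str | int | None = None,
) -> list[EegSegment]:
    """Cut each channel into overlapping fully-contained windows.

    Windows advance by ``win_s * (1 - overlap)``; a trailing partial window
    is dropped so every segment has exactly ``win_s * fs`` samples.
    """
    if not 0 <= overlap < 1:
        raise ValueError("overlap must lie in [0, 1)")
    win = int(round(win_s * rec.fs))
    hop = int(round(win_s * (1 - overlap) * rec.fs))
    if rec.n_times < win:
        warnings.warn(
            f"epoch of {rec.duration_s:.0f} s shorter than one {win_s:.0f} s "
            "window; no segments produced",
            stacklevel=2,
        )
        return []
    n_seg = (rec.n_times - win) // hop + 1
    segments = []
    for ci, label in enumerate(rec.channel_labels):
        for si in range(n_seg):
            start = si * hop
            segments.append(
                EegSegment(
                    samples=rec.samples[ci, start : start + win],
                    channel=label,
                    fs=rec.fs,
                    epoch_id=epoch_id,
                    segment_index=si,
                    channel_index=ci,
                )
            )
    return segments
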