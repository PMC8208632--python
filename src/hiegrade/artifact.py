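"""Two-stage high-amplitude artefact detection.

Movement of electrode leads produces brief, very large deflections.  After
band-pass filtering (0.5-10 Hz, 5th-order Butterworth, forward-backward),
the signal envelope (magnitude of the analytic signal) is thresholded in
two stages:

* stage 1 - any envelope sample above 300 uV flags a 10 s collar on both
  sides, on every channel of the same hemisphere (such artefacts are
  rarely confined to one electrode);
* stage 2 - on each channel's residual (samples at or below 300 uV), any
  envelope sample above 100 uV flags a 3 s collar on that channel only.

The final mask is the union; %artefact summarises flagged time per channel
and pooled over the epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import signal
from scipy.signal import hilbert

from .preprocess import EegRecording

__all__ = [
    "ArtifactMask",
    "DEFAULT_HEMISPHERES",
    "artifact_bandpass",
    "envelope",
    "detect_artifacts",
    "percent_artifact",
]

#: hemisphere of each default bipolar channel; odd-numbered electrodes are
#: left, even-numbered right; Cz-containing pairs take the side of the
#: lateral electrode (there are no midline channels in the analysis)
DEFAULT_HEMISPHERES = {
    "F4-C4": "right",
    "C4-O2": "right",
    "C4-P4": "right",
    "T4-C4": "right",
    "C4-Cz": "right",
    "F3-C3": "left",
    "C3-O1": "left",
    "C3-P3": "left",
    "Cz-C3": "left",
    "C3-T3": "left",
}


@dataclass
class ArtifactMask:
    """Boolean artefact annotation at signal resolution."""

    mask: np.ndarray  # (n_channels, n_times) bool
    fs: float
    channel_labels: list[str]
    hemisphere_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def percent(self) -> float:
        """Pooled %artefact over all channel-time."""
        return 100.0 * self.mask.mean() if self.mask.size else 0.0

    @property
    def percent_per_channel(self) -> dict[str, float]:
        return {
            lbl: 100.0 * float(row.mean())
            for lbl, row in zip(self.channel_labels, self.mask)
        }

    def intervals(self) -> pd.DataFrame:
        """Flagged runs as (channel, start_s, end_s) rows."""
        rows = []
        for lbl, row in zip(self.channel_labels, self.mask):
            edges = np.flatnonzero(np.diff(row.astype(np.int8)))
            starts = list(edges[row[edges + 1]] + 1)
            ends = list(edges[~row[edges + 1]] + 1)
            if row[0]:
                starts = [0] + starts
            if row[-1]:
                ends = ends + [row.size]
            for s, e in zip(starts, ends):
                rows.append({"channel": lbl, "start_s": s / self.fs,
                             "end_s": e / self.fs})
        return pd.DataFrame(rows, columns=["channel", "start_s", "end_s"])


def artifact_bandpass(
    rec: EegRecording, low_hz: float = 0.5, high_hz: float = 10.0, order: int = 5
) -> EegRecording:
    """5th-order Butterworth band-pass, forward-backward (phase neutral)."""
    if rec.fs <= 2 * high_hz:
        raise ValueError(
            f"sampling rate {rec.fs} Hz too low for a {high_hz} Hz passband"
        )
    sos = signal.butter(order, (low_hz, high_hz), btype="bandpass",
                        fs=rec.fs, output="sos")
    out = signal.sosfiltfilt(sos, rec.samples, axis=1)
    return EegRecording(out, rec.fs, list(rec.channel_labels), rec.start_time)


def envelope(x: np.ndarray) -> np.ndarray:
    """Signal envelope: magnitude of the analytic associate."""
    return np.abs(hilbert(np.asarray(x, dtype=float)))


def _collar_mask(flags: np.ndarray, collar_samples: int) -> np.ndarray:
    """Union of [i - collar, i + collar] over flagged samples i (clipped)."""
    out = np.zeros(flags.size, dtype=bool)
    idx = np.flatnonzero(flags)
    if idx.size == 0:
        return out
    # merge into intervals first; far cheaper than dilating sample-wise
    starts = np.maximum(idx - collar_samples, 0)
    ends = np.minimum(idx + collar_samples + 1, flags.size)
    s0, e0 = starts[0], ends[0]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= e0:
            e0 = max(e0, e)
        else:
            out[s0:e0] = True
            s0, e0 = s, e
    out[s0:e0] = True
    return out


def detect_artifacts(
    rec: EegRecording,
    hemisphere_map: Mapping[str, str] | None = None,
    stage1_threshold_uv: float = 300.0,
    stage1_collar_s: float = 10.0,
    stage2_threshold_uv: float = 100.0,
    stage2_collar_s: float = 3.0,
) -> ArtifactMask:
    """Run the two-stage detector on a band-passed recording."""
    hemis = dict(DEFAULT_HEMISPHERES if hemisphere_map is None else hemisphere_map)
    sides = []
    for lbl in rec.channel_labels:
        side = hemis.get(lbl) or hemis.get(lbl.upper())
        if side not in ("left", "right"):
            raise ValueError(f"channel {lbl!r} is not mapped to a hemisphere")
        sides.append(side)

    envs = np.stack([envelope(ch) for ch in rec.samples])
    c1 = int(round(stage1_collar_s * rec.fs))
    c2 = int(round(stage2_collar_s * rec.fs))

    stage1 = np.zeros_like(envs, dtype=bool)
    per_channel_s1 = [
        _collar_mask(env > stage1_threshold_uv, c1) for env in envs
    ]
    for side in ("left", "right"):
        members = [i for i, s in enumerate(sides) if s == side]
        if not members:
            continue
        combined = np.zeros(rec.n_times, dtype=bool)
        for i in members:
            combined |= per_channel_s1[i]
        for i in members:
            stage1[i] = combined

    stage2 = np.zeros_like(envs, dtype=bool)
    for i, env in enumerate(envs):
        residual = (env <= stage1_threshold_uv) & (env > stage2_threshold_uv)
        stage2[i] = _collar_mask(residual, c2)

    return ArtifactMask(
        mask=stage1 | stage2,
        fs=rec.fs,
        channel_labels=list(rec.channel_labels),
        hemisphere_map=hemis,
    )


def percent_artifact(mask: ArtifactMask) -> tuple[float, dict[str, float]]:
    """(pooled epoch %, per-channel %) of flagged time."""
    return mask.percent, mask.percent_per_channel
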