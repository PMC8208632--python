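"""End-to-end composition: recording -> montage -> filter -> segments ->
TFD images -> CNN -> voting.

The same stages serve both the full 8-channel system and the reduced
2-channel mode (F3-C3 and F4-C4 only, one-step voting), which mirrors how
2-channel aEEG-style montages are used at the cot side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ThreeBranchCnn, predict_segment
from .preprocess import (
    EegRecording,
    MontageSpec,
    derive_montage,
    lowpass_and_resample,
    segment_epoch,
)
from .tfd import TfdKernelParams, tfd_pipeline
from .train import LabelledDataset
from .vote import build_vote_matrix, majority, one_step_vote, two_step_vote

__all__ = ["GradeResult", "recording_to_tfds", "grade_recording",
           "REDUCED_PAIRS"]

#: the 2-channel reduced montage
REDUCED_PAIRS = (("F3", "C3"), ("F4", "C4"))


@dataclass
class GradeResult:
    """Epoch grade plus everything that led to it."""

    epoch_grade: int
    vote_matrix: np.ndarray
    segments: pd.DataFrame  # per-segment channel/index/grade/probabilities
    scheme: str
    config: dict = field(default_factory=dict)


def _prepare(rec: EegRecording, montage: MontageSpec | None,
             already_bipolar: bool) -> EegRecording:
    if not already_bipolar:
        rec = derive_montage(rec, montage)
    return lowpass_and_resample(rec)


def recording_to_tfds(
    rec: EegRecording,
    kernel: TfdKernelParams | None = None,
    montage: MontageSpec | None = None,
    epoch_id=None,
    already_bipolar: bool = False,
) -> list:
    """All per-channel 5-min TFD images of one epoch."""
    prepared = _prepare(rec, montage, already_bipolar)
    segments = segment_epoch(prepared, epoch_id=epoch_id)
    return [tfd_pipeline(seg, kernel) for seg in segments]


def epoch_dataset(
    recordings: list[tuple[EegRecording, int, object]],
    kernel: TfdKernelParams | None = None,
    montage: MontageSpec | None = None,
    already_bipolar: bool = False,
) -> LabelledDataset:
    """LabelledDataset from (recording, grade, subject_id) epochs.

    Every segment of an epoch inherits that epoch's grade.
    """
    items = []
    for rec, grade, subject in recordings:
        for tfd in recording_to_tfds(rec, kernel, montage, epoch_id=subject,
                                     already_bipolar=already_bipolar):
            items.append((tfd, grade, subject))
    return LabelledDataset.from_tfds(items)


def grade_recording(
    rec: EegRecording,
    model: ThreeBranchCnn,
    kernel: TfdKernelParams | None = None,
    scheme: str = "two-step",
    channels: int = 8,
    montage: MontageSpec | None = None,
    tie_rule: str = "severe",
) -> GradeResult:
    """Grade one epoch; ``channels=2`` selects the reduced F3-C3/F4-C4 mode.

    The reduced mode uses one-step voting, as a 2-channel matrix gives the
    per-period channel majority little to average over.
    """
    if channels == 2:
        montage = MontageSpec(pairs=REDUCED_PAIRS)
        scheme = "one-step"
    elif montage is None:
        montage = MontageSpec()
    tfds = recording_to_tfds(rec, kernel, montage)
    rows = []
    for tfd in tfds:
        pred = predict_segment(model, tfd)
        rows.append(
            {
                "channel": tfd.meta["channel"],
                "channel_index": tfd.meta["channel_index"],
                "segment_index": tfd.meta["segment_index"],
                "grade": pred.label,
                **{f"p{g}": pred.probs[g - 1] for g in (1, 2, 3, 4)},
            }
        )
    seg_df = pd.DataFrame(rows).sort_values(["channel_index", "segment_index"])
    per_channel = {
        ch: grp.sort_values("segment_index")["grade"].tolist()
        for ch, grp in seg_df.groupby("channel", sort=False)
    }
    m = build_vote_matrix(per_channel, tie_rule=tie_rule)
    if scheme not in ("one-step", "two-step"):
        raise ValueError(f"unknown voting scheme {scheme!r}")
    if np.all(m.grades == 0):
        # epoch too short for the 20-min period structure: fall back to a
        # plain majority over every segment grade
        grade = majority(seg_df["grade"].tolist(), tie_rule)
    elif scheme == "two-step":
        grade = two_step_vote(m, tie_rule)
    else:
        grade = one_step_vote(m, tie_rule)
    return GradeResult(
        epoch_grade=grade,
        vote_matrix=m.grades,
        segments=seg_df.reset_index(drop=True),
        scheme=scheme,
        config={"channels": channels,
                "kernel": (kernel or TfdKernelParams()).__dict__ if kernel else
                TfdKernelParams().__dict__,
                "tie_rule": tie_rule},
    )
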