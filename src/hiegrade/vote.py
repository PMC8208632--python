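"""Majority-vote fusion of per-segment grades into an epoch grade.

Per channel, the grades of the seven 5-min segments (50% overlap) fully
contained in each 20-min period are fused by majority, giving an 8 x 3
channel-by-period matrix M_cn.  The epoch grade is then either the global
majority over all cells (one-step voting) or the majority of the three
per-period channel majorities SM_n (two-step voting).  Ties break towards
the more severe (higher) grade by default: a severity-biased error is the
clinically conservative one.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "VoteMatrix",
    "majority",
    "build_vote_matrix",
    "one_step_vote",
    "two_step_vote",
    "MISSING",
]

#: sentinel for a channel/period cell that could not be computed
MISSING = 0

#: segments per epoch / per period for the canonical 60-min epoch
SEGMENTS_PER_CHANNEL = 23
SEGMENTS_PER_PERIOD = 7
N_PERIODS = 3


@dataclass
class VoteMatrix:
    """Channel-by-period grade matrix with per-cell provenance."""

    grades: np.ndarray  # (n_channels, n_periods); MISSING where undefined
    provenance: list = field(default_factory=list)  # contributing grades per cell

    def __post_init__(self) -> None:
        self.grades = np.asarray(self.grades, dtype=int)
        bad = ~np.isin(self.grades, (MISSING, 1, 2, 3, 4))
        if bad.any():
            raise ValueError("vote matrix entries must be grades 1-4 or MISSING")

    @property
    def n_channels(self) -> int:
        return self.grades.shape[0]


def majority(grades: Sequence[int], tie_rule: str = "severe") -> int:
    """Modal label; ties resolved by tie_rule ('severe' or 'mild')."""
    grades = [int(g) for g in grades]
    if not grades:
        raise ValueError("majority of an empty list is undefined")
    counts = Counter(grades)
    top = max(counts.values())
    tied = [g for g, c in counts.items() if c == top]
    if tie_rule == "severe":
        return max(tied)
    if tie_rule == "mild":
        return min(tied)
    raise ValueError(f"unknown tie rule {tie_rule!r}")


def _period_segments(
    period: int, win_s: float = 300.0, hop_s: float = 150.0, period_s: float = 1200.0
) -> list[int]:
    """Segment indices fully contained in [period*20 min, (period+1)*20 min]."""
    lo, hi = period * period_s, (period + 1) * period_s
    out = []
    i = 0
    while i * hop_s + win_s <= 3 * period_s + win_s:  # generous scan bound
        start = i * hop_s
        if start >= lo and start + win_s <= hi:
            out.append(i)
        i += 1
    return out


def build_vote_matrix(
    seg_grades: Mapping[str, Sequence[int]] | np.ndarray,
    tie_rule: str = "severe",
    n_periods: int = N_PERIODS,
) -> VoteMatrix:
    """Fuse ordered per-channel segment grades into M_cn.

    ``seg_grades`` maps channel -> ordered segment grades (or is an array of
    shape (n_channels, n_segments)).  A period whose seven contributing
    segments are not all present is marked missing and excluded from later
    votes.  Segments straddling a period boundary contribute to no period.
    """
    if isinstance(seg_grades, Mapping):
        rows = list(seg_grades.values())
    else:
        rows = [list(r) for r in np.atleast_2d(np.asarray(seg_grades))]
    grades = np.full((len(rows), n_periods), MISSING, dtype=int)
    provenance: list[list[list[int]]] = []
    for ci, row in enumerate(rows):
        prov_row = []
        for p in range(n_periods):
            idx = _period_segments(p)
            if idx and idx[-1] < len(row):
                cell = [int(row[i]) for i in idx]
                grades[ci, p] = majority(cell, tie_rule)
            else:
                cell = []
            prov_row.append(cell)
        provenance.append(prov_row)
    return VoteMatrix(grades=grades, provenance=provenance)


def one_step_vote(m: VoteMatrix, tie_rule: str = "severe") -> int:
    """Global majority over all non-missing cells of M_cn."""
    cells = m.grades[m.grades != MISSING]
    if cells.size == 0:
        raise ValueError("vote matrix has no non-missing cells")
    return majority(cells.tolist(), tie_rule)


def two_step_vote(m: VoteMatrix, tie_rule: str = "severe") -> int:
    """Majority across channels per period (SM_n), then across periods (GM)."""
    sm = []
    for p in range(m.grades.shape[1]):
        col = m.grades[:, p][m.grades[:, p] != MISSING]
        if col.size:
            sm.append(majority(col.tolist(), tie_rule))
    if not sm:
        raise ValueError("vote matrix has no non-missing cells")
    return majority(sm, tie_rule)
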