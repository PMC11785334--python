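"""Closed-loop reward feedback: rank each trial's movement time against
the participant's last 20 trials and convert the rank percentile to
points (0-5 pence).

Percentile = 100 x (number of buffer MTs strictly slower) / buffer size;
ties count in the participant's favour (an equal MT is not "slower").
Point bins: >= 90 -> 5p, [80, 90) -> 4p, [60, 80) -> 3p, [40, 60) -> 2p,
[20, 40) -> 1p, < 20 -> 0p.  Because the comparison set is the rolling
window of the participant's own recent trials, the criterion adapts:
steady improvement keeps the award near the middle of the scale rather
than saturating at 5p.

The printed "top three" phrasing conflicts with the >= 90% percentile
bound (top 3 of 20 is >= 85%); the percentile bins are taken as
normative, with a ``mode='rank_bands'`` switch implementing the literal
top-three/bottom-three reading.

At block boundaries the buffer is seeded with the final 20 trials of the
previous block; with fewer than 20 available the award is computed
against what exists and flagged as warm-up.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

CAPACITY = 20

#: (lower percentile bound, points), scanned top-down.
BIN_EDGES: tuple[tuple[float, int], ...] = (
    (90.0, 5), (80.0, 4), (60.0, 3), (40.0, 2), (20.0, 1), (0.0, 0),
)


@dataclass
class RewardState:
    """Rolling buffer of the most recent movement times (s)."""

    buffer: deque
    capacity: int = CAPACITY
    warm_up: bool = False

    @classmethod
    def empty(cls, capacity: int = CAPACITY) -> "RewardState":
        return cls(buffer=deque(maxlen=capacity), capacity=capacity,
                   warm_up=True)

    def __len__(self) -> int:
        return len(self.buffer)


@dataclass(frozen=True)
class FeedbackResult:
    points: int        # 0..5 pence
    percentile: float  # 0..100
    rank: int          # 1 = fastest among (buffer + current)
    warm_up: bool


def points_for_percentile(p: float, edges=BIN_EDGES) -> int:
    for lower, pts in edges:
        if p >= lower:
            return pts
    return edges[-1][1]


def score_trial(
    state: RewardState,
    mt: float,
    mode: str = "percentile",
    edges=BIN_EDGES,
) -> FeedbackResult:
    """Points for the current trial against the buffered MTs.

    ``mode='percentile'`` (default) uses the percentile bins;
    ``mode='rank_bands'`` awards 5p to the top three ranks and 0p to the
    bottom three of a full 20-trial buffer, percentile bins otherwise.
    """
    if mt <= 0:
        raise ValueError("movement time must be positive")
    n = len(state.buffer)
    if n == 0:
        raise ValueError("cannot score against an empty buffer")
    slower = sum(1 for b in state.buffer if b > mt)
    percentile = 100.0 * slower / n
    rank = n - slower + 1  # position from fastest, ties resolved upward
    warm_up = n < state.capacity
    if mode == "rank_bands" and n == state.capacity:
        if rank <= 3:
            points = 5
        elif rank >= n - 2:
            points = 0
        else:
            points = points_for_percentile(percentile, edges)
    elif mode in ("percentile", "rank_bands"):
        points = points_for_percentile(percentile, edges)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return FeedbackResult(points=points, percentile=percentile,
                          rank=rank, warm_up=warm_up)


def update_state(state: RewardState, mt: float) -> RewardState:
    """Append ``mt``, evicting the oldest entry when over capacity."""
    state.buffer.append(mt)
    state.warm_up = len(state.buffer) < state.capacity
    return state


def seed_block_boundary(prev_block: Sequence[float],
                        capacity: int = CAPACITY) -> RewardState:
    """Buffer initialised with the final ``capacity`` MTs of the previous
    block (all of them, flagged warm-up, when fewer exist)."""
    tail = list(prev_block)[-capacity:]
    state = RewardState(buffer=deque(tail, maxlen=capacity),
                        capacity=capacity)
    state.warm_up = len(tail) < capacity
    return state


def replay_block(
    state: RewardState,
    mts: Sequence[float],
    mode: str = "percentile",
) -> pd.DataFrame:
    """Score a block of trials sequentially, updating the buffer after each.

    Returns one row per trial: points, percentile, rank, warm_up.
    """
    rows = []
    for mt in mts:
        if len(state) == 0:  # nothing to compare the very first trial to
            rows.append({
                "mt": mt, "points": float("nan"), "percentile": float("nan"),
                "rank": 1, "warm_up": True,
            })
        else:
            fb = score_trial(state, mt, mode=mode)
            rows.append({
                "mt": mt, "points": fb.points, "percentile": fb.percentile,
                "rank": fb.rank, "warm_up": fb.warm_up,
            })
        update_state(state, mt)
    return pd.DataFrame(rows)
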