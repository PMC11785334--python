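"""Per-trial kinematic metrics for sequential reaching trajectories.

Converts a raw (t, x, y) cursor trajectory into the trial metrics used by
the analysis: movement time (MT), the eight per-segment maximum
velocities v_max, and the seven per-transition fusion indices

    FI = 1 - (mean(v_max1, v_max2) - v_min) / mean(v_max1, v_max2)
       = v_min / mean(v_max1, v_max2)

where v_min is the velocity trough between the two adjacent segments'
peaks.  FI = 1 indicates a fully fused transition (no slowdown between
reaches); FI = 0 a complete stop.

Conventions (documented because the source protocol leaves them open):

* Target entry/exit is the cursor *centre* crossing the target's 0.5 cm
  radius disc boundary (point-cursor convention).
* Speed is the Euclidean norm of first differences of (x, y) divided by
  the sampling interval, smoothed with a Gaussian kernel (sigma = 2
  samples, truncated at 4 sigma, reflective boundaries).
* The v_min search window is the open interval between the two adjacent
  peak-speed samples.
* MT runs from start-box exit to first entry into the final target;
  reaction time uses the separate 2 cm displacement rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from seqreach.layout import DEFAULT_SEQUENCE, TargetLayout

#: Default Gaussian smoothing width for velocity profiles, in samples.
DEFAULT_SIGMA = 2.0

#: Relative tolerance on sampling-interval uniformity.
_DT_RTOL = 1e-6


class SegmentationError(ValueError):
    """A target was never entered, or was entered out of order."""


@dataclass
class VelocityProfile:
    """Speed over time for one trial."""

    t: np.ndarray       # time (s)
    v: np.ndarray       # Gaussian-smoothed speed (cm/s)
    raw_v: np.ndarray   # unsmoothed speed (cm/s)

    def __post_init__(self) -> None:
        if not (len(self.t) == len(self.v) == len(self.raw_v)):
            raise ValueError("t, v and raw_v must have equal length")


@dataclass(frozen=True)
class SegmentBounds:
    """Sample-index span of one of the eight reach segments."""

    segment_index: int  # 1..8
    start_idx: int
    end_idx: int

    def __post_init__(self) -> None:
        if self.end_idx <= self.start_idx:
            raise ValueError(
                f"segment {self.segment_index}: empty span "
                f"[{self.start_idx}, {self.end_idx}]"
            )


@dataclass
class TrialKinematics:
    """Derived per-trial metrics."""

    mt: float                 # movement time (s)
    reaction_time: float      # s
    vmax: np.ndarray          # 8 per-segment peak speeds (cm/s)
    vmax_mean: float          # mean of the 8 peaks (cm/s)
    fi: np.ndarray            # 7 per-transition fusion indices
    fi_sum: float             # sum of fi (<= 7)
    vmin: np.ndarray          # 7 trough speeds (cm/s)
    n_fi_clamped: int = 0     # transitions where raw FI fell outside [0, 1]


def _uniform_dt(t: np.ndarray) -> float:
    dt = np.diff(t)
    if len(dt) == 0:
        raise ValueError("need at least 2 samples")
    ref = float(np.median(dt))
    bad = np.nonzero(np.abs(dt - ref) > max(_DT_RTOL * ref, 1e-9))[0]
    if bad.size:
        i = int(bad[0])
        raise ValueError(
            f"non-uniform sampling: gap of {dt[i]:.6g} s between samples "
            f"{i} and {i + 1} (expected {ref:.6g} s)"
        )
    return ref


def compute_speed(trajectory, sigma: float = DEFAULT_SIGMA) -> VelocityProfile:
    """Speed profile from a trajectory with Gaussian smoothing.

    ``trajectory`` needs ``t``, ``x`` and ``y`` attributes (arrays).  The
    first-difference speed is prepended with its own first value so the
    profile keeps the trajectory's length.
    """
    t = np.asarray(trajectory.t, dtype=float)
    x = np.asarray(trajectory.x, dtype=float)
    y = np.asarray(trajectory.y, dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 samples")
    dt = _uniform_dt(t)
    step = np.hypot(np.diff(x), np.diff(y)) / dt
    raw_v = np.concatenate([step[:1], step])
    v = gaussian_filter1d(raw_v, sigma=sigma, mode="reflect", truncate=4.0)
    # smoothing can produce tiny negative round-off on exact zeros
    np.clip(v, 0.0, None, out=v)
    return VelocityProfile(t=t, v=v, raw_v=raw_v)


def segment_trial(
    trajectory,
    profile: VelocityProfile | None,
    layout: TargetLayout,
    sequence: Sequence[str] = DEFAULT_SEQUENCE,
) -> list[SegmentBounds]:
    """Split a trial into the 8 reach segments.

    Segment k spans from the sample where the cursor exits the previous
    target's disc to the sample where it exits target k's disc; the final
    segment ends at the first *entry* into the final target.

    Raises :class:`SegmentationError` naming the first target that is
    missed or entered out of order.
    """
    if profile is not None and len(profile.t) != len(trajectory.t):
        raise ValueError("profile and trajectory lengths differ")
    pos = np.column_stack([np.asarray(trajectory.x, float),
                           np.asarray(trajectory.y, float)])
    r = layout.target_radius
    names = sorted({"via", *sequence})
    inside = {
        n: np.hypot(*(pos - layout.point(n)).T) <= r for n in names
    }

    n = len(pos)
    if not inside["via"][0]:
        raise SegmentationError("trajectory does not start inside the via target")

    def first_true(mask: np.ndarray, start: int) -> int:
        idx = np.argmax(mask[start:])
        if not mask[start + idx]:
            return -1
        return start + int(idx)

    bounds: list[SegmentBounds] = []
    # exit of the starting via target
    prev_exit = first_true(~inside["via"], 0)
    if prev_exit < 0:
        raise SegmentationError("cursor never leaves the starting via target")
    prev_name = "via"
    cursor = prev_exit
    n_seg = len(sequence)
    for k, name in enumerate(sequence, start=1):
        entry = first_true(inside[name], cursor)
        if entry < 0:
            raise SegmentationError(
                f"target {name!r} (sequence position {k}) never entered"
            )
        # order check: no *other* sequence target entered first
        # (re-grazing the target just exited is tolerated)
        for other in names:
            if other in (name, prev_name):
                continue
            o_entry = first_true(inside[other], cursor)
            if 0 <= o_entry < entry:
                raise SegmentationError(
                    f"target {other!r} entered before expected target {name!r} "
                    f"(sequence position {k})"
                )
        if k == n_seg:
            end = entry  # final segment ends at first entry into final target
        else:
            end = first_true(~inside[name], entry)
            if end < 0:
                raise SegmentationError(
                    f"cursor never leaves target {name!r} (sequence position {k})"
                )
        bounds.append(SegmentBounds(segment_index=k, start_idx=prev_exit, end_idx=end))
        prev_exit = end
        prev_name = name
        cursor = end
    return bounds


def peak_velocities(
    profile: VelocityProfile, segments: Sequence[SegmentBounds]
) -> tuple[np.ndarray, float]:
    """Per-segment maximum of the smoothed speed, and the trial mean."""
    vmax = np.empty(len(segments))
    for i, seg in enumerate(segments):
        window = profile.v[seg.start_idx : seg.end_idx + 1]
        if window.size == 0:
            raise ValueError(f"segment {seg.segment_index} is empty")
        vmax[i] = window.max()
    return vmax, float(vmax.mean())


def _peak_indices(profile: VelocityProfile, segments: Sequence[SegmentBounds]) -> np.ndarray:
    idx = np.empty(len(segments), dtype=int)
    for i, seg in enumerate(segments):
        window = profile.v[seg.start_idx : seg.end_idx + 1]
        idx[i] = seg.start_idx + int(np.argmax(window))
    return idx


def fusion_index(
    vmax1: float, vmax2: float, vmin: float, clamp: bool = True
) -> float:
    """Fusion index of one transition.

    FI = 1 - (mean(vmax1, vmax2) - vmin) / mean(vmax1, vmax2).  A trough
    equal to the mean of the adjacent peaks gives 1 (fully fused); a full
    stop gives 0.  Values are clamped to [0, 1] when ``clamp`` (a trough
    can exceed the mean of the peaks when the two peaks differ).
    """
    if vmax1 <= 0 or vmax2 <= 0:
        raise ValueError("peak velocities must be positive")
    if vmin < 0:
        raise ValueError("trough velocity must be non-negative")
    mean_peak = (vmax1 + vmax2) / 2.0
    fi = 1.0 - (mean_peak - vmin) / mean_peak
    if clamp:
        fi = min(max(fi, 0.0), 1.0)
    return float(fi)


def trial_fusion(
    profile: VelocityProfile, segments: Sequence[SegmentBounds]
) -> tuple[np.ndarray, float, np.ndarray, int]:
    """Fusion indices for the 7 transitions of an 8-segment trial.

    Returns ``(fi, fi_sum, vmin, n_clamped)``.  For each transition the
    trough is the minimum smoothed speed strictly between the two
    adjacent segments' peak samples (falling back to the closed interval
    when the peaks are adjacent samples).
    """
    if len(segments) < 2:
        raise ValueError("need at least 2 segments")
    peaks = _peak_indices(profile, segments)
    n_tr = len(segments) - 1
    fi = np.empty(n_tr)
    vmin = np.empty(n_tr)
    n_clamped = 0
    for k in range(n_tr):
        a, b = sorted((peaks[k], peaks[k + 1]))
        window = profile.v[a + 1 : b] if b - a > 1 else profile.v[a : b + 1]
        vmin[k] = float(window.min())
        raw = fusion_index(profile.v[a], profile.v[b], vmin[k], clamp=False)
        if raw < 0.0 or raw > 1.0:
            n_clamped += 1
        fi[k] = min(max(raw, 0.0), 1.0)
    return fi, float(fi.sum()), vmin, n_clamped


def movement_time(
    trajectory,
    layout: TargetLayout,
    sequence: Sequence[str] = DEFAULT_SEQUENCE,
    go_time: float | None = None,
) -> tuple[float, float]:
    """Movement time and reaction time of a trial.

    MT = time of first entry into the final target minus time of exiting
    the start box (2 x 2 cm around the via target).  Reaction time = time
    at which displacement from the start position exceeds 2 cm, minus the
    go signal (defaults to the first sample).
    """
    t = np.asarray(trajectory.t, float)
    x = np.asarray(trajectory.x, float)
    y = np.asarray(trajectory.y, float)
    via = layout.point("via")
    half = layout.start_box_side / 2.0
    in_box = (np.abs(x - via[0]) <= half) & (np.abs(y - via[1]) <= half)
    if not in_box[0]:
        raise ValueError("trajectory does not start inside the start box")
    out = np.nonzero(~in_box)[0]
    if out.size == 0:
        raise ValueError("cursor never exits the start box")
    t_exit = t[out[0]]

    segments = segment_trial(trajectory, None, layout, sequence)
    t_final = t[segments[-1].end_idx]
    mt = float(t_final - t_exit)

    disp = np.hypot(x - x[0], y - y[0])
    moved = np.nonzero(disp > 2.0)[0]
    if moved.size == 0:
        raise ValueError("cursor displacement never exceeds 2 cm")
    t0 = t[0] if go_time is None else go_time
    rt = float(t[moved[0]] - t0)
    return mt, rt


def analyse_trial(
    trajectory,
    layout: TargetLayout,
    sigma: float = DEFAULT_SIGMA,
    sequence: Sequence[str] = DEFAULT_SEQUENCE,
) -> TrialKinematics:
    """Full per-trial kinematics: MT, peak velocities and fusion indices."""
    profile = compute_speed(trajectory, sigma=sigma)
    segments = segment_trial(trajectory, profile, layout, sequence)
    vmax, vmax_mean = peak_velocities(profile, segments)
    fi, fi_sum, vmin, n_clamped = trial_fusion(profile, segments)
    mt, rt = movement_time(trajectory, layout, sequence)
    return TrialKinematics(
        mt=mt,
        reaction_time=rt,
        vmax=vmax,
        vmax_mean=vmax_mean,
        fi=fi,
        fi_sum=fi_sum,
        vmin=vmin,
        n_fi_clamped=n_clamped,
    )


def kinematics_table(
    trajectories,
    layout: TargetLayout,
    sigma: float = DEFAULT_SIGMA,
    sequence: Sequence[str] = DEFAULT_SEQUENCE,
) -> pd.DataFrame:
    """Per-trial metrics table for an iterable of trajectories.

    Each trajectory's identifying metadata (participant, day, phase,
    trial number, flags) is carried through into the output rows.
    """
    rows = []
    for traj in trajectories:
        k = analyse_trial(traj, layout, sigma=sigma, sequence=sequence)
        row = dict(traj.meta)
        row.update(
            mt=k.mt,
            reaction_time=k.reaction_time,
            vmax_mean=k.vmax_mean,
            fi_sum=k.fi_sum,
            n_fi_clamped=k.n_fi_clamped,
        )
        rows.append(row)
    return pd.DataFrame(rows)
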