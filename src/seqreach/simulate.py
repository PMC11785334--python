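"""Synthetic cohorts and reaching trajectories for the sequential task.

The generator emulates the statistical structure the analysis assumes:

* each trial is eight point-to-point reaches through the target layout
  with a unimodal (bell-shaped) speed profile per segment;
* per-segment peak speed ("vigour") follows a participant-specific linear
  learning curve ``vigour0 + vigour_slope * trial``;
* the speed trough at each of the seven transitions is a programmed
  fraction of the mean of the adjacent peaks — exactly the quantity the
  fusion index measures — following ``fusion0 + fusion_slope * trial``;
* group membership (reward feedback, haloperidol vs placebo, working
  memory) shifts the learning slopes;
* motor noise enters as trial-level jitter on peak speed and trough
  fraction plus additive Gaussian positional noise.

Per-segment speed is built as

    v(u) = v_in + (v_out - v_in) * S5(u) + c * sin^4(pi * u),  u in [0, 1]

with S5 the quintic smoothstep.  Both terms have zero first and second
derivatives at the endpoints, so adjacent segments join with a smooth,
locally flat velocity trough that survives Gaussian smoothing; ``c`` is
solved so the maximum equals the programmed peak, and the segment
duration follows from the required displacement.  A trough fraction of 0
produces a full stop with a dwell of at least ``dwell_floor`` seconds.

Also simulates the two control tasks: a probabilistic Go/NoGo learner
with separate learning rates for wins and losses (to emulate the
drug-induced feedback asymmetry), and a verbal working-memory task whose
accuracy falls with array length and rises with latent WM ability.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from seqreach.layout import DEFAULT_SEQUENCE, TargetLayout, make_target_layout
from seqreach.protocol import build_schedule

REWARD_GROUPS = ("Rew", "NoRew")
DRUG_GROUPS = ("Halo", "Ctrl")
GROUPS = tuple(itertools.product(REWARD_GROUPS, DRUG_GROUPS))

_PHASE_CODE = {
    "Familiarisation": 0,
    "Baseline": 1,
    "Training": 2,
    "PostRew": 3,
    "PostNoRew": 4,
}

# trough speeds below this (cm/s) are realised as a full stop with dwell
_STOP_SPEED = 1e-9


@dataclass
class Trajectory:
    """Timestamped 2-D cursor path for one trial."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "x": self.x, "y": self.y})


@dataclass
class ParticipantProfile:
    """Group labels and simulation parameters of one participant."""

    id: str
    reward_group: str           # Rew | NoRew
    drug_group: str             # Halo | Ctrl
    wm_true: float              # latent working-memory ability (z-scale)
    vigour0: float              # baseline peak speed (cm/s)
    vigour_slope: float         # cm/s per training trial
    fusion0: float              # baseline trough fraction, [0, 1)
    fusion_slope: float         # trough-fraction change per trial
    noise_sd: float             # positional noise sd (cm)

    def __post_init__(self) -> None:
        if self.vigour0 <= 0:
            raise ValueError("vigour0 must be positive")
        if not 0 <= self.fusion0 < 1:
            raise ValueError("fusion0 must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.reward_group not in REWARD_GROUPS:
            raise ValueError(f"unknown reward group {self.reward_group!r}")
        if self.drug_group not in DRUG_GROUPS:
            raise ValueError(f"unknown drug group {self.drug_group!r}")


def _slope_dict(d: Mapping) -> dict:
    return dict(d)


@dataclass
class SimConfig:
    """All knobs of the synthetic cohort; the seed fully determines outputs."""

    n_per_group: int = 23
    seed: int = 0

    # schedule (trials per phase)
    n_familiarisation: int = 20
    n_baseline: int = 10
    n_training: int = 200
    n_post_day12: int = 20
    n_post_day7: int = 25
    days: tuple[int, ...] = (1, 2, 7)
    include_baseline_day2: bool = True
    include_familiarisation: bool = True

    # acquisition
    sampling_rate: float = 110.0
    dwell_floor: float = 0.2        # s; minimum dwell at a full-stop transition

    # vigour (peak speed) model, cm/s
    vigour0_mean: float = 25.0
    vigour0_sd: float = 2.5
    vigour0_reward_shift: float = 3.0
    # per-trial slope by (reward, drug): placebo-reward learns fastest,
    # haloperidol-reward flattens, no-reward groups intermediate
    vigour_slope_effects: dict = field(default_factory=lambda: _slope_dict({
        ("Rew", "Ctrl"): 2.4 / 180,
        ("Rew", "Halo"): -0.46 / 180,
        ("NoRew", "Ctrl"): 1.27 / 180,
        ("NoRew", "Halo"): 1.28 / 180,
    }))
    vigour_slope_sd: float = 0.003

    # fusion (trough fraction) model, unitless
    fusion0_mean: float = 0.10
    fusion0_sd: float = 0.03
    # per-trial slope by (drug, wm class): haloperidol flattens fusion
    # learning in high-WM participants only
    fusion_slope_effects: dict = field(default_factory=lambda: _slope_dict({
        ("Halo", "high"): 0.4e-3,
        ("Halo", "low"): 1.0e-3,
        ("Ctrl", "high"): 1.5e-3,
        ("Ctrl", "low"): 0.9e-3,
    }))
    fusion_slope_reward_boost: float = 0.4e-3
    fusion_slope_sd: float = 3e-4
    fusion_cap: float = 0.95        # programmed trough fraction is clamped here

    # motor noise
    noise_sd: float = 0.02          # positional (cm)
    peak_jitter_sd: float = 1.5     # trial-level peak-speed jitter (cm/s)
    fusion_jitter_sd: float = 0.03  # trial-level trough-fraction jitter

    # timing
    reaction_delay: float = 0.3     # s of stillness before movement onset
    reaction_jitter_sd: float = 0.05
    rest_tail: float = 0.2          # s of stillness after the final target

    # Go/NoGo task: win probabilities are configurable (not printed in any
    # protocol); two reward-associated and two loss-associated stimuli
    gonogo_win_prob_reward: float = 0.8
    gonogo_win_prob_loss: float = 0.2
    gonogo_presentations: int = 10
    gonogo_beta: float = 3.0
    gonogo_go_bias: float = 0.2
    # (drug, wm class) -> (alpha_win, alpha_loss); haloperidol shifts
    # learning toward wins in low-WM participants
    gonogo_alphas: dict = field(default_factory=lambda: _slope_dict({
        ("Halo", "low"): (0.45, 0.15),
        ("Halo", "high"): (0.30, 0.30),
        ("Ctrl", "low"): (0.30, 0.30),
        ("Ctrl", "high"): (0.30, 0.30),
    }))

    # verbal working-memory task
    vwm_n_trials: int = 60
    vwm_lengths: tuple[int, ...] = (5, 6, 7, 8, 9)
    vwm_intercept: float = 1.0
    vwm_wm_gain: float = 1.5
    vwm_length_cost: float = 0.8

    # table-level residual noise (fast simulation of the analysis table)
    table_vmax_resid_sd: float = 1.5
    table_fi_resid_sd: float = 0.35
    table_mt_resid_sd: float = 0.5

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# trajectory construction
# ---------------------------------------------------------------------------

#: Bounds (cm) on the hook arc a fused transition follows around a target.
#: The radius scales with trough speed (nominal hook duration ~0.15 s) but
#: stays inside the 0.5 cm target disc so every arc registers as a visit.
HOOK_RADIUS_MAX = 0.4
HOOK_RADIUS_MIN = 0.03
HOOK_DURATION = 0.15  # s

#: Target duration (s) of the constant-speed trough plateau around each
#: fused transition; short hook arcs are padded by straight-line holds at
#: trough speed so the plateau spans the velocity-smoothing kernel.
TROUGH_HOLD = 0.08


def _smoothstep5(u: np.ndarray) -> np.ndarray:
    return u * u * u * (10.0 + u * (-15.0 + 6.0 * u))


def _perp(v: np.ndarray) -> np.ndarray:
    return np.array([-v[1], v[0]])


def _rot(v: np.ndarray, phi: float) -> np.ndarray:
    c, s = np.cos(phi), np.sin(phi)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def _tangent_point_to_circle(S, C, r, s):
    """Tangent from point S to circle (C, r) with turn side s (+1 = CCW)."""
    sc = C - S
    L = float(np.hypot(*sc))
    d = _rot(sc / L, -s * np.arcsin(r / L))
    T = S + np.sqrt(L * L - r * r) * d
    return d, T


def _tangent_circle_to_point(C, E, r, s):
    ce = E - C
    L = float(np.hypot(*ce))
    d = _rot(ce / L, s * np.arcsin(r / L))
    T = E - np.sqrt(L * L - r * r) * d
    return d, T


def _tangent_circle_circle(C1, s1, r1, C2, s2, r2):
    """Common tangent between two hook circles respecting both turn sides."""
    ab = C2 - C1
    D = float(np.hypot(*ab))
    d = _rot(ab / D, np.arcsin((r1 * s1 - r2 * s2) / D))
    T1 = C1 - r1 * s1 * _perp(d)
    T2 = C2 - r2 * s2 * _perp(d)
    return d, T1, T2


def _arc_sweep(C, T_in, T_out, s):
    """Signed sweep (radians, in turn direction) from T_in to T_out."""
    phi_in = np.arctan2(*(T_in - C)[::-1])
    phi_out = np.arctan2(*(T_out - C)[::-1])
    if s > 0:
        return float((phi_out - phi_in) % (2.0 * np.pi)), float(phi_in)
    return float((phi_in - phi_out) % (2.0 * np.pi)), float(phi_in)


def _segment_speed_profile(
    v_in: float, v_out: float, v_peak: float,
    shoulder: float = 0.3, n_grid: int = 1024,
) -> tuple[np.ndarray, float]:
    """Flat-topped speed shape v(u) on [0, 1].

    Rises from ``v_in`` to ``v_peak`` over the first ``shoulder`` of the
    segment (quintic smoothstep, so first and second derivatives vanish
    at both ends), holds the peak, and falls to ``v_out`` symmetrically.
    The flat top and flat trough joins survive Gaussian smoothing of the
    sampled speed, keeping measured peaks and troughs at their
    programmed values.  Returns (v on a uniform grid, mean speed).
    """
    if v_peak <= 0:
        raise ValueError("peak speed must be positive")
    if min(v_in, v_out) < 0 or max(v_in, v_out) > v_peak * (1 + 1e-9) + 1e-12:
        raise ValueError("boundary speeds must lie in [0, v_peak]")
    u = np.linspace(0.0, 1.0, n_grid)
    v = np.full(n_grid, float(v_peak))
    rise = u < shoulder
    fall = u > 1.0 - shoulder
    v[rise] = v_in + (v_peak - v_in) * _smoothstep5(u[rise] / shoulder)
    v[fall] = v_out + (v_peak - v_out) * _smoothstep5((1.0 - u[fall]) / shoulder)
    mean = (
        shoulder * (v_in + v_peak) / 2.0
        + (1.0 - 2.0 * shoulder) * v_peak
        + shoulder * (v_peak + v_out) / 2.0
    )
    return v, mean


def make_trial_trajectory(
    layout: TargetLayout,
    peak_speeds: Sequence[float],
    trough_fractions: Sequence[float],
    *,
    sampling_rate: float = 110.0,
    dwell_floor: float = 0.2,
    noise_sd: float = 0.0,
    reaction_delay: float = 0.3,
    rest_tail: float = 0.2,
    rng: np.random.Generator | None = None,
    sequence: Sequence[str] = DEFAULT_SEQUENCE,
    meta: dict | None = None,
) -> Trajectory:
    """Noise-controlled trajectory with programmed peaks and troughs.

    ``peak_speeds`` (one per segment, cm/s) and ``trough_fractions`` (one
    per transition, in [0, 1]) fully determine the noise-free speed
    profile: transition k's trough speed is
    ``trough_fractions[k] * mean(peak_k, peak_{k+1})``, the value the
    fusion index recovers.  Fractions of 0 produce a full stop with a
    dwell of at least ``dwell_floor`` seconds.

    Fused transitions follow a circular hook of radius
    :data:`HOOK_RADIUS` around the target (inside its disc) at constant
    trough speed, joined to the straight legs by common tangents — a
    sharp polyline corner would corrupt the finite-difference speed,
    whereas real coarticulated reaches curve around the via point.
    """
    pts = layout.sequence_points(tuple(sequence))
    n_seg = len(pts) - 1
    vp = np.asarray(peak_speeds, dtype=float)
    f = np.asarray(trough_fractions, dtype=float)
    if vp.shape != (n_seg,):
        raise ValueError(f"need {n_seg} peak speeds, got {vp.shape}")
    if f.shape != (n_seg - 1,):
        raise ValueError(f"need {n_seg - 1} trough fractions, got {f.shape}")
    if np.any(vp <= 0):
        raise ValueError("peak speeds must be positive")
    if np.any((f < 0) | (f > 1)):
        raise ValueError("trough fractions must lie in [0, 1]")

    troughs = f * (vp[:-1] + vp[1:]) / 2.0
    too_high = troughs > np.minimum(vp[:-1], vp[1:]) + 1e-12
    if np.any(too_high):
        k = int(np.nonzero(too_high)[0][0])
        raise ValueError(
            f"transition {k + 1}: trough speed {troughs[k]:.3g} exceeds the "
            "smaller adjacent peak; reduce the trough fraction or equalise peaks"
        )

    dt_sample = 1.0 / sampling_rate

    # hook radius scales with trough speed (constant angular step per
    # sample, so the sampled chord tracks the arc within ~0.2%)
    stops = troughs < _STOP_SPEED
    radii = np.clip(troughs * HOOK_DURATION / np.pi,
                    HOOK_RADIUS_MIN, HOOK_RADIUS_MAX)
    radii[stops] = 0.0
    # compensate arc speed for chord shortening: full sampling steps on
    # the arc then measure exactly the programmed trough speed
    v_arc = np.where(
        stops, 0.0,
        (2.0 * radii / dt_sample)
        * np.arcsin(np.minimum(troughs * dt_sample / (2.0 * radii + 1e-30),
                               1.0)),
    )

    # nodes: start point, 7 transition targets (hook circle or full-stop
    # vertex), end point
    dirs_in = np.diff(pts, axis=0)
    dirs_in /= np.hypot(*dirs_in.T)[:, None]
    nodes: list[tuple] = [("point", pts[0], None, 0.0)]
    for k in range(1, n_seg):
        if stops[k - 1]:
            nodes.append(("point", pts[k], None, 0.0))
        else:
            cross = (dirs_in[k - 1][0] * dirs_in[k][1]
                     - dirs_in[k - 1][1] * dirs_in[k][0])
            side = 1.0 if cross >= 0 else -1.0
            nodes.append(("circle", pts[k], side, float(radii[k - 1])))
    nodes.append(("point", pts[-1], None, 0.0))

    # legs: common tangents between consecutive nodes
    legs = []       # (A, B) endpoints of each straight leg
    tangents = []   # per node k (1..7): (T_in, T_out) on its hook circle
    t_in_prev = None
    for k in range(n_seg):
        kind_a, P_a, s_a, r_a = nodes[k]
        kind_b, P_b, s_b, r_b = nodes[k + 1]
        if kind_a == "point" and kind_b == "point":
            A, B = P_a, P_b
        elif kind_a == "point":
            _, B = _tangent_point_to_circle(P_a, P_b, r_b, s_b)
            A = P_a
        elif kind_b == "point":
            _, A = _tangent_circle_to_point(P_a, P_b, r_a, s_a)
            B = P_b
        else:
            _, A, B = _tangent_circle_circle(P_a, s_a, r_a, P_b, s_b, r_b)
        legs.append((A, B))
        if k >= 1:
            tangents.append((t_in_prev, A))
        t_in_prev = B
    tangents.append((t_in_prev, None))  # end point, unused

    # precompute arc sweeps/durations and trough-hold padding per transition
    arcs: list[tuple | None] = []
    holds = np.zeros(n_seg - 1)
    for k in range(n_seg - 1):
        kind, centre, side, r_k = nodes[k + 1]
        if kind == "point":
            arcs.append(None)
            continue
        t_in, t_out = tangents[k]
        sweep, phi0 = _arc_sweep(centre, t_in, t_out, side)
        dur = r_k * sweep / float(v_arc[k])
        arcs.append((centre, side, r_k, sweep, phi0, dur))
        holds[k] = max(0.0, (TROUGH_HOLD - dur) / 2.0)

    t_pieces: list[np.ndarray] = []
    xy_pieces: list[np.ndarray] = []
    t0 = 0.0

    def add_piece(t_rel: np.ndarray, xy: np.ndarray) -> None:
        nonlocal t0
        t_pieces.append(t0 + t_rel)
        xy_pieces.append(xy)
        t0 += float(t_rel[-1])

    # initial stillness (go signal at t = 0, movement after reaction delay)
    if reaction_delay > 0:
        add_piece(np.array([0.0, reaction_delay]), np.vstack([pts[0], pts[0]]))

    for k in range(n_seg):
        A, B = legs[k]
        peak = float(vp[k])
        v_in = 0.0 if (k == 0 or stops[k - 1]) else min(float(v_arc[k - 1]), peak)
        v_out = 0.0 if (k == n_seg - 1 or stops[k]) else min(float(v_arc[k]), peak)
        leg_len = float(np.hypot(*(B - A)))
        d_hat = (B - A) / leg_len
        # straight-line holds at trough speed pad short hook arcs so the
        # smoothed speed minimum sits on a plateau
        hold_in = holds[k - 1] if k >= 1 else 0.0
        hold_out = holds[k] if k < n_seg - 1 else 0.0
        s_in, s_out = v_in * hold_in, v_out * hold_out
        if s_in + s_out > 0.8 * leg_len:
            shrink = 0.8 * leg_len / (s_in + s_out)
            s_in, s_out = s_in * shrink, s_out * shrink
            hold_in, hold_out = hold_in * shrink, hold_out * shrink
        if hold_in > 0:
            add_piece(np.array([0.0, hold_in]),
                      np.vstack([A, A + d_hat * s_in]))
        mid_len = leg_len - s_in - s_out
        v_shape, mean = _segment_speed_profile(v_in, v_out, peak)
        duration = mid_len / mean
        t_rel = np.linspace(0.0, duration, len(v_shape))
        s = np.concatenate([[0.0], np.cumsum(
            (v_shape[1:] + v_shape[:-1]) / 2.0 * np.diff(t_rel)
        )])
        s *= mid_len / s[-1]
        xy = (A + d_hat * s_in) + s[:, None] * d_hat
        add_piece(t_rel, xy)
        if hold_out > 0:
            add_piece(np.array([0.0, hold_out]),
                      np.vstack([B - d_hat * s_out, B]))

        if k == n_seg - 1:
            break
        if arcs[k] is None:  # full stop: dwell inside the target
            centre = nodes[k + 1][1]
            # margin so the *sampled* stillness spans >= dwell_floor
            dwell = dwell_floor + 3.0 * dt_sample
            add_piece(np.array([0.0, dwell]), np.vstack([centre, centre]))
        else:  # constant-speed hook around the target
            centre, side, r_k, sweep, phi0, dur = arcs[k]
            if sweep > 1e-9:
                n_arc = max(16, int(np.ceil(dur / dt_sample)) * 8)
                tau = np.linspace(0.0, 1.0, n_arc)
                phi = phi0 + side * sweep * tau
                xy = centre + r_k * np.column_stack(
                    [np.cos(phi), np.sin(phi)]
                )
                add_piece(dur * tau, xy)

    if rest_tail > 0:
        end = nodes[-1][1]
        add_piece(np.array([0.0, rest_tail]), np.vstack([end, end]))

    # concatenate, dropping each piece's duplicated first time point
    t_fine = np.concatenate(
        [p if i == 0 else p[1:] for i, p in enumerate(t_pieces)]
    )
    xy_fine = np.vstack(
        [p if i == 0 else p[1:] for i, p in enumerate(xy_pieces)]
    )

    t_samp = np.arange(0.0, t_fine[-1], dt_sample)
    x = np.interp(t_samp, t_fine, xy_fine[:, 0])
    y = np.interp(t_samp, t_fine, xy_fine[:, 1])
    if noise_sd > 0:
        if rng is None:
            raise ValueError("noise_sd > 0 requires an rng")
        x = x + rng.normal(0.0, noise_sd, len(x))
        y = y + rng.normal(0.0, noise_sd, len(y))
    return Trajectory(t=t_samp, x=x, y=y, meta=dict(meta or {}))


def _learning_index(phase: str, trial_in_phase: int, n_training: int) -> int:
    """Training-progress index driving the linear learning curves."""
    if phase == "Training":
        return trial_in_phase
    if phase in ("PostRew", "PostNoRew"):
        return n_training
    return 0  # Familiarisation, Baseline


def simulate_trajectory(
    profile: ParticipantProfile,
    trial_index: int,
    layout: TargetLayout,
    config: SimConfig,
    rng: np.random.Generator,
) -> Trajectory:
    """One trial's trajectory at a given training-progress index.

    Peak speed is ``vigour0 + vigour_slope * trial_index`` plus trial
    jitter; the trough fraction is ``fusion0 + fusion_slope * trial_index``
    clamped to [0, fusion_cap], plus jitter.
    """
    if trial_index < 0:
        raise ValueError("trial_index must be >= 0")
    vp_base = profile.vigour0 + profile.vigour_slope * trial_index
    if vp_base <= 0:
        raise ValueError(
            f"non-positive peak speed ({vp_base:.3g} cm/s) at trial {trial_index}"
        )
    vp = vp_base
    if config.peak_jitter_sd > 0:
        vp = vp + rng.normal(0.0, config.peak_jitter_sd)
    vp = max(vp, 0.2 * vp_base)

    f_base = profile.fusion0 + profile.fusion_slope * trial_index
    f = f_base
    if config.fusion_jitter_sd > 0:
        f = f + rng.normal(0.0, config.fusion_jitter_sd)
    f = float(np.clip(f, 0.0, config.fusion_cap))

    delay = config.reaction_delay
    if config.reaction_jitter_sd > 0:
        delay = max(0.05, delay + rng.normal(0.0, config.reaction_jitter_sd))

    return make_trial_trajectory(
        layout,
        peak_speeds=np.full(8, vp),
        trough_fractions=np.full(7, f),
        sampling_rate=config.sampling_rate,
        dwell_floor=config.dwell_floor,
        noise_sd=profile.noise_sd,
        reaction_delay=delay,
        rest_tail=config.rest_tail,
        rng=rng,
        meta={"participant_id": profile.id, "trial_index": trial_index},
    )


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def _participant_rng(seed: int, pidx: int, *stream: int) -> np.random.Generator:
    """Independent stream per participant (and sub-stream), so cohort-size
    changes never reshuffle existing participants."""
    return np.random.default_rng(np.random.SeedSequence([seed, pidx, *stream]))


def _draw_profile(config: SimConfig, pidx: int, reward: str, drug: str) -> ParticipantProfile:
    rng = _participant_rng(config.seed, pidx, 0)
    wm_true = rng.normal()
    wm_class = "high" if wm_true >= 0 else "low"
    vig0 = config.vigour0_mean + rng.normal(0.0, config.vigour0_sd)
    if reward == "Rew":
        vig0 += config.vigour0_reward_shift
    vig0 = max(vig0, 5.0)
    vslope = (
        config.vigour_slope_effects[(reward, drug)]
        + rng.normal(0.0, config.vigour_slope_sd)
    )
    fus0 = float(np.clip(
        config.fusion0_mean + rng.normal(0.0, config.fusion0_sd), 0.0, 0.5
    ))
    fslope = config.fusion_slope_effects[(drug, wm_class)] + rng.normal(
        0.0, config.fusion_slope_sd
    )
    if reward == "Rew":
        fslope += config.fusion_slope_reward_boost
    return ParticipantProfile(
        id=f"P{pidx:03d}",
        reward_group=reward,
        drug_group=drug,
        wm_true=wm_true,
        vigour0=vig0,
        vigour_slope=vslope,
        fusion0=fus0,
        fusion_slope=fslope,
        noise_sd=config.noise_sd,
    )


class Cohort:
    """A simulated cohort: profiles, the full trial schedule, and lazily
    generated trajectories (deterministic in the configuration seed)."""

    def __init__(self, config: SimConfig):
        self.config = config
        self.layout = make_target_layout()
        profiles: list[ParticipantProfile] = []
        pidx = 0
        for reward, drug in GROUPS:
            for _ in range(config.n_per_group):
                profiles.append(_draw_profile(config, pidx, reward, drug))
                pidx += 1
        self.profiles = {p.id: p for p in profiles}
        self._pidx = {p.id: i for i, p in enumerate(profiles)}
        self.trials = self._build_trials()

    def _build_trials(self) -> pd.DataFrame:
        cfg = self.config
        rows = []
        for i, p in enumerate(self.profiles.values()):
            post_order = "RewFirst" if i % 2 == 0 else "NoRewFirst"
            for day in cfg.days:
                sched = build_schedule(
                    day,
                    post_order=post_order,
                    n_familiarisation=cfg.n_familiarisation if (
                        day == 1 and cfg.include_familiarisation) else 0,
                    n_baseline=cfg.n_baseline,
                    n_training=cfg.n_training,
                    n_post_day12=cfg.n_post_day12,
                    n_post_day7=cfg.n_post_day7,
                    include_baseline=(day == 1 or cfg.include_baseline_day2),
                )
                df = sched.trials()
                df.insert(0, "participant_id", p.id)
                df.insert(1, "reward_group", p.reward_group)
                df.insert(2, "drug_group", p.drug_group)
                rows.append(df)
        out = pd.concat(rows, ignore_index=True)
        out["learn_index"] = [
            _learning_index(ph, tr, cfg.n_training)
            for ph, tr in zip(out["phase"], out["trial_in_phase"])
        ]
        return out

    def trajectory(self, trial_row) -> Trajectory:
        """Regenerate the trajectory for one row of :attr:`trials`."""
        p = self.profiles[trial_row["participant_id"]]
        pidx = self._pidx[p.id]
        rng = _participant_rng(
            self.config.seed,
            pidx,
            1,
            int(trial_row["day"]),
            _PHASE_CODE[trial_row["phase"]],
            int(trial_row["trial_in_phase"]),
        )
        traj = simulate_trajectory(
            p, int(trial_row["learn_index"]), self.layout, self.config, rng
        )
        traj.meta.update(
            participant_id=p.id,
            reward_group=p.reward_group,
            drug_group=p.drug_group,
            day=int(trial_row["day"]),
            phase=trial_row["phase"],
            trial_in_phase=int(trial_row["trial_in_phase"]),
            dual_task=bool(trial_row["dual_task"]),
        )
        return traj

    def iter_trajectories(self, **filters) -> Iterator[Trajectory]:
        """Yield trajectories, optionally filtered on trial-table columns
        (e.g. ``day=1, phase='Training'``)."""
        df = self.trials
        for col, val in filters.items():
            df = df[df[col] == val]
        for _, row in df.iterrows():
            yield self.trajectory(row)

    def gonogo(self, participant_id: str) -> pd.DataFrame:
        p = self.profiles[participant_id]
        rng = _participant_rng(self.config.seed, self._pidx[participant_id], 2)
        wm_class = "high" if p.wm_true >= 0 else "low"
        a_win, a_loss = self.config.gonogo_alphas[(p.drug_group, wm_class)]
        return simulate_gonogo(
            p, self.config, rng, alpha_win=a_win, alpha_loss=a_loss
        )

    def vwm(self, participant_id: str) -> pd.DataFrame:
        p = self.profiles[participant_id]
        rng = _participant_rng(self.config.seed, self._pidx[participant_id], 3)
        return simulate_vwm(p, self.config, rng)

    def vwm_scores(self) -> pd.DataFrame:
        """Per-participant VWM accuracy over array lengths 7-9 (%)."""
        rows = []
        for pid in self.profiles:
            df = self.vwm(pid)
            hi = df[df["length"] >= 7]
            rows.append({
                "participant_id": pid,
                "score": 100.0 * hi["correct"].mean(),
            })
        return pd.DataFrame(rows)


def simulate_cohort(config: SimConfig) -> Cohort:
    """Four groups (Rew/NoRew x Halo/Ctrl) of ``n_per_group`` participants
    with the full Day 1/2/7 trial schedule; reproducible from the seed."""
    if config.n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    return Cohort(config)


# ---------------------------------------------------------------------------
# control tasks
# ---------------------------------------------------------------------------

def simulate_gonogo(
    profile: ParticipantProfile,
    config: SimConfig,
    rng: np.random.Generator,
    alpha_win: float | None = None,
    alpha_loss: float | None = None,
    go_bias: float | None = None,
) -> pd.DataFrame:
    """Go/NoGo learning phase: 4 stimuli x 10 presentations in random order.

    The learner keeps a value per stimulus, responds Go with probability
    ``go_bias + (1 - go_bias) * sigmoid(beta * Q)``, and updates only
    after Go feedback, with separate learning rates for wins and losses.
    """
    if alpha_win is None or alpha_loss is None:
        wm_class = "high" if profile.wm_true >= 0 else "low"
        a = config.gonogo_alphas[(profile.drug_group, wm_class)]
        alpha_win = a[0] if alpha_win is None else alpha_win
        alpha_loss = a[1] if alpha_loss is None else alpha_loss
    gb = config.gonogo_go_bias if go_bias is None else go_bias

    win_probs = np.array([
        config.gonogo_win_prob_reward, config.gonogo_win_prob_reward,
        config.gonogo_win_prob_loss, config.gonogo_win_prob_loss,
    ])
    reward_assoc = np.array([True, True, False, False])
    order = np.repeat(np.arange(4), config.gonogo_presentations)
    rng.shuffle(order)

    q = np.zeros(4)
    rows = []
    for s in order:
        p_go = gb + (1.0 - gb) * expit(config.gonogo_beta * q[s])
        go = rng.random() < p_go
        feedback = None
        if go:
            won = rng.random() < win_probs[s]
            feedback = 1 if won else -1
            alpha = alpha_win if won else alpha_loss
            q[s] += alpha * (feedback - q[s])
        rows.append({
            "stimulus": int(s),
            "reward_assoc": bool(reward_assoc[s]),
            "go": bool(go),
            "feedback": feedback,
        })
    df = pd.DataFrame(rows)
    df.index.name = "trial"
    return df.reset_index()


def simulate_vwm(
    profile: ParticipantProfile,
    config: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Verbal working-memory task: 60 trials, array lengths 5-9.

    P(correct) = 0.5 + 0.5 * sigmoid(intercept + wm_gain * wm_true -
    length_cost * (length - 7)); the 0.5 floor reflects guessing between
    match/non-match.  Accuracy rises with latent WM and falls with array
    length, reaching 100% in the high-ability limit.
    """
    lengths = np.tile(config.vwm_lengths,
                      config.vwm_n_trials // len(config.vwm_lengths))
    rng.shuffle(lengths)
    z = (
        config.vwm_intercept
        + config.vwm_wm_gain * profile.wm_true
        - config.vwm_length_cost * (lengths - 7.0)
    )
    p_correct = 0.5 + 0.5 * expit(z)
    correct = rng.random(len(lengths)) < p_correct
    df = pd.DataFrame({"length": lengths, "correct": correct})
    df.index.name = "trial"
    return df.reset_index()


# ---------------------------------------------------------------------------
# fast table-level simulation (for statistical power/recovery studies)
# ---------------------------------------------------------------------------

def simulate_kinematics_table(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    n_analysis_trials: int = 180,
) -> pd.DataFrame:
    """Per-trial analysis table drawn directly from the linear models.

    Skips trajectory synthesis: each participant's vmax_mean, fi_sum and
    mt follow the same participant-level learning curves the trajectory
    generator uses, with Gaussian trial-level residuals.  Intended for
    statistical simulations (parameter recovery, permutation power) where
    the kinematic extraction step is not under study.  Includes Training
    analysis trials 1..n plus the two post-assessment phases.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rows = []
    pidx = 0
    wm_latents = []
    profiles = []
    for reward, drug in GROUPS:
        for _ in range(config.n_per_group):
            p = _draw_profile(config, pidx, reward, drug)
            profiles.append(p)
            wm_latents.append(p.wm_true)
            pidx += 1
    wm_median = float(np.median(wm_latents))
    for p in profiles:
        wm_class = "high" if p.wm_true >= wm_median else "low"
        trials = np.arange(1, n_analysis_trials + 1)
        phases = [("Training", trials)]
        post_trials = np.arange(1, config.n_post_day12 + 1)
        phases += [("PostRew", post_trials), ("PostNoRew", post_trials)]
        for phase, tr in phases:
            k = tr if phase == "Training" else np.full(len(tr), n_analysis_trials)
            vmax = (
                p.vigour0 + p.vigour_slope * k
                + rng.normal(0.0, config.table_vmax_resid_sd, len(tr))
            )
            f = np.clip(p.fusion0 + p.fusion_slope * k, 0.0, config.fusion_cap)
            fi = np.clip(
                7.0 * f + rng.normal(0.0, config.table_fi_resid_sd, len(tr)),
                0.0, 7.0,
            )
            # MT falls as vigour and fusion rise: path length over mean speed
            mean_speed = 0.375 * np.maximum(vmax, 1.0) * (1.0 + 0.6 * f)
            mt = 60.0 / mean_speed + rng.normal(
                0.0, config.table_mt_resid_sd, len(tr)
            )
            for j, t_j in enumerate(tr):
                rows.append({
                    "participant": p.id,
                    "reward": p.reward_group,
                    "drug": p.drug_group,
                    "wm": wm_class,
                    "phase": phase,
                    "trial": int(t_j),
                    "vmax_mean": vmax[j],
                    "fi_sum": fi[j],
                    "mt": max(mt[j], 0.5),
                })
    return pd.DataFrame(rows)
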