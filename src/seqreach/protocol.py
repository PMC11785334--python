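"""Experiment schedule and pre-analysis exclusion filters.

Days 1 and 2: Baseline (10 trials), Training (200), and two post
assessments of 20 trials each (reward first or no-reward first,
counterbalanced).  Day 7: the two post assessments only, 25 trials each.
A force-sensor dual task occupies every 10th Training trial and every
5th trial of the other phases; those trials are flagged here and dropped
before analysis, as are trials longer than 10 s.  Participants whose
mean Baseline movement time exceeds 8.5 s are excluded outright.

After removals, analysis trial numbers are recomputed densely per
participant/day/phase, so Day-1 Training runs 1..180.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import pandas as pd

VALID_DAYS = (1, 2, 7)


@dataclass(frozen=True)
class Phase:
    name: str
    n_trials: int
    rewarded: bool            # reward feedback available (Rew groups only)
    dual_task_every: int      # cadence of dual-task trials (0 = none)
    analysed: bool = True     # familiarisation is generated but never analysed

    def dual_task_flags(self) -> list[bool]:
        # indexed from trial 1 of the phase: trials every, 2*every, ... flagged
        if self.dual_task_every <= 0:
            return [False] * self.n_trials
        return [(i % self.dual_task_every) == 0
                for i in range(1, self.n_trials + 1)]


@dataclass(frozen=True)
class Schedule:
    day: int
    phases: tuple[Phase, ...]

    def trials(self) -> pd.DataFrame:
        rows = []
        for ph in self.phases:
            flags = ph.dual_task_flags()
            for i in range(1, ph.n_trials + 1):
                rows.append({
                    "day": self.day,
                    "phase": ph.name,
                    "trial_in_phase": i,
                    "dual_task": flags[i - 1],
                    "rewarded": ph.rewarded,
                    "analysed": ph.analysed,
                })
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        return json.dumps(
            {"day": self.day, "phases": [asdict(p) for p in self.phases]},
            indent=2,
        )


def build_schedule(
    day: int,
    post_order: str = "RewFirst",
    *,
    n_familiarisation: int = 0,
    n_baseline: int = 10,
    n_training: int = 200,
    n_post_day12: int = 20,
    n_post_day7: int = 25,
    include_baseline: bool = True,
) -> Schedule:
    """Phase list for one day, with dual-task flags.

    Dual-task cadence is every 10th trial in Training and every 5th trial
    elsewhere, counted from trial 1 of each phase.
    """
    if day not in VALID_DAYS:
        raise ValueError(f"invalid day {day!r}; must be one of {VALID_DAYS}")
    if post_order not in ("RewFirst", "NoRewFirst"):
        raise ValueError(f"invalid post_order {post_order!r}")

    phases: list[Phase] = []
    if day in (1, 2):
        if n_familiarisation > 0:
            phases.append(Phase("Familiarisation", n_familiarisation,
                                rewarded=False, dual_task_every=5,
                                analysed=False))
        if include_baseline:
            phases.append(Phase("Baseline", n_baseline,
                                rewarded=False, dual_task_every=5))
        phases.append(Phase("Training", n_training,
                            rewarded=True, dual_task_every=10))
        n_post = n_post_day12
    else:
        n_post = n_post_day7
    post_rew = Phase("PostRew", n_post, rewarded=True, dual_task_every=5)
    post_norew = Phase("PostNoRew", n_post, rewarded=False, dual_task_every=5)
    if post_order == "RewFirst":
        phases += [post_rew, post_norew]
    else:
        phases += [post_norew, post_rew]
    return Schedule(day=day, phases=tuple(phases))


@dataclass
class ExclusionReport:
    """Bookkeeping of removed participants/trials; counts are conserved."""

    removed_participants: list = field(default_factory=list)  # (id, reason)
    removed_trials: dict = field(default_factory=dict)        # reason -> count
    retained_trials: int = 0
    input_trials: int = 0

    @property
    def total_removed_trials(self) -> int:
        return sum(self.removed_trials.values())

    def check_conserved(self) -> bool:
        return self.retained_trials + self.total_removed_trials == self.input_trials

    def to_json(self) -> str:
        return json.dumps({
            "removed_participants": self.removed_participants,
            "removed_trials": self.removed_trials,
            "retained_trials": self.retained_trials,
            "input_trials": self.input_trials,
        }, indent=2)


def exclude_baseline_outlier_participants(
    baseline_mts: Mapping[str, Sequence[float]],
    threshold: float = 8.5,
) -> ExclusionReport:
    """Flag participants whose mean Baseline MT exceeds ``threshold`` (s)."""
    report = ExclusionReport()
    n_trials = 0
    for pid, mts in baseline_mts.items():
        mts = list(mts)
        if not mts:
            raise ValueError(f"participant {pid!r} has no Baseline MTs")
        n_trials += len(mts)
        mean = sum(mts) / len(mts)
        if mean > threshold:
            report.removed_participants.append(
                (pid, f"baseline mean MT {mean:.2f}s > {threshold}s")
            )
    report.input_trials = n_trials
    report.retained_trials = n_trials
    return report


def exclude_trials(
    trial_table: pd.DataFrame,
    mt_cap: float = 10.0,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop dual-task and overlong (> ``mt_cap`` s) trials, renumber densely.

    The filtered table gains an ``analysis_trial`` column: 1..n within
    each (participant, day, phase) in the original trial order, so a full
    Day-1 Training block renumbers to 1..180.  Idempotent.
    """
    if "mt" not in trial_table or "dual_task" not in trial_table:
        raise ValueError("trial table must carry 'mt' and 'dual_task' columns")
    report = ExclusionReport(input_trials=len(trial_table))
    dual = trial_table["dual_task"].astype(bool)
    overlong = (trial_table["mt"] > mt_cap) & ~dual
    drop_fam = (
        (trial_table["analysed"] == False) & ~dual & ~overlong  # noqa: E712
        if "analysed" in trial_table else pd.Series(False, index=trial_table.index)
    )
    report.removed_trials = {
        "dual_task": int(dual.sum()),
        "overlong": int(overlong.sum()),
        "not_analysed": int(drop_fam.sum()),
    }
    kept = trial_table[~dual & ~overlong & ~drop_fam].copy()
    report.retained_trials = len(kept)

    group_cols = [c for c in ("participant_id", "participant", "day", "phase")
                  if c in kept.columns]
    if group_cols:
        kept["analysis_trial"] = kept.groupby(group_cols).cumcount() + 1
    else:
        kept["analysis_trial"] = range(1, len(kept) + 1)
    return kept, report
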