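"""End-to-end orchestration: simulate -> kinematics -> exclusions ->
reward replay -> statistics, persisted as a reproducible run directory.

A run is fully determined by its :class:`RunConfig`; every intermediate
table is written out, and a manifest records the config hash, seed and
library versions so any artifact can be regenerated.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from seqreach import kinematics as km
from seqreach import stats as st
from seqreach.protocol import (
    exclude_baseline_outlier_participants,
    exclude_trials,
)
from seqreach.reward import replay_block, seed_block_boundary
from seqreach.simulate import SimConfig, simulate_cohort

log = logging.getLogger("seqreach")


@dataclass
class RunConfig:
    """Everything a pipeline run depends on."""

    sim: SimConfig = field(default_factory=SimConfig)
    sigma: float = 2.0                 # velocity smoothing (samples)
    mt_cap: float = 10.0               # overlong-trial threshold (s)
    baseline_outlier_threshold: float = 8.5
    reward_mode: str = "percentile"
    n_perm: int = 5000
    alpha: float = 0.05
    analysis_days: tuple[int, ...] = (1,)
    lmm_dvs: tuple[str, ...] = ("vmax_mean", "fi_sum", "mt")
    write_trajectories: bool = False
    out_dir: str = "seqreach_run"

    @classmethod
    def demo(cls, seed: int = 0, out_dir: str = "seqreach_run") -> "RunConfig":
        """Small, fast profile for smoke runs."""
        sim = SimConfig(
            n_per_group=2, seed=seed, n_familiarisation=0, n_baseline=10,
            n_training=40, n_post_day12=10, n_post_day7=10, days=(1,),
        )
        return cls(sim=sim, n_perm=200, out_dir=out_dir)

    @classmethod
    def paper_scale(cls, seed: int = 0, out_dir: str = "seqreach_run") -> "RunConfig":
        """Full study-scale profile (4 x 23 participants, 200 training
        trials, 5000 permutations).  Slow."""
        return cls(sim=SimConfig(n_per_group=23, seed=seed),
                   n_perm=5000, out_dir=out_dir)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # dict keys that are tuples do not serialise; flatten
        for key in ("vigour_slope_effects", "fusion_slope_effects",
                    "gonogo_alphas"):
            d["sim"][key] = {"|".join(k): v for k, v in d["sim"][key].items()}
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", {})
        for key in ("vigour_slope_effects", "fusion_slope_effects",
                    "gonogo_alphas"):
            if key in sim_raw:
                sim_raw[key] = {
                    tuple(k.split("|")): (tuple(v) if isinstance(v, list) else v)
                    for k, v in sim_raw[key].items()
                }
        for key in ("days", "vwm_lengths"):
            if key in sim_raw:
                sim_raw[key] = tuple(sim_raw[key])
        for key in ("analysis_days", "lmm_dvs"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(sim=SimConfig(**sim_raw), **raw)


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory.

    Stages: cohort simulation, kinematic extraction, participant/trial
    exclusion, closed-loop reward replay, LMM + marginal slopes +
    pairwise z-tests, permutation window test, post-assessment ANOVA,
    and Go/NoGo + working-memory positive-control summaries.  Stage
    failures abort with the stage name; partial outputs stay on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.StreamHandler(sys.stderr)
    if not log.handlers:
        log.addHandler(handler)
        log.setLevel(logging.INFO)
    outputs: dict[str, str] = {}
    stage = "init"

    def _write(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False)
        outputs[name] = _file_hash(path)

    def _write_json(obj, name: str) -> None:
        path = out / name
        path.write_text(json.dumps(obj, indent=2, default=str))
        outputs[name] = _file_hash(path)

    try:
        stage = "simulate"
        log.info("stage %s", stage)
        cohort = simulate_cohort(config.sim)
        _write(cohort.trials, "schedule.csv")
        profiles = pd.DataFrame([dataclasses.asdict(p)
                                 for p in cohort.profiles.values()])
        _write(profiles, "profiles.csv")

        stage = "kinematics"
        log.info("stage %s", stage)
        traj_dir = out / "trajectories"
        if config.write_trajectories:
            traj_dir.mkdir(exist_ok=True)
        rows = []
        for traj in cohort.iter_trajectories():
            k = km.analyse_trial(traj, cohort.layout, sigma=config.sigma)
            row = dict(traj.meta)
            row.pop("trial_index", None)
            row.update(mt=k.mt, reaction_time=k.reaction_time,
                       vmax_mean=k.vmax_mean, fi_sum=k.fi_sum,
                       n_fi_clamped=k.n_fi_clamped)
            rows.append(row)
            if config.write_trajectories:
                m = traj.meta
                fname = (f"{m['participant_id']}_d{m['day']}_{m['phase']}"
                         f"_{m['trial_in_phase']:03d}.csv")
                traj.to_frame().to_csv(traj_dir / fname, index=False)
        trial_table = pd.DataFrame(rows)
        sched_cols = cohort.trials[
            ["participant_id", "day", "phase", "trial_in_phase", "analysed"]
        ]
        trial_table = trial_table.merge(
            sched_cols, on=["participant_id", "day", "phase", "trial_in_phase"]
        )
        _write(trial_table, "trials.csv")

        stage = "exclusions"
        log.info("stage %s", stage)
        base = trial_table[(trial_table["day"] == 1)
                           & (trial_table["phase"] == "Baseline")]
        baseline_mts = {pid: g["mt"].tolist()
                        for pid, g in base.groupby("participant_id")}
        p_report = exclude_baseline_outlier_participants(
            baseline_mts, threshold=config.baseline_outlier_threshold
        )
        removed_ids = {pid for pid, _ in p_report.removed_participants}
        kept = trial_table[~trial_table["participant_id"].isin(removed_ids)]
        analysis, t_report = exclude_trials(kept, mt_cap=config.mt_cap)
        _write(analysis, "analysis_trials.csv")
        _write_json({
            "participants": json.loads(p_report.to_json()),
            "trials": json.loads(t_report.to_json()),
        }, "exclusion_report.json")

        stage = "reward_replay"
        log.info("stage %s", stage)
        fb_rows = []
        rewarded = trial_table[
            trial_table["reward_group"] == "Rew"
        ].sort_values(["participant_id", "day", "phase", "trial_in_phase"])
        for (pid, day), g in rewarded.groupby(["participant_id", "day"]):
            prev = g[g["phase"] == "Baseline"]["mt"].tolist()
            for phase in ("Training", "PostRew"):
                block = g[g["phase"] == phase]
                if block.empty:
                    continue
                state = seed_block_boundary(prev) if prev else None
                if state is None:
                    continue
                fb = replay_block(state, block["mt"].tolist(),
                                  mode=config.reward_mode)
                fb.insert(0, "participant_id", pid)
                fb.insert(1, "day", day)
                fb.insert(2, "phase", phase)
                fb.insert(3, "trial_in_phase",
                          block["trial_in_phase"].to_numpy())
                fb_rows.append(fb)
                prev = block["mt"].tolist()
        if fb_rows:
            _write(pd.concat(fb_rows, ignore_index=True), "feedback.csv")

        stage = "positive_control"
        log.info("stage %s", stage)
        scores = cohort.vwm_scores()
        wm = st.wm_median_split(scores)
        ra_rows = []
        for pid, prof in cohort.profiles.items():
            ra = st.response_accuracy(cohort.gonogo(pid))
            ra_rows.append({
                "participant_id": pid, "drug": prof.drug_group,
                "learn_plus": ra.learn_plus, "learn_minus": ra.learn_minus,
                "delta": ra.delta,
            })
        ra_df = pd.DataFrame(ra_rows).merge(
            wm[["participant_id", "wm_class"]], on="participant_id"
        )
        _write(ra_df, "gonogo_accuracy.csv")
        _write(wm, "wm_split.csv")

        stage = "stats"
        log.info("stage %s", stage)
        lmm_table = analysis[(analysis["phase"] == "Training")].merge(
            wm[["participant_id", "wm_class"]], on="participant_id"
        ).rename(columns={
            "participant_id": "participant", "reward_group": "reward",
            "drug_group": "drug", "wm_class": "wm",
            "analysis_trial": "trial",
        })
        stats_summary: dict = {}
        for day in config.analysis_days:
            day_tab = lmm_table[lmm_table["day"] == day]
            if day_tab.empty:
                continue
            day_summary: dict = {}
            # the full three-factor design needs every Reward x Drug x WM
            # cell populated; small cohorts drop WM (flagged)
            cells = day_tab.groupby(["reward", "drug", "wm"], observed=True)[
                "participant"].nunique()
            factors = (("reward", "drug", "wm") if len(cells) == 8
                       else ("reward", "drug"))
            for dv in config.lmm_dvs:
                try:
                    res = st.fit_lmm(day_tab, dv, factors=factors)
                except Exception as exc:  # noqa: BLE001 - recorded, not fatal
                    day_summary[dv] = {"error": str(exc)}
                    continue
                slopes = st.marginal_slopes(res, grouping=("reward", "drug"))
                ztests = st.pairwise_slope_ztests(slopes)
                day_summary[dv] = {
                    "converged": res.converged,
                    "fallback": res.fallback,
                    "wm_in_model": "wm" in factors,
                    "fixed_effects": res.table.to_dict(orient="records"),
                    "marginal_slopes": [dataclasses.asdict(s) for s in slopes],
                    "pairwise_z": ztests.to_dict(orient="records"),
                }
            # permutation window test: Halo vs Ctrl within the Rew groups
            rew = day_tab[day_tab["reward"] == "Rew"]
            piv = rew.pivot_table(index="participant", columns="trial",
                                  values="vmax_mean")
            halo_ids = rew[rew["drug"] == "Halo"]["participant"].unique()
            a = piv.loc[piv.index.isin(halo_ids)]
            b = piv.loc[~piv.index.isin(halo_ids)]
            if len(a) >= 2 and len(b) >= 2:
                wres = st.permutation_window_test(
                    a, b, n_perm=config.n_perm, alpha=config.alpha,
                    rng=np.random.default_rng(config.sim.seed + 1),
                )
                day_summary["permutation_vmax_rew"] = {
                    "windows": [[int(s), int(e)] for s, e in wres.windows],
                    "n_significant": int(wres.significant.sum()),
                }
            # post assessments
            post = analysis[
                (analysis["day"] == day)
                & analysis["phase"].isin(["PostRew", "PostNoRew"])
            ].merge(wm[["participant_id", "wm_class"]], on="participant_id"
                    ).rename(columns={
                        "participant_id": "participant",
                        "reward_group": "reward", "drug_group": "drug",
                        "wm_class": "wm",
                    })
            try:
                pres = st.post_assessment_anova(post, "vmax_mean",
                                                alpha=config.alpha)
                day_summary["post_anova_vmax"] = {
                    "anova": pres.anova.to_dict(orient="records"),
                    "ks": pres.ks.to_dict(orient="records"),
                    "followups": (pres.followups.to_dict(orient="records")
                                  if pres.followups is not None else None),
                }
            except ValueError as exc:
                day_summary["post_anova_vmax"] = {"error": str(exc)}
            stats_summary[f"day{day}"] = day_summary
        _write_json(stats_summary, "stats_summary.json")

        stage = "manifest"
        import scipy
        import statsmodels
        manifest = {
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "seed": config.sim.seed,
            "versions": {
                "python": sys.version.split()[0],
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "scipy": scipy.__version__,
                "statsmodels": statsmodels.__version__,
            },
            "outputs": outputs,
        }
        _write_json(manifest, "manifest.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out
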