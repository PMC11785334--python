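"""Statistical procedures: WM split, response accuracy, mixed models,
marginal slopes, permutation windows, post-assessment ANOVA."""

import itertools
import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from patsy import dmatrix

import statsmodels.formula.api as smf

from seqreach.simulate import SimConfig, simulate_kinematics_table
from seqreach.stats import (
    LmmResult,
    SlopeEstimate,
    fit_lmm,
    lmm_formula,
    marginal_slopes,
    pairwise_slope_ztests,
    permutation_window_test,
    post_assessment_anova,
    response_accuracy,
    se_from_ci95,
    wm_median_split,
)


class TestWmMedianSplit:
    def test_two_participants(self):
        out = wm_median_split({"a": 40.0, "b": 60.0})
        cls = dict(zip(out["participant_id"], out["wm_class"]))
        assert cls == {"a": "low", "b": "high"}

    def test_ties_at_median_go_high(self):
        out = wm_median_split({"a": 50.0, "b": 50.0, "c": 50.0})
        assert (out["wm_class"] == "high").all()

    def test_cohort_scale_split(self):
        scores = {f"P{i}": 40.0 for i in range(44)}
        scores.update({f"P{i}": 60.0 for i in range(44, 92)})
        out = wm_median_split(scores)
        assert (out["wm_class"] == "low").sum() == 44
        assert (out["wm_class"] == "high").sum() == 48


class TestResponseAccuracy:
    def test_always_go(self):
        log = pd.DataFrame({
            "reward_assoc": [True] * 20 + [False] * 20,
            "go": [True] * 40,
        })
        ra = response_accuracy(log)
        assert ra.learn_plus == 100.0 and ra.learn_minus == 0.0

    def test_hand_built_counts(self):
        rows = []
        for stim in range(2):  # reward runes: 7/10 Go
            rows += [{"reward_assoc": True, "go": i < 7} for i in range(10)]
        for stim in range(2):  # loss runes: 6/10 NoGo
            rows += [{"reward_assoc": False, "go": i >= 6} for i in range(10)]
        ra = response_accuracy(pd.DataFrame(rows))
        assert ra.learn_plus == pytest.approx(70.0)
        assert ra.learn_minus == pytest.approx(60.0)
        assert ra.delta == pytest.approx(10.0)


def _fixed_result(formula_rhs, data, params, factor_levels, trial_col="trial"):
    design = dmatrix(formula_rhs, data)
    names = design.design_info.column_names
    beta = pd.Series([params[n] for n in names], index=names)
    cov = np.eye(len(names)) * 1e-4
    return LmmResult.from_fixed(beta, cov, design.design_info, trial_col,
                                factor_levels)


class TestMarginalSlopes:
    def test_main_effect_only_gives_common_slope(self):
        data = pd.DataFrame({
            "reward": ["Rew", "NoRew"] * 4, "trial": np.arange(8.0)
        })
        rhs = "C(reward, Treatment('NoRew')) * trial"
        params = {
            "Intercept": 1.0,
            "C(reward, Treatment('NoRew'))[T.Rew]": 0.5,
            "trial": 0.3,
            "C(reward, Treatment('NoRew'))[T.Rew]:trial": 0.0,
        }
        res = _fixed_result(rhs, data, params,
                            {"reward": ["NoRew", "Rew"]})
        slopes = marginal_slopes(res, grouping=("reward",))
        assert all(s.beta == pytest.approx(0.3) for s in slopes)

    def test_interaction_adds_to_reference_slope(self):
        data = pd.DataFrame({
            "reward": ["Rew", "NoRew"] * 4, "trial": np.arange(8.0)
        })
        rhs = "C(reward, Treatment('NoRew')) * trial"
        params = {
            "Intercept": 1.0,
            "C(reward, Treatment('NoRew'))[T.Rew]": 0.5,
            "trial": 0.3,
            "C(reward, Treatment('NoRew'))[T.Rew]:trial": 0.2,
        }
        res = _fixed_result(rhs, data, params,
                            {"reward": ["NoRew", "Rew"]})
        by_label = {s.group["reward"]: s.beta
                    for s in marginal_slopes(res, grouping=("reward",))}
        assert by_label["NoRew"] == pytest.approx(0.3)
        assert by_label["Rew"] == pytest.approx(0.5)

    def test_matches_per_group_ols_on_noise_free_data(self):
        """Marginal slopes from the factorial fit equal per-cell
        least-squares slopes averaged over the non-grouping factor."""
        rng = np.random.default_rng(0)
        cells = list(itertools.product(("Rew", "NoRew"), ("Halo", "Ctrl"),
                                       ("high", "low")))
        slopes_true = {c: rng.uniform(-1, 1) for c in cells}
        rows = []
        for c in cells:
            for trial in range(1, 11):
                rows.append({
                    "reward": c[0], "drug": c[1], "wm": c[2], "trial": trial,
                    "dv": 2.0 + slopes_true[c] * trial,
                })
        df = pd.DataFrame(rows)
        ols = smf.ols(lmm_formula("dv"), df).fit()
        res = LmmResult.from_fixed(
            ols.params, ols.cov_params(), ols.model.data.design_info,
            "trial", {f: sorted(df[f].unique())
                      for f in ("reward", "drug", "wm")},
        )
        for s in marginal_slopes(res, grouping=("reward", "drug")):
            oracle = np.mean([
                slopes_true[(s.group["reward"], s.group["drug"], wm)]
                for wm in ("high", "low")
            ])
            assert s.beta == pytest.approx(oracle, abs=1e-6)

    def test_unknown_grouping_factor_rejected(self):
        data = pd.DataFrame({"reward": ["Rew", "NoRew"], "trial": [0.0, 1.0]})
        res = _fixed_result(
            "C(reward, Treatment('NoRew')) * trial", data,
            {"Intercept": 0, "C(reward, Treatment('NoRew'))[T.Rew]": 0,
             "trial": 0, "C(reward, Treatment('NoRew'))[T.Rew]:trial": 0},
            {"reward": ["NoRew", "Rew"]},
        )
        with pytest.raises(ValueError, match="outside the design"):
            marginal_slopes(res, grouping=("dose",))


class TestPairwiseZ:
    def test_identical_slopes_null(self):
        s = [SlopeEstimate("a", {}, 1.0, 0.2, (0.6, 1.4), 0.1),
             SlopeEstimate("b", {}, 1.0, 0.2, (0.6, 1.4), 0.1)]
        out = pairwise_slope_ztests(s)
        assert out["z"].iloc[0] == 0.0
        assert out["p_raw"].iloc[0] == pytest.approx(1.0)

    def test_published_interval_conversion(self):
        """z from two slopes reported with 95% CIs (SE = width/3.92)."""
        se_a = se_from_ci95(1.0, 3.7)
        se_b = se_from_ci95(-1.76, 0.85)
        s = [SlopeEstimate("ctrl-r", {}, 2.4, se_a, (1.0, 3.7), 0.0),
             SlopeEstimate("halo-r", {}, -0.46, se_b, (-1.76, 0.85), 0.0)]
        out = pairwise_slope_ztests(s)
        assert abs(out["z"].iloc[0]) == pytest.approx(2.99, abs=0.01)

    def test_bonferroni_over_six_pairs(self):
        s = [SlopeEstimate(f"g{i}", {}, 0.1 * i, 0.5, (0, 0), 0.5)
             for i in range(4)]
        out = pairwise_slope_ztests(s)
        assert len(out) == 6
        assert np.allclose(out["p_bonferroni"],
                           np.minimum(out["p_raw"] * 6, 1.0))

    def test_zero_se_rejected(self):
        s = [SlopeEstimate("a", {}, 1.0, 0.0, (1, 1), 0.0),
             SlopeEstimate("b", {}, 2.0, 0.1, (1.8, 2.2), 0.0)]
        with pytest.raises(ValueError):
            pairwise_slope_ztests(s)


@pytest.fixture(scope="module")
def small_table():
    cfg = SimConfig(n_per_group=4, seed=21)
    tab = simulate_kinematics_table(cfg, n_analysis_trials=40)
    return tab[tab["phase"] == "Training"]


class TestFitLmm:
    def test_full_factorial_terms_present(self, small_table):
        res = fit_lmm(small_table, "vmax_mean")
        assert len(res.fe_params) == 16  # 2*2*2*2 factorial expansion
        assert res.converged
        terms = set(res.table["term"])
        assert "Reward[Rew] x Drug[Ctrl] x Wm[high] x trial" in terms

    def test_location_equivariance(self, small_table):
        res1 = fit_lmm(small_table, "vmax_mean")
        shifted = small_table.assign(vmax_mean=small_table["vmax_mean"] + 10.0)
        res2 = fit_lmm(shifted, "vmax_mean")
        assert (res2.fe_params["Intercept"] - res1.fe_params["Intercept"]
                == pytest.approx(10.0, abs=1e-4))
        rest1 = res1.fe_params.drop("Intercept")
        rest2 = res2.fe_params.drop("Intercept")
        assert np.allclose(rest1, rest2, atol=1e-5)

    def test_agrees_with_lme4_reference(self, small_table, tmp_path):
        """Fixed effects match an independent lme4 REML fit of the same
        random-intercept + random-slope model."""
        assert shutil.which("Rscript"), "Rscript expected on PATH"
        csv = tmp_path / "table.csv"
        small_table.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(f"""
suppressMessages(library(lme4)); suppressMessages(library(jsonlite))
d <- read.csv("{csv}")
d$reward <- relevel(factor(d$reward), ref="NoRew")
d$drug <- relevel(factor(d$drug), ref="Halo")
d$wm <- relevel(factor(d$wm), ref="low")
m <- lmer(vmax_mean ~ reward*drug*wm*trial + (trial | participant),
          data=d, REML=TRUE)
cat(toJSON(list(fixef=as.list(fixef(m))), digits=12))
""")
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr[-500:]
        ref = json.loads(out.stdout)["fixef"]

        res = fit_lmm(small_table, "vmax_mean")

        def r_name(term):
            t = term.replace("C(reward, Treatment('NoRew'))[T.Rew]",
                             "rewardRew")
            t = t.replace("C(drug, Treatment('Halo'))[T.Ctrl]", "drugCtrl")
            t = t.replace("C(wm, Treatment('low'))[T.high]", "wmhigh")
            return t.replace("Intercept", "(Intercept)")

        for term, beta in res.fe_params.items():
            expected = ref[r_name(term)][0]
            assert beta == pytest.approx(expected, abs=1e-4), term


class TestPermutationWindow:
    def test_identical_groups_never_significant(self, rng):
        a = rng.normal(0, 1, (6, 30))
        res = permutation_window_test(a, a.copy(), n_perm=300, rng=rng)
        assert np.allclose(res.t_obs, 0.0)
        assert not res.significant.any()
        assert res.windows == []

    def test_strong_shift_localised(self, rng):
        a = rng.normal(0, 1, (12, 50))
        b = rng.normal(0, 1, (12, 50))
        b[:, 20:25] += 3.0
        res = permutation_window_test(a, b, n_perm=400, rng=rng)
        sig_trials = set(res.trial_labels[res.significant])
        assert {21, 22, 23, 24, 25} <= sig_trials

    def test_nan_trials_handled(self, rng):
        a = rng.normal(0, 1, (6, 20))
        b = rng.normal(0, 1, (6, 20))
        a[0, 3] = np.nan
        res = permutation_window_test(a, b, n_perm=200, rng=rng)
        assert np.isfinite(res.t_obs).all()

    def test_small_group_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 2"):
            permutation_window_test(np.zeros((1, 10)), np.zeros((5, 10)),
                                    rng=rng)

    def test_low_n_perm_warns(self, rng):
        a = rng.normal(0, 1, (4, 10))
        with pytest.warns(UserWarning, match="n_perm"):
            permutation_window_test(a, a + 0.1, n_perm=50, rng=rng)


def _post_table(rng, n_per_group=23, shift_group=None, shift=0.0,
                noise=0.5, n_trials=10):
    rows = []
    pid = 0
    for reward in ("Rew", "NoRew"):
        for drug in ("Halo", "Ctrl"):
            for i in range(n_per_group):
                base = rng.normal(0, 1)
                wm = "high" if i % 2 == 0 else "low"
                for phase in ("PostRew", "PostNoRew"):
                    bump = (shift if (phase == "PostRew"
                                      and (reward, drug) == shift_group)
                            else 0.0)
                    for _ in range(n_trials):
                        rows.append({
                            "participant": f"P{pid}", "reward": reward,
                            "drug": drug, "wm": wm, "phase": phase,
                            "dv": base + bump + rng.normal(0, noise),
                        })
                pid += 1
    return pd.DataFrame(rows)


class TestPostAssessmentAnova:
    def test_participant_medians_match_brute_force(self, rng):
        tab = _post_table(rng, n_per_group=3)
        res = post_assessment_anova(tab, "dv")
        for _, row in res.medians.iterrows():
            for phase in ("PostRew", "PostNoRew"):
                direct = tab[(tab["participant"] == row["participant"])
                             & (tab["phase"] == phase)]["dv"].median()
                assert row[phase] == pytest.approx(direct)

    def test_constant_dv_yields_no_effects(self, rng):
        tab = _post_table(rng, n_per_group=4, noise=0.0)
        tab["dv"] = 3.0
        res = post_assessment_anova(tab, "dv")
        assert not (res.anova["p"] < 0.5).any()  # F are 0/NaN under nullity
        assert res.followups is None

    def test_missing_phase_rejected(self, rng):
        tab = _post_table(rng, n_per_group=3)
        broken = tab[~((tab["participant"] == "P0")
                       & (tab["phase"] == "PostRew"))]
        with pytest.raises(ValueError, match="missing phase"):
            post_assessment_anova(broken, "dv")

    def test_timepoint_shift_in_one_group_detected(self):
        """A post-Rew-only shift in the placebo-reward group surfaces as the
        Timepoint x Reward x Drug interaction in most simulated cohorts."""
        rng = np.random.default_rng(99)
        hits = 0
        n_sims = 100
        for _ in range(n_sims):
            tab = _post_table(rng, shift_group=("Rew", "Ctrl"), shift=0.6)
            res = post_assessment_anova(tab, "dv")
            p = res.anova.set_index("effect").loc["timepoint:reward:drug", "p"]
            hits += p < 0.05
        assert hits >= 0.9 * n_sims

    def test_followups_report_fdr_and_effect_size(self):
        rng = np.random.default_rng(5)
        tab = _post_table(rng, shift_group=("Rew", "Ctrl"), shift=1.0)
        res = post_assessment_anova(tab, "dv")
        assert res.followups is not None
        assert {"p_raw", "p_fdr", "cohens_d"} <= set(res.followups.columns)
        # FDR-adjusted p-values are monotone in the raw ones
        ordered = res.followups.sort_values("p_raw")
        assert ordered["p_fdr"].is_monotonic_increasing
        assert res.ks["p"].notna().all()
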