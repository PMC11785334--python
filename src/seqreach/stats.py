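"""Inference procedures for the sequential reaching analysis.

* working-memory median split (below-median -> low, ties -> high);
* Go/NoGo response accuracy (Learn+ / Learn-);
* linear mixed model ``dv ~ Reward*Drug*WM*Trial + (Trial | participant)``
  fitted by REML with treatment coding (NoReward, haloperidol and low WM
  as reference levels), delegated to statsmodels MixedLM;
* marginal per-group trial slopes from the fixed-effect contrast, with
  pairwise z-tests and Bonferroni correction;
* a row-shuffle permutation test locating trial windows where two groups
  differ (per-trial Welch t against a label-permutation null);
* mixed ANOVA on per-participant post-assessment medians (between:
  Reward, Drug, WM; within: Timepoint), with Kolmogorov-Smirnov
  normality checks and Wilcoxon rank-sum follow-ups under FDR control.

Fixed-effect tests use Wald z statistics (the large-sample normal
approximation); confidence intervals are beta +/- 1.96 * SE.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from patsy import build_design_matrices
from statsmodels.stats.multitest import multipletests

FACTORS = ("reward", "drug", "wm")
REFERENCE_LEVELS = {"reward": "NoRew", "drug": "Halo", "wm": "low"}


# ---------------------------------------------------------------------------
# working memory and Go/NoGo accuracy
# ---------------------------------------------------------------------------

def wm_median_split(scores) -> pd.DataFrame:
    """Classify participants as low/high WM by the cohort median score.

    ``scores``: mapping id -> score, or a DataFrame with columns
    ``participant_id`` and ``score`` (percent correct over array lengths
    7-9).  Scores strictly below the median are 'low'; ties go 'high'.
    """
    if isinstance(scores, Mapping):
        df = pd.DataFrame(
            {"participant_id": list(scores), "score": list(scores.values())}
        )
    else:
        df = scores[["participant_id", "score"]].copy()
    if len(df) < 2:
        raise ValueError("need at least 2 participants for a median split")
    median = float(df["score"].median())
    df["cohort_median"] = median
    df["wm_class"] = np.where(df["score"] < median, "low", "high")
    return df


@dataclass(frozen=True)
class ResponseAccuracy:
    learn_plus: float   # % Go on reward-associated stimuli
    learn_minus: float  # % NoGo on loss-associated stimuli

    @property
    def delta(self) -> float:
        return self.learn_plus - self.learn_minus


def response_accuracy(log: pd.DataFrame) -> ResponseAccuracy:
    """Learn+ / Learn- accuracy from a Go/NoGo response log.

    ``log`` needs boolean columns ``reward_assoc`` and ``go``.
    """
    rew = log[log["reward_assoc"].astype(bool)]
    loss = log[~log["reward_assoc"].astype(bool)]
    learn_plus = 100.0 * rew["go"].astype(bool).mean() if len(rew) else np.nan
    learn_minus = 100.0 * (~loss["go"].astype(bool)).mean() if len(loss) else np.nan
    return ResponseAccuracy(float(learn_plus), float(learn_minus))


# ---------------------------------------------------------------------------
# linear mixed model and marginal slopes
# ---------------------------------------------------------------------------

def _clean_term(term: str) -> str:
    out = term
    for factor, ref in REFERENCE_LEVELS.items():
        out = out.replace(f"C({factor}, Treatment('{ref}'))", factor.capitalize())
    return out.replace("[T.", "[").replace(":", " x ")


@dataclass
class LmmResult:
    """Fixed-effect estimates and covariance of the fitted mixed model."""

    dv: str
    trial_col: str
    formula: str
    fe_params: pd.Series        # fixed-effect estimates
    cov_fe: pd.DataFrame        # their covariance
    bse: pd.Series
    tvalues: pd.Series          # Wald z statistics
    pvalues: pd.Series          # two-sided normal p-values
    design_info: object         # patsy design info of the fixed part
    factor_levels: dict         # observed levels per factor
    converged: bool = True
    fallback: str | None = None  # e.g. 'dropped_random_slope'
    cov_re: pd.DataFrame | None = None  # random-effect (co)variances
    aic: float = np.nan
    bic: float = np.nan
    llf: float = np.nan

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": [_clean_term(t) for t in self.fe_params.index],
            "estimate": self.fe_params.values,
            "se": self.bse.values,
            "z": self.tvalues.values,
            "p": self.pvalues.values,
        })

    @classmethod
    def from_fixed(cls, params, cov, design_info, trial_col, factor_levels,
                   dv="dv", formula="") -> "LmmResult":
        """Wrap externally fitted fixed effects (e.g. an OLS fit) so the
        marginal-slope machinery can be applied/validated against them."""
        params = pd.Series(params)
        cov = pd.DataFrame(cov, index=params.index, columns=params.index)
        bse = pd.Series(np.sqrt(np.diag(cov)), index=params.index)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = params / bse
        p = pd.Series(2 * scipy.stats.norm.sf(np.abs(z)), index=params.index)
        return cls(dv=dv, trial_col=trial_col, formula=formula,
                   fe_params=params, cov_fe=cov, bse=bse, tvalues=z,
                   pvalues=p, design_info=design_info,
                   factor_levels=dict(factor_levels))


def lmm_formula(dv: str, trial_col: str = "trial",
                factors: Sequence[str] = FACTORS) -> str:
    parts = [
        f"C({f}, Treatment('{REFERENCE_LEVELS[f]}'))" for f in factors
    ] + [trial_col]
    return f"{dv} ~ " + " * ".join(parts)


def fit_lmm(
    table: pd.DataFrame,
    dv: str,
    trial_col: str = "trial",
    group_col: str = "participant",
    reml: bool = True,
    random_slope: bool = True,
    factors: Sequence[str] = FACTORS,
) -> LmmResult:
    """Fit the full-factorial mixed model for one dependent variable.

    Fixed part: Reward * Drug * WM * TrialNumber with treatment coding
    (references: NoReward, haloperidol, low WM).  Random part: intercept
    and TrialNumber slope per participant.  REML by default.  If the
    random-slope model fails to converge the model is refitted with a
    random intercept only and the result flagged (``fallback``), never
    silently.  ``factors`` may be a subset of the three between factors
    when a design cell is unpopulated (small cohorts).
    """
    missing = [c for c in (*factors, trial_col, group_col, dv)
               if c not in table.columns]
    if missing:
        raise ValueError(f"trial table is missing columns: {missing}")
    formula = lmm_formula(dv, trial_col, factors)
    factor_levels = {f: sorted(table[f].unique()) for f in factors}
    for f, levels in factor_levels.items():
        if REFERENCE_LEVELS[f] not in levels:
            raise ValueError(
                f"factor {f!r} lacks its reference level {REFERENCE_LEVELS[f]!r}"
            )

    def _fit(re_formula):
        model = smf.mixedlm(formula, table, groups=table[group_col],
                            re_formula=re_formula)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return model.fit(reml=reml, method=["lbfgs", "powell"])

    fallback = None
    res = None
    if random_slope:
        try:
            res = _fit(f"~{trial_col}")
        except (np.linalg.LinAlgError, ValueError):
            res = None
        if res is None or not res.converged:
            fallback = "dropped_random_slope"
            res = _fit("~1")
    else:
        res = _fit("~1")

    fe_names = list(res.model.exog_names)
    cov_all = res.cov_params()
    cov_fe = pd.DataFrame(np.asarray(cov_all)[: len(fe_names), : len(fe_names)],
                          index=fe_names, columns=fe_names)
    fe = res.fe_params.copy()
    bse = res.bse_fe.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        z = fe / bse
    p = pd.Series(2 * scipy.stats.norm.sf(np.abs(z)), index=fe.index)
    return LmmResult(
        dv=dv,
        trial_col=trial_col,
        formula=formula,
        fe_params=fe,
        cov_fe=cov_fe,
        bse=bse,
        tvalues=pd.Series(z, index=fe.index),
        pvalues=p,
        design_info=res.model.data.design_info,
        factor_levels=factor_levels,
        converged=bool(res.converged),
        fallback=fallback,
        cov_re=pd.DataFrame(res.cov_re),
        aic=float(getattr(res, "aic", np.nan)),
        bic=float(getattr(res, "bic", np.nan)),
        llf=float(res.llf),
    )


@dataclass(frozen=True)
class SlopeEstimate:
    """A group's marginal per-trial slope of the dependent variable."""

    label: str
    group: dict
    beta: float
    se: float
    ci95: tuple
    p: float


def _slope_contrast(result: LmmResult, cell: dict) -> np.ndarray:
    lo = dict(cell, **{result.trial_col: 0.0})
    hi = dict(cell, **{result.trial_col: 1.0})
    frame = pd.DataFrame([lo, hi])
    (X,) = build_design_matrices([result.design_info], frame)
    X = np.asarray(X)
    return X[1] - X[0]


def marginal_slopes(
    result: LmmResult,
    grouping: Sequence[str] = ("reward", "drug"),
) -> list[SlopeEstimate]:
    """Per-group trial slopes from linear combinations of fixed effects.

    For each combination of the ``grouping`` factors, the slope is the
    contrast X(trial+1) - X(trial), averaged with equal weight over the
    levels of the remaining factors; the SE is the corresponding
    quadratic form of the coefficient covariance.
    """
    unknown = [g for g in grouping if g not in result.factor_levels]
    if unknown:
        raise ValueError(f"grouping factors outside the design: {unknown}")
    others = [f for f in result.factor_levels if f not in grouping]
    beta_vec = result.fe_params.values
    cov = result.cov_fe.values
    out: list[SlopeEstimate] = []
    for combo in itertools.product(*(result.factor_levels[g] for g in grouping)):
        group = dict(zip(grouping, combo))
        contrasts = []
        for other_combo in itertools.product(
            *(result.factor_levels[o] for o in others)
        ):
            cell = dict(group, **dict(zip(others, other_combo)))
            contrasts.append(_slope_contrast(result, cell))
        c = np.mean(contrasts, axis=0)
        beta = float(c @ beta_vec)
        se = float(np.sqrt(c @ cov @ c))
        z = beta / se if se > 0 else np.nan
        p = float(2 * scipy.stats.norm.sf(abs(z))) if se > 0 else np.nan
        out.append(SlopeEstimate(
            label=":".join(f"{k}={v}" for k, v in group.items()),
            group=group,
            beta=beta,
            se=se,
            ci95=(beta - 1.96 * se, beta + 1.96 * se),
            p=p,
        ))
    return out


def se_from_ci95(lo: float, hi: float) -> float:
    """SE recovered from a normal 95% CI: width / 3.92."""
    return (hi - lo) / 3.92


def pairwise_slope_ztests(slopes: Sequence[SlopeEstimate]) -> pd.DataFrame:
    """All pairwise z-tests between group slopes, Bonferroni corrected.

    z = (beta_1 - beta_2) / sqrt(SE_1^2 + SE_2^2), two-sided normal p.
    """
    if len(slopes) < 2:
        raise ValueError("need at least 2 slopes")
    if any(s.se <= 0 for s in slopes):
        raise ValueError("slopes must have positive standard errors")
    pairs = list(itertools.combinations(slopes, 2))
    rows = []
    for a, b in pairs:
        z = (a.beta - b.beta) / np.hypot(a.se, b.se)
        p = 2 * scipy.stats.norm.sf(abs(z))
        rows.append({"group_a": a.label, "group_b": b.label,
                     "z": z, "p_raw": p})
    df = pd.DataFrame(rows)
    df["p_bonferroni"] = np.minimum(df["p_raw"] * len(pairs), 1.0)
    return df


# ---------------------------------------------------------------------------
# row-shuffle permutation trial-window test
# ---------------------------------------------------------------------------

@dataclass
class WindowResult:
    trial_labels: np.ndarray   # analysis trial numbers
    t_obs: np.ndarray          # observed per-trial Welch t
    threshold: np.ndarray      # per-trial (1 - alpha) quantile of |t| null
    p: np.ndarray              # per-trial permutation p-values
    significant: np.ndarray    # boolean mask
    windows: list = field(default_factory=list)  # [(start_label, end_label)]
    n_perm: int = 0
    alpha: float = 0.05


def _welch_t(a: np.ndarray, b: np.ndarray, nan_aware: bool) -> np.ndarray:
    if nan_aware:
        na = np.sum(~np.isnan(a), axis=0)
        nb = np.sum(~np.isnan(b), axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ma, mb = np.nanmean(a, axis=0), np.nanmean(b, axis=0)
            va, vb = np.nanvar(a, axis=0, ddof=1), np.nanvar(b, axis=0, ddof=1)
    else:
        na, nb = a.shape[0], b.shape[0]
        ma, mb = a.mean(axis=0), b.mean(axis=0)
        va, vb = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    denom = np.sqrt(va / na + vb / nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (ma - mb) / denom, 0.0)
    return t


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    runs = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(mask) - 1))
    return runs


def permutation_window_test(
    series_a,
    series_b,
    n_perm: int = 5000,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> WindowResult:
    """Trial windows where two groups differ, by row-shuffle permutation.

    ``series_a``/``series_b``: per-participant trial series aligned on
    analysis trial numbers — DataFrames (participants x trials, columns =
    trial numbers) or 2-D arrays.  Per trial, the observed Welch t is
    compared with the (1 - alpha) quantile of |t| under ``n_perm``
    shuffles of the participant group labels; maximal runs of significant
    trials are returned as windows.
    """
    if rng is None:
        rng = np.random.default_rng()
    labels = None
    if isinstance(series_a, pd.DataFrame):
        labels = np.asarray(series_a.columns)
    A = np.asarray(series_a, dtype=float)
    B = np.asarray(series_b, dtype=float)
    if A.ndim != 2 or B.ndim != 2 or A.shape[1] != B.shape[1]:
        raise ValueError("series must be 2-D with matching trial axes")
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("each group needs at least 2 participants")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse permutation null",
                      stacklevel=2)
    if labels is None:
        labels = np.arange(1, A.shape[1] + 1)

    na = A.shape[0]
    X = np.vstack([A, B])
    nan_aware = bool(np.isnan(X).any())
    t_obs = _welch_t(A, B, nan_aware)
    null = np.empty((n_perm, X.shape[1]))
    n_total = X.shape[0]
    for i in range(n_perm):
        idx = rng.permutation(n_total)
        null[i] = _welch_t(X[idx[:na]], X[idx[na:]], nan_aware)
    abs_null = np.abs(null)
    threshold = np.quantile(abs_null, 1.0 - alpha, axis=0)
    p = (1.0 + (abs_null >= np.abs(t_obs)).sum(axis=0)) / (n_perm + 1.0)
    sig = np.abs(t_obs) > threshold
    windows = [(labels[s], labels[e]) for s, e in _runs(sig)]
    return WindowResult(
        trial_labels=labels, t_obs=t_obs, threshold=threshold, p=p,
        significant=sig, windows=windows, n_perm=n_perm, alpha=alpha,
    )


# ---------------------------------------------------------------------------
# post-assessment mixed ANOVA
# ---------------------------------------------------------------------------

@dataclass
class PostAssessmentResult:
    medians: pd.DataFrame      # per-participant medians per timepoint
    ks: pd.DataFrame           # Kolmogorov-Smirnov normality checks
    anova: pd.DataFrame        # combined between/within ANOVA table
    followups: pd.DataFrame | None  # Wilcoxon rank-sum tests, FDR corrected


def _anova_ols(formula: str, data: pd.DataFrame) -> pd.DataFrame:
    model = smf.ols(formula, data).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = sm.stats.anova_lm(model, typ=3)
    ss_res = table.loc["Residual", "sum_sq"]
    table["partial_eta2"] = table["sum_sq"] / (table["sum_sq"] + ss_res)
    return table


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                     / (na + nb - 2))
    return float((a.mean() - b.mean()) / pooled) if pooled > 0 else np.nan


def post_assessment_anova(
    table: pd.DataFrame,
    dv: str,
    alpha: float = 0.05,
    phase_col: str = "phase",
    timepoints: tuple[str, str] = ("PostRew", "PostNoRew"),
) -> PostAssessmentResult:
    """Mixed ANOVA over the two post-assessment timepoints.

    Per-participant medians of ``dv`` per timepoint are the analysis
    input (the raw trial distributions are not normal).  With a two-level
    within factor the split-plot ANOVA decomposes exactly into two OLS
    ANOVAs (type III, sum coding): between-subject effects on the
    participant means across timepoints, and Timepoint effects on the
    within-participant differences (the intercept of the difference model
    is the Timepoint main effect).  Significant Timepoint-involving
    effects are followed by Wilcoxon rank-sum tests on the per-subject
    post-Rew minus post-NoRew change between groups, FDR corrected, with
    Cohen's d effect sizes.
    """
    required = {"participant", "reward", "drug", "wm", phase_col, dv}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table is missing columns: {sorted(missing)}")
    sub = table[table[phase_col].isin(timepoints)]
    med = sub.pivot_table(
        index=["participant", "reward", "drug", "wm"],
        columns=phase_col, values=dv, aggfunc="median",
    ).reset_index()
    for tp in timepoints:
        if tp not in med.columns or med[tp].isna().any():
            bad = (med.loc[med[tp].isna(), "participant"].tolist()
                   if tp in med.columns else "all")
            raise ValueError(f"missing phase {tp!r} for participants: {bad}")

    ks_rows = []
    for tp in timepoints:
        x = med[tp].to_numpy(float)
        z = (x - x.mean()) / x.std(ddof=1) if x.std(ddof=1) > 0 else x * 0.0
        stat, p = scipy.stats.kstest(z, "norm")
        ks_rows.append({"timepoint": tp, "ks_stat": stat, "p": p})
    ks = pd.DataFrame(ks_rows)

    factors = [f for f in FACTORS if med[f].nunique() > 1]
    if not factors:
        raise ValueError("no between factor has two levels")
    rhs = " * ".join(f"C({f}, Sum)" for f in factors)
    med = med.copy()
    med["_mean"] = med[list(timepoints)].mean(axis=1)
    med["_diff"] = med[timepoints[0]] - med[timepoints[1]]

    between = _anova_ols(f"_mean ~ {rhs}", med)
    within = _anova_ols(f"_diff ~ {rhs}", med)

    def _tidy(tab: pd.DataFrame, within_part: bool) -> list[dict]:
        rows = []
        for term, row in tab.iterrows():
            if term == "Residual":
                continue
            name = term
            for f in factors:
                name = name.replace(f"C({f}, Sum)", f)
            if within_part:
                name = "timepoint" if term == "Intercept" else f"timepoint:{name}"
            elif term == "Intercept":
                continue
            rows.append({
                "effect": name, "F": row["F"], "p": row["PR(>F)"],
                "partial_eta2": row["partial_eta2"],
                "df": row["df"],
            })
        return rows

    anova = pd.DataFrame(_tidy(between, False) + _tidy(within, True))

    followups = None
    tp_effects = anova[anova["effect"].str.startswith("timepoint")]
    if (tp_effects["p"] < alpha).any():
        med["group"] = med["drug"] + "-" + med["reward"].map(
            {"Rew": "R", "NoRew": "NR"}
        )
        pairs = [("Halo-R", "Ctrl-R"), ("Halo-NR", "Ctrl-NR"),
                 ("Halo-R", "Halo-NR"), ("Ctrl-R", "Ctrl-NR")]
        rows = []
        for ga, gb in pairs:
            da = med.loc[med["group"] == ga, "_diff"].to_numpy()
            db = med.loc[med["group"] == gb, "_diff"].to_numpy()
            if len(da) == 0 or len(db) == 0:
                continue
            stat, p = scipy.stats.ranksums(da, db)
            rows.append({"group_a": ga, "group_b": gb, "z": stat,
                         "p_raw": p, "cohens_d": cohens_d(da, db)})
        if rows:
            followups = pd.DataFrame(rows)
            followups["p_fdr"] = multipletests(
                followups["p_raw"], method="fdr_bh"
            )[1]

    return PostAssessmentResult(
        medians=med.drop(columns=["_mean"]),
        ks=ks, anova=anova, followups=followups,
    )
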