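# Methods notes

## The synthetic trajectory model

Each trial is eight point-to-point reaches through the target layout
(via → T1 → via → T2 → via → T3 → via → T4 → via).  Two per-trial
parameters control the kinematics, mirroring the two learning processes
the analysis is designed to separate:

* **peak speed** `v_p` (cm/s), one per segment — the vigour parameter;
* **trough fraction** `f ∈ [0, 1]`, one per transition — the fusion
  parameter.  Transition k's programmed trough speed is
  `f · (v_p,k + v_p,k+1)/2`, exactly the quantity the fusion index
  measures, so FI is analytically controllable.

### Path geometry

A straight polyline through the targets would corrupt the measured
trough: the finite-difference speed across a sharp corner (and
especially across the full reversals at the outer targets) drops below
the programmed value because the chord between samples is shorter than
the path.  Real coarticulated reaches curve around the via point, so the
generated path does too: each fused transition follows a circular *hook*
around the target centre, joined to the straight legs by common
tangents.  The hook radius scales with trough speed
(`r = v_t · 0.15 s / π`, clamped to [0.03, 0.4] cm) so the angular step
per sample is constant and small; the radius never exceeds 0.4 cm, so
the hook stays inside the 0.5 cm target disc and every target still
registers as visited.  The arc is traversed at a constant speed slightly
above the programmed trough (`v_c = (2r/Δt)·asin(v_t Δt / 2r)`) so the
*sampled chord speed* equals the programmed trough exactly.

### Speed profile

Along each straight leg the speed follows a flat-topped profile: a
quintic-smoothstep rise from the entry trough to the peak over 30% of
the leg, a plateau at the peak, and a symmetric fall.  Both the
smoothstep and the plateau have vanishing first and second derivatives
at their joins, and short hook arcs are padded by brief constant-speed
holds (total trough plateau ≈ 0.08 s), so Gaussian smoothing of the
sampled speed (σ = 2 samples at 110 Hz) preserves programmed peaks and
troughs.  On noise-free trials in the cohort's speed range (peaks
~18–32 cm/s) the recovered FI matches the programmed fraction within
0.02 and peaks within ~1%; accuracy degrades above ~35 cm/s, where a
5 cm reach lasts under ~15 samples and the smoothing kernel can no
longer resolve peak and trough separately — outside the regime the
simulated cohorts occupy.  Recovery also degrades if a trough is pushed
close to the *smaller* of two very unequal adjacent peaks (smoothing
blends the boundary); cohort trials use equal per-segment peaks, where
this does not arise.

A trough fraction of 0 is realised as a full stop with a dwell of at
least `dwell_floor` (default 0.2 s) inside the target.  Trial-level
motor noise enters as Gaussian jitter on peak speed (default SD
1.5 cm/s) and trough fraction (SD 0.03), plus additive positional noise
(SD 0.02 cm, the precision class of an electromagnetic motion tracker).

### Cohort structure

Four groups (reward × drug) of `n_per_group` participants (default 23,
i.e. a 92-participant cohort).  Each participant draws a baseline peak
speed (25 ± 2.5 cm/s, +3 cm/s for rewarded participants), a baseline
trough fraction (0.10 ± 0.03), and per-trial learning slopes around
group means.  The default slope pattern follows the qualitative result
the design anticipates: vigour learning is strongest under
placebo + reward (+2.4 cm/s over 180 trials), abolished under
haloperidol + reward (−0.46), intermediate without reward (+1.27/+1.28);
fusion learning is attenuated by haloperidol in high-WM participants
only, with a reward boost.  The magnitudes place a typical participant's
FI growth at ≈ +0.3 trough fraction over training — visible
coarticulation growth — since only the pattern, not the printed scale,
of slope coefficients is meaningful at simulation scale.  Learning is
indexed by the within-day training trial number; baseline trials sit at
index 0 and post-assessment trials at the end-of-training index (no
retention or consolidation model across days).

Each participant owns independent random streams keyed by (seed,
participant index, stream), so enlarging the cohort never reshuffles
existing participants, and every trajectory is regenerated on demand
from its (participant, day, phase, trial) key rather than stored.

### What the generator does not emulate

No biomechanical arm model, reaction-time psychology, target misses or
repeated trials, within-trial submovement corrections, or day-to-day
retention.  Passing tests therefore certify the *analysis machinery*
(metric extraction, scheduling, feedback and inference under a known
generative model), not claims about real cohorts.

## Kinematic conventions

Where the procedure admits more than one reading, the package fixes:

* target entry/exit is the cursor **centre** crossing the 0.5 cm disc
  radius (point-cursor convention);
* speed from first differences; Gaussian smoothing σ = 2 samples,
  truncated at ±4σ, reflective boundaries;
* the trough search window is the open interval between adjacent peak
  samples;
* FI is clamped to [0, 1] (a trough can exceed the mean of two unequal
  peaks); clamp events are counted per trial (`n_fi_clamped`);
* MT runs from start-box exit to first entry into the final target;
  reaction time is reported separately via the 2 cm displacement rule.

## Reward engine

Percentile = 100 × (buffer MTs strictly slower)/buffer size; ties score
in the participant's favour.  With distinct MTs the percentile bins and
the "top three / bottom three of 20" reading coincide (rank ≤ 3 ⇔
percentile ≥ 90); both are implemented (`mode='percentile'` |
`'rank_bands'`) and differ only under ties.  At block boundaries the
buffer seeds from the last 20 trials of the previous block; shorter
histories are used as-is and flagged as warm-up.

## Protocol

Days 1/2: Baseline 10, Training 200, two post-assessments of 20 (order
counterbalanced); Day 7: two post-assessments of 25.  Dual-task trials
fall on every 10th Training trial and every 5th trial elsewhere, counted
from trial 1 of each phase.  Exclusions: participants with mean baseline
MT > 8.5 s; trials with MT > 10 s; all dual-task trials.  Analysis trial
numbers are recomputed densely per participant/day/phase, so a full
training block renumbers to 1–180.  A 20-trial familiarisation phase is
generated on Day 1 but never analysed.  Baseline is assumed repeated on
Day 2 (configurable off).

## Statistics

* **LMM.** `dv ~ Reward*Drug*WM*Trial + (Trial | participant)`, REML,
  treatment coding with NoReward/haloperidol/low-WM references,
  delegated to statsmodels `MixedLM` (cross-checked against an lme4 REML
  fit to ~1e-10 in the test suite).  Fixed-effect tests use Wald z
  statistics — the large-sample normal approximation — rather than
  Satterthwaite degrees of freedom, which the backend does not provide;
  at the cohort sizes analysed here (≥ 84 residual df) the two are
  practically indistinguishable.  Non-convergence of the random-slope
  model triggers a flagged refit with random intercept only.  Cohorts
  too small to populate every Reward×Drug×WM cell drop WM from the fixed
  part, flagged in the pipeline output.
* **Marginal slopes.** A group's per-trial slope is the design contrast
  X(trial+1) − X(trial) at that group's factor levels, averaged with
  equal weights over the remaining factors; SE from the quadratic form
  of the coefficient covariance; 95% CI as β ± 1.96·SE.  Pairwise
  z = (β₁−β₂)/√(SE₁²+SE₂²), Bonferroni over pairs.  When only a CI is
  published, SE = width/3.92.
* **Permutation windows.** Per analysis trial, a Welch t between groups;
  the null is built by shuffling participant rows (group labels), 5 000
  permutations by default with an explicit seed; a trial is significant
  when |t| exceeds the (1−α) quantile of its permutation |t| null, and
  maximal runs of significant trials form the reported windows.  No
  across-trial cluster correction is applied (per-trial thresholding is
  the procedure being reproduced); trials missing for one participant
  are handled by NaN-aware statistics.
* **Post-assessments.** Per-participant medians per timepoint are the
  ANOVA input (the trial distributions are non-normal, checked by
  one-sample Kolmogorov–Smirnov on standardised medians).  With a
  two-level within factor the mixed ANOVA decomposes exactly into two
  between-subject ANOVAs (type III, sum coding): one on participant
  means across timepoints (between effects) and one on within-
  participant differences (Timepoint effects; the intercept tests the
  Timepoint main effect).  Significant Timepoint-involving effects are
  followed by Wilcoxon rank-sum tests on the per-subject post-Rew −
  post-NoRew change across four group pairings, FDR-corrected
  (Benjamini–Hochberg), with Cohen's d.
* **Positive control.** Go/NoGo: 4 stimuli × 10 presentations; win
  probabilities default to 0.8/0.8 (reward runes) and 0.2/0.2 (loss
  runes) — they are not part of any printed protocol and stay
  configurable.  The simulated learner updates stimulus values only
  after Go feedback with separate win/loss learning rates; the
  drug asymmetry (faster win-learning, slower loss-learning under
  haloperidol) is applied in low-WM participants, where the published
  effect concentrates.  Response accuracy: Learn+ = %Go on reward
  stimuli, Learn− = %NoGo on loss stimuli.  VWM: 60 trials, array
  lengths 5–9; P(correct) = 0.5 + 0.5·sigmoid(1.0 + 1.5·wm −
  0.8·(length−7)); the 7–9 score feeds the median split (ties → high).

## Problem sizes in tests

The statistical acceptance checks run 200 exchangeable-null replicates
(type-I error), 100 study-scale cohorts (4 × 23 participants × 180
trials) for slope-sign recovery, and 100 cohorts for window
localisation with 400 permutations per test; the kinematic oracle check
uses 200 noise-free trials.  The pipeline's `demo` profile (2 per
group, 40 training trials) exists for smoke runs; `paper` is the full
scale.

## Known limitations

* Wald z instead of Satterthwaite df (see above) — anticonservative
  only for very small cohorts.
* The trajectory family is one smooth-reaching idealisation; FI
  recovery guarantees hold in the simulated speed regime, not for
  arbitrary kinematics.
* The permutation test treats trials independently (no cluster-mass
  correction), matching the procedure it reproduces.
* Reward "top three" vs percentile-bin readings are only distinguishable
  under tied MTs, which continuous simulation never produces.
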