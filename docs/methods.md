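# Methods

## The task model

The ongoing (OG) task is a visual search for a rightward horizontal arrow
among 10 oriented arrows.  Difficulty is controlled by two distractor
parameters: the minimum angular distance from the 0° target (5°, 15°, 25°,
45°, 65°, 75°) and the maximum variance above that minimum (10°, 20°, 40°).
Crossing the sets and excluding pairs with `min + variance > 90°` (distractors
would cross the vertical plane) leaves 15 conditions; dropping the 75° set —
the pilot configuration — leaves 14.  The mapping of retained pairs onto
ordinal levels is not uniquely determined by the construction; `pmflex`
orders them by descending minimum distance, then ascending variance
(level 1 = most target-distant, most homogeneous distractors = easiest),
which reproduces the monotone reaction-time/accuracy profile across levels.
The ordering is exposed as an argument for users who prefer another
permutation.

Distractor orientations are drawn uniformly on
`[min_distance, min_distance + variance]` and reflected independently across
the horizontal (θ → 360 − θ) and vertical (θ → 180 − θ) planes with
probability 0.5 each, confining them to [5°, 175°] ∪ [185°, 355°].  To avoid
pop-out from frame to frame, no distractor may fall within 5° (circular) of
the orientation shown at the same slot on the previous display; offending
draws are resampled up to 100 times, after which that slot's constraint is
relaxed with a logged warning rather than failing the whole display.

Trials are sequences of 1–15 two-second probes (1.9 s response window).
Difficulty follows one of five trajectories — increase from level 1, increase
from 8, fixed at 8, decrease from 15, decrease from 8 — one ±1 step per
probe, saturating at the endpoints.  Each block crosses the five trajectories
with three PM types (face target, scene target, none), 15 trials per block;
five per block are catch trials of 2–7 probes.  The lower catch bound of 2 is
a package choice (the design only bounds catch trials above, at "fewer than
8"): it guarantees at least one pure search probe before the target probe.
Catch assignments cycle a shuffled list of the 15 type × trajectory
combinations, so they are counterbalanced across the session, and the same
multiset of trial lengths is given to each PM type whenever the block count
is divisible by 3 — making face, scene and no-target probe totals exactly
equal (otherwise as equal as possible).  On PM trials the target reappears
exactly once, on the final probe; this holds for catch trials too.  The
ongoing-task localizer is generated as blocks of exactly 60 probes split into
8 trials of 2–12 probes (an exact-sum composition found by sum-preserving ±1
perturbations of a seed partition), with dynamic trajectories only.

## The synthetic cohort

Each simulated participant carries a latent strategy state θ ∈ [0, 1]
(0 = fully reactive, 1 = fully proactive) that starts at `theta0` and drifts
linearly within each trial at a condition rate (`drift_dec = +0.04`,
`drift_inc = −0.04`, `drift_fix = +0.02` per probe) plus a per-trial jitter
(`drift_sd = 0.08`), clipped to [0, 1].  The jitter is essential, not
cosmetic: the phenomenon under study is trial-to-trial variation in strategy
adjustment, and without it the measured cost slope would carry no information
about the trial's final strategy state.

Behavior is generated as:

- non-PM probe RT = `rt_base(level) + ε`, with `rt_base` linear from 0.60 s
  (level 1) to 1.25 s (level 15) and ε ~ N(0, 0.15 s); PM probes add
  `θ_t · cost_amplitude · decay(level)` with `cost_amplitude = 0.25 s` and
  `decay(level) = max(0, 1 − 0.9·(level−1)/14)`.  The multiplicative
  attenuation is the package's mechanism for the observed decline of
  expressed cost with difficulty; the data constrain the decline, not the
  mechanism.
- RTs are floored at 0.3 s; raw RTs beyond the 1.9 s deadline become
  omissions (no RT, incorrect).
- OG correctness is Bernoulli with accuracy linear from 0.97 to 0.62 across
  levels.
- On the final probe of a PM trial the target reappears and the hit
  probability is `reactive_floor + (1 − reactive_floor) · σ(pm_intercept +
  gain · (θ_final − theta0))` with `reactive_floor = 0.45`,
  `pm_intercept = 0.1`, `gain = +5` on decreasing and fixed trials and
  `−2.5` on increasing trials.  The direction-specific gain encodes the
  adaptive-match principle: a shift toward proactive control helps when
  resources are freeing up and hurts (weakly) when demands are rising.  A hit
  preempts the ongoing-task response on that probe (single response per
  probe).  Setting `pm_slope_gain = 0` zeroes both gains, giving the null
  generator.

Defaults land the cohort near the descriptive ranges of the paradigm
(ongoing-task accuracy ≈ 80%, PM accuracy ≈ 79%, cost ≈ 135 ms at easy and
≈ 20 ms at hard levels, condition slope means of roughly +4 / 0 / −3 ms/s);
they are study conditions, not fitted estimates.

The neural generator emits one sample per 2 s TR: unit Gaussian noise plus
`snr ×` a fixed Gaussian template for the sample's class (face, scene,
ongoing task, rest), plus `coupling · (θ̄ − 0.5)` along the target template on
PM-trial samples (θ̄ = trial mean strategy).  Signal is placed two samples
after its event, and the decoder's label alignment shifts labels forward two
TRs to compensate — the standard hemodynamic-lag convention at TR = 2 s.
Rest labels come from inter-trial intervals with a one-sample guard on both
edges (guard samples carry an empty label and are never trained or scored).
Task blocks become runs; an ongoing-task localizer run and a face/scene
localizer run are appended.  `simulate_balanced_neural` builds run-balanced
four-class data (no lag, no coupling) for decoder calibration, where
scrambled-label chance is exactly 25%.

What the generator does **not** emulate: temporally autocorrelated fMRI
noise, hemodynamic convolution beyond the fixed label shift, stimulus-level
variability (actual images), speed–accuracy trade-offs, feedback effects, or
practice curves beyond the early/late baseline split.  Passing tests
therefore demonstrate that the analysis chain recovers structure *of the kind
the design assumes*, at realistic noise levels — not that it is robust to
every pathology of real data.  In particular, the scrambled-label chance on
synthetic data sits at the theoretical 25%; on real recordings residual
temporal structure typically leaves it a few points higher.

## The strategy metrics

Responses faster than 300 ms are discarded (strictly faster: 0.300 s is
kept).  Baselines are mean correct non-PM RTs per (difficulty level,
early/late half of the blocks); with an odd block count the extra block goes
to the late bin (a 5-block session splits 1–2 / 3–5).  A control variant uses
all responses.  Empty cells fall back to the same level's other bin with a
logged warning — never across levels, since the level profile is the quantity
of interest.  PM cost subtracts the matched baseline from each PM-trial probe
RT.  The cost slope is `(mean(last window) − mean(first window)) / n_probes /
2 s`, windows = probes 1–3 and n−3..n−1, the target probe excluded; the
division by the 2 s probe duration expresses the per-probe definition in
ms/s.  Trials with fewer than 7 probes (overlapping windows) are undefined,
as are trials with fewer than `min_window_n` (default 1, configurable to 3)
usable costs in either window.  Incorrect-response probes are dropped from
windows by default (calendar-probe windows with correct-only costs).  Trials
below 50% ongoing-task accuracy are excluded.

A property worth knowing: the slope statistic measures change in *expressed*
cost, which conflates strategy change with the difficulty profile of the
trial.  With a constant strategy and a positive difficulty decay, decreasing
trials still show positive slopes.  The true null of the statistic is
constant strategy *and* no difficulty attenuation; the calibration tests use
exactly that null.

## Model selection

Per-trial polynomial fits (orders 1–3) of cost on difficulty use the
Gaussian-likelihood criterion `AIC = n·ln(RSS/n) + 2k` with `k = order + 2`
(coefficients + intercept + error variance; only Δ within a comparison
matters, and the convention is configurable).  `AICc` adds
`2k(k+1)/(n−k−1)`; models with `n − k − 1 ≤ 0` — or order 3 below 5 points —
are disqualified rather than silently scored ±∞.  Fixed-difficulty trials
have a constant regressor and are excluded from these fits.  The
super-subject bootstrap z-scores costs within participant, pools all dynamic
trials, draws 50 trials per trajectory condition per iteration, and selects
the lowest-AIC order on the pooled points; a 1-df chi-square tests
linear-wins against the 1/3 chance rate.

## Inference

Bootstrap iterations resample the full participant count with replacement
and pool their trials; logistic models of PM hit are pooled fixed-effect
fits (no random effects — the participant level enters through the
resampling).  Percentile 2.5/97.5 CIs; the two-sided bootstrap p-value is
`2 · min(frac ≤ 0, frac ≥ 0)` floored at 1/n_iter — a convention made
explicit because "bootstrap p" is otherwise under-defined.  Iterations with
(quasi-)separation are dropped
and counted; a run fails if a model loses more than 5% of iterations.  The
logistic solver inside the loops is an in-package Newton/IRLS routine
(needed for throughput at thousands of iterations), verified against
`statsmodels.Logit` maximum-likelihood estimates in the tests; one-off fits
and oracles go through statsmodels/scikit-learn.  Model comparison fits all
main-effect/interaction combinations of cost slope, PM intention evidence
and trial direction, selects the best behavior-only and neural-only models
and the full combined model per iteration, converts AICs to Akaike weights,
and summarises with medians, Wilcoxon signed-rank tests and median weight
ratios.

## Decoding

Features are z-scored over time; a one-way ANOVA across the four classes
keeps features with p < 0.05, refit inside every cross-validation fold
(screening on the full dataset is a leakage bug, and a regression test
verifies it would change results).  One ridge-penalised logistic classifier
per class (penalty 50 on the squared-coefficient term; scikit-learn
`C = 1/50`) yields probability-scale evidence that deliberately does not
normalise across classes; predictions are argmax with ties broken in fixed
class order (face, scene, og, rest).  Evaluation is leave-one-task-run-out
with localizer rows always in training and final-probe samples excluded from
training but scored.  The scrambled baseline permutes labels within run
(preserving run structure and class counts) and reruns the pipeline;
`max_folds` caps the rotation inside permutation loops.  PM intention
evidence is `evidence(target) − evidence(nontarget)` per time point,
averaged per trial with the target-reappearance probe excluded (consistent
with its exclusion from training), plus a within-trial least-squares slope
in EV/s.

## Numerical choices and problem sizes

Seeds derive from a master seed via `numpy.random.SeedSequence` spawning
(per participant) and a counter-based scheme (per pipeline stage), so every
stage and participant regenerates independently.  Exact polynomial fits
guard `RSS = 0` with a 1e-300 floor inside the log.  IRLS declares
separation when coefficients exceed 30 in absolute value or the information
matrix is singular.  The test suite runs recovery at the full cohort scale
(78 participants, 6 blocks, 2000 bootstrap iterations, 20 replicates) and
calibration on reduced cohorts (20 participants, 3 blocks, 400 iterations,
40 replicates); the acceptance script averages four balanced datasets of 640
samples × 100 permutations each.  These sizes were chosen so each check's
Monte-Carlo error is small against the effect it measures.

## Known limitations

Group regressions are pooled fixed-effect fits, not mixed models; the
neural stage is a simplified feature-matrix pipeline (no NIfTI I/O,
preprocessing, GLM contrasts or searchlights); the generator's linear drift
and logistic hit model are conveniences, not mechanistic claims; and the
within-fixed-trial expectancy drift is a free parameter with no empirical
anchor.
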