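# pmflex

Analysis tools for **dynamic prospective memory (PM)**: how people adjust the
cognitive control strategy that keeps a delayed intention alive while the
demands of an ongoing task rise and fall from moment to moment.

The paradigm embeds a delayed target-detection task (remember to report the
reappearance of a face or scene) in a continuous visual search over oriented
arrows whose difficulty shifts by one level every 2 s probe.  Two strategies
can support the intention: *proactive control* (holding the target in working
memory and monitoring for it, which slows the ongoing task) and *reactive
control* (relying on cue-triggered retrieval, with little or no slowing).
`pmflex` implements the full analysis chain for this design, exercised on a
synthetic cohort generator with known ground truth:

- **`task_design`** — the 15-level difficulty parameterisation (minimum
  distractor–target angle × distractor variance, excluding pairs crossing the
  90° vertical plane), distractor-array sampling with anti-pop-out
  constraints, per-trial difficulty trajectories, and block/session/localizer
  designs serialised as probe-level event TSVs.
- **`synthetic_cohort`** — behavioral and neural data generators built around
  a latent strategy state θ ∈ [0, 1] that drifts within trials and expresses
  itself as reaction-time cost and classifier evidence.
- **`pm_cost`** — the strategy metrics.  **PM cost** for probe *i* at
  difficulty *d* in practice bin *b*:

  `cost_i = RT_i − baseline(d, b)`

  with baselines from correct non-PM responses (15 difficulties × 2 bins,
  responses < 300 ms discarded).  **PM cost slope** per trial of *n* probes:

  `slope = [ mean(cost_{n−3..n−1}) − mean(cost_{1..3}) ] / n / 2 s`

  in ms/s, the target probe excluded; trials below 50% search accuracy are
  excluded.
- **`trial_models`** — per-trial polynomial fits of cost on difficulty with
  `AIC = n·ln(RSS/n) + 2k`, `AICc = AIC + 2k(k+1)/(n−k−1)`, Akaike weights
  `w_i = exp(−Δ_i/2)/Σ exp(−Δ_j/2)`, and a super-subject bootstrap of model
  selection.
- **`strategy_inference`** — participant-resampling bootstrap logistic
  regressions of PM hit/miss on cost slope (per trajectory direction, plus
  the slope × direction interaction), partial R², and wAIC comparison of
  behavior-only / neural-only / combined predictor models.
- **`mvpa`** — one-vs-rest L2-penalised logistic classifiers (ridge weight
  50) over face/scene/ongoing-task/rest with leave-one-run-out
  cross-validation, in-fold ANOVA feature screening, scrambled-label chance
  calibration, and per-trial **PM intention evidence**
  `EV = evidence(target) − evidence(nontarget)`.
- **`pipeline`** / the `pmflex` CLI — end-to-end orchestration from a YAML
  config, reproducible from a single seed.

## Worked example

```python
from pmflex import pm_cost, strategy_inference as si, synthetic_cohort as sc

probes, _ = sc.simulate_cohort(sc.SynthParams(n_participants=30, seed=3))
summary, profiles = pm_cost.summarize_trials(pm_cost.filter_responses(probes))
print(profiles["cost_level_trend"]["slope_ms_per_level"])
models = si.slope_accuracy_model(summary, n_iter=1000, rng_seed=5)
print(models["dec"].to_frame())
```

This prints a pooled cost-by-difficulty trend of **−9.6 ms per level** — PM
cost is large when search is easy and nearly vanishes when it is hard, the
signature of strategy withdrawal under load — and, for decreasing-difficulty
trials, a slope→accuracy coefficient of **β = +0.055, 95% CI [+0.021,
+0.097], p = 0.001**: trials on which the participant ramped up proactive
control as resources freed were more likely to end in a successful intention
report.  The same run gives a non-significant β on increasing trials and a
positive slope × direction interaction (**+0.061, p = 0.02**) — shifting
strategy in the direction the demand trend favours is what pays off.

The `examples/` directory holds one short script per capability
(`01_generate_design.py` … `06_link_strategy_to_accuracy.py`); each builds a
small input, runs one stage and explains the numbers it prints.

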