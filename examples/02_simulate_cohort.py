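"""Simulate a behavioral cohort and inspect the difficulty profile.

The generator plants a latent strategy state (theta) that expresses itself as
a reaction-time cost on PM trials; the cost is attenuated as search difficulty
rises, so the expressed PM cost declines from easy to hard levels.
"""

from pmflex import pm_cost, synthetic_cohort as sc

params = sc.SynthParams(n_participants=10, seed=42)
probes, trials = sc.simulate_cohort(params)
print(f"simulated {params.n_participants} participants, "
      f"{len(probes)} probes, {len(trials)} trials")

filtered = pm_cost.filter_responses(probes)
summary, profiles = pm_cost.summarize_trials(filtered)

og_acc = summary["og_accuracy"].mean()
pm_acc = summary.loc[summary["pm_type"] != "non_pm", "pm_hit"].mean()
print(f"ongoing-task accuracy: {og_acc:.1%}   PM accuracy: {pm_acc:.1%}")

level_cost = (profiles["level_cost"]
              .groupby("difficulty_level")["mean_cost"].mean() * 1000)
print("\nmean PM cost (ms) by difficulty level:")
for level in (1, 4, 8, 12, 15):
    print(f"  level {level:>2}: {level_cost.get(level, float('nan')):6.1f}")
trend = profiles["cost_level_trend"]
print(f"pooled linear trend: {trend['slope_ms_per_level']:.1f} ms per level")
# the negative trend is the behavioral signature of strategy withdrawal:
# as search gets harder, less proactive cost is expressed.
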