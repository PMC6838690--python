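"""Build the dual-task session design.

Constructs the 15-level difficulty table from the two distractor parameters,
generates a 6-block session (15 trials per block = 3 PM types x 5 difficulty
trajectories, 5 catch trials per block) and a localizer block, and prints the
counts that define the paradigm.
"""

from pmflex import task_design as td

specs = td.build_difficulty_table()
print(f"difficulty conditions: {len(specs)}")
print("easiest :", specs[0])
print("hardest :", specs[-1])
# level 1 pairs the most target-distant, most homogeneous distractors;
# level 15 the nearest, most variable ones.

traj = td.make_trajectory("inc_mid", 10)
print("\n10-probe trial rising from level 8:", traj.levels)
# difficulty shifts one level per probe and saturates at the endpoint (15).

session = td.generate_session(n_blocks=6, rng_seed=7)
per_block = session.trials.groupby("block").size()
catch = session.trials.groupby("block")["is_catch"].sum()
totals = session.trials.groupby("pm_type")["n_probes"].sum()
print(f"\nsession: {len(session.trials)} trials "
      f"({per_block.iloc[0]} per block, {catch.iloc[0]} catch each)")
print("probe totals by PM type:", totals.to_dict())
# equal totals mean face, scene and no-target trials contribute the same
# number of 2 s probes to the experiment.

loc = td.generate_localizer_design(1, rng_seed=7)
print(f"\nlocalizer block: {loc.trials['n_probes'].sum()} probes "
      f"from {len(loc.trials)} trials "
      f"(lengths {loc.trials['n_probes'].min()}-{loc.trials['n_probes'].max()})")
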