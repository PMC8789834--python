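"""How the force constant shapes foraging morphology.

Runs the fixed-duration foraging protocol at c = 1, 10, 100, 1000 and
reports how much of the domain the trails can reach.  Low c is a
noise-dominated space-filling wander; high c is a deterministic
star-burst straight to the nearest food source.
"""

import myxonet as mx
from myxonet.experiments import c_sweep_experiment
from myxonet.pipeline import PipelineConfig

layout = mx.generate_layout(7, min_spacing=80.0, seed=1)
result = c_sweep_experiment(layout, PipelineConfig(sim=mx.SimConfig(seed=1)),
                            n_seeds=2)

print("mean accessible fraction of the 800 x 800 px domain")
print("c       within 160 px  within 80 px  within 8 px   trail cost")
for c, grp in result.table.groupby("c"):
    print(f"{c:6g}  {grp['accessibility_20pct'].mean():12.3f}  "
          f"{grp['accessibility_10pct'].mean():11.3f}  "
          f"{grp['accessibility_1pct'].mean():10.4f}   {grp['trail_cost'].iloc[0]:,}")

print(f"\ntrail cost spread across c: "
      f"{100 * result.summary['max_rel_diff_trail_cost']:.1f}% "
      "(same agents, same duration - foraging effort is c-independent)")
print("Accessibility falls with c at every reach: stronger attraction "
      "trades exploration for exploitation.")
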