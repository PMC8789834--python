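"""Start the growth anywhere: the refined network barely changes.

Grows one seven-source layout seven times, once from each attractor.
The preliminary meshes differ wildly, but the shortest-walk refinement
recovers essentially the same network every time.
"""

import myxonet as mx
from myxonet.experiments import start_invariance_experiment
from myxonet.pipeline import PipelineConfig

layout = mx.generate_layout(7, min_spacing=80.0, seed=1)
result = start_invariance_experiment(layout, PipelineConfig(sim=mx.SimConfig(seed=1)))

print("start  frames  trail pts   network cost (px)")
for _, row in result.table.iterrows():
    print(f"{int(row['start_index']):4d}  {int(row['frames']):6d}  "
          f"{int(row['n_trail_points']):9,}  {row['cost']:12.1f}")

spread = 100 * result.summary["max_rel_diff_cost"]
print(f"\nmax pairwise relative cost difference: {spread:.2f}%")
print("Meshes vary by tens of percent in size, yet final costs agree to "
      "within about a percent: refinement decouples the designed network "
      "from the vagaries of growth.")
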