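"""Grow a slime-mould-style network between seven food sources.

Generates a random seven-point attractor layout, runs the two-stage
model (agent foraging -> proximity mesh -> shortest-walk refinement)
and prints the efficiency metrics of the refined network.
"""

import myxonet as mx
from myxonet.pipeline import PipelineConfig, run_model

layout = mx.generate_layout(7, min_spacing=80.0, seed=1)
config = PipelineConfig(sim=mx.SimConfig(seed=1))

result = run_model(layout, config)
log, net, m = result.sim_log, result.network, result.metrics

print(f"foraging: {log.terminated_frame} frames "
      f"({log.terminated_frame / config.sim.frames_per_second:.0f} s of growth), "
      f"{len(result.cloud):,} trail points, trail cost {mx.trail_cost(log):,} agent-frames")
print(f"mesh:     {result.mesh.n_nodes:,} nodes, {result.mesh.n_edges:,} edges, "
      f"cost {mx.mesh_cost(result.mesh):,.0f} px")
print(f"network:  {len(net.links)} links between sources, "
      f"{len(net.segments)} drawn segments")
print(f"  cost          {m.cost:8.1f} px   (total length of all links)")
print(f"  travel time   {m.travel_time:8.1f} px   (mean source-to-source path)")
print(f"  vulnerability {m.vulnerability:8.1f} px   (mean travel-time rise per fault)")
print()
print("Cost is what the network spends on infrastructure; travel time is "
      "how far an average trip is; vulnerability is how much an average "
      "single-segment failure lengthens trips.")
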