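"""Benchmark a built network against the model's performance curve.

Loads a small synthetic "built" network (a plausible hand-drawn
connection of the same seven sources), grows model networks at
p = 1..5 over the same sources, and finds the closest point on the
fitted model trendline to the built network in the normalized
travel-time-vs-cost plane.
"""

import numpy as np

import myxonet as mx
from myxonet.metrics import MetricsReport, compare_to_reference, performance_curve
from myxonet.network_io import ReferenceNetwork
from myxonet.pipeline import PipelineConfig, run_model

layout = mx.generate_layout(7, min_spacing=80.0, seed=1)
result = run_model(layout, PipelineConfig(sim=mx.SimConfig(seed=1)))

# synthetic built network: ring through all seven sources ordered by
# angle, a shape a human planner might draw for these stops
center = layout.coords.mean(axis=0)
order = np.argsort(np.arctan2(*(layout.coords - center).T[::-1]))
ring_edges = [(int(order[i]), int(order[(i + 1) % 7])) for i in range(7)]
built = ReferenceNetwork(nodes=list(layout.points), edges=ring_edges)

g = built.graph
import itertools
import networkx as nx
cost = sum(d["weight"] for _, _, d in g.edges(data=True))
pair_lengths = [nx.dijkstra_path_length(g, a, b, weight="weight")
                for a, b in itertools.combinations(range(7), 2)]
built_report = MetricsReport(cost=cost, travel_time=float(np.mean(pair_lengths)),
                             vulnerability=1.0, label="built-ring")

curve = performance_curve(result.mesh, p_range=range(1, 6),
                          extra_reports=[built_report],
                          fit_families={"tt_vs_c": "poly3"})
built_scored = mx.normalize_and_score(
    [r for _, r in curve.points] + [built_report])[-1]

cmp = compare_to_reference(curve, built_scored, "tt_vs_c")
print(f"built ring:  cost {cost:.0f} px, travel time {built_report.travel_time:.0f} px")
print(f"closest model point on the trendline: "
      f"(normalized cost {cmp.closest_point[0]:.3f}, travel time {cmp.closest_point[1]:.3f})")
print(f"distance in the normalized plane: {cmp.distance:.3f} "
      f"(per-axis {cmp.percent_dx:+.1f}% cost, {cmp.percent_dy:+.1f}% travel time)")
print("A small distance means the built design sits on the model's "
      "cost/travel-time frontier; a large one flags a design that the "
      "grown networks dominate.")
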