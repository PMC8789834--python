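"""Trade cost against travel time and robustness with the proximity coefficient.

Refines one mesh at p = 1..5 and fits the trendlines used for
network comparison.  Raising p buys extra connections: cost rises
(close to linearly) while travel time and fault vulnerability fall.
"""

import myxonet as mx
from myxonet.metrics import performance_curve
from myxonet.pipeline import PipelineConfig, run_model

layout = mx.generate_layout(7, min_spacing=80.0, seed=1)
result = run_model(layout, PipelineConfig(sim=mx.SimConfig(seed=1)))

curve = performance_curve(
    result.mesh,
    p_range=range(1, 6),
    fit_families={"tt_vs_c": "poly3", "v_vs_c": "power", "v_vs_tt": "linear"},
)

print("p    cost(px)  travel(px)  vulnerability(px)   normalized c/tt/v")
for p, r in curve.points:
    print(f"{p}   {r.cost:8.1f}  {r.travel_time:9.1f}  {r.vulnerability:13.1f}"
          f"      {r.normalized_cost:.2f} / {r.normalized_travel_time:.2f} / "
          f"{r.normalized_vulnerability:.2f}")

tl = curve.fits["v_vs_c"]
print(f"\nvulnerability vs cost trendline ({tl.family}): "
      f"a={tl.coefficients[0]:.3g}, b={tl.coefficients[1]:.3g}")
print("A designer picks the p whose point on these curves matches the "
      "budget: cheap-but-fragile at p=1, expensive-but-robust at p=5.")
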