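# myxonet

A two-stage model of *Physarum polycephalum* growth for bio-inspired
transport-network design.

The true slime mould forages as a population of nutrient-attracted
protoplasmic extensions, first laying down a dense exploratory mesh
between food sources and only then refining it into an efficient
transport network. `myxonet` reproduces this behaviour in two
**decoupled** stages, so the designer can intervene between growth and
refinement:

1. **Biased meshing.** *n* agents (default 50) are released into an
   800 × 800 px domain holding a set of attractor points (food
   sources). Each frame, an agent sums a stochastic unit vector — whose
   heading wanders under one-dimensional fractal Perlin noise — with a
   deterministic pull of magnitude

   *F* = √(*c* / *D*)

   toward its nearest active source (distance *D*, force constant
   *c* = 10 by default), then moves exactly 1.5 px (90 px/s at
   60 fps). A source that receives ⌈*n*/10⌉ arrivals is depleted and
   releases a fresh population of *n* agents. Agent positions sampled
   every 3 frames form a trail point cloud, which is meshed by
   connecting every point to its *p*ₘ = 10 nearest neighbours.

2. **Shortest-walk refining.** Each food source is routed through the
   mesh to its *p* nearest neighbour sources (the proximity
   coefficient, default *p* = 3; extra routes are added if needed to
   connect all sources). The union of these minimum-length walks,
   decomposed into distinct source-to-source links, is the refined
   network.

Networks are scored with three efficiency metrics: **cost** (total
length of all links), **travel time** (mean source-to-source
shortest-path length) and **vulnerability** (mean travel-time increase
over single-link removals, with disconnected pairs charged the intact
network's total length). Normalised ratios and products of these
(P_tt/c, P_v/c, P_v/tt, P_ctt, …), trendline fits over *p*, and
closest-point comparison against digitized reference networks support
benchmarking grown, modelled and built systems against each other.

Raising *p* buys robustness with length: cost grows almost linearly in
*p* while travel time (third-order-polynomial-like) and vulnerability
(power-law-like) fall — a tunable cost/efficiency/resilience frontier.

## A worked example

```bash
python examples/grow_and_refine.py
```

```
foraging: 1812 frames (30 s of growth), 102,477 trail points, trail cost 307,276 agent-frames
mesh:     102,484 nodes, 581,752 edges, cost 1,353,953 px
network:  12 links between sources, 15 drawn segments
  cost            3605.5 px   (total length of all links)
  travel time      438.3 px   (mean source-to-source path)
  vulnerability     22.4 px   (mean travel-time rise per fault)
```

Seven food sources were scattered with 80 px minimum spacing; foraging
colonized all of them in 30 simulated seconds, leaving a ~100k-point
trail cloud; the 10-neighbour mesh over that cloud was refined at
*p* = 3 into 12 source-to-source links. An average trip between two
sources travels 438 px over 3606 px of built infrastructure, and
knocking out an average link lengthens trips by 22 px.

Other example scripts: `tune_proximity.py` (the *p* frontier and its
trendlines), `start_invariance.py` (grow from every attractor — final
costs agree within ~1%), `force_constant_sweep.py` (how *c* trades
exploration for exploitation), `compare_to_built_network.py`
(benchmarking a hand-drawn ring against the model's frontier).

A thin CLI wraps the same pipeline:

```bash
myxonet layout -n 7 --seed 1 --out oats.csv
myxonet pipeline oats.csv --seed 1 --out run1/
myxonet experiment p_sweep oats.csv --seed 1 --out sweep.csv
```

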