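# Methods

## Model overview

`myxonet` simulates plasmodial slime-mould growth as two independent
stages. Stage one is an agent-based foraging simulation that produces
a trail point cloud and, from it, a dense k-nearest-neighbour
proximity mesh biased to the food-source field. Stage two computes a
shortest-walk network over that mesh connecting every food source to
its nearest neighbour sources. Decoupling the stages is the point of
the design: the refinement can be re-run with different objectives
over one grown mesh, and growth can be restarted anywhere without
changing the designed network.

All geometry is planar Euclidean, in continuous pixels, origin at the
lower-left of an 800 × 800 px domain (y up). There is no geographic
CRS; digitized reference networks are rescaled uniformly into the
domain when compared.

## Stage one: foraging

Each of *n* agents carries a position and a heading. Per frame the
displacement is

```
step · unit( noise_vector + F · unit(nearest_source − position) )
```

with `F = sqrt(c / max(D, 1 px))`. The 1-px clamp removes the
singularity at the source. Speed is reset after summation, so every
live agent moves exactly `step_length` per frame; walls reflect the
outward component of motion.

**Stochastic steering.** One fractal-noise stream per agent drives the
*heading angle* of a constant-magnitude stochastic vector:
θ(t) = 4π · noise(t), components (cos θ, sin θ) · amplitude. The 4π
gain maps the noise range across two full turns, which makes the
time-averaged heading distribution effectively uniform on the circle
(a 2π gain leaves a measurable +x bias because noise values
concentrate near zero). An alternative `components` mode (two
independent streams for x and y) is available in `SimConfig`; it
produces a markedly more deterministic forage because the two
components are often simultaneously small. The heading mode is the
default because it makes the force constant directly interpretable —
the pull outweighs unit noise within D < c pixels of a source, so
c = 1 is a noise-dominated space-filling wander and c = 1000 an
almost uninterrupted beeline — and because it reproduces the ~35 s
(≈2100-frame) colonization time scale of a seven-source layout under
the default parameters without further adjustment.

The noise itself is classic 1-D gradient (Perlin) noise: hashed unit
gradients on an integer lattice, quintic-fade interpolation, summed
over 4 octaves with frequency doubling and range halving per octave
(base frequency 0.01 per frame). Values are bounded by twice the
first-octave amplitude, and consecutive samples are strongly
correlated — the "memory" that turns steering into smooth curves
rather than jitter. The implementation is deterministic in
(seed, stream id, frame); per-agent stream ids are derived from a
global agent counter so respawned populations get fresh streams.

**Colonization and depletion.** An agent within the colonization
radius (5 px) of its nearest *active* source arrives there. A source
consumes arrivals only up to the depletion threshold ⌈n/10⌉ — closest
agents first, deterministically — then deactivates and releases a
fresh population of *n* agents from its own location; the rest of a
converging wave keeps foraging. Arrival must be a discrete, countable
event for the n/10 rule, hence absorption; capping absorption at the
threshold keeps the forager population (and with it trail coverage)
from being silently bled by large waves. The run ends when every
source is depleted; a `max_frames` cap (20,000) guards against
non-termination and raises an error carrying partial results.

Positions of all live agents are sampled every `sample_stride` = 3
frames into the trail cloud. `trail_cost` is the number of live agents
summed over frames — total foraging effort in agent-frames.

For the force-constant sweep experiment only, colonization is disabled
and every variant runs for a fixed 2100 frames, so trail morphology is
compared at equal effort; with depletion enabled, a c = 1 walk
essentially never colonizes and the comparison would confound
morphology with runtime.

## Stage one output: the mesh

Sources plus trail points (near-duplicates merged at 1e-9 px) are
connected each to their p_m = 10 nearest neighbours; the directed
relation is symmetrised by union into a simple weighted graph, edge
weight = Euclidean length. Exact k-NN ties break toward the smaller
node index; clouds above 4096 points use a cKDTree (ties there are
resolved by the tree's deterministic scan order — exact float ties do
not occur for continuous foraging coordinates). Mesh cost (summed edge
lengths) grows essentially linearly with p_m, and meshes are nested in
p_m.

## Stage two: shortest-walk refinement

Terminal pairs are chosen by Euclidean proximity: each source is
paired with its min(p, S−1) nearest other sources (ties to the lower
index), pairs deduplicated. Every pair is routed by Dijkstra over the
mesh (scipy's sparse implementation; its fixed scan order makes
routing deterministic). "A minimum of p neighbours" is enforced as a
connectivity guarantee: if the routed union leaves source groups
apart, the Euclidean-closest source pair across groups is routed too,
until one component remains. The refined network therefore always
connects all food sources, and the disconnection penalty below can
only ever be triggered by a fault-removal, not by the intact network.

**Assessment linework.** For metric assessment the network is
simplified to distinct source-to-source *links*. A routed pair (A, C)
is split at an intermediate source B when B lies within the corridor
half-width (15 px) of the straight A–C segment, strictly between the
endpoints, recursively; each link's length is the along-mesh
shortest-path distance between its end sources, and links are
deduplicated by source pair. Two properties motivated this design:

* the split decision is a function of the layout geometry alone, so
  repeated runs on one layout yield identical link sets — decomposing
  the *realized* trails instead puts a cliff wherever a source sits
  near (but not on) another pair's corridor, and whole links then
  flip in and out between runs;
* 15 px matches the colonized cluster each source accretes (arriving
  and respawned agents deposit a dense trail blob extending 15–20 px),
  i.e. the width at which drawn linework passes "through" a source,
  while staying well below half the minimum source spacing.

Corridors shorter than twice the half-width never split. The
mesh-edge union of all routed paths is retained alongside the links:
it backs serialization, the Network ⊆ Mesh invariant, and the
decomposition into *segments* (maximal chains whose interior nodes are
non-source degree-2 nodes).

## Efficiency metrics

On the link graph (default granularity; `segment` and `edge`
granularities are available for sensitivity analysis):

* **cost** — sum of link lengths;
* **travel time** — mean Dijkstra distance over all C(S,2) unordered
  source pairs;
* **vulnerability** — remove each link in turn, recompute travel time
  with disconnected pairs assigned the *intact* network's total
  length, floor each increase at zero, average over removals. Reading
  the penalty as the intact rather than post-removal length is a
  choice; the two differ by one link length and move all compared
  networks together. A two-source, single-link network has
  vulnerability exactly 0 under this rule.

Normalisation divides each metric by its maximum over the compared
collection (reference networks can be pooled in), from which
performance ratios (P_tt/c, P_v/c, P_v/tt) and products (P_ctt, P_cv,
P_ttv, and collection averages) are formed. Trendlines over p come
from least squares in six families (linear, polynomials of order 2–4,
power a·xᵇ, exponential a·e^{bx}; the nonlinear families get
log-linear starts refined by `curve_fit`), and a reference network is
compared to a curve by densely sampling the fitted line (1000 points
across the observed span) and taking the closest sample in the
normalized plane — uniform across families, no per-family projection
algebra.

## Synthetic layouts

`generate_layout` emulates the hand-arranged oat patterns growth
experiments use: 2–9 points rejection-sampled uniformly over the
domain with a minimum spacing (default 80 px) and half that spacing
kept from the boundary; deterministic per seed. It does not emulate
two features of real arrangements: hand-designed layouts avoid
near-collinear triples of oats, whereas random layouts occasionally
contain a source sitting near the corridor of another routed pair
(the assessment handles these deterministically, but such geometries
genuinely route differently and their metrics are more variable); and
real oats have finite extent while model sources are points. Passing
tests therefore demonstrate reproducibility of the model's behaviour
on random layouts of the stated density, not performance claims about
any particular real arrangement.

## Problem sizes and numerical choices

Default-condition runs (7 sources, n = 50, c = 10) forage for roughly
1,500–3,700 frames and leave 100k–270k trail points; meshing and
routing on such clouds take a few seconds each, and a full pipeline
run completes in under ten seconds on one CPU. The test suite and the
acceptance script use these full-size conditions; only counts of
repeats are modest (7 start choices, 5 repeat seeds, 5 c-sweep seeds),
chosen to match the corresponding experiments.

Reproducibility spreads are reported as the maximum pairwise relative
difference, (max − min)/min — the strictest reading of a set of values
lying "within x% of one another". Under the default conditions the
cost spread across start choices and across seeded repeats is
~0.6–0.7% and travel time ~0.7%; vulnerability, whose removal deltas
are amplified by the total-length penalty, spreads ~1.4% — about twice
the cost spread, and the quantity most sensitive to residual
trail-coverage luck. Runs whose depletion completes unusually early
can leave a corridor between never-directly-trafficked source pairs
thinly covered; the route for that link then genuinely detours, which
is the dominant source of outlier spreads on unlucky layout/seed
combinations.

Other numerical choices: distances deduplicate at 1e-9 px; agent
speed is exact to 1e-9 px per frame; the zero-resultant steering case
falls back to the previous heading (+x on the first frame);
accessibility fractions are measured on a 1-px grid of cell centers
against the exact nearest trail point (cKDTree), not a raster
approximation.

## Known limitations

* No anti-attractors (repellants), no flux/thickness feedback, no
  multi-nutrient chemistry — the stages are deliberately decoupled
  and feedback-free.
* The refinement can only use paths between attractor points; it
  cannot invent Steiner junctions, so for small source counts
  (especially 3) it produces triangle-like morphologies where a
  minimum tree would do better.
* Trail-coverage holes on unlucky runs inflate single links (see
  above); averaging refinement over pooled clouds would remove this
  but is deliberately not done, to keep one run = one organism.
* The scaling of digitized reference coordinates into the model
  domain is a uniform fit; metric *ratios* are scale-free but raw
  pixel metrics of rescaled networks are not comparable across
  different fits.
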