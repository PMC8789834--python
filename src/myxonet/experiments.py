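"""Batch experiments: invariance, consistency and parameter sweeps.

Each experiment runs the pipeline repeatedly while varying one knob —
the start attractor, the master seed, the proximity coefficient p, the
force constant c, or the mesh neighbour count p_m — and aggregates the
per-run metrics into a tidy table with the summary statistics used to
judge the model (max pairwise relative differences, trend statistics).
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .foraging import grid_nearest_distances, run_foraging, trail_cost
from .layouts import AttractorLayout
from .meshing import build_mesh, mesh_cost
from .metrics import compute_metrics
from .pipeline import PipelineConfig, derive_seed, run_model
from .refinement import RefineConfig, shortest_walk

log = logging.getLogger("myxonet")

EXPERIMENT_KINDS = (
    "start_invariance", "repeat_consistency", "p_sweep", "c_sweep", "pm_sweep"
)


def max_pairwise_relative_difference(values) -> float:
    """Largest |a-b|/min(a,b) over all pairs, i.e. (max-min)/min.

    The strictest reading of a set of values being "within x% of one
    another".  Returned as a fraction (multiply by 100 for percent).
    """
    vals = np.asarray(list(values), dtype=float)
    if len(vals) < 2:
        return 0.0
    lo, hi = vals.min(), vals.max()
    if lo <= 0:
        raise ValueError("relative difference undefined for non-positive values")
    return float((hi - lo) / lo)


@dataclass
class ExperimentResult:
    """Tidy per-run table plus experiment-level summary statistics."""

    kind: str
    table: pd.DataFrame
    summary: dict[str, float] = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _metric_row(result, **extra) -> dict:
    row = dict(extra)
    row["trail_cost"] = trail_cost(result.sim_log)
    row["mesh_cost"] = mesh_cost(result.mesh) if result.mesh is not None else np.nan
    row["n_trail_points"] = len(result.cloud)
    row["frames"] = result.sim_log.terminated_frame
    m = result.metrics
    if m is not None:
        row.update(cost=m.cost, travel_time=m.travel_time,
                   vulnerability=m.vulnerability,
                   n_segments=len(result.network.segments))
    return row


def start_invariance_experiment(
    layout: AttractorLayout, config: PipelineConfig | None = None
) -> ExperimentResult:
    """Grow from each attractor in turn; final networks should agree.

    The meshing stage is highly variable in morphology, but refinement
    recovers essentially the same network: the headline claim is < 1%
    variation in cost across start choices.
    """
    config = config or PipelineConfig()
    rows = []
    for i in range(len(layout)):
        cfg_i = config.with_seed(derive_seed(config.sim.seed, 1, i))
        res = run_model(layout.with_spawn(i), cfg_i)
        rows.append(_metric_row(res, start_index=i, seed=cfg_i.sim.seed))
        log.info("start_invariance: start=%d cost=%.1f", i, rows[-1].get("cost", np.nan))
    table = pd.DataFrame(rows)
    summary = {
        f"max_rel_diff_{m}": max_pairwise_relative_difference(table[m])
        for m in ("cost", "travel_time", "vulnerability") if m in table
    }
    return ExperimentResult("start_invariance", table, summary)


def repeat_consistency_experiment(
    layout: AttractorLayout,
    config: PipelineConfig | None = None,
    n_repeats: int = 5,
) -> ExperimentResult:
    """Repeat the full pipeline with independent seeds on one layout."""
    config = config or PipelineConfig()
    rows = []
    for r in range(n_repeats):
        cfg_r = config.with_seed(derive_seed(config.sim.seed, 2, r))
        res = run_model(layout, cfg_r)
        rows.append(_metric_row(res, repeat=r, seed=cfg_r.sim.seed))
    table = pd.DataFrame(rows)
    summary = {
        f"max_rel_diff_{m}": max_pairwise_relative_difference(table[m])
        for m in ("cost", "travel_time", "vulnerability") if m in table
    }
    return ExperimentResult("repeat_consistency", table, summary)


def p_sweep_experiment(
    layout: AttractorLayout,
    config: PipelineConfig | None = None,
    p_values=range(1, 6),
) -> ExperimentResult:
    """One grow + mesh, refined at each proximity coefficient p.

    Cost should rise (close to linearly) with p while travel time and
    vulnerability fall.
    """
    config = config or PipelineConfig()
    res = run_model(layout, config)  # network at default p; mesh reused below
    rows = []
    for p in p_values:
        net = shortest_walk(res.mesh, cfg=RefineConfig(proximity_coefficient=p))
        m = compute_metrics(net)
        rows.append(dict(p=p, cost=m.cost, travel_time=m.travel_time,
                         vulnerability=m.vulnerability,
                         n_segments=len(net.segments)))
    table = pd.DataFrame(rows)
    summary = {}
    if len(table) >= 2:
        summary["cost_vs_p_pearson_r"] = float(pearsonr(table["p"], table["cost"])[0])
        summary["cost_nondecreasing"] = float(np.all(np.diff(table["cost"]) >= -1e-9))
        summary["travel_time_nonincreasing"] = float(
            np.all(np.diff(table["travel_time"]) <= 1e-9))
        summary["vulnerability_nonincreasing"] = float(
            np.all(np.diff(table["vulnerability"]) <= 1e-9))
    return ExperimentResult("p_sweep", table, summary)


def c_sweep_experiment(
    layout: AttractorLayout,
    config: PipelineConfig | None = None,
    c_values=(1.0, 10.0, 100.0, 1000.0),
    reach_fractions=(0.20, 0.10, 0.01),
    n_seeds: int = 5,
    fixed_frames: int = 2100,
) -> ExperimentResult:
    """Vary the force constant; measure trail cost and accessibility.

    Runs the fixed-duration foraging protocol (colonization disabled,
    ``fixed_frames`` frames — the reference 35 s at 60 fps) so trail
    morphology is compared across c at equal foraging effort.  Trail
    cost is expected to be essentially independent of c, while the
    fraction of the domain within reach of the trail falls as foraging
    becomes more deterministic.
    """
    config = config or PipelineConfig()
    reaches = [f * layout.domain.width for f in reach_fractions]
    rows = []
    for c, s in itertools.product(c_values, range(n_seeds)):
        sim = dataclasses.replace(
            config.sim, force_constant=float(c), colonize=False,
            max_frames=fixed_frames,
            seed=derive_seed(config.sim.seed, 3, int(c * 1000), s))
        cloud, sim_log = run_foraging(layout, sim)
        row = dict(c=c, seed_rep=s, seed=sim.seed,
                   trail_cost=trail_cost(sim_log),
                   n_trail_points=len(cloud), frames=sim_log.terminated_frame)
        dist_field = grid_nearest_distances(cloud, layout.domain)
        for frac, reach in zip(reach_fractions, reaches):
            row[f"accessibility_{int(frac * 100)}pct"] = float(
                np.mean(dist_field <= reach))
        rows.append(row)
        log.info("c_sweep: c=%g rep=%d trail_cost=%d", c, s, row["trail_cost"])
    table = pd.DataFrame(rows)
    summary = {"max_rel_diff_trail_cost":
               max_pairwise_relative_difference(table["trail_cost"])}
    for frac in reach_fractions:
        col = f"accessibility_{int(frac * 100)}pct"
        mean_by_c = table.groupby("c")[col].mean()
        summary[f"{col}_nonincreasing_in_c"] = float(
            np.all(np.diff(mean_by_c.values) <= 1e-12))
    return ExperimentResult("c_sweep", table, summary)


def pm_sweep_experiment(
    layout: AttractorLayout,
    config: PipelineConfig | None = None,
    pm_values=range(2, 15),
) -> ExperimentResult:
    """One foraging cloud, meshed at each neighbour count p_m.

    Mesh cost grows with p_m and the growth is close to linear.
    """
    config = config or PipelineConfig()
    res = run_model(layout, config)
    pts = np.vstack([layout.coords, res.cloud.points])
    rows = []
    for pm in pm_values:
        mesh = build_mesh(pts, n_sources=len(layout), p_m=pm)
        rows.append(dict(p_m=pm, n_edges=mesh.n_edges, mesh_cost=mesh_cost(mesh)))
    table = pd.DataFrame(rows)
    summary = {}
    if len(table) >= 2:
        summary["mesh_cost_vs_pm_pearson_r"] = float(
            pearsonr(table["p_m"], table["mesh_cost"])[0])
        summary["mesh_cost_nondecreasing"] = float(
            np.all(np.diff(table["mesh_cost"]) >= -1e-9))
    return ExperimentResult("pm_sweep", table, summary)


def run_experiment(
    kind: str,
    layout: AttractorLayout,
    config: PipelineConfig | None = None,
    **kwargs,
) -> ExperimentResult:
    """Dispatch an experiment by name (see ``EXPERIMENT_KINDS``)."""
    dispatch = {
        "start_invariance": start_invariance_experiment,
        "repeat_consistency": repeat_consistency_experiment,
        "p_sweep": p_sweep_experiment,
        "c_sweep": c_sweep_experiment,
        "pm_sweep": pm_sweep_experiment,
    }
    if kind not in dispatch:
        raise ValueError(f"unknown experiment kind {kind!r}; expected one of "
                         f"{EXPERIMENT_KINDS}")
    return dispatch[kind](layout, config, **kwargs)
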