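"""End-to-end pipeline orchestration: grow -> mesh -> refine -> metrics.

A run consumes an attractor layout plus a configuration, executes the
two model stages and the metric analysis, writes every intermediate
artifact to an output directory, and records a manifest sufficient to
reproduce the run bit-identically from the master seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .foraging import SimConfig, TrailCloud, SimLog, run_foraging, trail_cost
from .layouts import AttractorLayout, read_layout
from .meshing import Mesh, build_mesh, mesh_cost
from .metrics import compute_metrics, normalize_and_score
from .network_io import write_network, write_segments_csv
from .refinement import Network, RefineConfig, shortest_walk

log = logging.getLogger("myxonet")


@dataclass
class PipelineConfig:
    """Combined Stage-one + Stage-two configuration."""

    sim: SimConfig = field(default_factory=SimConfig)
    p_m: int = 10
    refine: RefineConfig = field(default_factory=RefineConfig)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load from YAML or JSON mirroring the config field names."""
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.get("sim", {}))
        refine = RefineConfig(**raw.get("refine", {}))
        return cls(sim=sim, p_m=int(raw.get("p_m", 10)), refine=refine)

    def to_dict(self) -> dict:
        return {
            "sim": dataclasses.asdict(self.sim),
            "p_m": self.p_m,
            "refine": dataclasses.asdict(self.refine),
        }

    def with_seed(self, seed: int) -> "PipelineConfig":
        return PipelineConfig(
            sim=dataclasses.replace(self.sim, seed=int(seed)),
            p_m=self.p_m,
            refine=self.refine,
        )


def derive_seed(master_seed: int, *counters: int) -> int:
    """Counter-based sub-seed derivation (stable, below 2**31)."""
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, *map(int, counters)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class RunResult:
    """In-memory result of one grow -> mesh -> refine run."""

    layout: AttractorLayout
    cloud: TrailCloud
    sim_log: SimLog
    mesh: Mesh | None
    network: Network | None

    @property
    def metrics(self):
        if self.network is None:
            return None
        return compute_metrics(self.network)


def run_model(
    layout: AttractorLayout, config: PipelineConfig | None = None
) -> RunResult:
    """Run both model stages in memory and return every intermediate.

    With a single food source the refinement stage is skipped (there is
    nothing to route) and ``network`` is None.
    """
    config = config or PipelineConfig()
    cloud, sim_log = run_foraging(layout, config.sim)
    pts = np.vstack([layout.coords, cloud.points])
    mesh = network = None
    if len(layout) >= 2:
        mesh = build_mesh(pts, n_sources=len(layout), p_m=config.p_m)
        network = shortest_walk(mesh, cfg=config.refine)
    else:
        log.info("single-source layout: meshing and refinement skipped")
    return RunResult(layout=layout, cloud=cloud, sim_log=sim_log,
                     mesh=mesh, network=network)


@dataclass
class RunManifest:
    """Reproducibility record written at the end of a pipeline run."""

    config: dict
    master_seed: int
    outputs: dict[str, str]
    timings: dict[str, float]
    version: str = __version__
    status: str = "ok"
    failure_stage: str | None = None

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        tmp = path.with_suffix(".tmp")
        with open(tmp, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
        os.replace(tmp, path)
        return path


def run_pipeline(
    layout_path: str | Path,
    config_path: str | Path | None,
    out_dir: str | Path,
    seed: int | None = None,
) -> RunManifest:
    """File-to-file pipeline: read layout, run the model, write artifacts.

    Writes ``trails.csv``, ``mesh.geojson`` (edge list CSV alongside),
    ``network.geojson``, ``segments.csv``, ``metrics.json`` and
    ``manifest.json`` into ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = (PipelineConfig.from_file(config_path) if config_path
              else PipelineConfig())
    if seed is not None:
        config = config.with_seed(seed)

    outputs: dict[str, str] = {}
    timings: dict[str, float] = {}
    manifest = RunManifest(config=config.to_dict(), master_seed=config.sim.seed,
                           outputs=outputs, timings=timings)
    stage = "load"
    try:
        layout = read_layout(layout_path)
        t0 = time.perf_counter()
        stage = "grow"
        cloud, sim_log = run_foraging(layout, config.sim)
        timings["grow"] = time.perf_counter() - t0
        outputs["trails"] = str(cloud.to_csv(out_dir / "trails.csv"))
        outputs["sim_log"] = str(sim_log.to_json(out_dir / "sim_log.json"))
        log.info("grow: %d trail points, %d frames, trail cost %d",
                 len(cloud), sim_log.terminated_frame, trail_cost(sim_log))

        metrics_path = out_dir / "metrics.json"
        if len(layout) < 2:
            log.warning("single-source layout: meshing and refinement skipped")
            with open(metrics_path, "w", encoding="utf-8") as fh:
                json.dump({"note": "refinement skipped: single-source layout"}, fh)
            outputs["metrics"] = str(metrics_path)
        else:
            t0 = time.perf_counter()
            stage = "mesh"
            pts = np.vstack([layout.coords, cloud.points])
            mesh = build_mesh(pts, n_sources=len(layout), p_m=config.p_m)
            timings["mesh"] = time.perf_counter() - t0
            outputs["mesh"] = str(_write_mesh_csv(mesh, out_dir / "mesh.csv"))
            log.info("mesh: %d nodes, %d edges, cost %.1f px",
                     mesh.n_nodes, mesh.n_edges, mesh_cost(mesh))

            t0 = time.perf_counter()
            stage = "refine"
            network = shortest_walk(mesh, cfg=config.refine)
            timings["refine"] = time.perf_counter() - t0
            outputs["network"] = str(write_network(network, out_dir / "network.geojson"))
            outputs["segments"] = str(write_segments_csv(network, out_dir / "segments.csv"))

            t0 = time.perf_counter()
            stage = "metrics"
            report = compute_metrics(network)
            scored = normalize_and_score([report])[0]
            timings["metrics"] = time.perf_counter() - t0
            with open(metrics_path, "w", encoding="utf-8") as fh:
                json.dump({
                    "cost": report.cost,
                    "travel_time": report.travel_time,
                    "vulnerability": report.vulnerability,
                    "ratios": scored.ratios,
                    "n_segments": len(network.segments),
                    "trail_cost": trail_cost(sim_log),
                    "mesh_cost": mesh_cost(mesh),
                }, fh, indent=2, sort_keys=True)
            outputs["metrics"] = str(metrics_path)
    except Exception:
        manifest.status = "failed"
        manifest.failure_stage = stage
        manifest.write(out_dir / "manifest.json")
        raise
    manifest.write(out_dir / "manifest.json")
    return manifest


def _write_mesh_csv(mesh: Mesh, path: Path) -> Path:
    data = np.column_stack([mesh.edges, mesh.weights])
    np.savetxt(path, data, delimiter=",", header="u,v,length", comments="",
               fmt=["%d", "%d", "%.9f"])
    return path
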