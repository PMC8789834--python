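"""Stage one: attractor-biased agent foraging.

A population of n agents (analogous to differentiated plasmodial
nuclei) is released at a spawn point.  Each frame every agent sums a
stochastic fractal-noise vector with a deterministic attraction vector
pointing at its nearest active food source, whose magnitude is
F = sqrt(c / D) for distance D (clamped below at 1 px) and force
constant c.  Speed is reset after summation so agents always move
step_length px per frame.  An agent that comes within the colonization
radius of an active source is absorbed and counted as an arrival; once
ceil(n/10) agents arrive, the source is depleted (deactivated) and
releases a fresh population of n agents from its own location.  The
run ends when every source is depleted.  Live-agent positions sampled
every few frames form the trail point cloud that Stage two meshes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .geometry import Domain, Point2D
from .layouts import AttractorLayout
from .perlin import NoiseStream, fractal_noise


@dataclass(frozen=True)
class SimConfig:
    """Foraging simulation parameters.

    Defaults reproduce the standard study conditions: n = 50 agents,
    force constant c = 10, 1.5 px/frame at 60 frames per second
    (90 px/s), one trail point per three frames, depletion after
    n/10 arrivals, in an 800 x 800 px domain.
    """

    n_agents: int = 50
    force_constant: float = 10.0
    step_length: float = 1.5
    frames_per_second: float = 60.0
    sample_stride: int = 3
    depletion_fraction: float = 0.1
    colonization_radius: float = 5.0
    noise_mode: str = "heading"
    noise_amplitude: float = 1.0
    noise_base_frequency: float = 0.01
    noise_octaves: int = 4
    max_frames: int = 20_000
    colonize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_agents < 1:
            raise ValueError("n_agents must be >= 1")
        if self.force_constant <= 0:
            raise ValueError("force_constant must be > 0")
        if self.step_length <= 0:
            raise ValueError("step_length must be > 0")
        if not (0 < self.depletion_fraction <= 1):
            raise ValueError("depletion_fraction must be in (0, 1]")
        if self.noise_octaves < 1:
            raise ValueError("noise_octaves must be >= 1")
        if self.noise_mode not in ("heading", "components"):
            raise ValueError("noise_mode must be 'heading' or 'components'")
        if self.sample_stride < 1:
            raise ValueError("sample_stride must be >= 1")

    @property
    def depletion_threshold(self) -> int:
        """Arrivals needed to deplete a source: ceil(n * fraction)."""
        return math.ceil(self.n_agents * self.depletion_fraction)


@dataclass
class Agent:
    """Single forager state (scalar API; the simulation is vectorised)."""

    position: Point2D
    noise_stream_x: NoiseStream
    noise_stream_y: NoiseStream
    heading: tuple[float, float] = (1.0, 0.0)
    alive: bool = True


@dataclass
class TrailCloud:
    """Sampled agent positions ("nuclei" point cloud) left by foraging."""

    points: np.ndarray  # (N, 2) pixels
    frame_of: np.ndarray  # (N,) frame index of each sample
    provenance: np.ndarray  # (N,) agent id of each sample

    def __len__(self) -> int:
        return len(self.points)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        header = "agent_id,frame,x,y"
        data = np.column_stack(
            [self.provenance, self.frame_of, self.points[:, 0], self.points[:, 1]]
        )
        np.savetxt(path, data, delimiter=",", header=header, comments="",
                   fmt=["%d", "%d", "%.9f", "%.9f"])
        return path


@dataclass
class SimLog:
    """Bookkeeping of a foraging run."""

    depletion_events: list[tuple[int, int]] = field(default_factory=list)
    spawn_events: list[tuple[tuple[float, float], int, int]] = field(default_factory=list)
    total_agent_frames: int = 0
    terminated_frame: int = 0
    completed: bool = False

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)
        return path


class NonTerminationError(RuntimeError):
    """Foraging hit the frame cap before all sources were depleted."""

    def __init__(self, msg: str, cloud: "TrailCloud", log: "SimLog"):
        super().__init__(msg)
        self.cloud = cloud
        self.log = log


def attraction_force(distance, force_constant: float = 10.0):
    """Attraction magnitude F = sqrt(c / D), with D clamped below at 1 px.

    Strictly decreasing in distance above the clamp; the clamp avoids
    the singularity as an agent reaches a food source.
    """
    if force_constant <= 0:
        raise ValueError("force_constant must be > 0")
    d = np.maximum(np.asarray(distance, dtype=float), 1.0)
    out = np.sqrt(force_constant / d)
    return float(out) if out.ndim == 0 else out


def nearest_active_attractor(
    position: Point2D | tuple[float, float], layout: AttractorLayout
) -> tuple[int, float]:
    """Index and distance of the closest active food source.

    Depleted sources are never returned; exact distance ties go to the
    lower index.
    """
    if not layout.active.any():
        raise RuntimeError("no active attractor: the simulation should have terminated")
    pos = np.asarray(position, dtype=float)
    d = np.linalg.norm(layout.coords - pos, axis=1)
    d = np.where(layout.active, d, np.inf)
    idx = int(np.argmin(d))
    return idx, float(d[idx])


def _step_kernel(
    positions: np.ndarray,
    headings: np.ndarray,
    stream_x: np.ndarray,
    stream_y: np.ndarray,
    active_coords: np.ndarray,
    t: int,
    cfg: SimConfig,
    domain: Domain,
) -> tuple[np.ndarray, np.ndarray]:
    """Advance all agents one frame.  Returns (positions, headings)."""
    # deterministic pull toward the nearest active source
    d = cdist(positions, active_coords)
    j = np.argmin(d, axis=1)
    dn = d[np.arange(len(positions)), j]
    force = attraction_force(dn, cfg.force_constant)
    vec = active_coords[j] - positions
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(dn[:, None] > 0, vec / np.where(dn == 0, 1.0, dn)[:, None], 0.0)

    # stochastic component.  In the default "heading" mode one noise
    # stream per agent wanders the angle of a constant-magnitude
    # stochastic vector (x and y are its cos/sin components); the unit
    # magnitude makes the force constant directly interpretable: the
    # pull beats the noise once F = sqrt(c/D) > amplitude, i.e. within
    # D < c px of a source for amplitude 1.  "components" mode instead
    # draws x and y from two independent noise streams.
    if cfg.noise_mode == "heading":
        # the noise value (bounded in [-2, 2]) is mapped across two
        # full turns per unit so the wandering heading covers the
        # circle without directional bias
        theta = 4.0 * np.pi * fractal_noise(
            float(t), stream_x, cfg.seed, cfg.noise_base_frequency,
            cfg.noise_octaves, 1.0)
        nx = cfg.noise_amplitude * np.cos(theta)
        ny = cfg.noise_amplitude * np.sin(theta)
    else:
        nx = fractal_noise(float(t), stream_x, cfg.seed, cfg.noise_base_frequency,
                           cfg.noise_octaves, cfg.noise_amplitude)
        ny = fractal_noise(float(t), stream_y, cfg.seed, cfg.noise_base_frequency,
                           cfg.noise_octaves, cfg.noise_amplitude)

    v = np.column_stack([nx, ny]) + force[:, None] * unit
    norm = np.linalg.norm(v, axis=1)
    degenerate = norm < 1e-12
    if degenerate.any():
        v[degenerate] = headings[degenerate]
        norm[degenerate] = np.linalg.norm(v[degenerate], axis=1)
    heading = v / norm[:, None]

    new_pos = positions + cfg.step_length * heading
    # reflect the outward component at the walls
    for axis, hi in ((0, domain.width), (1, domain.height)):
        low = new_pos[:, axis] < 0
        new_pos[low, axis] = -new_pos[low, axis]
        heading[low, axis] = -heading[low, axis]
        high = new_pos[:, axis] > hi
        new_pos[high, axis] = 2 * hi - new_pos[high, axis]
        heading[high, axis] = -heading[high, axis]
    return new_pos, heading


def step_agent(agent: Agent, layout: AttractorLayout, cfg: SimConfig, t: int) -> Agent:
    """Advance a single agent one frame (see module docstring for the rule)."""
    if not agent.alive:
        raise ValueError("cannot step a dead agent")
    active_coords = layout.coords[layout.active]
    if len(active_coords) == 0:
        raise RuntimeError("no active attractor")
    pos = np.asarray([agent.position], dtype=float)
    heading = np.asarray([agent.heading], dtype=float)
    sx = np.asarray([agent.noise_stream_x.stream_id], dtype=np.int64)
    sy = np.asarray([agent.noise_stream_y.stream_id], dtype=np.int64)
    new_pos, new_heading = _step_kernel(
        pos, heading, sx, sy, active_coords, t, cfg, layout.domain
    )
    return Agent(
        position=Point2D(float(new_pos[0, 0]), float(new_pos[0, 1])),
        noise_stream_x=agent.noise_stream_x,
        noise_stream_y=agent.noise_stream_y,
        heading=(float(new_heading[0, 0]), float(new_heading[0, 1])),
        alive=True,
    )


def run_foraging(layout: AttractorLayout, cfg: SimConfig) -> tuple[TrailCloud, SimLog]:
    """Run the full Stage-one simulation until every source is depleted.

    Returns the sampled trail cloud and a log of depletion/spawn events.
    Raises :class:`NonTerminationError` (carrying partial results) if
    ``cfg.max_frames`` is reached first.

    With ``cfg.colonize`` False the colonization/depletion cycle is
    disabled: the initial population forages for exactly
    ``cfg.max_frames`` frames with every source persistently attractive.  This is the
    fixed-duration protocol of the force-constant sweep, where trail
    morphology rather than network growth is the object of study.
    """
    layout = layout.reset()
    domain = layout.domain
    coords = layout.coords
    active = layout.active
    arrivals = layout.arrivals
    threshold = cfg.depletion_threshold

    log = SimLog()
    sample_pts: list[np.ndarray] = []
    sample_frames: list[np.ndarray] = []
    sample_ids: list[np.ndarray] = []

    next_agent_id = 0

    def spawn(location: tuple[float, float], count: int, frame: int):
        nonlocal positions, headings, stream_x, stream_y, agent_ids, next_agent_id
        ids = np.arange(next_agent_id, next_agent_id + count, dtype=np.int64)
        next_agent_id += count
        positions = np.vstack([positions, np.tile(np.asarray(location, float), (count, 1))])
        headings = np.vstack([headings, np.tile([1.0, 0.0], (count, 1))])
        stream_x = np.concatenate([stream_x, 2 * ids])
        stream_y = np.concatenate([stream_y, 2 * ids + 1])
        agent_ids = np.concatenate([agent_ids, ids])
        log.spawn_events.append(((float(location[0]), float(location[1])), count, frame))

    positions = np.empty((0, 2))
    headings = np.empty((0, 2))
    stream_x = np.empty(0, dtype=np.int64)
    stream_y = np.empty(0, dtype=np.int64)
    agent_ids = np.empty(0, dtype=np.int64)
    spawn(tuple(layout.spawn), cfg.n_agents, 0)

    t = 0
    while active.any():
        if t >= cfg.max_frames:
            if not cfg.colonize:
                break  # fixed-duration forage complete
            cloud = _assemble_cloud(sample_pts, sample_frames, sample_ids)
            log.terminated_frame = t
            raise NonTerminationError(
                f"foraging did not deplete all sources within {cfg.max_frames} frames "
                f"({int(active.sum())} still active)", cloud, log,
            )
        t += 1
        if len(positions):
            positions, headings = _step_kernel(
                positions, headings, stream_x, stream_y, coords[active], t, cfg, domain
            )
            log.total_agent_frames += len(positions)

            # sample the trail cloud at the configured stride
            if t % cfg.sample_stride == 0:
                sample_pts.append(positions.copy())
                sample_frames.append(np.full(len(positions), t, dtype=np.int64))
                sample_ids.append(agent_ids.copy())

            if not cfg.colonize:
                continue

            # colonization: agents within radius of their nearest active source
            # arrive there.  A source only consumes arrivals up to the
            # depletion threshold (the closest agents first); once the
            # threshold is met it deactivates and stops being attractive,
            # so the rest of a converging wave forages on.
            d = cdist(positions, coords[active])
            jrel = np.argmin(d, axis=1)
            dn = d[np.arange(len(positions)), jrel]
            in_radius = dn <= cfg.colonization_radius
            if in_radius.any():
                active_idx = np.flatnonzero(active)
                absorb = np.zeros(len(positions), dtype=bool)
                for jrel_src in np.unique(jrel[in_radius]):
                    j = active_idx[jrel_src]
                    cand = np.flatnonzero(in_radius & (jrel == jrel_src))
                    need = threshold - arrivals[j]
                    if need <= 0:
                        continue
                    if len(cand) > need:
                        cand = cand[np.argsort(dn[cand], kind="stable")[:need]]
                    arrivals[j] += len(cand)
                    absorb[cand] = True
                if absorb.any():
                    keep = ~absorb
                    positions, headings = positions[keep], headings[keep]
                    stream_x, stream_y = stream_x[keep], stream_y[keep]
                    agent_ids = agent_ids[keep]

        # depletion: deactivate saturated sources, each releasing n offspring
        depleted = np.flatnonzero(active & (arrivals >= threshold))
        for jdep in depleted:
            active[jdep] = False
            log.depletion_events.append((int(jdep), t))
            spawn(tuple(coords[jdep]), cfg.n_agents, t)

    log.terminated_frame = t
    log.completed = True
    cloud = _assemble_cloud(sample_pts, sample_frames, sample_ids)
    return cloud, log


def _assemble_cloud(pts, frames, ids) -> TrailCloud:
    if pts:
        return TrailCloud(
            points=np.vstack(pts),
            frame_of=np.concatenate(frames),
            provenance=np.concatenate(ids),
        )
    return TrailCloud(
        points=np.empty((0, 2)),
        frame_of=np.empty(0, dtype=np.int64),
        provenance=np.empty(0, dtype=np.int64),
    )


def trail_cost(log: SimLog) -> int:
    """Total foraging effort: live-agent count summed over all frames."""
    return int(log.total_agent_frames)


def grid_nearest_distances(cloud: TrailCloud, domain: Domain | None = None) -> np.ndarray:
    """Distance from each 1-px grid-cell center to the nearest trail point.

    Shared by accessibility measurements at several reaches so the
    nearest-neighbour field is computed once per cloud.
    """
    domain = domain or Domain()
    w, h = int(round(domain.width)), int(round(domain.height))
    if len(cloud) == 0:
        return np.full((h, w), np.inf)
    xs = np.arange(w) + 0.5
    tree = cKDTree(cloud.points)
    out = np.empty((h, w))
    # row-chunked queries keep peak memory modest for large grids
    for iy in range(h):
        centers = np.column_stack([xs, np.full(w, iy + 0.5)])
        out[iy], _ = tree.query(centers, k=1)
    return out


def accessibility_fraction(
    cloud: TrailCloud, domain: Domain | None = None, reach: float = 80.0
) -> float:
    """Fraction of the domain within ``reach`` px of any trail point.

    Measured on a 1-px grid of cell centers; an empty cloud covers
    nothing.
    """
    if reach < 0:
        raise ValueError("reach must be >= 0")
    d = grid_nearest_distances(cloud, domain)
    return float(np.mean(d <= reach))
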