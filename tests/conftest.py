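"""Shared fixtures: toy networks with hand-computable metrics and one
standard foraging run reused across the mesh/refinement/metrics tests."""

from __future__ import annotations

import numpy as np
import pytest

import myxonet as mx
from myxonet.meshing import build_mesh
from myxonet.refinement import RefineConfig, shortest_walk


def toy_network(points, p_m, p):
    """Mesh + shortest walk over explicit source points (all sources)."""
    mesh = build_mesh(np.asarray(points, float), n_sources=len(points), p_m=p_m)
    return shortest_walk(mesh, cfg=RefineConfig(proximity_coefficient=p))


@pytest.fixture
def unit_triangle():
    """Equilateral unit triangle of 3 sources; every pair directly linked."""
    pts = [(0.0, 0.0), (1.0, 0.0), (0.5, np.sqrt(3) / 2)]
    return toy_network(pts, p_m=2, p=2)


@pytest.fixture
def chain_abc():
    """Collinear A-B-C with 100 px spacing; A-C must route through B."""
    pts = [(0.0, 0.0), (100.0, 0.0), (200.0, 0.0)]
    return toy_network(pts, p_m=1, p=2)


@pytest.fixture
def single_edge():
    """Two sources joined by one 50 px edge."""
    pts = [(0.0, 0.0), (50.0, 0.0)]
    return toy_network(pts, p_m=1, p=1)


@pytest.fixture(scope="session")
def seven_layout():
    return mx.generate_layout(7, min_spacing=80.0, seed=1)


@pytest.fixture(scope="session")
def forage_run(seven_layout):
    """One standard foraging run (default config) shared across tests."""
    cfg = mx.SimConfig(seed=11)
    cloud, log = mx.run_foraging(seven_layout, cfg)
    return seven_layout, cfg, cloud, log


@pytest.fixture(scope="session")
def forage_mesh(forage_run):
    layout, _, cloud, _ = forage_run
    pts = np.vstack([layout.coords, cloud.points])
    return build_mesh(pts, n_sources=len(layout), p_m=10)
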