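"""Stage two: shortest-walk network refinement over the mesh.

Each food source is routed to its p closest neighbouring sources
(Euclidean proximity; p is the proximity coefficient, default 3) by the
minimum-length path through mesh edges.  The refined network is the
union of all such paths, with shared edges stored once.  Increasing p
adds connectivity — and cost — while reducing travel time and fault
vulnerability, which is the design dial the two-stage model exposes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import dijkstra

from .geometry import pairwise_distances
from .meshing import Mesh


@dataclass(frozen=True)
class RefineConfig:
    """Refinement parameters.

    ``proximity_coefficient`` (p) is the number of nearest neighbour
    sources each food source is routed to.  ``source_snap_radius`` is
    the corridor half-width (px) used when routed pairs are decomposed
    into source-to-source links for assessment: an intermediate food
    source lying within this distance of the straight corridor between
    a routed pair is treated as a node the route passes through, and
    the pair splits there.  Foraging deposits a dense cluster of trail
    points extending 15-20 px around each colonized source (arriving
    and respawned agents), so a corridor threading that cluster runs
    through the source at the scale the simplified linework is drawn;
    15 px matches the cluster, and stays well below half the minimum
    source spacing.
    """

    proximity_coefficient: int = 3
    source_snap_radius: float = 15.0

    def __post_init__(self) -> None:
        if self.proximity_coefficient < 1:
            raise ValueError("proximity_coefficient must be >= 1")
        if self.source_snap_radius < 0:
            raise ValueError("source_snap_radius must be >= 0")


class RefinementError(RuntimeError):
    """A terminal source pair could not be connected through the mesh."""


@dataclass
class Segment:
    """Maximal chain whose interior nodes are non-source degree-2 nodes."""

    nodes: list[int]  # mesh node ids, endpoints first/last
    length: float  # pixels

    @property
    def endpoints(self) -> tuple[int, int]:
        return self.nodes[0], self.nodes[-1]

    @property
    def n_mesh_edges(self) -> int:
        return len(self.nodes) - 1

    def edge_keys(self) -> list[tuple[int, int]]:
        return [
            (min(a, b), max(a, b)) for a, b in zip(self.nodes[:-1], self.nodes[1:])
        ]


@dataclass
class Network:
    """Refined subgraph of the mesh connecting the food sources.

    Two coupled representations are kept.  ``edges``/``weights`` hold
    the union of all routed mesh edges (shared edges once) — the
    geometric subgraph that is serialized and whose maximal chains are
    the simplified segments.  ``links`` is the assessment-level
    simplified linework: one entry per distinct source-to-source
    stretch of routed path (paths are split where they pass through, or
    within the snap radius of, an intermediate food source), mapping
    the unordered source pair to its along-mesh length.
    """

    mesh: Mesh
    edges: np.ndarray  # (E, 2) int, u < v — subset of mesh edges
    weights: np.ndarray  # (E,) pixels
    terminal_pairs: set[tuple[int, int]]
    source_ids: np.ndarray
    links: dict[tuple[int, int], float] | None = None
    link_paths: dict[tuple[int, int], list[int]] | None = None
    _graph: nx.Graph | None = field(default=None, repr=False, compare=False)
    _segments: list[Segment] | None = field(default=None, repr=False, compare=False)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_set(self) -> set[tuple[int, int]]:
        return {(int(u), int(v)) for u, v in self.edges}

    @property
    def graph(self) -> nx.Graph:
        if self._graph is None:
            g = nx.Graph()
            g.add_nodes_from(int(s) for s in self.source_ids)
            for (u, v), w in zip(self.edges, self.weights):
                g.add_edge(int(u), int(v), weight=float(w))
            self._graph = g
        return self._graph

    @property
    def segments(self) -> list[Segment]:
        if self._segments is None:
            self._segments = simplify_network(self)
        return self._segments

    @property
    def total_cost(self) -> float:
        return float(self.weights.sum())

    @property
    def link_graph(self) -> nx.Graph:
        """Simplified source-level graph: one weighted edge per link."""
        if not self.links:
            raise ValueError("network carries no link decomposition")
        g = nx.Graph()
        g.add_nodes_from(int(s) for s in self.source_ids)
        for (a, b), ln in self.links.items():
            g.add_edge(int(a), int(b), weight=float(ln))
        return g


def select_terminal_pairs(source_points: np.ndarray, p: int) -> set[tuple[int, int]]:
    """Each source paired with its min(p, S-1) Euclidean-nearest sources.

    Pairs are unordered and deduplicated; exact distance ties prefer the
    lower index.
    """
    pts = np.asarray(source_points, dtype=float)
    s = len(pts)
    if s < 2:
        raise ValueError("need at least 2 sources")
    d = pairwise_distances(pts)
    np.fill_diagonal(d, np.inf)
    k = min(p, s - 1)
    pairs: set[tuple[int, int]] = set()
    for i in range(s):
        order = np.argsort(d[i], kind="stable")[:k]
        for j in order:
            pairs.add((min(i, int(j)), max(i, int(j))))
    return pairs


def shortest_walk(
    mesh: Mesh,
    source_ids: np.ndarray | list[int] | None = None,
    cfg: RefineConfig | None = None,
) -> Network:
    """Union of minimum-length mesh paths between all terminal pairs.

    Runs Dijkstra from every source over the mesh adjacency and keeps
    every edge used by some terminal-pair path; shared edges are stored
    once.  Every source is routed to a *minimum* of p nearest
    neighbours: if the union still leaves source groups apart, the
    closest source pairs across groups are routed too, so the refined
    network always connects all food sources.  Raises
    :class:`RefinementError` if a pair is disconnected in the mesh
    itself (a larger p_m densifies the mesh and usually fixes this).
    """
    cfg = cfg or RefineConfig()
    if source_ids is None:
        source_ids = mesh.source_ids
    source_ids = np.asarray(source_ids, dtype=int)
    if len(source_ids) < 2:
        raise ValueError("refinement needs at least 2 sources")
    s = len(source_ids)
    pairs_local = select_terminal_pairs(mesh.points[source_ids], cfg.proximity_coefficient)

    adj = mesh.adjacency()
    dist, pred = dijkstra(adj, directed=False, indices=source_ids, return_predecessors=True)

    edge_keys: set[tuple[int, int]] = set()
    terminal_pairs: set[tuple[int, int]] = set()
    routed_local: list[tuple[int, int]] = []

    def route(ia: int, ib: int) -> None:
        a, b = int(source_ids[ia]), int(source_ids[ib])
        terminal_pairs.add((min(a, b), max(a, b)))
        routed_local.append((ia, ib))
        if not np.isfinite(dist[ia, b]):
            raise RefinementError(
                f"sources {a} and {b} are disconnected in the mesh "
                f"(p_m = {mesh.p_m}); try a larger p_m"
            )
        node = b
        while node != a:
            prev = int(pred[ia, node])
            edge_keys.add((min(prev, node), max(prev, node)))
            node = prev

    for (ia, ib) in sorted(pairs_local):
        route(ia, ib)

    # connectivity guarantee: join remaining source groups through their
    # Euclidean-closest source pair until one component remains
    comp = list(range(s))

    def find(i):
        while comp[i] != i:
            comp[i] = comp[comp[i]]
            i = comp[i]
        return i

    def union(i, j):
        comp[find(i)] = find(j)

    for (ia, ib) in pairs_local:
        union(ia, ib)
    d_src = pairwise_distances(mesh.points[source_ids])
    while len({find(i) for i in range(s)}) > 1:
        best = None
        for ia in range(s):
            for ib in range(ia + 1, s):
                if find(ia) != find(ib):
                    key = (d_src[ia, ib], ia, ib)
                    if best is None or key < best:
                        best = key
        _, ia, ib = best
        route(ia, ib)
        union(ia, ib)

    lut = {(int(u), int(v)): float(w) for (u, v), w in zip(mesh.edges, mesh.weights)}
    edges = np.asarray(sorted(edge_keys), dtype=np.int64)
    weights = np.asarray([lut[k] for k in map(tuple, edges)], dtype=float)
    links, link_paths = _decompose_links(
        mesh, source_ids, routed_local, dist, pred, cfg.source_snap_radius
    )
    return Network(
        mesh=mesh,
        edges=edges,
        weights=weights,
        terminal_pairs=terminal_pairs,
        source_ids=source_ids,
        links=links,
        link_paths=link_paths,
    )


def _decompose_links(
    mesh: Mesh,
    source_ids: np.ndarray,
    routed_pairs: list[tuple[int, int]],
    dist: np.ndarray,
    pred: np.ndarray,
    snap_radius: float,
) -> tuple[dict[tuple[int, int], float], dict[tuple[int, int], list[int]]]:
    """Decompose routed pairs into distinct source-to-source links.

    A routed pair (A, C) passes *through* an intermediate food source B
    when B lies within ``snap_radius`` of the straight A-C corridor and
    strictly between its endpoints; the pair then splits into (A, B)
    and (B, C), recursively.  The decision is purely geometric — a
    function of the layout, not of the particular trails a run grew —
    so repeated runs on one layout produce identical link sets.  Each
    link's length is the along-mesh shortest-path distance between its
    end sources; links are deduplicated by source pair.
    """
    source_ids = np.asarray(source_ids, dtype=int)
    src_pts = mesh.points[source_ids]
    s = len(source_ids)
    links: dict[tuple[int, int], float] = {}
    link_paths: dict[tuple[int, int], list[int]] = {}

    def add_link(ia: int, ib: int) -> None:
        a, b = int(source_ids[ia]), int(source_ids[ib])
        key = (min(a, b), max(a, b))
        if key in links:
            return
        links[key] = float(dist[ia, b])
        path = [b]
        node = b
        while node != a:
            node = int(pred[ia, node])
            path.append(node)
        link_paths[key] = path[::-1]

    seen: set[tuple[int, int]] = set()

    def split(ia: int, ic: int) -> None:
        key = (min(ia, ic), max(ia, ic))
        if key in seen:
            add_link(ia, ic)
            return
        seen.add(key)
        a, c = src_pts[ia], src_pts[ic]
        ac = c - a
        length2 = float(ac @ ac)
        best: tuple[float, int] | None = None
        # corridors not appreciably longer than the snap scale cannot
        # meaningfully pass "through" a third source
        if length2 > (2.0 * snap_radius) ** 2:
            for ib in range(s):
                if ib in (ia, ic):
                    continue
                t = float((src_pts[ib] - a) @ ac) / length2
                if not (0.0 < t < 1.0):
                    continue
                off = float(np.linalg.norm(src_pts[ib] - (a + t * ac)))
                if off <= snap_radius and (best is None or (off, ib) < best):
                    best = (off, ib)
        if best is None:
            add_link(ia, ic)
            return
        ib = best[1]
        # fall back to the direct link if the mesh cannot realize a half
        if not (np.isfinite(dist[ia, int(source_ids[ib])])
                and np.isfinite(dist[ib, int(source_ids[ic])])):
            add_link(ia, ic)
            return
        split(ia, ib)
        split(ib, ic)

    for ia, ic in sorted(routed_pairs):
        split(ia, ic)
    return links, link_paths


def simplify_network(network: Network) -> list[Segment]:
    """Decompose the network edge set into maximal chains (segments).

    Interior nodes of a segment have degree 2 and are not sources;
    endpoints are sources or junctions.  The segments partition the
    edge set exactly, so summed segment lengths equal the network cost.
    """
    g = network.graph
    sources = set(int(s) for s in network.source_ids)
    is_breakpoint = {
        n: (n in sources or g.degree(n) != 2) for n in g.nodes
    }
    visited: set[tuple[int, int]] = set()
    segments: list[Segment] = []

    def walk(start: int, nxt: int) -> Segment:
        nodes = [start, nxt]
        length = g[start][nxt]["weight"]
        visited.add((min(start, nxt), max(start, nxt)))
        while not is_breakpoint[nodes[-1]]:
            cur = nodes[-1]
            nbrs = [m for m in g.neighbors(cur) if m != nodes[-2]]
            if not nbrs:
                break  # dangling degree-1 chain end
            m = nbrs[0]
            key = (min(cur, m), max(cur, m))
            if key in visited:
                break
            visited.add(key)
            length += g[cur][m]["weight"]
            nodes.append(m)
        return Segment(nodes=nodes, length=float(length))

    for n in sorted(g.nodes):
        if not is_breakpoint[n]:
            continue
        for m in sorted(g.neighbors(n)):
            key = (min(n, m), max(n, m))
            if key not in visited:
                segments.append(walk(n, m))
    # pure degree-2 cycles with no breakpoint (cannot arise from
    # source-anchored paths, but handle defensively)
    for u, v in g.edges:
        key = (min(u, v), max(u, v))
        if key not in visited:
            segments.append(walk(u, v))
    return segments
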