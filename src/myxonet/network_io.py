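"""Serialization of refined and externally digitized networks.

Networks travel as GeoJSON FeatureCollections of LineStrings (one per
simplified segment, with ``length_px`` and ``segment_id`` properties)
or as CSV edge lists ``u,v,length``.  Externally digitized reference
networks (node + edge lists of built systems) are consumed in the same
formats for performance comparison.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .geometry import Domain, Point2D, as_array
from .refinement import Network


@dataclass
class ReferenceNetwork:
    """A digitized built network: nodes with roles, edges with lengths.

    Edge lengths default to the Euclidean distance of their endpoints
    and may exceed it (curved streets); they can never be shorter.
    """

    nodes: list[Point2D]
    edges: list[tuple[int, int]]
    lengths: list[float] | None = None
    roles: list[str] | None = None  # source | junction

    def __post_init__(self) -> None:
        self.nodes = [Point2D(float(x), float(y)) for x, y in self.nodes]
        if self.roles is None:
            self.roles = ["source"] * len(self.nodes)
        if self.lengths is None:
            self.lengths = [
                self.nodes[u].distance_to(self.nodes[v]) for u, v in self.edges
            ]
        for i, ((u, v), ln) in enumerate(zip(self.edges, self.lengths)):
            if u == v:
                raise ValueError(f"edge {i} is a self-loop")
            euclid = self.nodes[u].distance_to(self.nodes[v])
            if ln < euclid - 1e-6:
                raise ValueError(
                    f"edge {i} length {ln} shorter than endpoint distance {euclid}"
                )

    @property
    def source_ids(self) -> list[int]:
        return [i for i, r in enumerate(self.roles) if r == "source"]

    @property
    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self.nodes)))
        for (u, v), ln in zip(self.edges, self.lengths):
            g.add_edge(u, v, weight=float(ln))
        return g

    def rescale_to_domain(self, domain: Domain, margin: float = 40.0) -> "ReferenceNetwork":
        """Uniformly fit node coordinates into a pixel domain.

        Preserves aspect ratio and scales edge lengths by the same
        factor, so metric ratios are unchanged.
        """
        arr = as_array(self.nodes)
        lo, hi = arr.min(axis=0), arr.max(axis=0)
        span = np.maximum(hi - lo, 1e-12)
        scale = min((domain.width - 2 * margin) / span[0],
                    (domain.height - 2 * margin) / span[1])
        out = (arr - lo) * scale + margin
        return ReferenceNetwork(
            nodes=[Point2D(x, y) for x, y in out],
            edges=list(self.edges),
            lengths=[ln * scale for ln in self.lengths],
            roles=list(self.roles),
        )


def _network_segments(network: Network | ReferenceNetwork):
    """(segment_id, coordinate list, length) triples for serialization."""
    if isinstance(network, Network):
        for i, seg in enumerate(network.segments):
            coords = [tuple(map(float, network.mesh.points[n])) for n in seg.nodes]
            yield i, coords, seg.length
    else:
        for i, ((u, v), ln) in enumerate(zip(network.edges, network.lengths)):
            yield i, [tuple(network.nodes[u]), tuple(network.nodes[v])], float(ln)


def write_network(
    network: Network | ReferenceNetwork, path: str | Path, format: str | None = None
) -> Path:
    """Write a network as GeoJSON LineStrings or a CSV edge list.

    GeoJSON features carry ``segment_id`` and ``length_px``; the CSV
    edge list has columns ``u,v,length`` with node ids from the
    underlying graph.
    """
    path = Path(path)
    if format is None:
        format = "geojson" if path.suffix.lower() in (".geojson", ".json") else "csv"
    if format == "geojson":
        feats = []
        for sid, coords, length in _network_segments(network):
            feats.append({
                "type": "Feature",
                "geometry": {"type": "LineString", "coordinates": [list(c) for c in coords]},
                "properties": {"segment_id": sid, "length_px": length},
            })
        if not feats:
            warnings.warn(f"writing empty network to {path}", stacklevel=2)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)
    elif format == "csv":
        if isinstance(network, Network):
            rows = [(int(u), int(v), float(w))
                    for (u, v), w in zip(network.edges, network.weights)]
        else:
            rows = [(u, v, float(ln)) for (u, v), ln in zip(network.edges, network.lengths)]
        if not rows:
            warnings.warn(f"writing empty network to {path}", stacklevel=2)
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["u", "v", "length"])
            for u, v, ln in rows:
                writer.writerow([u, v, repr(ln)])
    else:
        raise ValueError(f"unsupported network format {format!r}")
    return path


def write_segments_csv(network: Network, path: str | Path) -> Path:
    """Simplified-segment table: id, endpoints, length, mesh-edge count."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["segment_id", "endpoint_u", "endpoint_v", "length", "n_mesh_edges"])
        for i, seg in enumerate(network.segments):
            u, v = seg.endpoints
            writer.writerow([i, u, v, repr(seg.length), seg.n_mesh_edges])
    return path


def read_reference_network(path: str | Path, format: str | None = None) -> ReferenceNetwork:
    """Read a digitized network from GeoJSON LineStrings or CSV edge list.

    GeoJSON: endpoints of each LineString become nodes (coordinates
    deduplicated to 1e-6 px); interior vertices contribute to the edge
    length only.  CSV needs a companion understanding that node ids are
    coordinates-free, so CSV input expects columns ``ux,uy,vx,vy[,length]``.
    """
    path = Path(path)
    if format is None:
        format = "geojson" if path.suffix.lower() in (".geojson", ".json") else "csv"
    nodes: list[Point2D] = []
    index: dict[tuple[float, float], int] = {}

    def node_id(x: float, y: float) -> int:
        key = (round(x, 6), round(y, 6))
        if key not in index:
            index[key] = len(nodes)
            nodes.append(Point2D(x, y))
        return index[key]

    edges: list[tuple[int, int]] = []
    lengths: list[float] = []
    if format == "geojson":
        with open(path, encoding="utf-8") as fh:
            gj = json.load(fh)
        for feat in gj.get("features", []):
            geom = feat.get("geometry") or {}
            if geom.get("type") != "LineString":
                continue
            coords = geom["coordinates"]
            u = node_id(*coords[0])
            v = node_id(*coords[-1])
            props = feat.get("properties") or {}
            ln = props.get("length_px")
            if ln is None:
                ln = float(sum(
                    np.hypot(x2 - x1, y2 - y1)
                    for (x1, y1), (x2, y2) in zip(coords[:-1], coords[1:])
                ))
            edges.append((u, v))
            lengths.append(float(ln))
    elif format == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            required = {"ux", "uy", "vx", "vy"}
            if reader.fieldnames is None or not required <= set(reader.fieldnames):
                raise ValueError(f"{path}: reference CSV requires columns ux,uy,vx,vy")
            for row in reader:
                u = node_id(float(row["ux"]), float(row["uy"]))
                v = node_id(float(row["vx"]), float(row["vy"]))
                edges.append((u, v))
                ln = row.get("length")
                lengths.append(
                    float(ln) if ln else nodes[u].distance_to(nodes[v])
                )
    else:
        raise ValueError(f"unsupported network format {format!r}")
    return ReferenceNetwork(nodes=nodes, edges=edges, lengths=lengths)
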