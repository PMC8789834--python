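"""Attractor (food-source) layouts: container, readers/writers, generator.

A layout is an ordered set of attractor points inside the foraging
domain, each carrying an activity flag and an arrival counter used by
the depletion rule during foraging.  Layouts round-trip through CSV
(columns ``id,x,y[,role]``) and GeoJSON point collections.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import Domain, Point2D, as_array


class LayoutFormatError(ValueError):
    """Raised when a layout file is malformed."""


class LayoutValidationError(ValueError):
    """Raised when layout contents violate domain constraints."""


@dataclass
class AttractorLayout:
    """Ordered food-source points with activity state.

    ``spawn`` is where the initial agent population is released: either
    the index of an attractor, or a free point (defaults to the domain
    center).  ``arrivals`` counts absorbed agents per attractor and
    drives the depletion rule.
    """

    points: list[Point2D]
    domain: Domain = field(default_factory=Domain)
    spawn_index: int | None = None
    spawn_point: Point2D | None = None
    active: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    arrivals: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.points) < 1:
            raise LayoutValidationError("layout needs at least one point")
        self.points = [Point2D(float(x), float(y)) for x, y in self.points]
        for i, p in enumerate(self.points):
            if not (np.isfinite(p.x) and np.isfinite(p.y)):
                raise LayoutValidationError(f"point {i} has non-finite coordinates")
            if not self.domain.contains(p):
                raise LayoutValidationError(
                    f"point {i} at ({p.x}, {p.y}) lies outside the "
                    f"{self.domain.width} x {self.domain.height} domain"
                )
        if self.spawn_index is not None and not (0 <= self.spawn_index < len(self.points)):
            raise LayoutValidationError(f"spawn_index {self.spawn_index} out of range")
        if self.active is None:
            self.active = np.ones(len(self.points), dtype=bool)
        else:
            self.active = np.asarray(self.active, dtype=bool).copy()
        if self.arrivals is None:
            self.arrivals = np.zeros(len(self.points), dtype=int)
        else:
            self.arrivals = np.asarray(self.arrivals, dtype=int).copy()
            if (self.arrivals < 0).any():
                raise LayoutValidationError("arrival counts must be non-negative")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def coords(self) -> np.ndarray:
        return as_array(self.points)

    @property
    def spawn(self) -> Point2D:
        """Release point for the initial population (domain center by default)."""
        if self.spawn_index is not None:
            return self.points[self.spawn_index]
        if self.spawn_point is not None:
            return self.spawn_point
        return self.domain.center

    def with_spawn(self, spawn_index: int) -> "AttractorLayout":
        """Copy of this layout started from a given attractor."""
        return AttractorLayout(
            points=list(self.points), domain=self.domain, spawn_index=spawn_index
        )

    def reset(self) -> "AttractorLayout":
        """Fresh copy with all attractors active and zero arrivals."""
        return AttractorLayout(
            points=list(self.points),
            domain=self.domain,
            spawn_index=self.spawn_index,
            spawn_point=self.spawn_point,
        )


def read_layout(
    path: str | Path, format: str | None = None, domain: Domain | None = None
) -> AttractorLayout:
    """Read an attractor layout from CSV or GeoJSON.

    CSV requires a header with columns ``id,x,y`` and an optional
    ``role`` column; a row with role ``spawn`` marks the start
    attractor.  GeoJSON expects a FeatureCollection of Points.
    Input ordering is preserved.
    """
    path = Path(path)
    if format is None:
        format = "geojson" if path.suffix.lower() in (".geojson", ".json") else "csv"
    domain = domain or Domain()

    rows: list[tuple[float, float, str]] = []
    if format == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {"id", "x", "y"} <= set(reader.fieldnames):
                raise LayoutFormatError(
                    f"{path}: layout CSV requires columns id,x,y "
                    f"(found {reader.fieldnames})"
                )
            for row in reader:
                rows.append((float(row["x"]), float(row["y"]), (row.get("role") or "attractor")))
    elif format == "geojson":
        with open(path, encoding="utf-8") as fh:
            gj = json.load(fh)
        try:
            for feat in gj["features"]:
                x, y = feat["geometry"]["coordinates"]
                role = (feat.get("properties") or {}).get("role", "attractor")
                rows.append((float(x), float(y), role))
        except (KeyError, TypeError, ValueError) as exc:
            raise LayoutFormatError(f"{path}: malformed GeoJSON layout: {exc}") from exc
    else:
        raise LayoutFormatError(f"unsupported layout format {format!r}")

    if not rows:
        raise LayoutFormatError(f"{path}: layout file contains no points")
    spawn_index = None
    for i, (_, _, role) in enumerate(rows):
        if role.strip().lower() == "spawn":
            spawn_index = i
    return AttractorLayout(
        points=[Point2D(x, y) for x, y, _ in rows],
        domain=domain,
        spawn_index=spawn_index,
    )


def write_layout(layout: AttractorLayout, path: str | Path, format: str | None = None) -> Path:
    """Write a layout as CSV (``id,x,y,role``) or a GeoJSON point collection."""
    path = Path(path)
    if format is None:
        format = "geojson" if path.suffix.lower() in (".geojson", ".json") else "csv"
    roles = [
        "spawn" if layout.spawn_index == i else "attractor" for i in range(len(layout))
    ]
    if format == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "x", "y", "role"])
            for i, (p, role) in enumerate(zip(layout.points, roles)):
                writer.writerow([i, repr(p.x), repr(p.y), role])
    elif format == "geojson":
        features = [
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [p.x, p.y]},
                "properties": {"id": i, "role": role},
            }
            for i, (p, role) in enumerate(zip(layout.points, roles))
        ]
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)
    else:
        raise LayoutFormatError(f"unsupported layout format {format!r}")
    return path


def generate_layout(
    n_points: int,
    domain: Domain | None = None,
    min_spacing: float = 80.0,
    seed: int = 0,
    max_attempts: int = 10_000,
) -> AttractorLayout:
    """Scatter food sources over the domain with a minimum spacing.

    Emulates the oat layouts used in the growth experiments: a handful
    of points (typically 2-9) spread across the 800 x 800 px domain so
    that no two are closer than ``min_spacing`` and none is closer than
    ``min_spacing / 2`` to the boundary.  Rejection sampling;
    deterministic for a fixed seed.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if min_spacing < 0:
        raise ValueError("min_spacing must be >= 0")
    domain = domain or Domain()
    margin = min_spacing / 2.0
    if 2 * margin >= domain.width or 2 * margin >= domain.height:
        raise LayoutValidationError("min_spacing too large for the domain")
    rng = np.random.default_rng(seed)
    pts: list[Point2D] = []
    attempts = 0
    while len(pts) < n_points:
        if attempts >= max_attempts:
            raise LayoutValidationError(
                f"could not place {n_points} points with spacing {min_spacing} "
                f"in a {domain.width} x {domain.height} domain "
                f"({max_attempts} attempts)"
            )
        attempts += 1
        x = rng.uniform(margin, domain.width - margin)
        y = rng.uniform(margin, domain.height - margin)
        cand = Point2D(x, y)
        if all(cand.distance_to(p) >= min_spacing for p in pts):
            pts.append(cand)
    return AttractorLayout(points=pts, domain=domain)
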