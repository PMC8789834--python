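"""Planar geometry primitives for the foraging domain.

All coordinates are continuous Cartesian pixels with the origin at the
lower-left corner and y increasing upward.  There is no geographic CRS;
the model lives in an abstract pixel space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
from scipy.spatial.distance import pdist, squareform


class Point2D(NamedTuple):
    """A point in the pixel domain."""

    x: float
    y: float

    def distance_to(self, other: "Point2D") -> float:
        return math.hypot(self.x - other.x, self.y - other.y)


@dataclass(frozen=True)
class Domain:
    """Rectangular foraging domain, default 800 x 800 pixels."""

    width: float = 800.0
    height: float = 800.0

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ValueError("Domain dimensions must be positive")

    @property
    def center(self) -> Point2D:
        return Point2D(self.width / 2.0, self.height / 2.0)

    @property
    def diagonal(self) -> float:
        return math.hypot(self.width, self.height)

    def contains(self, p: Point2D | tuple[float, float]) -> bool:
        x, y = p
        return 0.0 <= x <= self.width and 0.0 <= y <= self.height


def as_array(points: Iterable[Point2D]) -> np.ndarray:
    """Stack points into an (N, 2) float array."""
    arr = np.asarray([(p[0], p[1]) for p in points], dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected a sequence of 2-D points")
    return arr


def pairwise_distances(points: Iterable[Point2D] | np.ndarray) -> np.ndarray:
    """Symmetric Euclidean distance matrix for a point set.

    The zero-diagonal symmetric matrix over all point pairs; this is the
    distance matrix from which both the proximity mesh and the
    terminal-pair selection are derived.
    """
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2:
        arr = as_array(points)
    if len(arr) == 0:
        raise ValueError("at least one point required")
    if len(arr) == 1:
        return np.zeros((1, 1))
    return squareform(pdist(arr))
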