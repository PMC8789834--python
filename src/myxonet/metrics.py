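"""Transport-network efficiency metrics and performance comparison.

Three descriptors characterise a refined network:

* **cost** — total length of all unique network edges (px);
* **travel time** — mean shortest-path length between all unordered
  food-source pairs within the network (px);
* **vulnerability** — mean increase in travel time over single-segment
  removals, where a pair disconnected by a removal is assigned the
  intact network's total length as its distance (px).

For comparison across networks, each metric is normalised to the
largest value in the compared collection; normalised metrics combine
into performance ratios (P_tt/c, P_v/c, P_v/tt) and products (P_ctt,
P_cv, P_ttv).  Curves of these quantities over the proximity
coefficient p are fitted with simple trendline families and compared to
reference (grown or built) networks by closest point along the curve.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
from scipy.optimize import curve_fit

from .refinement import Network, RefineConfig, shortest_walk


@dataclass
class MetricsReport:
    """Raw and (optionally) normalised efficiency metrics of one network."""

    cost: float
    travel_time: float
    vulnerability: float
    label: str | int | None = None
    normalized_cost: float | None = None
    normalized_travel_time: float | None = None
    normalized_vulnerability: float | None = None
    ratios: dict[str, float] = field(default_factory=dict)
    products: dict[str, float] = field(default_factory=dict)

    def metric(self, name: str, normalized: bool = False) -> float:
        key = ("normalized_" + name) if normalized else name
        val = getattr(self, key)
        if val is None:
            raise ValueError(f"{key} not computed; call normalize_and_score first")
        return float(val)


def _pair_distances(
    g: nx.Graph, sources: list[int], penalty: float | None = None
) -> dict[tuple[int, int], float]:
    """Shortest-path length for every unordered source pair.

    Disconnected pairs get ``penalty`` if given, else raise.
    """
    out: dict[tuple[int, int], float] = {}
    lengths: dict[int, dict[int, float]] = {}
    for s in sources:
        if g.has_node(s):
            lengths[s] = nx.single_source_dijkstra_path_length(g, s, weight="weight")
    for a, b in itertools.combinations(sources, 2):
        d = lengths.get(a, {}).get(b)
        if d is None:
            if penalty is None:
                raise RuntimeError(f"sources {a} and {b} are disconnected in the network")
            d = penalty
        out[(a, b)] = float(d)
    return out


def _assessment_graph(network: Network, granularity: str) -> nx.Graph:
    """The graph a metric is computed on, at the requested granularity.

    ``link`` (default): the simplified linework — one weighted edge per
    distinct source-to-source stretch of routed path.  ``segment`` /
    ``edge``: the mesh-level union subgraph (for sensitivity analysis).
    """
    if granularity == "link":
        return network.link_graph
    if granularity in ("segment", "edge"):
        return network.graph
    raise ValueError("granularity must be 'link', 'segment' or 'edge'")


def network_cost(network: Network, granularity: str = "link") -> float:
    """Total length of all edges within the network (pixels).

    At the default ``link`` granularity this sums the simplified
    source-to-source links; at ``edge`` granularity it sums the unique
    underlying mesh edges (shared path edges counted once).
    """
    if network.n_edges == 0:
        warnings.warn("empty network has zero cost", stacklevel=2)
        return 0.0
    if granularity == "link":
        return float(sum(network.links.values()))
    if granularity in ("segment", "edge"):
        return network.total_cost
    raise ValueError("granularity must be 'link', 'segment' or 'edge'")


def travel_time(
    network: Network,
    sources: list[int] | None = None,
    disconnection_penalty: float | None = None,
    granularity: str = "link",
) -> float:
    """Mean shortest-path length between all unordered source pairs (px).

    A shortest-walk network at p >= 2 connects all sources and every
    pair has a finite path.  At p = 1 the union of nearest-neighbour
    routes can leave clusters mutually unreachable; by default that is
    an error, but ``disconnection_penalty`` (typically the network's
    total length, the same convention the vulnerability fault rule
    uses) assigns that distance to unreachable pairs instead.
    """
    srcs = [int(s) for s in (network.source_ids if sources is None else sources)]
    if len(srcs) < 2:
        raise ValueError("travel time needs at least 2 sources")
    g = _assessment_graph(network, granularity)
    d = _pair_distances(g, srcs, penalty=disconnection_penalty)
    return float(np.mean(list(d.values())))


def vulnerability(
    network: Network,
    sources: list[int] | None = None,
    granularity: str = "link",
) -> float:
    """Mean travel-time increase over single-fault removals (px).

    Each network element — a source-to-source link at the default
    granularity, or a simplified segment / raw mesh edge for
    sensitivity analysis — is removed in turn; pairs disconnected by
    the removal are assigned the intact network's total length as their
    distance.  The per-removal increase is floored at zero and
    averaged.
    """
    srcs = [int(s) for s in (network.source_ids if sources is None else sources)]
    if len(srcs) < 2:
        raise ValueError("vulnerability needs at least 2 sources")
    g = _assessment_graph(network, granularity)
    penalty = network_cost(network, granularity)
    baseline = travel_time(network, srcs, disconnection_penalty=penalty,
                           granularity=granularity)

    if granularity == "link":
        removals: list[list[tuple[int, int]]] = [[k] for k in network.links]
    elif granularity == "segment":
        removals = [s.edge_keys() for s in network.segments]
    else:
        removals = [[(int(u), int(v))] for u, v in network.edges]
    if not removals:
        raise ValueError("network has no removable elements")

    deltas = []
    for keys in removals:
        h = g.copy()
        h.remove_edges_from(keys)
        d = _pair_distances(h, srcs, penalty=penalty)
        tt = float(np.mean(list(d.values())))
        deltas.append(max(tt - baseline, 0.0))
    return float(np.mean(deltas))


def compute_metrics(
    network: Network,
    sources: list[int] | None = None,
    label=None,
    granularity: str = "link",
) -> MetricsReport:
    """Cost, travel time and vulnerability of one refined network.

    Source pairs left unreachable by a sparse refinement (possible at
    p = 1) are scored with the total-network-length penalty, keeping
    the metrics defined across the whole p range.
    """
    cost = network_cost(network, granularity)
    return MetricsReport(
        cost=cost,
        travel_time=travel_time(network, sources, disconnection_penalty=cost,
                                granularity=granularity),
        vulnerability=vulnerability(network, sources, granularity=granularity),
        label=label,
    )


_RATIO_DEFS = {"tt/c": ("travel_time", "cost"),
               "v/c": ("vulnerability", "cost"),
               "v/tt": ("vulnerability", "travel_time")}
_PRODUCT_DEFS = {"ctt": ("cost", "travel_time"),
                 "cv": ("cost", "vulnerability"),
                 "ttv": ("travel_time", "vulnerability")}


def normalize_and_score(
    reports: list[MetricsReport], mode: str = "ratio"
) -> list[MetricsReport]:
    """Normalise each metric to the collection maximum and derive P-values.

    ``mode='ratio'`` fills P_tt/c, P_v/c, P_v/tt; ``'product'`` fills
    P_ctt, P_cv, P_ttv; ``'average_product'`` additionally attaches the
    collection-mean of each product to every report (under key
    ``'avg_<name>'``).  Returns new reports; inputs are unmodified.
    """
    if not reports:
        raise ValueError("need at least one report")
    maxima = {
        m: max(getattr(r, m) for r in reports)
        for m in ("cost", "travel_time", "vulnerability")
    }
    for m, v in maxima.items():
        if v <= 0:
            raise ValueError(f"cannot normalize: maximum {m} is {v}")
    out = []
    for r in reports:
        nr = replace(
            r,
            normalized_cost=r.cost / maxima["cost"],
            normalized_travel_time=r.travel_time / maxima["travel_time"],
            normalized_vulnerability=r.vulnerability / maxima["vulnerability"],
            ratios=dict(r.ratios),
            products=dict(r.products),
        )
        norm = {"cost": nr.normalized_cost,
                "travel_time": nr.normalized_travel_time,
                "vulnerability": nr.normalized_vulnerability}
        if mode == "ratio":
            for name, (a, b) in _RATIO_DEFS.items():
                nr.ratios[name] = norm[a] / norm[b] if norm[b] > 0 else math.inf
        elif mode in ("product", "average_product"):
            for name, (a, b) in _PRODUCT_DEFS.items():
                nr.products[name] = norm[a] * norm[b]
        else:
            raise ValueError("mode must be ratio, product or average_product")
        out.append(nr)
    if mode == "average_product":
        for name in _PRODUCT_DEFS:
            avg = float(np.mean([r.products[name] for r in out]))
            for r in out:
                r.products["avg_" + name] = avg
    return out


# ---------------------------------------------------------------- trendlines

_FAMILIES = ("linear", "poly2", "poly3", "poly4", "power", "exponential")


@dataclass
class Trendline:
    """Least-squares fit of y(x) in one of the supported families."""

    family: str
    coefficients: np.ndarray
    x_range: tuple[float, float]

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        c = self.coefficients
        if self.family in ("linear", "poly2", "poly3", "poly4"):
            return np.polyval(c, x)
        if self.family == "power":
            return c[0] * np.power(x, c[1])
        if self.family == "exponential":
            return c[0] * np.exp(c[1] * x)
        raise ValueError(f"unknown family {self.family}")


def fit_trendline(x, y, family: str = "linear") -> Trendline:
    """Fit one of the named trendline families by least squares."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 points to fit")
    if family not in _FAMILIES:
        raise ValueError(f"family must be one of {_FAMILIES}")
    if family in ("linear", "poly2", "poly3", "poly4"):
        degree = {"linear": 1, "poly2": 2, "poly3": 3, "poly4": 4}[family]
        degree = min(degree, len(x) - 1)
        coef = np.polyfit(x, y, degree)
    elif family == "power":
        if (x <= 0).any() or (y <= 0).any():
            raise ValueError("power fit needs positive x and y")
        b, loga = np.polyfit(np.log(x), np.log(y), 1)
        coef, _ = curve_fit(lambda t, a, bb: a * np.power(t, bb), x, y,
                            p0=[math.exp(loga), b], maxfev=10_000)
    else:  # exponential
        if (y <= 0).any():
            raise ValueError("exponential fit needs positive y")
        b, loga = np.polyfit(x, np.log(y), 1)
        coef, _ = curve_fit(lambda t, a, bb: a * np.exp(bb * t), x, y,
                            p0=[math.exp(loga), b], maxfev=10_000)
    return Trendline(family=family, coefficients=np.asarray(coef, dtype=float),
                     x_range=(float(x.min()), float(x.max())))


_PAIR_AXES = {
    "tt_vs_c": ("cost", "travel_time"),
    "v_vs_c": ("cost", "vulnerability"),
    "v_vs_tt": ("travel_time", "vulnerability"),
}


@dataclass
class PerformanceCurve:
    """Metrics of networks refined at several proximity coefficients."""

    points: list[tuple[int, MetricsReport]]
    fits: dict[str, Trendline] = field(default_factory=dict)

    def reports(self) -> list[MetricsReport]:
        return [r for _, r in self.points]

    def axes(self, pair: str, normalized: bool = True) -> tuple[np.ndarray, np.ndarray]:
        xm, ym = _PAIR_AXES[pair]
        xs = np.array([r.metric(xm, normalized) for _, r in self.points])
        ys = np.array([r.metric(ym, normalized) for _, r in self.points])
        return xs, ys

    def fit(self, pair: str, family: str) -> Trendline:
        xs, ys = self.axes(pair)
        tl = fit_trendline(xs, ys, family)
        self.fits[pair] = tl
        return tl


def performance_curve(
    mesh,
    source_ids=None,
    p_range=range(1, 6),
    extra_reports: list[MetricsReport] | None = None,
    fit_families: dict[str, str] | None = None,
) -> PerformanceCurve:
    """Refine a mesh at each p, normalise the resulting metrics jointly.

    ``extra_reports`` (e.g. a digitized reference network's raw metrics)
    are pooled into the normalisation, matching comparison against the
    largest local value.  ``fit_families`` maps metric-pair names
    (``tt_vs_c``, ``v_vs_c``, ``v_vs_tt``) to trendline families.
    """
    p_values = list(p_range)
    if not p_values:
        raise ValueError("p_range must be non-empty")
    raw = []
    for p in p_values:
        net = shortest_walk(mesh, source_ids, RefineConfig(proximity_coefficient=p))
        raw.append(compute_metrics(net, label=p))
    pooled = raw + list(extra_reports or [])
    scored = normalize_and_score(pooled, mode="ratio")
    curve = PerformanceCurve(points=list(zip(p_values, scored[: len(p_values)])))
    if len(p_values) < 2:
        warnings.warn("single-point curve: trendline fitting skipped", stacklevel=2)
        return curve
    for pair, family in (fit_families or {}).items():
        curve.fit(pair, family)
    return curve


@dataclass
class CurveComparison:
    """Closest point on a fitted trendline to a reference network."""

    pair: str
    closest_point: tuple[float, float]
    distance: float
    dx: float
    dy: float
    percent_dx: float
    percent_dy: float
    extrapolated: bool = False


def compare_to_reference(
    curve: PerformanceCurve,
    reference: MetricsReport,
    metric_pair: str,
    n_samples: int = 1000,
) -> CurveComparison:
    """Closest point along the fitted trendline to the reference network.

    The trendline is sampled densely across the observed x-domain and
    the sample minimising Euclidean distance to the reference in the
    normalised metric plane is returned, with per-axis differences.
    """
    if metric_pair not in curve.fits:
        raise ValueError(f"no fitted trendline for {metric_pair!r}; call curve.fit first")
    tl = curve.fits[metric_pair]
    xm, ym = _PAIR_AXES[metric_pair]
    rx, ry = reference.metric(xm, normalized=True), reference.metric(ym, normalized=True)
    xs = np.linspace(tl.x_range[0], tl.x_range[1], n_samples)
    ys = tl(xs)
    d2 = (xs - rx) ** 2 + (ys - ry) ** 2
    i = int(np.argmin(d2))
    extrapolated = not (tl.x_range[0] <= rx <= tl.x_range[1])
    if extrapolated:
        warnings.warn(
            f"reference x={rx:.4g} outside fitted domain {tl.x_range}; "
            "nearest endpoint returned", stacklevel=2,
        )
    cx, cy = float(xs[i]), float(ys[i])
    return CurveComparison(
        pair=metric_pair,
        closest_point=(cx, cy),
        distance=float(math.sqrt(d2[i])),
        dx=cx - rx,
        dy=cy - ry,
        percent_dx=100.0 * (cx - rx) / rx if rx else math.inf,
        percent_dy=100.0 * (cy - ry) / ry if ry else math.inf,
        extrapolated=extrapolated,
    )
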