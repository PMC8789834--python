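import itertools
import math

import networkx as nx
import numpy as np
import pytest

from myxonet.metrics import (
    MetricsReport,
    compare_to_reference,
    compute_metrics,
    fit_trendline,
    network_cost,
    normalize_and_score,
    performance_curve,
    travel_time,
    vulnerability,
)
from myxonet.refinement import RefineConfig, shortest_walk


def brute_force_metrics(link_graph, sources):
    """Independent recomputation: all-pairs Dijkstra and remove-one-edge
    re-evaluation with the stated total-length disconnection penalty."""
    cost = sum(d["weight"] for _, _, d in link_graph.edges(data=True))

    def tt(g):
        vals = []
        for a, b in itertools.combinations(sources, 2):
            try:
                vals.append(nx.dijkstra_path_length(g, a, b, weight="weight"))
            except nx.NetworkXNoPath:
                vals.append(cost)
        return float(np.mean(vals))

    base = tt(link_graph)
    deltas = []
    for u, v in list(link_graph.edges):
        h = link_graph.copy()
        h.remove_edge(u, v)
        deltas.append(max(tt(h) - base, 0.0))
    return cost, base, float(np.mean(deltas))


class TestToyOracles:
    def test_unit_triangle(self, unit_triangle):
        assert network_cost(unit_triangle) == pytest.approx(3.0)
        assert travel_time(unit_triangle) == pytest.approx(1.0)
        # remove any side: one pair detours over the other two sides
        assert vulnerability(unit_triangle) == pytest.approx(1 / 3)

    def test_chain(self, chain_abc):
        assert network_cost(chain_abc) == pytest.approx(200.0)
        assert travel_time(chain_abc) == pytest.approx(400 / 3)
        # each removal disconnects pairs at penalty 200: delta = 100/3
        assert vulnerability(chain_abc) == pytest.approx(100 / 3)

    def test_single_edge_has_zero_vulnerability(self, single_edge):
        assert network_cost(single_edge) == pytest.approx(50.0)
        assert travel_time(single_edge) == pytest.approx(50.0)
        # the penalty equals the whole network's length: no increase
        assert vulnerability(single_edge) == pytest.approx(0.0)

    def test_two_sources_one_edge_travel_time_is_length(self, single_edge):
        assert travel_time(single_edge) == network_cost(single_edge)

    @pytest.mark.parametrize("fixture", ["unit_triangle", "chain_abc", "single_edge"])
    def test_matches_brute_force(self, fixture, request):
        net = request.getfixturevalue(fixture)
        srcs = [int(s) for s in net.source_ids]
        cost, tt, vuln = brute_force_metrics(net.link_graph, srcs)
        assert network_cost(net) == pytest.approx(cost)
        assert travel_time(net) == pytest.approx(tt)
        assert vulnerability(net) == pytest.approx(vuln)


class TestForagingNetworkMetrics:
    def test_brute_force_equivalence_on_grown_network(self, forage_mesh):
        net = shortest_walk(forage_mesh)
        srcs = [int(s) for s in net.source_ids]
        cost, tt, vuln = brute_force_metrics(net.link_graph, srcs)
        assert network_cost(net) == pytest.approx(cost, abs=1e-9)
        assert travel_time(net) == pytest.approx(tt, abs=1e-9)
        assert vulnerability(net) == pytest.approx(vuln, abs=1e-9)

    def test_travel_time_at_least_mean_euclidean(self, forage_mesh):
        net = shortest_walk(forage_mesh)
        srcs = net.source_ids
        pts = forage_mesh.points[srcs]
        eu = [np.linalg.norm(pts[i] - pts[j])
              for i, j in itertools.combinations(range(len(srcs)), 2)]
        assert travel_time(net) >= np.mean(eu)

    def test_edge_union_cost_counts_shared_edges_once(self, forage_mesh):
        net = shortest_walk(forage_mesh)
        assert network_cost(net, granularity="edge") == pytest.approx(
            float(net.weights.sum()))
        # union and link costs describe the same structure at two
        # granularities and agree to within the path-sharing overlap
        assert network_cost(net, granularity="edge") == pytest.approx(
            network_cost(net, granularity="link"), rel=0.15)

    def test_vulnerability_nonnegative(self, forage_mesh):
        for p in (1, 3):
            net = shortest_walk(forage_mesh, cfg=RefineConfig(proximity_coefficient=p))
            assert vulnerability(net) >= 0.0


class TestNormalization:
    def test_single_report_normalizes_to_one(self):
        r = MetricsReport(cost=10.0, travel_time=5.0, vulnerability=2.0)
        out = normalize_and_score([r])[0]
        assert out.normalized_cost == 1.0
        assert out.ratios == {"tt/c": 1.0, "v/c": 1.0, "v/tt": 1.0}

    def test_costs_two_and_four(self):
        rs = [MetricsReport(2.0, 1.0, 1.0), MetricsReport(4.0, 1.0, 1.0)]
        out = normalize_and_score(rs)
        assert [r.normalized_cost for r in out] == [0.5, 1.0]

    def test_ratio_and_product_definitions(self):
        rs = [MetricsReport(4.0, 1.0, 3.0), MetricsReport(4.0, 2.0, 3.0)]
        ratio = normalize_and_score(rs, mode="ratio")
        assert ratio[0].ratios["tt/c"] == pytest.approx(0.5)
        prod = normalize_and_score(rs, mode="product")
        assert prod[0].products["ctt"] == pytest.approx(0.5)

    def test_average_product_attached_to_all(self):
        rs = [MetricsReport(2.0, 1.0, 1.0), MetricsReport(4.0, 2.0, 2.0)]
        out = normalize_and_score(rs, mode="average_product")
        avg = np.mean([r.products["ctt"] for r in out])
        assert all(r.products["avg_ctt"] == pytest.approx(avg) for r in out)

    def test_max_of_each_normalized_metric_is_one(self):
        rng = np.random.default_rng(1)
        rs = [MetricsReport(*rng.uniform(1, 10, 3)) for _ in range(6)]
        out = normalize_and_score(rs)
        for m in ("normalized_cost", "normalized_travel_time", "normalized_vulnerability"):
            assert max(getattr(r, m) for r in out) == pytest.approx(1.0)

    def test_inputs_not_mutated(self):
        r = MetricsReport(2.0, 1.0, 1.0)
        normalize_and_score([r])
        assert r.normalized_cost is None

    def test_zero_maximum_rejected(self):
        with pytest.raises(ValueError):
            normalize_and_score([MetricsReport(0.0, 1.0, 1.0)])


class TestTrendlines:
    def test_linear_exact_recovery(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        tl = fit_trendline(x, 2 * x + 1, "linear")
        np.testing.assert_allclose(tl.coefficients, [2.0, 1.0], atol=1e-12)

    def test_power_recovery(self):
        x = np.linspace(1, 5, 20)
        tl = fit_trendline(x, 3.0 * x**-1.5, "power")
        np.testing.assert_allclose(tl.coefficients, [3.0, -1.5], rtol=1e-6)

    def test_exponential_recovery(self):
        x = np.linspace(0, 2, 20)
        tl = fit_trendline(x, 0.5 * np.exp(1.2 * x), "exponential")
        np.testing.assert_allclose(tl.coefficients, [0.5, 1.2], rtol=1e-6)

    def test_poly3_interpolates_four_points(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([1.0, 0.0, 4.0, -2.0])
        tl = fit_trendline(x, y, "poly3")
        np.testing.assert_allclose(tl(x), y, atol=1e-9)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            fit_trendline([1, 2], [1, 2], "spline")


@pytest.fixture(scope="module")
def curve(forage_mesh):
    return performance_curve(
        forage_mesh,
        fit_families={"tt_vs_c": "poly3", "v_vs_c": "poly3", "v_vs_tt": "linear"},
    )


class TestPerformanceCurve:
    def test_five_points_with_monotone_metrics(self, curve):
        assert len(curve.points) == 5
        costs = [r.cost for _, r in curve.points]
        tts = [r.travel_time for _, r in curve.points]
        vs = [r.vulnerability for _, r in curve.points]
        assert all(b >= a - 1e-9 for a, b in zip(costs, costs[1:]))
        assert all(b <= a + 1e-9 for a, b in zip(tts, tts[1:]))
        assert all(b <= a + 1e-9 for a, b in zip(vs, vs[1:]))

    def test_normalized_maxima_are_one(self, curve):
        for m in ("cost", "travel_time", "vulnerability"):
            assert max(r.metric(m, normalized=True) for _, r in curve.points) == (
                pytest.approx(1.0))

    def test_single_point_curve_skips_fit(self, forage_mesh):
        with pytest.warns(UserWarning, match="single-point"):
            c = performance_curve(forage_mesh, p_range=[3])
        assert len(c.points) == 1 and not c.fits

    def test_reference_point_on_curve_has_zero_distance(self, curve):
        _, r = curve.points[2]
        ref = MetricsReport(
            cost=1.0, travel_time=1.0, vulnerability=1.0,
            normalized_cost=r.normalized_cost,
            normalized_travel_time=r.normalized_travel_time,
            normalized_vulnerability=r.normalized_vulnerability,
        )
        cmp = compare_to_reference(curve, ref, "tt_vs_c")
        # the fitted poly3 passes within numerical wobble of its own data
        assert cmp.distance < 0.05


class TestCompareToReference:
    def make_line_curve(self):
        pts = []
        for i, (c, t) in enumerate([(0.0, 0.0), (0.5, 0.5), (1.0, 1.0)]):
            pts.append((i + 1, MetricsReport(
                cost=1, travel_time=1, vulnerability=1,
                normalized_cost=c, normalized_travel_time=t,
                normalized_vulnerability=1.0)))
        from myxonet.metrics import PerformanceCurve

        curve = PerformanceCurve(points=pts)
        curve.fit("tt_vs_c", "linear")
        return curve

    def test_projection_onto_diagonal(self):
        curve = self.make_line_curve()
        ref = MetricsReport(1, 1, 1, normalized_cost=1.0,
                            normalized_travel_time=0.0,
                            normalized_vulnerability=1.0)
        cmp = compare_to_reference(curve, ref, "tt_vs_c")
        assert cmp.closest_point[0] == pytest.approx(0.5, abs=1e-3)
        assert cmp.closest_point[1] == pytest.approx(0.5, abs=1e-3)
        assert cmp.distance == pytest.approx(math.sqrt(2) / 2, abs=1e-3)

    def test_reference_outside_domain_warns(self):
        curve = self.make_line_curve()
        ref = MetricsReport(1, 1, 1, normalized_cost=2.0,
                            normalized_travel_time=2.0,
                            normalized_vulnerability=1.0)
        with pytest.warns(UserWarning, match="outside"):
            cmp = compare_to_reference(curve, ref, "tt_vs_c")
        assert cmp.extrapolated
        assert cmp.closest_point[0] == pytest.approx(1.0)

    def test_unfitted_pair_rejected(self):
        curve = self.make_line_curve()
        ref = MetricsReport(1, 1, 1, normalized_cost=1.0,
                            normalized_travel_time=1.0,
                            normalized_vulnerability=1.0)
        with pytest.raises(ValueError):
            compare_to_reference(curve, ref, "v_vs_c")


class TestGranularitySensitivity:
    def test_segment_and_edge_granularities_available(self, forage_mesh):
        net = shortest_walk(forage_mesh)
        v_link = vulnerability(net, granularity="link")
        v_seg = vulnerability(net, granularity="segment")
        v_edge = vulnerability(net, granularity="edge")
        assert v_link >= 0 and v_seg >= 0 and v_edge >= 0

    def test_compute_metrics_report(self, forage_mesh):
        net = shortest_walk(forage_mesh)
        rep = compute_metrics(net, label="p3")
        assert rep.cost > 0 and rep.travel_time > 0 and rep.vulnerability >= 0
        assert rep.label == "p3"
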