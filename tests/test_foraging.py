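import math

import numpy as np
import pytest

import myxonet as mx
from myxonet.foraging import (
    Agent,
    SimConfig,
    TrailCloud,
    accessibility_fraction,
    attraction_force,
    nearest_active_attractor,
    run_foraging,
    step_agent,
    trail_cost,
)
from myxonet.geometry import Domain, Point2D
from myxonet.layouts import AttractorLayout
from myxonet.perlin import NoiseStream


def make_agent(x, y, heading=(1.0, 0.0), seed=0):
    return Agent(
        position=Point2D(x, y),
        noise_stream_x=NoiseStream(seed=seed, stream_id=0),
        noise_stream_y=NoiseStream(seed=seed, stream_id=1),
        heading=heading,
    )


class TestAttractionForce:
    @pytest.mark.parametrize(
        "distance,c,expected",
        [
            (10.0, 10.0, 1.0),
            (40.0, 10.0, 0.5),
            (0.0, 10.0, math.sqrt(10.0)),  # clamp at D = 1 px
            (0.5, 10.0, math.sqrt(10.0)),
            (100.0, 100.0, 1.0),
        ],
    )
    def test_inverse_square_root_law(self, distance, c, expected):
        assert attraction_force(distance, c) == pytest.approx(expected)

    def test_strictly_decreasing_above_clamp(self):
        d = np.linspace(1.0, 500.0, 200)
        f = attraction_force(d, 10.0)
        assert (np.diff(f) < 0).all()

    def test_positive_force_constant_required(self):
        with pytest.raises(ValueError):
            attraction_force(10.0, 0.0)


class TestNearestActiveAttractor:
    def test_returns_closest(self):
        lay = AttractorLayout(points=[(10.0, 0.0), (20.0, 0.0)], domain=Domain())
        idx, d = nearest_active_attractor((0.0, 0.0), lay)
        assert idx == 0 and d == pytest.approx(10.0)

    def test_depleted_source_never_returned(self):
        lay = AttractorLayout(points=[(10.0, 0.0), (20.0, 0.0)], domain=Domain())
        lay.active[0] = False
        idx, d = nearest_active_attractor((0.0, 0.0), lay)
        assert idx == 1 and d == pytest.approx(20.0)

    def test_tie_goes_to_lower_index(self):
        lay = AttractorLayout(points=[(390.0, 400.0), (410.0, 400.0)], domain=Domain())
        idx, d = nearest_active_attractor((400.0, 400.0), lay)
        # brute force: both distances are exactly 10
        assert d == 10.0 and idx == 0

    def test_no_active_attractor_is_state_error(self):
        lay = AttractorLayout(points=[(10.0, 10.0)], domain=Domain())
        lay.active[0] = False
        with pytest.raises(RuntimeError):
            nearest_active_attractor((0.0, 0.0), lay)


class TestStepAgent:
    def test_pure_attraction_moves_straight_at_step_length(self):
        lay = AttractorLayout(points=[(100.0, 0.0)], domain=Domain())
        cfg = SimConfig(noise_amplitude=0.0, seed=0)
        agent = make_agent(0.0, 0.0)
        out = step_agent(agent, lay, cfg, t=1)
        assert out.position.x == pytest.approx(1.5, abs=1e-12)
        assert out.position.y == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("mode", ["heading", "components"])
    def test_displacement_magnitude_is_exactly_step_length(self, mode):
        lay = AttractorLayout(points=[(600.0, 500.0)], domain=Domain())
        cfg = SimConfig(seed=3, noise_mode=mode)
        agent = make_agent(200.0, 200.0, seed=3)
        for t in range(1, 20):
            nxt = step_agent(agent, lay, cfg, t)
            dx = nxt.position.x - agent.position.x
            dy = nxt.position.y - agent.position.y
            assert math.hypot(dx, dy) == pytest.approx(1.5, abs=1e-9)
            agent = nxt

    def test_sixty_frames_cover_ninety_pixels(self):
        # 1.5 px/frame at 60 fps: foraging speed is 90 px per second
        lay = AttractorLayout(points=[(700.0, 400.0)], domain=Domain())
        cfg = SimConfig(seed=5)
        agent = make_agent(300.0, 400.0, seed=5)
        path = 0.0
        for t in range(1, 61):
            nxt = step_agent(agent, lay, cfg, t)
            path += math.hypot(nxt.position.x - agent.position.x,
                               nxt.position.y - agent.position.y)
            agent = nxt
        assert path == pytest.approx(90.0, abs=1e-9)

    def test_wall_reflection_keeps_agent_inside(self):
        lay = AttractorLayout(points=[(0.0, 400.0)], domain=Domain())
        cfg = SimConfig(noise_amplitude=0.0, seed=0)
        agent = make_agent(0.5, 400.0, heading=(-1.0, 0.0))
        out = step_agent(agent, lay, cfg, t=1)
        assert out.position.x == pytest.approx(1.0)
        assert out.heading[0] == pytest.approx(1.0)
        assert lay.domain.contains(out.position)


class TestRunForaging:
    def test_single_attractor_at_spawn_depletes_immediately(self):
        lay = AttractorLayout(points=[(400.0, 400.0)], domain=Domain())
        cfg = SimConfig(seed=2)
        cloud, log = run_foraging(lay, cfg)
        assert log.completed
        assert len(log.depletion_events) == 1
        assert len(log.spawn_events) == 2  # initial population + offspring
        assert log.terminated_frame <= math.ceil(cfg.colonization_radius / 1.5) + 1

    def test_straight_line_arrival_time(self):
        # noise off, source 150 px east, tight radius: arrival at frame 100
        lay = AttractorLayout(points=[(550.0, 400.0)], domain=Domain())
        cfg = SimConfig(noise_amplitude=0.0, colonization_radius=0.75, seed=0)
        cloud, log = run_foraging(lay, cfg)
        assert log.depletion_events == [(0, 100)]

    def test_deterministic_for_fixed_seed(self):
        lay = mx.generate_layout(2, min_spacing=150, seed=4)
        cfg = SimConfig(seed=9)
        c1, l1 = run_foraging(lay, cfg)
        c2, l2 = run_foraging(lay, cfg)
        np.testing.assert_array_equal(c1.points, c2.points)
        np.testing.assert_array_equal(c1.provenance, c2.provenance)
        assert l1.depletion_events == l2.depletion_events
        assert l1.total_agent_frames == l2.total_agent_frames

    def test_trail_points_stay_inside_domain(self, forage_run):
        layout, _, cloud, _ = forage_run
        assert (cloud.points >= 0).all()
        assert (cloud.points[:, 0] <= layout.domain.width).all()
        assert (cloud.points[:, 1] <= layout.domain.height).all()

    def test_one_depletion_event_per_attractor(self, forage_run):
        layout, _, _, log = forage_run
        assert sorted(i for i, _ in log.depletion_events) == list(range(len(layout)))
        # each depletion releases a fresh population of n agents
        assert len(log.spawn_events) == len(layout) + 1

    def test_sampling_respects_stride(self, forage_run):
        _, cfg, cloud, _ = forage_run
        assert (cloud.frame_of % cfg.sample_stride == 0).all()

    def test_max_frames_guard_carries_partial_results(self):
        # c = 1 noise-dominated walk cannot colonize a far source fast
        lay = AttractorLayout(points=[(50.0, 50.0), (750.0, 750.0)], domain=Domain())
        cfg = SimConfig(force_constant=1.0, max_frames=200, seed=1)
        with pytest.raises(mx.NonTerminationError) as exc:
            run_foraging(lay, cfg)
        assert exc.value.log.terminated_frame == 200
        assert len(exc.value.cloud) > 0

    def test_monotone_approach_without_noise(self):
        lay = AttractorLayout(points=[(600.0, 400.0)], domain=Domain())
        cfg = SimConfig(noise_amplitude=0.0, colonize=False, max_frames=60,
                        sample_stride=1, seed=0)
        cloud, _ = run_foraging(lay, cfg)
        dist_by_frame = [
            np.linalg.norm(cloud.points[cloud.frame_of == f] - (600.0, 400.0), axis=1).mean()
            for f in range(1, 61)
        ]
        assert (np.diff(dist_by_frame) < 0).all()


class TestTrailCost:
    def test_product_of_agents_and_frames_without_colonization(self):
        lay = mx.generate_layout(3, min_spacing=100, seed=8)
        cfg = SimConfig(colonize=False, max_frames=600, seed=1)
        _, log = run_foraging(lay, cfg)
        assert trail_cost(log) == 50 * 600

    def test_zero_frames_zero_cost(self):
        lay = mx.generate_layout(3, min_spacing=100, seed=8)
        cfg = SimConfig(colonize=False, max_frames=0, seed=1)
        _, log = run_foraging(lay, cfg)
        assert trail_cost(log) == 0

    def test_absorption_reduces_cost_below_upper_bound(self, forage_run):
        layout, cfg, _, log = forage_run
        n_spawned = sum(c for _, c, _ in log.spawn_events)
        assert trail_cost(log) < n_spawned * log.terminated_frame


class TestAccessibility:
    def empty_cloud(self):
        return TrailCloud(points=np.empty((0, 2)),
                          frame_of=np.empty(0, dtype=np.int64),
                          provenance=np.empty(0, dtype=np.int64))

    def one_point_cloud(self, x, y):
        return TrailCloud(points=np.array([[x, y]]),
                          frame_of=np.zeros(1, dtype=np.int64),
                          provenance=np.zeros(1, dtype=np.int64))

    def test_empty_cloud_covers_nothing(self):
        assert accessibility_fraction(self.empty_cloud(), Domain(), 100.0) == 0.0

    def test_full_reach_covers_everything(self):
        dom = Domain(100, 100)
        c = self.one_point_cloud(50, 50)
        assert accessibility_fraction(c, dom, reach=dom.diagonal) == 1.0

    def test_central_disc_area(self):
        # one central point with reach 80 covers ~ pi * 80^2 of 800^2
        c = self.one_point_cloud(400.0, 400.0)
        frac = accessibility_fraction(c, Domain(), reach=80.0)
        assert frac == pytest.approx(math.pi * 80**2 / 800**2, rel=0.02)

    def test_negative_reach_rejected(self):
        with pytest.raises(ValueError):
            accessibility_fraction(self.empty_cloud(), Domain(), -1.0)
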