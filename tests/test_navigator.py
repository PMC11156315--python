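"""The heading-update rules: component construction, activity and
weight redistribution, route memory formation and progression."""

import math

import numpy as np
import pytest

from artnav.circkit import wrap_angle
from artnav.navigator import (
    AgentState,
    ComponentStreams,
    NavigationWeights,
    PrecisionSchedule,
    SocialContext,
    advance,
    estimated_future_position,
    goal_component,
    memorise_step,
    memory_component,
    social_component_sample,
    social_mixing_proportion,
    step_heading,
)
from artnav.world import build_world

W_DEFAULT = NavigationWeights(0.25, 0.20, 0.05, 0.50)


def make_agent(weights=W_DEFAULT, seed=0, **kw):
    a = AgentState(0, weights, **kw)
    return a


def begin(agent, world, seed=0):
    agent.begin_journey(world, ComponentStreams((seed, agent.agent_id), agent.precisions))
    return agent


class FakeStreams:
    """Deterministic streams: each component draw returns a fixed offset
    (0 means the sample equals the component centre)."""

    def __init__(self, goal=0.0, social=0.0, memory=0.0, continuity=0.0, noise=0.0):
        self._vals = {"goal": goal, "social": social, "memory": memory,
                      "continuity": continuity, "noise": noise}
        self.counts = dict.fromkeys(self._vals, 0)

    def set_memory_kappa(self, kappa):
        pass

    def _draw(self, name):
        self.counts[name] += 1
        return self._vals[name]

    def vm_goal(self):
        return self._draw("goal")

    def vm_social(self):
        return self._draw("social")

    def vm_memory(self):
        return self._draw("memory")

    def vm_continuity(self):
        return self._draw("continuity")

    def noise(self):
        return self._draw("noise")


class TestParameterTypes:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            NavigationWeights(0.5, 0.5, 0.5, 0.5)
        with pytest.raises(ValueError):
            NavigationWeights(-0.1, 0.5, 0.3, 0.3)

    def test_memory_kappa_schedule(self):
        p = PrecisionSchedule()
        assert p.kappa_memory(1) == 0.0
        assert p.kappa_memory(2) == 1.82
        assert p.kappa_memory(3) == 2.29
        assert p.kappa_memory(5) == 4.19
        assert p.kappa_memory(6) == 6.78
        assert p.kappa_memory(40) == 6.78
        with pytest.raises(ValueError):
            p.kappa_memory(0)

    def test_memory_schedule_must_be_nondecreasing(self):
        with pytest.raises(ValueError):
            PrecisionSchedule(memory_ramp=(5.0, 1.0, 2.0, 3.0))

    def test_replace_memory_keeps_journey_one_uniform(self):
        p = PrecisionSchedule().replace_memory(2.18)
        assert p.kappa_memory(1) == 0.0
        assert p.kappa_memory(2) == 2.18
        assert p.kappa_memory(10) == 2.18

    def test_default_kappas_are_study_values(self):
        p = PrecisionSchedule()
        assert (p.goal, p.social, p.continuity) == (1.54, 2.18, 8.69)


class TestComponents:
    def test_goal_component_due_east(self, small_world):
        a = begin(make_agent(), small_world)
        c = goal_component(a, small_world)
        assert c.mu == pytest.approx(0.0)
        assert c.kappa == 1.54

    def test_goal_component_due_north(self, small_world):
        a = begin(make_agent(), small_world)
        a.x, a.y = 152.0, 64.0
        assert goal_component(a, small_world).mu == pytest.approx(math.pi / 2)

    def test_goal_component_at_goal_rejected(self, small_world):
        a = begin(make_agent(), small_world)
        a.x, a.y = small_world.goal
        with pytest.raises(ValueError):
            goal_component(a, small_world)

    @pytest.mark.parametrize(
        "pos,h,expected",
        [((0, 0), 0.0, (1, 0)), ((0, 0), math.pi / 2, (0, 1)), ((3, 4), math.pi, (2, 4))],
    )
    def test_estimated_future_position(self, pos, h, expected):
        fx, fy = estimated_future_position(pos, h)
        assert (fx, fy) == pytest.approx(expected, abs=1e-12)

    def test_social_mixing_proportion(self):
        assert social_mixing_proportion(0.5) == pytest.approx(0.5)
        assert social_mixing_proportion(0.0) == pytest.approx(2.87e-7, rel=0.01)
        assert social_mixing_proportion(1.0) == pytest.approx(1 - 2.87e-7, rel=0.01)
        with pytest.raises(ValueError):
            social_mixing_proportion(-0.1)

    def test_social_sample_pure_convergence_far_away(self, small_world):
        """At distance >> 0.5 the composite is the convergence VM."""
        a = begin(make_agent(), small_world)
        ctx = SocialContext((a.x + 5.0, a.y), math.pi / 2)  # partner due east
        fake = FakeStreams()
        s = social_component_sample(a, ctx, fake)
        # convergence bearing: towards partner's predicted position (east+north)
        expected = math.atan2(1.0, 5.0)
        assert s == pytest.approx(expected, abs=1e-9)
        assert fake.counts["social"] == 2  # always two draws

    def test_social_sample_pure_alignment_when_coincident(self, small_world):
        a = begin(make_agent(), small_world)
        ctx = SocialContext((a.x, a.y), 1.2)
        s = social_component_sample(a, ctx, FakeStreams())
        # zero distance -> alignment only -> partner heading (future position
        # offset is along that heading, mixing is irrelevant at p ~ 0)
        assert s == pytest.approx(1.2, abs=1e-6)

    def test_social_sample_none_when_partner_unstarted_and_coincident(self, small_world):
        a = begin(make_agent(), small_world)
        ctx = SocialContext((a.x, a.y), None)
        assert social_component_sample(a, ctx, FakeStreams()) is None


class TestRouteMemory:
    def test_memorises_along_first_journey(self, default_world):
        a = begin(make_agent(), default_world)
        for _ in range(120):
            advance(a, default_world, 0.0)
        assert len(a.memory.landmark_ids) > 0
        # consecutive duplicates are collapsed
        seq = a.memory.landmark_ids
        assert all(x != y for x, y in zip(seq, seq[1:]))

    def test_no_memorisation_without_landmarks(self):
        w = build_world(landmark_seed=0, n_landmarks=0)
        a = begin(make_agent(), w)
        for _ in range(50):
            advance(a, w, 0.0)
        assert a.memory.landmark_ids == []

    def test_sequence_frozen_after_first_journey(self, default_world):
        a = begin(make_agent(), default_world)
        for _ in range(120):
            advance(a, default_world, 0.0)
        a.end_journey()
        frozen = list(a.memory.landmark_ids)
        begin(a, default_world)  # second journey
        for _ in range(120):
            advance(a, default_world, 1.0)
        assert a.memory.landmark_ids == frozen
        assert a.memory.frozen

    def test_memory_component_first_journey_is_uniform(self, default_world):
        a = begin(make_agent(), default_world)
        c = memory_component(a, default_world)
        assert c is not None and c.kappa == 0.0

    def test_memory_component_second_journey_uses_ramp(self, default_world):
        a = begin(make_agent(), default_world)
        for _ in range(120):
            advance(a, default_world, 0.0)
        a.end_journey()
        begin(a, default_world)
        c = memory_component(a, default_world)
        assert c is not None and c.kappa == 1.82

    def test_memory_component_none_when_exhausted(self, default_world):
        a = begin(make_agent(), default_world)
        for _ in range(30):
            advance(a, default_world, 0.0)
        a.end_journey()
        begin(a, default_world)
        a.memory.pointer = len(a.memory.landmark_ids)
        assert memory_component(a, default_world) is None

    def test_single_step_progression(self, default_world):
        """The pointer advances at most one landmark per query even when
        several memorised landmarks are within the capture threshold."""
        a = begin(make_agent(), default_world)
        for _ in range(120):
            advance(a, default_world, 0.0)
        a.end_journey()
        begin(a, default_world)
        before = a.memory.pointer
        memory_component(a, default_world)
        assert a.memory.pointer <= before + 1


class TestStepHeading:
    def test_pure_goal_high_precision_is_straight(self, small_world):
        w = NavigationWeights(1.0, 0.0, 0.0, 0.0)
        a = make_agent(w, precisions=PrecisionSchedule(goal=1e8))
        begin(a, small_world)
        for _ in range(104):
            h = step_heading(a, small_world, None)
            advance(a, small_world, h)
        assert a.arrived
        assert a.travelled == pytest.approx(104, abs=1.5)

    def test_redistribution_equals_renormalised_circular_mean(self, small_world):
        """Solo first step: social and continuity inactive; heading is the
        weighted circular mean of goal and (uniform) memory samples with
        weights renormalised over the active pair."""
        a = begin(make_agent(), small_world)
        fake = FakeStreams(memory=math.pi / 2)
        a.streams = fake
        h = step_heading(a, small_world, None)
        wg, wm = 0.25, 0.05
        expected = np.angle(wg * np.exp(0j) + wm * np.exp(1j * math.pi / 2))
        assert h == pytest.approx(expected, abs=1e-12)
        assert fake.counts == {"goal": 1, "social": 0, "memory": 1, "continuity": 0, "noise": 0}

    def test_continuity_active_after_first_step(self, small_world):
        a = begin(make_agent(), small_world)
        a.heading = 0.3
        fake = FakeStreams(noise=0.0)
        a.streams = fake
        step_heading(a, small_world, None)
        assert fake.counts["continuity"] == 1

    def test_lesioned_component_keeps_weight_draws_noise(self, small_world):
        a = begin(make_agent(), small_world)
        fake = FakeStreams(noise=math.pi / 2)
        a.streams = fake
        h = step_heading(a, small_world, None, lesioned=frozenset({"goal"}))
        # goal noise pi/2 (w .25) + memory journey-1 vm draw 0 (w .05)
        expected = np.angle(0.25 * np.exp(1j * math.pi / 2) + 0.05 * np.exp(0j))
        assert h == pytest.approx(expected, abs=1e-12)
        assert fake.counts["noise"] == 1 and fake.counts["goal"] == 0

    def test_lesion_does_not_touch_other_streams(self, small_world):
        """Same seeds, with and without a memory lesion: the goal
        component consumes the identical draw."""
        world = small_world

        def first_goal_draw(lesion):
            a = make_agent()
            begin(a, world, seed=42)
            h = step_heading(a, world, None, lesioned=lesion)
            return a.streams._buf["goal"][0]

        assert first_goal_draw(frozenset()) == first_goal_draw(frozenset({"memory"}))

    def test_all_inactive_rejected(self, small_world):
        w = NavigationWeights(0.0, 1.0, 0.0, 0.0)  # social only, no partner
        a = begin(make_agent(w), small_world)
        with pytest.raises(RuntimeError):
            step_heading(a, small_world, None)

    def test_unknown_lesion_rejected(self):
        with pytest.raises(ValueError):
            AgentState(0, W_DEFAULT, lesions=frozenset({"teleport"}))


class TestAdvance:
    def test_moves_one_unit_per_step(self, small_world):
        a = begin(make_agent(), small_world)
        advance(a, small_world, 0.0)
        assert (a.x, a.y) == pytest.approx((49.0, 65.0))
        assert a.travelled == 1.0
        advance(a, small_world, math.pi / 2)
        assert (a.x, a.y) == pytest.approx((49.0, 66.0))
        assert a.travelled == 2.0

    def test_arrival_flag_near_goal(self, small_world):
        a = begin(make_agent(), small_world)
        a.x, a.y = 150.5, 65.0
        advance(a, small_world, 0.0)  # now at 151.5, within 1 unit of goal
        assert a.arrived
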