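"""The artificial navigator: per-step heading updates and route memory.

An agent's next heading is the weighted circular mean of one sample per
navigation rule, each drawn from a Von Mises distribution:

* **goal direction** — centred on the bearing to the goal (kappa_goal);
* **social proximity** — a composite of *convergence* (bearing to the
  partner's estimated next position) and *alignment* (the partner's
  current heading), mixed by a distance-dependent proportion p;
* **route memory** — centred on the bearing to the next landmark of the
  route memorised during the agent's first journey, with a per-journey
  precision ramp;
* **continuity** — centred on the agent's current heading, damping
  erratic turns.

Weights are fixed at agent initialisation and sum to 1.  When a rule has
no defined bearing (no partner; first step of a journey for continuity;
an empty or exhausted landmark sequence on journey >= 2) it is *inactive*
and its weight is redistributed proportionally over the active rules.
The memory rule on an agent's *first* journey is a special case: there is
no memorised route yet, so it stays active but draws from the uniform
circular distribution (kappa = 0), keeping its weight — this is also
exactly what a "lesion" does to a component.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .circkit import VonMisesComponent, wrap_angle
from .world import World, nearest_landmark

__all__ = [
    "NavigationWeights",
    "PrecisionSchedule",
    "RouteMemory",
    "AgentState",
    "SocialContext",
    "ComponentStreams",
    "COMPONENTS",
    "goal_component",
    "estimated_future_position",
    "social_mixing_proportion",
    "social_component_sample",
    "memorise_step",
    "memory_component",
    "step_heading",
    "advance",
]

COMPONENTS = ("goal", "social", "memory", "continuity")

_SQRT2 = math.sqrt(2.0)

#: landmark capture / progression threshold: 10x the per-step travel distance
CAPTURE_RADIUS = 10.0
#: goal arrival radius: one step distance (the agent arrives when it could
#: step onto the goal), so travelled distance at arrival is commensurate
#: with the start-goal separation and route efficiency tops out near 1
ARRIVAL_RADIUS = 1.0


@dataclass(frozen=True)
class NavigationWeights:
    """Mixture weights (w_goal, w_social, w_memory, w_continuity), sum 1."""

    goal: float
    social: float
    memory: float
    continuity: float

    def __post_init__(self) -> None:
        t = self.as_tuple()
        if any(w < 0 for w in t):
            raise ValueError("weights must be non-negative")
        if abs(sum(t) - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {sum(t)!r}")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.goal, self.social, self.memory, self.continuity)


@dataclass(frozen=True)
class PrecisionSchedule:
    """Concentration (kappa) parameters of the four rules.

    Memory precision ramps up with an agent's own experience: journey 1
    has no memorised route (kappa treated as 0 -> uniform), journeys 2-5
    use ``memory_ramp`` and later journeys the plateau.  The defaults are
    the fixed values used throughout the study conditions, equivalent to
    circular SDs of 1.0 (goal), 0.80 (social), 0.9 -> 0.4 (memory) and
    0.35 (continuity).
    """

    goal: float = 1.54
    social: float = 2.18
    continuity: float = 8.69
    memory_ramp: tuple[float, ...] = (1.82, 2.29, 2.98, 4.19)
    memory_plateau: float = 6.78

    def __post_init__(self) -> None:
        ks = (self.goal, self.social, self.continuity, self.memory_plateau, *self.memory_ramp)
        if any(k < 0 for k in ks):
            raise ValueError("kappa values must be >= 0")
        seq = (0.0, *self.memory_ramp, self.memory_plateau)
        if any(b < a for a, b in zip(seq, seq[1:])):
            raise ValueError("memory kappa schedule must be non-decreasing")

    def kappa_memory(self, journey_number: int) -> float:
        """Memory kappa for an agent's ``journey_number``-th journey (1-based)."""
        if journey_number < 1:
            raise ValueError("journey_number is 1-based")
        if journey_number == 1:
            return 0.0
        i = journey_number - 2
        if i < len(self.memory_ramp):
            return self.memory_ramp[i]
        return self.memory_plateau

    def replace_memory(self, kappa: float) -> "PrecisionSchedule":
        """Schedule with the whole memory ramp collapsed to one kappa
        (journey 1 remains uniform) — used by precision-variation runs."""
        return PrecisionSchedule(
            goal=self.goal,
            social=self.social,
            continuity=self.continuity,
            memory_ramp=(kappa, kappa, kappa, kappa),
            memory_plateau=kappa,
        )


@dataclass
class RouteMemory:
    """Ordered landmark IDs memorised on the first journey.

    The sequence is frozen once the first journey ends; on later journeys
    ``pointer`` tracks the current target landmark and advances whenever
    the agent comes within ``capture_radius`` of it.
    """

    landmark_ids: list[int] = field(default_factory=list)
    frozen: bool = False
    pointer: int = 0
    capture_radius: float = CAPTURE_RADIUS
    strategy: str = "nearest_per_step"  # or "spaced"
    progression: str = "single"  # "single" | "skip"


@dataclass
class SocialContext:
    """Time-t state of the one other active agent (pairs only)."""

    position: tuple[float, float]
    heading: float | None  # None on the partner's first step of a journey


class ComponentStreams:
    """Per-component, independently seeded random streams for one agent.

    Each navigation rule draws from its own stream, plus one shared noise
    stream for uniform (lesion / kappa=0) draws.  This keeps the number
    of draws a rule consumes independent of what happens to the others,
    so lesioning one component never perturbs another's sample path.

    Centred Von Mises draws VM(0, kappa) are pre-generated in blocks
    (kappa is fixed per journey), and the bearing is added at use time.
    """

    _CHUNK = 1024

    def __init__(self, seed_key: tuple[int, ...], precisions: PrecisionSchedule) -> None:
        gens = [
            np.random.Generator(np.random.PCG64(np.random.SeedSequence((*seed_key, i))))
            for i in range(5)
        ]
        self._g_goal, self._g_social, self._g_memory, self._g_cont, self._g_noise = gens
        self._precisions = precisions
        self._buf: dict[str, list[float]] = {}
        self._pos: dict[str, int] = {}
        self._kappa_memory = 0.0

    def set_memory_kappa(self, kappa: float) -> None:
        self._kappa_memory = float(kappa)
        self._buf.pop("memory", None)

    def _draw(self, name: str, gen: np.random.Generator, kappa: float | None) -> float:
        buf = self._buf.get(name)
        pos = self._pos.get(name, 0)
        if buf is None or pos >= len(buf):
            if kappa is None:  # uniform noise
                buf = gen.uniform(-math.pi, math.pi, self._CHUNK).tolist()
            elif kappa == 0.0:
                buf = gen.uniform(-math.pi, math.pi, self._CHUNK).tolist()
            else:
                buf = gen.vonmises(0.0, kappa, self._CHUNK).tolist()
            self._buf[name] = buf
            pos = 0
        self._pos[name] = pos + 1
        return buf[pos]

    def vm_goal(self) -> float:
        return self._draw("goal", self._g_goal, self._precisions.goal)

    def vm_social(self) -> float:
        return self._draw("social", self._g_social, self._precisions.social)

    def vm_memory(self) -> float:
        return self._draw("memory", self._g_memory, self._kappa_memory)

    def vm_continuity(self) -> float:
        return self._draw("continuity", self._g_cont, self._precisions.continuity)

    def noise(self) -> float:
        return self._draw("noise", self._g_noise, None)


class AgentState:
    """Mutable state of one agent across journeys."""

    __slots__ = (
        "agent_id",
        "x",
        "y",
        "heading",
        "travelled",
        "journeys_completed",
        "memory",
        "weights",
        "precisions",
        "lesions",
        "arrived",
        "streams",
        "_last_memorised",
        "_seen",
    )

    def __init__(
        self,
        agent_id: int,
        weights: NavigationWeights,
        precisions: PrecisionSchedule | None = None,
        lesions: frozenset[str] = frozenset(),
        capture_radius: float = CAPTURE_RADIUS,
        memory_strategy: str = "nearest_per_step",
        memory_progression: str = "single",
    ) -> None:
        unknown = set(lesions) - set(COMPONENTS)
        if unknown:
            raise ValueError(f"unknown lesion component(s): {sorted(unknown)}")
        self.agent_id = agent_id
        self.weights = weights
        self.precisions = precisions or PrecisionSchedule()
        self.lesions = frozenset(lesions)
        if memory_strategy not in ("spaced", "nearest_per_step", "all_in_range"):
            raise ValueError(f"unknown memory strategy {memory_strategy!r}")
        if memory_progression not in ("single", "skip"):
            raise ValueError(f"unknown memory progression {memory_progression!r}")
        self.memory = RouteMemory(
            capture_radius=capture_radius,
            strategy=memory_strategy,
            progression=memory_progression,
        )
        self.x = 0.0
        self.y = 0.0
        self.heading: float | None = None
        self.travelled = 0.0
        self.journeys_completed = 0
        self.arrived = False
        self.streams: ComponentStreams | None = None
        self._last_memorised: int | None = None
        self._seen: set[int] = set()

    @property
    def journey_number(self) -> int:
        """1-based index of the journey currently underway."""
        return self.journeys_completed + 1

    @property
    def position(self) -> tuple[float, float]:
        return (self.x, self.y)

    def begin_journey(self, world: World, streams: ComponentStreams) -> None:
        self.x, self.y = world.start
        self.heading = None
        self.travelled = 0.0
        self.arrived = False
        self.streams = streams
        self.memory.pointer = 0
        self._last_memorised = None
        streams.set_memory_kappa(self.precisions.kappa_memory(self.journey_number))
        if self.journey_number == 1:
            memorise_step(self, world)

    def end_journey(self) -> None:
        if self.journey_number == 1:
            self.memory.frozen = True
        self.journeys_completed += 1


# ---------------------------------------------------------------------------
# the four rules


def goal_component(agent: AgentState, world: World) -> VonMisesComponent:
    """Goal-direction rule: VM centred on the bearing to the goal."""
    gx, gy = world.goal
    dx, dy = gx - agent.x, gy - agent.y
    if dx == 0.0 and dy == 0.0:
        raise ValueError("agent is exactly at the goal; journey should have ended")
    return VonMisesComponent(math.atan2(dy, dx), agent.precisions.goal)


def estimated_future_position(
    position: tuple[float, float], heading: float, v: float = 1.0
) -> tuple[float, float]:
    """Dead-reckoned position one step ahead at constant speed ``v``."""
    return (position[0] + v * math.cos(heading), position[1] + v * math.sin(heading))


def social_mixing_proportion(distance: float) -> float:
    """Convergence-vs-alignment mixing proportion p = Phi((d - 0.5) / 0.1).

    Larger inter-agent distances favour convergence (steering toward the
    partner); at close range alignment (matching the partner's heading)
    dominates.
    """
    if distance < 0:
        raise ValueError("distance must be >= 0")
    return 0.5 * (1.0 + math.erf((distance - 0.5) / (0.1 * _SQRT2)))


def social_component_sample(
    agent: AgentState, context: SocialContext, streams: ComponentStreams
) -> float | None:
    """One draw from the social-proximity composite, or ``None`` if no
    bearing is defined (partner coincident with agent and heading-less).

    A convergence sample (VM centred on the bearing to the partner's
    estimated next position) and an alignment sample (VM centred on the
    partner's heading) are combined as a two-element weighted circular
    mean with weights (p, 1 - p).  Both draws are always consumed so the
    social stream advances deterministically.
    """
    px, py = context.position
    if context.heading is None:
        # partner has not moved yet: no predicted position, no alignment
        dx, dy = px - agent.x, py - agent.y
        if dx == 0.0 and dy == 0.0:
            return None
        return wrap_angle(math.atan2(dy, dx) + streams.vm_social())
    fx, fy = px + math.cos(context.heading), py + math.sin(context.heading)
    a_align = context.heading + streams.vm_social()
    dx, dy = fx - agent.x, fy - agent.y
    if dx == 0.0 and dy == 0.0:
        # predicted position coincides with the agent: alignment only
        streams.vm_social()  # keep draw count fixed
        return wrap_angle(a_align)
    a_conv = math.atan2(dy, dx) + streams.vm_social()
    d = math.hypot(px - agent.x, py - agent.y)
    if d == 0.0:
        return wrap_angle(a_align)
    p = social_mixing_proportion(d)
    cx = p * math.cos(a_conv) + (1.0 - p) * math.cos(a_align)
    cy = p * math.sin(a_conv) + (1.0 - p) * math.sin(a_align)
    if cx == 0.0 and cy == 0.0:  # opposed draws, probability ~0
        return wrap_angle(a_conv)
    return math.atan2(cy, cx)


def memorise_step(agent: AgentState, world: World) -> None:
    """On the first journey, commit passed landmarks to memory.

    Under the default ``nearest_per_step`` strategy the nearest landmark
    within the capture radius is recorded at every step, deduplicating
    consecutive repeats.  The memorised sequence is therefore dense —
    about one landmark per two units of path — so re-tracing it under
    the one-landmark-per-step progression rule is paced by the first
    journey's own (in)efficiency, which is what carries route quality
    (and its improvement) between generations.

    Two alternative readings are kept as strategy hooks for sensitivity
    checks: ``spaced`` commits a new landmark only after leaving the
    capture zone of the previous one (coarse waypoints), and
    ``all_in_range`` commits every landmark in range, once, in
    first-encounter order (very dense sequences).
    """
    if agent.journeys_completed != 0 or agent.memory.frozen:
        return
    mem = agent.memory
    if mem.strategy == "all_in_range":
        ids = world.index.all_within(agent.x, agent.y, mem.capture_radius)
        seen = agent._seen
        for lid in ids:
            if lid not in seen:
                mem.landmark_ids.append(lid)
                seen.add(lid)
        return
    if mem.strategy == "spaced" and agent._last_memorised is not None:
        lx, ly = world.landmarks[agent._last_memorised]
        if (lx - agent.x) ** 2 + (ly - agent.y) ** 2 <= mem.capture_radius**2:
            return
    lid = nearest_landmark(world, (agent.x, agent.y), mem.capture_radius)
    if lid is not None and lid != agent._last_memorised:
        mem.landmark_ids.append(lid)
        agent._last_memorised = lid


def _advance_memory_pointer(agent: AgentState, world: World) -> int | None:
    """Advance the route pointer per the progression rule and return the
    current target landmark ID, or None once the sequence is exhausted.

    ``single`` (default): one check per time step — if the agent is
    within the capture threshold of the current target, move on to the
    next landmark.  Traversal of the memorised sequence is therefore
    paced at one landmark per step, so re-tracing a long first journey
    remains costly — the route's badness is inherited, which is what
    leaves room for intergenerational improvement.

    ``skip``: catch up past every landmark already within the threshold
    (a look-ahead that smooths the route aggressively).
    """
    mem = agent.memory
    ids = mem.landmark_ids
    n = len(ids)
    r2 = mem.capture_radius * mem.capture_radius
    pts = world.landmarks
    if mem.progression == "single":
        if mem.pointer < n:
            lx, ly = pts[ids[mem.pointer]]
            if (lx - agent.x) ** 2 + (ly - agent.y) ** 2 <= r2:
                mem.pointer += 1
    else:
        while mem.pointer < n:
            lx, ly = pts[ids[mem.pointer]]
            if (lx - agent.x) ** 2 + (ly - agent.y) ** 2 <= r2:
                mem.pointer += 1
            else:
                break
    if mem.pointer >= n:
        return None
    return ids[mem.pointer]


def memory_component(agent: AgentState, world: World) -> VonMisesComponent | None:
    """Route-memory rule.

    On the agent's first journey this is the uniform circular
    distribution (kappa = 0, weight retained).  On later journeys it is a
    VM centred on the bearing to the current target landmark of the
    memorised sequence, with the experience-indexed kappa; ``None`` once
    the sequence is empty or exhausted (the weight is then
    redistributed).
    """
    if agent.journeys_completed == 0:
        return VonMisesComponent(0.0, 0.0)
    target = _advance_memory_pointer(agent, world)
    if target is None:
        return None
    lx, ly = world.landmarks[target]
    mu = math.atan2(ly - agent.y, lx - agent.x)
    return VonMisesComponent(mu, agent.precisions.kappa_memory(agent.journey_number))


# ---------------------------------------------------------------------------
# heading update


def step_heading(
    agent: AgentState,
    world: World,
    context: SocialContext | None,
    generation: int = 1,
    lesioned: frozenset[str] | None = None,
) -> float:
    """Draw one sample per active rule and combine them into h(t+1).

    Inactive rules' weights are redistributed proportionally over the
    active ones.  Lesioned rules stay active but their sample is replaced
    by uniform circular noise (weight retained).  The result is returned
    (not applied); callers advance all agents synchronously from time-t
    state.
    """
    streams = agent.streams
    if streams is None:
        raise RuntimeError("agent has no random streams; call begin_journey first")
    if lesioned is None:
        lesioned = agent.lesions
    wg, ws, wm, wc = agent.weights.as_tuple()
    sx = 0.0
    sy = 0.0
    wsum = 0.0

    if wg > 0.0:
        if "goal" in lesioned:
            a = streams.noise()
        else:
            gx, gy = world.goal
            a = math.atan2(gy - agent.y, gx - agent.x) + streams.vm_goal()
        sx += wg * math.cos(a)
        sy += wg * math.sin(a)
        wsum += wg

    if ws > 0.0 and context is not None:
        if "social" in lesioned:
            a = streams.noise()
        else:
            s = social_component_sample(agent, context, streams)
            a = s if s is not None else None
        if a is not None:
            sx += ws * math.cos(a)
            sy += ws * math.sin(a)
            wsum += ws

    if wm > 0.0:
        if agent.journeys_completed == 0:
            a = streams.noise() if "memory" in lesioned else streams.vm_memory()
            sx += wm * math.cos(a)
            sy += wm * math.sin(a)
            wsum += wm
        else:
            target = _advance_memory_pointer(agent, world)
            if target is not None:
                if "memory" in lesioned:
                    a = streams.noise()
                else:
                    lx, ly = world.landmarks[target]
                    a = math.atan2(ly - agent.y, lx - agent.x) + streams.vm_memory()
                sx += wm * math.cos(a)
                sy += wm * math.sin(a)
                wsum += wm

    if wc > 0.0 and agent.heading is not None:
        a = streams.noise() if "continuity" in lesioned else agent.heading + streams.vm_continuity()
        sx += wc * math.cos(a)
        sy += wc * math.sin(a)
        wsum += wc

    if wsum <= 0.0:
        raise RuntimeError("no active navigation component (all weights inactive)")
    # redistribution is implicit: atan2 is invariant to rescaling by wsum
    if math.hypot(sx, sy) / wsum < 1e-12:
        # perfectly opposed samples: retain previous heading (tie-break)
        if agent.heading is not None:
            return agent.heading
        gx, gy = world.goal
        return math.atan2(gy - agent.y, gx - agent.x)
    return math.atan2(sy, sx)


def advance(
    agent: AgentState,
    world: World,
    new_heading: float,
    arrival_radius: float = ARRIVAL_RADIUS,
    v: float = 1.0,
) -> None:
    """Apply h(t+1), move one step at speed ``v``, update travelled
    distance, memorise (first journey) and flag arrival at the goal."""
    agent.heading = new_heading
    agent.x += v * math.cos(new_heading)
    agent.y += v * math.sin(new_heading)
    agent.travelled += v
    if agent.journeys_completed == 0:
        memorise_step(agent, world)
    gx, gy = world.goal
    if (gx - agent.x) ** 2 + (gy - agent.y) ** 2 <= arrival_radius * arrival_radius:
        agent.arrived = True
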