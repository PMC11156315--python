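"""Drivers for journeys, conditions and experiment campaigns.

Three conditions mirror the generational-turnover design:

* ``solo`` — one agent makes 60 consecutive journeys;
* ``pair`` — two agents journey together, no turnover;
* ``experimental`` — pairs with generational turnover: generation 1 is a
  single agent journeying alone for 12 journeys, a naive partner is
  added for generation 2, and at each later generation boundary the most
  experienced agent is replaced by a fresh naive one (5 generations of
  12 journeys, 5 distinct agents in total).

Journeys run from a fixed start to a fixed goal 104 units apart, at unit
speed, capped at 2,506 units of travel.  Lesion experiments replace a
component's samples with uniform circular noise (weight retained);
precision experiments rescale one component's concentration via the
circular-SD equivalent.

Randomness: every (run, agent, journey, component) tuple gets its own
counter-based seeded stream, so runs are reproducible, repetitions are
independent, and lesioning one component never perturbs the sample paths
of the others.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import metrics
from .circkit import circular_sd_from_kappa, kappa_from_circular_sd
from .navigator import (
    COMPONENTS,
    AgentState,
    ComponentStreams,
    NavigationWeights,
    PrecisionSchedule,
    SocialContext,
    advance,
    step_heading,
)
from .world import World, build_world

__all__ = [
    "CONDITIONS",
    "ConditionSpec",
    "LesionSpec",
    "JourneyRecord",
    "ExperimentResult",
    "WEIGHTS_FINAL_EFFICIENCY",
    "WEIGHTS_IMPROVEMENT",
    "WEIGHTS_SOLO_BEST",
    "run_journey",
    "run_condition",
    "run_replicates",
    "weight_grid",
    "sweep_weights",
    "precision_variation",
]

CONDITIONS = ("solo", "pair", "experimental")

#: weight optima (goal, social, memory, continuity) for final-generation
#: efficiency, for intergenerational improvement, and for the solo condition
WEIGHTS_FINAL_EFFICIENCY = NavigationWeights(0.25, 0.20, 0.05, 0.50)
WEIGHTS_IMPROVEMENT = NavigationWeights(0.15, 0.25, 0.40, 0.20)
WEIGHTS_SOLO_BEST = NavigationWeights(0.35, 0.05, 0.05, 0.55)

#: "very high precision" kappas used in the precision-variation suite
VERY_HIGH_KAPPA = {"goal": 101.0, "social": 101.0, "memory": 1e12, "continuity": 401.0}


@dataclass(frozen=True)
class ConditionSpec:
    """Journey-count layout and physical limits for one condition."""

    name: str
    journeys_total: int = 60
    journeys_per_generation: int = 12
    max_travel: float = 2506.0
    arrival_radius: float = 1.0
    capture_radius: float = 10.0
    speed: float = 1.0
    memory_strategy: str = "nearest_per_step"
    memory_progression: str = "single"

    def __post_init__(self) -> None:
        if self.name not in CONDITIONS:
            raise ValueError(f"unknown condition {self.name!r}")
        if self.journeys_total % self.journeys_per_generation:
            raise ValueError("journeys_total must be a multiple of journeys_per_generation")

    @property
    def n_generations(self) -> int:
        return self.journeys_total // self.journeys_per_generation

    def generation_of(self, journey: int) -> int:
        """1-based generation (12-journey block) of 1-based journey index."""
        return 1 + (journey - 1) // self.journeys_per_generation


@dataclass(frozen=True)
class LesionSpec:
    """Which components are replaced by uniform noise, and for the goal
    component, whether the lesion applies from generation 1 or only from
    generation 2 onward."""

    components: frozenset[str]
    goal_scope: str = "all"  # "all" | "after_first_generation"

    def __post_init__(self) -> None:
        unknown = set(self.components) - set(COMPONENTS)
        if unknown:
            raise ValueError(f"unknown lesion component(s): {sorted(unknown)}")
        if self.goal_scope not in ("all", "after_first_generation"):
            raise ValueError(f"unknown goal_scope {self.goal_scope!r}")

    def active_for(self, generation: int) -> frozenset[str]:
        comps = set(self.components)
        if "goal" in comps and self.goal_scope == "after_first_generation" and generation == 1:
            comps.discard("goal")
        return frozenset(comps)


@dataclass
class JourneyRecord:
    """One agent's account of one journey (the unit metrics consume)."""

    run: int
    condition: str
    generation: int
    journey: int
    agent_id: int
    journey_of_agent: int
    naive: bool
    travelled: float
    arrived: bool
    n_steps: int
    positions: np.ndarray | None = None
    headings: np.ndarray | None = None


@dataclass
class ExperimentResult:
    """Per-journey efficiencies over all runs of one condition, with
    provenance (weights, precisions, lesion, seeds)."""

    condition: str
    weights: NavigationWeights
    precisions: PrecisionSchedule
    lesion: LesionSpec | None
    base_seed: int
    n_reps: int
    spec: ConditionSpec
    frame: pd.DataFrame
    records: list[JourneyRecord] | None = None
    memories: dict[tuple[int, int], list[int]] = field(default_factory=dict)
    world_kwargs: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return metrics.summarize(self)


def _landmark_seed(seed_key: tuple[int, ...]) -> int:
    return int(np.random.SeedSequence((*seed_key, 0xBEEF)).generate_state(1)[0] % (2**31))


def run_journey(
    agents: Sequence[AgentState],
    world: World,
    spec: ConditionSpec,
    *,
    run: int = 0,
    generation: int = 1,
    journey: int = 1,
    lesion: LesionSpec | None = None,
    seed_key: tuple[int, ...] = (0,),
    naive_ids: frozenset[int] = frozenset(),
    keep_paths: bool = False,
) -> list[JourneyRecord]:
    """Run one journey for 1 or 2 agents; returns one record per agent.

    All agents are reset to the start.  Headings are computed
    synchronously from time-t state, then all positions advance.  An
    agent stops on arrival (within the arrival radius of the goal) or on
    reaching the travel cap; when one pair member stops, the other
    continues with the social weight redistributed.
    """
    if not 1 <= len(agents) <= 2:
        raise ValueError("run_journey supports 1 or 2 agents")
    lesioned = lesion.active_for(generation) if lesion is not None else frozenset()
    for a in agents:
        streams = ComponentStreams((*seed_key, a.agent_id, journey), a.precisions)
        a.begin_journey(world, streams)
    paths: dict[int, list[tuple[float, float]]] = {}
    heads: dict[int, list[float]] = {}
    if keep_paths:
        for a in agents:
            paths[a.agent_id] = [(a.x, a.y)]
            heads[a.agent_id] = []

    active = [a for a in agents]
    max_travel = spec.max_travel
    while active:
        if len(active) == 2:
            a0, a1 = active
            c0 = SocialContext((a1.x, a1.y), a1.heading)
            c1 = SocialContext((a0.x, a0.y), a0.heading)
            h0 = step_heading(a0, world, c0, generation, lesioned)
            h1 = step_heading(a1, world, c1, generation, lesioned)
            advance(a0, world, h0, spec.arrival_radius, spec.speed)
            advance(a1, world, h1, spec.arrival_radius, spec.speed)
        else:
            a0 = active[0]
            h0 = step_heading(a0, world, None, generation, lesioned)
            advance(a0, world, h0, spec.arrival_radius, spec.speed)
        if keep_paths:
            for a in active:
                paths[a.agent_id].append((a.x, a.y))
                heads[a.agent_id].append(a.heading)  # type: ignore[arg-type]
        active = [a for a in active if not a.arrived and a.travelled < max_travel]

    out = []
    for a in agents:
        assert a.travelled <= max_travel + 1e-9, "travel cap exceeded"
        out.append(
            JourneyRecord(
                run=run,
                condition=spec.name,
                generation=generation,
                journey=journey,
                agent_id=a.agent_id,
                journey_of_agent=a.journey_number,
                naive=a.agent_id in naive_ids,
                travelled=a.travelled,
                arrived=a.arrived,
                n_steps=int(round(a.travelled / spec.speed)),
                positions=np.asarray(paths[a.agent_id]) if keep_paths else None,
                headings=np.asarray(heads[a.agent_id]) if keep_paths else None,
            )
        )
        a.end_journey()
    return out


def run_condition(
    condition: str | ConditionSpec,
    weights: NavigationWeights,
    precisions: PrecisionSchedule | None = None,
    lesion: LesionSpec | None = None,
    run_seed: int = 0,
    *,
    run: int = 0,
    world: World | None = None,
    world_kwargs: dict | None = None,
    keep_paths: bool = False,
    memories: dict | None = None,
) -> list[JourneyRecord]:
    """Run one full 60-journey repetition of a condition.

    The landmark field is redrawn per repetition (derived from the run
    seed) unless an explicit ``world`` is supplied.
    """
    spec = condition if isinstance(condition, ConditionSpec) else ConditionSpec(condition)
    precisions = precisions or PrecisionSchedule()
    seed_key = (int(run_seed), int(run))
    if world is None:
        kw = dict(world_kwargs or {})
        kw.setdefault("landmark_seed", _landmark_seed(seed_key))
        world = build_world(**kw)

    def new_agent(agent_id: int) -> AgentState:
        return AgentState(
            agent_id,
            weights,
            precisions,
            capture_radius=spec.capture_radius,
            memory_strategy=spec.memory_strategy,
            memory_progression=spec.memory_progression,
        )

    next_id = itertools.count()
    if spec.name == "solo":
        agents = [new_agent(next(next_id))]
    else:
        agents = [new_agent(next(next_id)), new_agent(next(next_id))]
    if spec.name == "experimental":
        agents = agents[:1]  # generation 1 is a single agent journeying alone

    records: list[JourneyRecord] = []
    for gen in range(1, spec.n_generations + 1):
        if spec.name == "experimental" and gen >= 2:
            if gen == 2:
                agents.append(new_agent(next(next_id)))
            else:
                veteran = max(agents, key=lambda a: a.journeys_completed)
                agents = [a for a in agents if a is not veteran]
                agents.append(new_agent(next(next_id)))
        naive_ids = frozenset(a.agent_id for a in agents if a.journeys_completed == 0)
        for j_in_gen in range(1, spec.journeys_per_generation + 1):
            journey = (gen - 1) * spec.journeys_per_generation + j_in_gen
            records.extend(
                run_journey(
                    agents,
                    world,
                    spec,
                    run=run,
                    generation=gen,
                    journey=journey,
                    lesion=lesion,
                    seed_key=seed_key,
                    naive_ids=naive_ids,
                    keep_paths=keep_paths,
                )
            )
            if memories is not None:
                for a in agents:
                    if a.journeys_completed == 1:  # just froze its route
                        memories[(run, a.agent_id)] = list(a.memory.landmark_ids)
    return records


def _frame_from_records(records: Iterable[JourneyRecord], distance: float) -> pd.DataFrame:
    rows = [
        (
            r.run,
            r.condition,
            r.generation,
            r.journey,
            r.agent_id,
            r.journey_of_agent,
            r.naive,
            r.travelled,
            r.arrived,
            metrics.route_efficiency(r, distance),
        )
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "run",
            "condition",
            "generation",
            "journey",
            "agent",
            "journey_of_agent",
            "naive",
            "travelled",
            "arrived",
            "efficiency",
        ],
    )


def run_replicates(
    condition: str | ConditionSpec,
    weights: NavigationWeights,
    precisions: PrecisionSchedule | None = None,
    lesion: LesionSpec | None = None,
    n_reps: int = 50,
    base_seed: int = 0,
    *,
    world_kwargs: dict | None = None,
    keep_paths: bool = False,
) -> ExperimentResult:
    """Run ``n_reps`` independently seeded repetitions of a condition."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    spec = condition if isinstance(condition, ConditionSpec) else ConditionSpec(condition)
    precisions = precisions or PrecisionSchedule()
    all_records: list[JourneyRecord] = []
    memories: dict[tuple[int, int], list[int]] = {}
    for run in range(n_reps):
        all_records.extend(
            run_condition(
                spec,
                weights,
                precisions,
                lesion,
                run_seed=base_seed,
                run=run,
                world_kwargs=world_kwargs,
                keep_paths=keep_paths,
                memories=memories,
            )
        )
    kw = dict(world_kwargs or {})
    probe = build_world(**{**kw, "landmark_seed": 0, "n_landmarks": 0})
    frame = _frame_from_records(all_records, probe.start_goal_distance)
    return ExperimentResult(
        condition=spec.name,
        weights=weights,
        precisions=precisions,
        lesion=lesion,
        base_seed=base_seed,
        n_reps=n_reps,
        spec=spec,
        frame=frame,
        records=all_records if keep_paths else None,
        memories=memories,
        world_kwargs=kw,
    )


def weight_grid(
    w_goal: Sequence[float] = tuple(np.round(np.arange(0.05, 0.351, 0.05), 2)),
    w_social: Sequence[float] = tuple(np.round(np.arange(0.05, 0.351, 0.05), 2)),
    w_memory: Sequence[float] = tuple(np.round(np.arange(0.05, 0.501, 0.05), 2)),
) -> list[NavigationWeights]:
    """The sweep grid: all (goal, social, memory) combinations with sum
    <= 1; continuity makes up the difference."""
    out = []
    for g, s, m in itertools.product(w_goal, w_social, w_memory):
        tot = round(g + s + m, 10)
        if tot <= 1.0 + 1e-12:
            out.append(NavigationWeights(g, s, m, round(1.0 - tot, 10)))
    return out


def sweep_weights(
    grid: Sequence[NavigationWeights] | None = None,
    conditions: Sequence[str] = CONDITIONS,
    n_reps: int = 50,
    base_seed: int = 0,
    precisions: PrecisionSchedule | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Aggregate final efficiency and generational increase over a weight
    grid: one row per (weight combination, condition)."""
    grid = list(grid) if grid is not None else weight_grid()
    rows = []
    for w in grid:
        for cond in conditions:
            res = run_replicates(cond, w, precisions, n_reps=n_reps, base_seed=base_seed, **kwargs)
            s = metrics.summarize(res)
            rows.append(
                {
                    "condition": cond,
                    "w_goal": w.goal,
                    "w_social": w.social,
                    "w_memory": w.memory,
                    "w_continuity": w.continuity,
                    **{f"final_efficiency_{k}": v for k, v in s["final_efficiency"].items()},
                    **{
                        f"generational_increase_{k}": v
                        for k, v in s["generational_increase"].items()
                    },
                }
            )
    return pd.DataFrame(rows)


def precision_variation(component: str, level: str) -> PrecisionSchedule:
    """Precision schedule for the precision-control suite.

    ``level`` is one of ``very_high``, ``high``, ``normal``, ``low``:
    *high* halves and *low* doubles the component's circular-SD
    equivalent before converting back to kappa; *very_high* uses fixed
    near-deterministic kappas.  For memory, the whole ramp is replaced by
    the single resulting kappa (journey 1 remains uniform).
    """
    if component not in COMPONENTS:
        raise ValueError(f"unknown component {component!r}")
    base = PrecisionSchedule()
    if level == "normal":
        return base
    if level == "very_high":
        kappa = VERY_HIGH_KAPPA[component]
    else:
        ref = {
            "goal": base.goal,
            "social": base.social,
            "continuity": base.continuity,
            "memory": base.memory_plateau,
        }[component]
        sd = circular_sd_from_kappa(ref)
        if level == "high":
            kappa = kappa_from_circular_sd(sd / 2.0)
        elif level == "low":
            kappa = kappa_from_circular_sd(sd * 2.0)
        else:
            raise ValueError(f"unknown precision level {level!r}")
    if component == "memory":
        return base.replace_memory(kappa)
    return PrecisionSchedule(**{**base.__dict__, component: kappa})
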