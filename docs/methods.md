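# Model and methods

## The navigation model

Agents move at constant speed (1 map unit per time unit) on a 200 × 130
unit map, from a fixed start (48, 65) to a fixed goal (152, 65), 104
units apart. At every time step an agent draws one sample from each of
up to four Von Mises distributions and sets its next heading to their
weighted circular mean

    h(t+1) = atan2( Σₖ wₖ sin aₖ , Σₖ wₖ cos aₖ ),

with weights w = (w_goal, w_social, w_memory, w_continuity) summing
to 1 and fixed at agent initialisation. The components are

| component  | centre of the distribution                              | κ (default)  | SD equiv. |
|------------|---------------------------------------------------------|--------------|-----------|
| goal       | bearing to the goal                                     | 1.54         | 1.00      |
| social     | convergence/alignment composite (see below)             | 2.18         | 0.80      |
| memory     | bearing to the next memorised landmark                  | 0 → 1.82, 2.29, 2.98, 4.19 → 6.78 | 0.9 → 0.4 |
| continuity | current heading                                         | 8.69         | 0.35      |

κ and circular SD are interconverted through sd = √(−2 ln R̄(κ)) with
R̄ = I₁(κ)/I₀(κ); κ = 0 encodes the uniform circular distribution.

**Social proximity** (pairs only) mixes a *convergence* sample — a VM
draw centred on the bearing to the partner's dead-reckoned position one
step ahead — with an *alignment* sample centred on the partner's current
heading. The two draws are combined as a two-element weighted circular
mean with weights (p, 1 − p), where p = Φ((d − 0.5)/0.1) for
inter-agent distance d: distant partners are converged upon, close
partners are aligned with. Two draws are consumed every step regardless
of the regime, so the social stream is reproducible across variants.

**Route memory** is formed on an agent's first journey: at every
position, the nearest landmark within the capture threshold (10 units =
10 × the per-step travel distance) is committed to memory, deduplicating
consecutive repeats. The resulting sequence — roughly one landmark per
two units of path — is frozen when the first journey ends. On later
journeys the agent navigates toward the current target landmark of the
sequence and moves on to the next *one landmark per time step* whenever
it is within the capture threshold of the current one. This pacing is
load-bearing: re-tracing a tortuous first journey through a dense
sequence costs close to the original journey's travel, so route quality
(and its improvement) is inherited between journeys and, through naive
partners memorising the pair's path, between generations. A catch-up
progression rule ("skip": advance past every in-range landmark at once)
and two alternative memorisation strategies ("spaced", "all_in_range")
are kept as configuration hooks; both flatten or destroy the
intergenerational improvement and are not defaults.

On an agent's first journey the memory component has no route to point
at: it stays in the mixture with its weight but draws from the uniform
distribution (κ = 0). From the second journey on, κ_memory follows the
experience-indexed ramp in the table (per-agent, not per-condition),
plateauing at 6.78 from the sixth journey. A journey-2+ agent whose
sequence is empty or exhausted drops the component and its weight is
redistributed proportionally over the active ones — as happens for the
social component of a solo agent and for continuity on the first step of
a journey (no previous heading).

**Arrival and caps.** A journey ends when the agent comes within one
step distance (1 unit) of the goal — it could step onto it — or when it
has travelled 2,506 units. Route efficiency is start–goal distance /
travelled distance for arrivals (clipped at 1, since arrival within the
radius can shave a fraction of a unit) and 0 otherwise. The arrival
radius is a model constant the efficiency scale is directly sensitive
to; one step distance is the only choice that reproduces the reported
final-efficiency levels of all three conditions simultaneously (a
10-unit radius, for instance, inflates them to ≈ 0.99).

## Conditions and experiments

* **solo** — one agent, 60 journeys; **pair** — two agents, 60 journeys;
  **experimental** — generation 1 is one agent alone for 12 journeys, a
  naive partner is added for generation 2, and at each later
  generation boundary the most experienced agent is replaced by a fresh
  naive one (5 generations × 12 journeys, 5 distinct agents).
* **Lesions** replace a component's samples with uniform noise while
  keeping its weight; the goal lesion optionally spares generation 1.
* **Precision variants** halve or double one component's circular-SD
  equivalent and convert back to κ (memory: the whole ramp collapses to
  the single resulting κ; journey 1 stays uniform).
* 50 independently seeded repetitions per cell. Every
  (run, agent, journey, component) tuple owns a counter-based PCG64
  stream, so repetitions are independent, reruns are bit-identical, and
  lesioning one component never perturbs another's draws. The landmark
  field (6,500 uniform points) is redrawn per repetition from a seed
  derived from the run key.

## Data reduction

Per journey, pair members' efficiencies are averaged; per generation,
the best of its 12 journeys represents it; final-generation efficiency
is generation 5's best, averaged over runs. The generational increase is
the mean difference between consecutive generations' bests, omitting the
single-agent first generation in the experimental condition (3
differences; solo and pair use their 12-journey blocks as
pseudo-generations, 4 differences). The goalward-bearing statistic
evaluates, at every step with both pair members active in generations
2–5, Δ = wrap(bearing(experienced → naive) − bearing(experienced →
goal)); the "goalward fraction" is the share of |Δ| < π/2.

## Fitting

`fitkit` estimates weights (on the simplex, via logits) and component
spreads (on the log circular-SD scale) from trajectories by maximum
likelihood with multi-start L-BFGS-B. Component centres are
reconstructed from the trajectory context; the memory component needs
the memorised landmark sequence, which the simulator exports but which
is unobservable for real animals — fitting field data therefore
requires an explicit landmark-sequence provider, and the social centre
collapses the convergence/alignment composite to its mean direction.

Because the generative update *averages* one sample per component, the
heading's law is not the Von Mises mixture itself; fitting the naive
mixture density mis-attributes nearly all weight to continuity. The
default likelihood ("mean" method) therefore models the heading as Von
Mises around the direction of the mean resultant Σ wₖR̄(κₖ)u(μₖ), with a
concentration obtained by moment-matching the resultant's transverse
variance. This linearisation is accurate for the concentrations the
model actually uses; component-wise mean absolute error of recovered
weights over ten grid-drawn settings is ≤ 0.1 (most ≈ 0.03–0.07).
Circular SDs are bounded to [0.05, 2.0]: components more diffuse than
SD 2 are directionally near-uniform and would otherwise form an
identifiability ridge (weight can be padded onto them without changing
the implied heading law). A single memory κ is fitted for journeys ≥ 2
(the generative ramp makes it an effective average); journey-1 memory
enters as the uniform density.

GPS preprocessing mirrors the homing-pigeon pipeline: forward transverse
Mercator projection (Karney-style 6th-order Krüger series, written
in-package and verified against a meridian-arc quadrature oracle),
sample-wise speed filtering to [25, 150] km/h, whole-flight exclusion
when any fix strays beyond twice the start–goal distance from the route
midpoint or the goal is never approached, and downsampling to one fix
per 20 s.

## What the synthetic data does and does not show

The simulator *is* the study system here: all quantitative checks run on
its output, and the fitting module is validated by parameter recovery on
trajectories whose generating parameters are known. Real GPS tracks
differ in ways the generator does not emulate — variable speed and
sampling rate, spatially structured landmark salience, wind, fatigue,
and leadership asymmetries — so passing recovery tests demonstrate the
estimator is consistent for this model class, not that the model
captures everything pigeons do.

## Numerical choices and degenerate inputs

* Angles live in (−π, π]; wrapping uses IEEE remainder with the boundary
  mapped to +π.
* κ ↔ SD conversion uses exponentially scaled Bessel functions and
  Brent root-finding (round-trip < 1e-8 relative).
* A weighted circular mean whose resultant is below 1e-12 (perfectly
  opposed samples) raises a dedicated error; the navigator's tie-break
  is to retain the previous heading (goal bearing on a first step).
* Coincident agents: the convergence bearing is undefined, so the social
  sample falls back to alignment; if the partner also has no heading yet
  (both at the start point), the social component is inactive that step.
* Zero-weight components are never sampled; lesioned components are
  sampled from a dedicated noise stream.
* Efficiency of a journey with zero travelled distance is undefined and
  raises.

## Known limitations

* The landmark memorisation rule and the arrival radius are
  under-determined by the published description; the defaults here are
  the readings that jointly reproduce the reported efficiency levels,
  the intergenerational improvement, and the lesion signatures, and the
  alternatives remain available as configuration.
* Pairs only (no larger flocks), constant speed, no environmental
  structure beyond the landmark field.
* The averaged-sample likelihood is a first-order approximation; at very
  diffuse settings (circular SD ≳ 1.5 on dominant components) weight
  attribution between goal and a goal-directed memorised route degrades.
* Reported pigeon parameter estimates are not reproduced here: they
  require the external GPS dataset. The pipeline supports such data but
  no result in this package depends on it.
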