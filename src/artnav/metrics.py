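"""Route-efficiency metrics and the goalward-bearing ("regression to the
goal") analysis.

Route efficiency is the start-goal distance divided by the distance
actually travelled, set to 0 when the goal was never reached; it ranges
from 0 to 1 (straight line).  The generation-level statistics follow the
data-reduction scheme of the study design: efficiencies are averaged
between paired agents, the most efficient journey represents each
12-journey generation, and the intergenerational increase is the mean
difference between consecutive generations' best efficiencies (the
single-agent first generation of the experimental condition is omitted).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "route_efficiency",
    "final_generation_efficiency",
    "generational_increase",
    "summarize",
    "BearingBias",
    "goalward_bearing_bias",
    "plot_efficiency_curves",
]


def route_efficiency(record, start_goal_distance: float = 104.0) -> float:
    """Start-goal distance / travelled distance; 0 if the goal was never
    reached.

    Clipped at 1: arrival is detected within a small radius of the goal,
    so a near-straight path can log marginally less than the full
    start-goal distance.
    """
    travelled = float(record.travelled)
    if travelled <= 0.0:
        raise ValueError("journey with no travelled distance")
    if not record.arrived:
        return 0.0
    return min(1.0, start_goal_distance / travelled)


def _best_per_generation(frame: pd.DataFrame) -> pd.DataFrame:
    """Per (run, generation): the best journey efficiency, where each
    journey is first averaged over the agents that flew it."""
    per_journey = (
        frame.groupby(["run", "generation", "journey"], sort=True)["efficiency"]
        .mean()
        .reset_index()
    )
    return per_journey.groupby(["run", "generation"], sort=True)["efficiency"].max().unstack()


def final_generation_efficiency(result, per_run: bool = False):
    """Best of the final generation's 12 journeys (agent-averaged),
    averaged over runs (or per run with ``per_run=True``)."""
    n_gen = result.spec.n_generations
    frame = result.frame
    if frame["generation"].max() < n_gen:
        raise ValueError("final generation missing from result")
    best = _best_per_generation(frame)
    series = best[n_gen]
    return series if per_run else float(series.mean())


def generational_increase(result, per_run: bool = False):
    """Mean difference between consecutive generations' best
    efficiencies, per run, averaged over runs.

    In the experimental condition the single-agent first generation is
    omitted (3 differences over generations 2-5); solo and pair use all
    12-journey blocks as pseudo-generations (4 differences).
    """
    best = _best_per_generation(result.frame)
    if result.condition == "experimental":
        best = best.drop(columns=[1])
    if best.shape[1] < 2:
        raise ValueError("need at least two scorable generations")
    diffs = best.diff(axis=1).iloc[:, 1:]
    series = diffs.mean(axis=1)
    return series if per_run else float(series.mean())


def summarize(result) -> dict:
    """Mean / SD / SEM over runs of final efficiency and generational
    increase."""
    out = {}
    for name, fn in (
        ("final_efficiency", final_generation_efficiency),
        ("generational_increase", generational_increase),
    ):
        per_run = fn(result, per_run=True)
        n = len(per_run)
        sd = float(per_run.std(ddof=1)) if n > 1 else float("nan")
        out[name] = {
            "mean": float(per_run.mean()),
            "sd": sd,
            "sem": sd / math.sqrt(n) if n > 1 else float("nan"),
            "n": n,
        }
    return out


@dataclass
class BearingBias:
    """Signed offsets between the experienced agent's bearing to its
    naive partner and its bearing to the goal, pooled over time steps."""

    offsets: np.ndarray  # radians in (-pi, pi]
    generations: np.ndarray  # generation label per offset

    @property
    def goalward_fraction(self) -> float:
        """Fraction of observations with |offset| < pi/2 (partner seen on
        the goalward side)."""
        return float(np.mean(np.abs(self.offsets) < math.pi / 2))

    def per_generation(self) -> dict[int, float]:
        return {
            int(g): float(np.mean(np.abs(self.offsets[self.generations == g]) < math.pi / 2))
            for g in np.unique(self.generations)
        }

    def histogram(self, bins: int = 36) -> tuple[np.ndarray, np.ndarray]:
        return np.histogram(self.offsets, bins=bins, range=(-math.pi, math.pi))


def goalward_bearing_bias(result, world) -> BearingBias:
    """Relative bearing of the naive partner as seen by the experienced
    agent, relative to the goal direction, in generations 2-5 of the
    experimental condition.

    For each time step with both pair members active, the offset is
    wrap(bearing(experienced -> naive) - bearing(experienced -> goal)):
    0 means the naive partner sits exactly on the experienced agent's
    line to the goal, |pi| diametrically away from it.  Requires a
    result run with ``keep_paths=True``.
    """
    if result.condition != "experimental":
        raise ValueError("bearing bias is defined for the experimental condition")
    if result.records is None:
        raise ValueError("result has no stored paths; rerun with keep_paths=True")
    gx, gy = world.goal
    offsets: list[np.ndarray] = []
    gens: list[np.ndarray] = []
    by_key: dict[tuple[int, int], list] = {}
    for r in result.records:
        if r.generation >= 2:
            by_key.setdefault((r.run, r.journey), []).append(r)
    for (_, _), pair in by_key.items():
        if len(pair) != 2:
            continue
        naive = next((r for r in pair if r.naive), None)
        exp = next((r for r in pair if not r.naive), None)
        if naive is None or exp is None:
            continue
        n = min(len(naive.positions), len(exp.positions))
        ex, ey = exp.positions[:n, 0], exp.positions[:n, 1]
        nx, ny = naive.positions[:n, 0], naive.positions[:n, 1]
        dx, dy = nx - ex, ny - ey
        ok = (dx != 0) | (dy != 0)  # coincident points (the shared start)
        b_naive = np.arctan2(dy[ok], dx[ok])
        b_goal = np.arctan2(gy - ey[ok], gx - ex[ok])
        d = np.remainder(b_naive - b_goal + math.pi, 2 * math.pi) - math.pi
        d[d <= -math.pi] += 2 * math.pi
        offsets.append(d)
        gens.append(np.full(d.shape, pair[0].generation, dtype=int))
    if not offsets:
        raise ValueError("no paired observations found")
    return BearingBias(np.concatenate(offsets), np.concatenate(gens))


def plot_efficiency_curves(results: dict, path: str, ci: float = 0.95) -> None:
    """Mean route efficiency vs journey number per condition, with
    normal-approximation confidence bands; saved to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy import stats

    z = stats.norm.ppf(0.5 + ci / 2)
    fig, ax = plt.subplots(figsize=(7, 4))
    for name, result in results.items():
        per = result.frame.groupby(["run", "journey"])["efficiency"].mean().unstack()
        mean = per.mean(axis=0)
        sem = per.std(axis=0, ddof=1) / np.sqrt(per.shape[0])
        ax.plot(mean.index, mean.values, label=name)
        ax.fill_between(mean.index, mean - z * sem, mean + z * sem, alpha=0.25)
    ax.set_xlabel("journey")
    ax.set_ylabel("route efficiency")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
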