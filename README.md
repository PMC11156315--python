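# artnav

Agent-based simulation of collective navigation in which cumulative
route improvements emerge across generations of paired agents — plus
maximum-likelihood fitting of the navigation model to trajectories.

## The problem

Homing birds released repeatedly from the same site develop idiosyncratic
but stable routes. When an experienced individual flies with a naive
partner, and the most experienced member of the pair is periodically
replaced ("generational turnover"), route efficiency improves across
generations — a candidate example of cumulative culture. `artnav`
implements a minimal cognitive architecture showing that this ratchet
needs no communication or evaluation: it emerges from four sampling
rules alone.

Each agent sets its heading by drawing one sample per rule from a Von
Mises distribution Φ and taking the weighted circular mean:

    h(t+1) = w_goal·Φ(b_goal, κ_goal) + w_social·Φ(b̂_other, κ_social)
           + w_memory·Φ(b_landmark, κ_memory,i) + w_continuity·Φ(h(t), κ_continuity)

with weights summing to 1: *goal direction* (a noisy compass bearing to
the goal), *social proximity* (converge on / align with the one
partner), *route memory* (steer for the next landmark memorised on the
agent's own first journey, with precision κ_memory,i growing over
journeys i), and *continuity* (avoid erratic turns). Naive partners have
no route memory and therefore err, on average, toward the goal relative
to the experienced agent's memorised detours; because agents seek
proximity, this "regression to the goal" subtly improves the route each
naive agent memorises — the ratchet.

The package reproduces the phenomenon and its controls: per-generation
route-efficiency statistics, lesion experiments (replacing one rule with
uniform noise), precision experiments (halving/doubling a rule's
circular-SD equivalent), the goalward-bearing analysis, and parameter
recovery by fitting the model back to simulated trajectories. See
`docs/methods.md` for the full model description.

## Worked example

Simulate 10 repetitions of the turnover condition at the
final-efficiency-optimal weights and summarise:

```bash
artnav simulate --condition experimental -w 0.25 0.20 0.05 0.50 \
                --reps 10 --seed 1 --out demo
```

```json
{
  "final_efficiency": {
    "mean": 0.9000898359290439,
    "sd": 0.020446319090873327,
    "sem": 0.0064656938093742965,
    "n": 10
  },
  "generational_increase": {
    "mean": 0.0019918616407873587,
    "sd": 0.010268005339432685,
    "sem": 0.0032470283899377617,
    "n": 10
  }
}
```

`final_efficiency` is the best of the last generation's 12 journeys
(start–goal distance / distance travelled, averaged over pair members),
averaged over the 10 runs: here the pair's best final-generation route
is ~11% longer than the straight line. `generational_increase` is the
mean improvement in per-generation best efficiency between consecutive
generations (first, single-agent generation omitted); at these weights
(memory weight only 0.05) it is small — rerun with
`-w 0.15 0.25 0.40 0.20`, the improvement-optimal weights, to see it
rise to ~0.1 per generation. The same library calls are available in
Python via `artnav.run_replicates(...)` and `artnav.metrics`.

Other entry points: `artnav table1` (lesion suite), `artnav table2`
(precision suite), `artnav fig4` (goalward-bearing bias), `artnav sweep`
(weight grid), `artnav fit` (trajectory fitting), `artnav make-fixtures`
(small synthetic dataset).

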