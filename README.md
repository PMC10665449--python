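# fadsim

Agent-based simulation and analysis of **boredom-driven collective
fashion trends** on a circular color space, together with an empirical
pipeline for monthly color sequences (e.g. magazine-cover colors) in
CIELAB space.

## The model

A population of *n<sub>i</sub>* agents repeatedly chooses colors,
represented as two-dimensional vectors on a circle (angle measured
clockwise from the reference direction [0, 1]; dissimilarity between two
colors is the arc angle δ ∈ [0, π], reported as *d* = δ/π ∈ [0, 1]).

On every trial each agent

1. **chooses** the vector sum of its memory of the last *m* stored
   colors, **y** = Σ<sub>j</sub> **x**<sub>j</sub>;
2. **samples** the displayed choice **z** of one random other agent
   (optionally popularity-weighted);
3. **stores** the sample, unit-normalized and scaled by a sigmoid
   *boredom weight*

   w(d) = 1 / (1 + exp(−20 (d − x₀))),

   where *d* is the angular difference between its own choice and the
   sample; the oldest memory entry drops out.

The shift x₀ encodes boredom proneness: a high x₀ means only very novel
colors (large *d*) receive substantial weight. Memory promotes
convergence of the population, boredom counteracts it; between the two
extremes the population develops transient color trends that cycle
through the color space.

Population read-outs: the **trend color** (angle of the summed
unit-normalized choices), **uniformity** (mean resultant length
‖Σ**ŷ**<sub>i</sub>‖ / n<sub>i</sub>, the Kuramoto-style order
parameter), its **chance threshold** (99th percentile under fully random
choices), the **trend change speed** (arc between consecutive trend
vectors, units of π), and a per-agent **impact index** (sampling-weight
× arc to the next trial's trend). Heterogeneous populations support
highly bored subgroups, tenfold-popular agents, a 17°/trial choice
drift, and a within-subgroup uniformity bias.

## Worked example

```python
import numpy as np
from fadsim import (PopulationConfig, GroupSpec, run_simulation,
                    trend_series, chance_threshold)

thr = chance_threshold(200, iters=10_000, percentile=99, rng=0)
print(f"chance uniformity threshold (n=200): {thr:.3f}")

cfg = PopulationConfig(n_agents=200, n_trials=2000, m=12,
                       groups=(GroupSpec(fraction=1.0, x0=0.7),), seed=1)
ts = trend_series(run_simulation(cfg).choices)
r = np.corrcoef(ts.uniformity[:-1], ts.change_speed)[0, 1]
print(f"max uniformity over 2000 trials:     {ts.uniformity.max():.3f}")
print(f"mean trend change speed (units pi):  {np.nanmean(ts.change_speed):.3f}")
print(f"uniformity vs change-speed Pearson r: {r:.2f}")
```

prints

```
chance uniformity threshold (n=200): 0.153
max uniformity over 2000 trials:     0.494
mean trend change speed (units pi):  0.076
uniformity vs change-speed Pearson r: -0.48
```

Uniformity mostly sits above the chance level 0.153 (a genuine trend
exists) but never approaches 1 (the trend keeps turning over), and
trends change fastest exactly when uniformity is low — the negative
correlation that characterizes the cycling regime. With x₀ = 0.5 the
same population converges to a single color (uniformity → 1); with
x₀ = 0.85 trends barely form.

## Command line

```sh
fadsim simulate --config cfg.yaml --seed 1 --out run/   # choices.csv, trends.csv, summary.json
fadsim threshold --n 200 --iters 10000 --seed 1
fadsim sweep --m 2:20:2 --x0 0.5:0.95:0.05 --out sweep.csv
fadsim analyze --result run/ --subgroup 0 --lags 30
fadsim fixtures --months 268 --regime walk --seed 7 --out colors.csv
fadsim magazine --input colors.csv --bin 8 --shuffle-test --seed 1
```

The `magazine` pipeline reads a `date,r,g,b` CSV of monthly colors,
converts to CIELAB, projects onto the plane of the two leading principal
components, tracks the 8-month moving vector sum of the unit color
vectors, and tests the trend dynamics against time-shuffled null
sequences. `fixtures` generates a synthetic monthly sequence (circular
random walk with occasional jumps) standing in for non-public cover
data.

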