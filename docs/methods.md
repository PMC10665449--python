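# Methods

## Model definition

Agents live on a circular color space. A color is a 2-vector; only its
angle identifies the color, measured clockwise in turn fractions from
the fixed reference [0, 1]. The dissimilarity of two colors is the arc
angle between their vectors divided by π, so *d* ∈ [0, 1] and diametral
colors score 1.

Each agent holds a FIFO memory of exactly *m* vectors, initialized with
independent unit vectors at uniformly random angles. Per trial:

1. *Choice.* **y** = Σ memory entries (no normalization). The displayed
   choice is **y** after the agent's drift rotation and uniformity bias
   (both default off).
2. *Sampling.* The agent draws one partner ≠ itself, with probability
   proportional to partner popularity weights (all 1 by default), and
   reads the partner's displayed choice **z**.
3. *Storage.* It stores w(d) · **ẑ**, where d = d(**y**, **z**) and
   w(d) = 1/(1 + exp(−20(d − x₀))); the oldest entry drops out.

The sigmoid's slope is fixed at 20; only the horizontal shift x₀ is
varied between conditions (an expert override of the slope exists on
`GroupSpec` but is deliberately undocumented elsewhere).

**Storage normalization.** The sampled vector is unit-normalized before
weighting, so the stored length is exactly w(d) ∈ (0, 1). The
alternative — storing w(d)·**z** with the partner's raw length — makes
the influence of an agent proportional to its memory coherence;
empirically that variant collapses into near-complete uniformity in all
tested regimes (max uniformity ≈ 0.98 at x₀ = 0.7), destroying the
trend cycling the model exists to produce. Normalized storage preserves
it. A consequence worth knowing: with normalized storage an agent's
choice *direction* depends only on weight ratios between its memory
entries, and in the logistic tail those ratios, e^{20·Δd}, do not
depend on x₀ — groups with different x₀ therefore differentiate only
through sigmoid saturation (d ≳ x₀). See *Known limitations*.

**Update discipline.** Default `synchronous`: all displayed choices are
frozen at trial start, all samples read from the frozen set, all memory
writes land afterwards. A `sequential` mode (agents in index order,
each sampling its partner's recomputed current choice) is provided for
comparison; both modes consume partner draws from one stream in
(trial, agent) order, so they are comparable seed for seed. Synchronous
is the default because it removes agent-order artifacts.

**Randomness.** One master seed spawns three independent child streams:
memory initialization, partner draws, and the degenerate-direction
fallback. Runs are bit-for-bit reproducible; a literal loop-based
transcription of the rules (in the test tree) agrees exactly with the
vectorized engine in both update modes.

**Degenerate vectors.** A choice can cancel to (near) zero
(‖y‖ < 1e−12). Its direction then falls back to the newest memory
entry's direction, or, if that is also degenerate, to a random unit
vector from the dedicated stream; occurrences are counted in the run
summary. Degenerate members are skipped (but still counted in the
denominator) when computing trend vectors and uniformity.

## Heterogeneity

Groups occupy contiguous agent-index blocks; group sizes are fractions
× n rounded to nearest (ties up), any remainder absorbed by the last
group. Supported attributes per group: boredom shift x₀, popularity
weight (10× in the trendsetting condition), a clockwise drift of the
displayed choice in degrees per trial, and a uniformity bias.

**Uniformity bias.** A biased member's displayed choice is
**y′** + 0.4 ‖**y′**‖ · **ŝ**, where **s** is the subgroup's summed
unit displayed vector *from the previous trial* (first trial: the
current pre-bias vector). The previous-trial reference was a deliberate
choice: it avoids a within-trial feedback loop *and* lets a drifting
subgroup's common attractor carry the accumulated rotation from trial
to trial — with a same-trial reference the drift can never compound,
because memory only ever stores other agents' colors, and the
drift-propagation experiment is then structurally impossible.

## Metrics

- *Trend color / uniformity*: members are unit-normalized once; the
  summed vector's angle is the trend, its length / n the uniformity.
  Both quantities share one vector sum by construction.
- *Chance threshold*: percentile (default 99) of uniformity over 10,000
  draws of n random unit vectors; ≈ 0.153 at n = 200, scaling ∝ 1/√n.
- *Change speed*: minimal arc between consecutive trend vectors in
  units of π. Algebraically identical to the turn-difference procedure
  (fold differences above half a turn as 1 − diff, then double);
  the equivalence is enforced by a test against that formulation.
- *Impact index* of agent i at trial t: Σ over samplers j of
  w_j(d) × arc(**y**_i, **s**_{t+1}), with the arc in radians (rank
  statistics are unaffected by the unit choice). Requires the engine's
  sampling log (who sampled whom, at what weight), which both update
  modes record.

## Analysis procedures

- *Sweeps* over (m, x₀) grids, one simulation per cell; read-outs are
  max-over-trials uniformity (detects convergence even when late) and
  mean change speed. Default grids m ∈ {2,4,…,20},
  x₀ ∈ {0.50,…,0.95} step 0.05 — grid choices of this package.
- *Mean-boredom matching*: a heterogeneous cell (fraction f at x₀ᵇ over
  residual x₀ʳ) is compared with the homogeneous cell of equal m and
  x₀ = f·x₀ᵇ + (1−f)·x₀ʳ; paired max-uniformity differences go into a
  signed-rank test (skipped below 5 pairs).
- *Lag profiles*: mean arc between the subgroup trend at t and the full
  population trend at t + lag, lag ∈ [−30, +30]. Positive lag = the
  subgroup's pattern appears in the population's future (avantgarde).
- *Drift propagation*: signed residual-trend change per 25 trials
  (positive = clockwise, the drift direction), compared between
  bias-on and bias-off conditions with a one-sided rank-sum test.
- *Shuffle test*: permute the color sequence, smooth both versions with
  the trailing moving vector sum (smoothing always after shuffling),
  compare change-speed distributions one-sidedly (observed < shuffled).
  Identical distributions (e.g. constant series) return p = 0.5
  explicitly. **Caveat:** because the overlapping smoothing window
  autocorrelates both samples, the nominal rank-sum calibration is
  optimistic — on i.i.d. null sequences the rate of p < 0.05 is ≈ 0.12,
  not 0.05. The tests pin this measured calibration; single p-values
  near the threshold should be read accordingly.
- Rank tests delegate to scipy with exact small-sample enumeration
  (n ≤ 25, tie-free) and mid-rank normal approximation otherwise;
  all-zero paired differences return p = 1. The Kolmogorov–Smirnov
  uniformity check rotates the circular origin randomly and subsamples
  100 trend angles before testing against Uniform(0, 1).

## Empirical color pipeline

Monthly RGB colors (CSV `date,r,g,b`) are converted to CIELAB (sRGB,
D65), pooled, and projected onto the plane of the two leading principal
components; each color becomes the clockwise angle of its plane
coordinates. Trends are trailing 8-month moving vector sums of the unit
color vectors — trailing rather than centered to keep the trend causal.
Cross-magazine coherence is the per-month uniformity across the
magazines' unit trend vectors, compared against time-shuffled series.
Dates are ISO year-month; duplicates are an error, gaps are reported,
nothing is imputed.

**Synthetic fixture.** The original cover dataset is not public, so the
package generates a stand-in: a circular random walk (Gaussian steps,
default sd 0.02 turns/month — long low-change phases) with
Poisson-thinned uniform jumps (default rate 0.05/month — short
high-change bursts), optionally attracted to 2–3 fixed hue clusters,
laid out at radius 40 in the (a*, b*) plane at L* = 60 and emitted as
in-gamut RGB. It emulates the qualitative temporal structure of real
cover sequences; it does not emulate their cluster shapes, lightness
variation, gamut edges, or measurement error, so passing pipeline tests
demonstrate procedural correctness, not empirical claims about real
magazines. The walk and i.i.d. regimes serve as positive and null
controls for the shuffle test.

## Problem sizes

The reference experiments use the study conditions throughout: 200
agents, memory 12, 2000 trials, 10 seeds per condition (2000 agents for
the divergence check; memory 10 for the drift and popularity
conditions). Fixture-based calibration runs use 120-month series and
100–200 generator seeds.

## Known limitations

- Quantitative reproduction of the originally reported single-run
  values is partial. The chance threshold (0.153), the convergence
  (x₀ = 0.5 → uniformity 1) and the suppression ordering
  (x₀ = 0.85 < x₀ = 0.7 in every paired seed) reproduce cleanly, as
  does popularity trendsetting (lag minimum at +2 in all seeds). But
  the cycling regimes run ≈ 19% more uniform than reported (10-seed
  median max uniformity ≈ 0.54 vs 0.451 at x₀ = 0.7; ≈ 0.34 vs 0.284
  at x₀ = 0.85), the bored subgroup's lag-profile minimum sits at 0
  (with the correct future-leaning asymmetry) rather than strictly
  positive, the uniformity–impact correlation of the bored subgroup
  comes out ≈ −0.37 rather than +0.44, and the drift propagation is
  directionally right in ~7/10 seeds but rarely significant. All of
  these trace to the storage-normalization consequence noted above:
  below saturation, groups with different x₀ share identical
  directional dynamics, so the bored subgroup differentiates less than
  originally described. Every variant consistent with the published
  update rules that we tested (raw-length storage, sequential updates,
  alternative impact pairings, cumulative drift) reproduces these
  quantities worse, not better.
- The model is deliberately abstract: random mixing (no network
  topology), discrete time, a fixed sigmoid family, no learning of x₀,
  circular geometry only.
- The impact index is reported in radians; only its rank order is
  interpreted.
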