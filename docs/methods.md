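# Methods

## Problem setting

A combination therapy mixes `N` drugs, drug `n` dosed at one of `M_n`
pre-specified concentrations `C_n = {c_n1 < ... < c_nMn}`. A cocktail is a
point `x` on the Cartesian grid `X = C_1 x ... x C_N` (`M = prod M_n`
combinations), and its efficacy is a normalized response `f(x)` with
`0 <= f <= 1` after min–max normalization over the grid. The goal of
closed-loop optimization is to find a *potent* combination — one with
`f(x) >= 0.95`, i.e. within 5% of the grid optimum — while physically
testing as few combinations as possible, since every evaluation is a wet-lab
experiment. Because responses are measured, evaluations carry noise:
`f_obs = f_true + eta`, `eta ~ U(-u, u)`.

## Search algorithms

All searches propose single-level moves and observe the proposed combination
through the measurement oracle.

**Gur Game finite-state automaton.** Each drug holds a fixed reference
concentration, the median of its set. At every step a uniform `r_n` is drawn
per drug; if `f(x^c) > r_n` the drug is *rewarded* — moved one level away
from its reference (clamped at the grid edge) — otherwise *penalized*, moved
one level toward it. The simultaneous variant updates all `N` drugs from the
same response in one iteration; the sequential variant updates one drug per
iteration. The automaton never adapts to the response at hand: responses
below 0.5 everywhere collapse the search onto the reference, responses above
0.5 push it to the grid edges. Both failure modes are covered by tests.

**Informed single-pair search** (`enhanced`). Updates one drug per
iteration. For the chosen drug the last recorded single-level move
`x -> x'` of that drug supplies a direction: if the response rose with
concentration, increasing is deemed beneficial (and conversely). The
beneficial direction is taken with probability
`g = min(1, (1 + alpha * max(f(x), f(x'))) / 2)`, its opposite with `1 - g`.
A drug with no history yet probes a uniformly random direction.

**Adaptive reference update (ARU).** Also one drug per iteration, but the
direction comes from a *reference combination* `x^ref`: the virtual slope
between `(x_n^c, f(x^c))` and `(x_n^ref, f(x^ref))` predicts the beneficial
direction, taken with probability `g = min(1, (1 + alpha *
max(f(x^c), f(x^ref))) / 2)` (always >= 0.5 for responses in [0, 1]). The
reference starts at the trial's initial combination and is replaced whenever
the visit trajectory passes a local maximum — detected from the last three
observed responses `f(t-2), f(t-1), f(t)` with strict inequalities on both
sides — so it tracks the *most recent* local maximum rather than the best
response seen, which keeps the search from dwelling on stale observations.
Anchoring directions to a (typically distant) local maximum reads the
long-range trend of the surface instead of single-step differences.

`alpha` in [0, 1] controls randomness for both adaptive searches:
`alpha = 0` is a symmetric random walk, `alpha = 1` (the default used in all
benchmarks) weights past observations maximally.

### Design choices where the scheme is underdetermined in N dimensions

These points are genuinely open for grids with more than one drug; the
package's choices, and why:

- **Drug selection order** (`drug_order`): sequential algorithms pick the
  drug to update uniformly at random per iteration. Strict round-robin
  cycling, combined with moves that always change exactly one level, freezes
  the walk's joint level-parity pattern: only `2N` of the `2^N` parity
  classes are ever visited, so some combinations — including optima — are
  unreachable from roughly half the starts on 4-drug grids (measured
  success saturates near 6/8 for three drugs and 8/16 for four, exactly the
  reachable-class fractions). Random selection has no such invariant.
  Round-robin remains available as an option.
- **Edge handling** (`edge_mode`): a prescribed move off the grid leaves the
  level unchanged (`clamp`, as in the Gur automaton). The alternative
  (`reflect`, bounce one level inward) preserves the always-move property
  and therefore re-introduces a parity invariant; it is kept as an option.
- **Ties and coincident levels in ARU**: the reference comparison carries no
  direction information for drug `n` when `x_n^c = x_n^ref` or the two
  responses are exactly equal. The update then falls back to the drug's last
  single-level move (the single-pair rule), and only failing that to a
  random probe. With a pure random fallback the reference — which sits
  adjacent to the current point much of the time once local maxima start
  being passed — leaves most updates uninformed, and ARU measurably
  underperforms the single-pair baseline, inverting the efficiency ordering
  the method is designed to deliver. The fallback keeps every update
  anchored to the most recent informative observations.
- **Local-maximum detection** is along the visit trajectory (three
  consecutive observations), the only definition that reduces exactly to the
  one-dimensional picture; plateaus (non-strict maxima) do not trigger an
  update.
- **Gur Game at the reference level**: the automaton's reward/penalty rules
  do not cover `x_n^c = c_n^ref`; a uniformly random feasible one-level move
  is used for both.

## Measurement oracle

Noise is additive uniform on `(-u, u)` applied to the normalized true
response; observed values are deliberately **not** clipped to [0, 1] (the
reward probability is capped at 1 instead). Two revisit strategies:
**type A** caches the first observation of each combination and reuses it on
revisits (no new evaluation is counted); **type B** re-measures every visit.
With `u = 0` the strategies are observationally identical and consume no
random numbers, so noiseless runs are strategy-invariant. Success is always
judged on the *true* response of a visited combination — the benchmark
surfaces are known, the algorithms only ever see the noisy observations.

## Benchmark surfaces

Nine built-in surfaces, evaluated once over their full grid at construction
and min–max normalized to span [0, 1]:

| name | grid | raw function |
|---|---|---|
| `dejong2` | 21 levels on [-2, 2]^2 | Rosenbrock's saddle `100(x1^2 - x2)^2 + (1 - x1)^2` |
| `f3a` | 11 on [-2.5, 2.5]^3 | `x1^2 sin^2(x2) cos^2(x3)` |
| `f3b` | 11 on [-3, 3]^3 | `peaks(x1, x2) * x3` |
| `f4a` | 11 on [-2, 2]^2 x [-3, 3]^2 | `x1 exp(-(x1^2+x2^2+x3^2+x4^2))` |
| `f4b` | 11 on [-3, 3]^4 | `cos^2(0.3 x1) sin(0.3 x2) tan(0.1 x3) x4` |
| `f5a` | 11 on [-2, 2]^2 x [-4.5, 4.5]^3 | `e^{-x1} cos^2(x2) x3^2 e^{-(x4+2)^2-(x5+3)^2} + e^{-(x4-2)^2-(x5-3)^2}` |
| `f5b` | 11 on [-3, 3]^5 | `(1/2) peaks(x1, x2) cos(0.5 x3) sin(0.5 x4) x5^2` |
| `f6a` | 11 on [-2.5, 2.5]^6 | `e^{-0.75 x1} sin^2(x2) + cos(x3) e^{-0.75(x4^2+x5^2)} x6` |
| `f6b` | 11 on [-2.5, 2.5]^6 | `e^{-0.1(x1^2-x2^2)-0.1(x3^2+x4^2)} cos^2(0.2 x5^3) sin(0.2 x6^3)` |

`peaks` is the standard MATLAB definition. `dejong2` is normalized as-is
(not inverted): the response to maximize peaks where the saddle is largest,
at the corners `(+-2, -2)`, and is below 0.5 over most of the grid — the
over-normalized regime in which the fixed Gur automaton fails. An `invert`
flag flips the orientation (optimum at the Rosenbrock valley `(1, 1)`) for
sensitivity checks. For `f5a` and `f6a` the printed formulas are parsed
literally left-to-right (the trailing exponential/product term is additive);
the grouping is ambiguous in the source material and these two surfaces are
not used for quantitative replication. Surfaces with sign-changing factors
are min–max normalized like the rest, so their "no effect" level sits near
0.5; scale-by-max and raw-response conventions were evaluated and agree
distinctly worse with the published benchmark outcomes.

Tabulated experimental surfaces (e.g. measured inhibition grids) load from
CSV: concentration columns plus a response column, one row per combination
of a complete Cartesian grid; no such measured data ships with the package.

## Benchmark harness

A trial starts at a uniformly random combination (its observation is
iteration 0), runs the algorithm until a visited combination's true response
reaches the threshold (0.95) or the budget is spent: `2M` iterations for two
drugs; 1,000 / 2,000 / 3,000 / 4,000 for three to six (extended linearly
beyond). Reported metrics: success rate over trials; over successful trials
only, the mean number of distinct combinations tested up to and including
the first potent one (the experimental-cost proxy under type-A revisits, the
initial combination counts) and the mean iteration count (the cost proxy
under type-B). The reference setting is 5,000 trials per condition
(`scripts/acceptance.py`); the test suite uses 250–800 trials per condition
to keep its runtime in seconds, with tolerances wide relative to the
corresponding Monte-Carlo standard errors. Per-trial RNG substreams derive
from `SeedSequence([master_seed, trial_index])`, split into separate
algorithm and noise streams, so any trial is reproducible in isolation and
type-A/type-B runs at the same sub-seed are paired. Reruns with the same
configuration and seed are bit-identical.

## What the benchmarks do and do not show

The analytic surfaces are cheap, noise is uniform and homoscedastic, and the
true response is available for success detection. Real dose-response
measurements have heteroscedastic, possibly biased errors, plate/batch
effects, and no ground truth; passing benchmarks here demonstrates correct
algorithm mechanics and the relative merits of the searches on structured
landscapes, not wet-lab performance.

Known limitations: on sign-varying 4-6 drug surfaces this implementation
reaches the optimum with substantially fewer tested combinations than the
numbers published for the original method variants, and its ARU loses more
success rate at the highest noise level (u = 0.08) on `f3b`/`f4a`/`f5b`/
`f6a` than the original reports — the equality fallback inherits some of
the single-pair rule's noise sensitivity. Both deviations trace to N-D
generalization details the source description leaves open; the
corresponding replication checks are left failing rather than tuned.
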