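# Methods

## Decision problem

A resource system occupies one of finitely many states `x` on a grid. At each
decision epoch `t = 0, …, T−1` the manager chooses an action `a` from a finite
(possibly state-restricted) set, receives an immediate return `R(a | x)`, and
the system moves to `x'` with probability `P(x' | x, a)`. For a single known
model, optimal values satisfy the backward recursion

    V_t(x) = max_a { R(a|x) + γ Σ_{x'} P(x'|x,a) V_{t+1}(x') },

with `V_T` a supplied terminal condition (default 0) and `γ ∈ (0, 1]`
(default 1, the cumulative objective). Ties in the maximization within
`tie_tolerance = 1e-10` resolve to the lowest action index, so policies are
deterministic and platform-independent. `brute_force_value` enumerates every
time-and-state policy and evaluates each by the fixed-policy recursion; on
tiny instances it provides an exact, structurally independent oracle.

## Model uncertainty

Structural uncertainty is carried by a finite set of candidate models
`{(P_k, R_k)}` and a *model state* `q`, a probability vector of confidence
weights. After observing a transition `(x, a) → x'` the model state updates
by Bayes' theorem, `q'(k) ∝ q(k) P_k(x' | x, a)`; an observation with zero
likelihood under every positively weighted model raises
`ImpossibleObservationError`. The belief-averaged composite model has kernel
`Σ_k q(k) P_k` and returns `Σ_k q(k) R_k`.

When the model set is a complete cross of two uncertainty factors (e.g.
survival hypothesis × reproduction hypothesis), a `FactorView` splits `q`
into the factor marginal and within-level conditional beliefs. Levels with
zero marginal weight have undefined conditionals and are excluded (they
contribute nothing to any expectation).

## Passive and active adaptive optimization

- **Passive**: solve the belief-averaged model with `q` frozen for the whole
  time frame. This is how model uncertainty typically enters operational
  harvest strategies: uncertainty is accounted for, anticipated learning is
  not.
- **Active**: solve the Bellman equation on the joint (system state, model
  state) space,

      V_t(x, q) = max_a { Rbar(a|x,q) + γ Σ_{x'} Pbar(x'|x,a,q) V_{t+1}(x', q') },

  where `Rbar`/`Pbar` are belief-averaged and `q'` is the Bayes posterior for
  the observed transition. Two implementations are provided:
  `exact_reachable` recurses over the finitely many posteriors reachable from
  the initial belief (exact; memoized; guarded by `max_nodes` because the
  tree can grow exponentially with the horizon), and `grid` performs backward
  induction on a fixed simplex lattice, projecting posteriors back by linear
  interpolation (two models) or nearest lattice point (three or more). Grid
  values converge to the exact values as the resolution grows; the test suite
  checks this on a two-model problem at resolutions 2, 4, 8.

## Information-value metrics

With `V*_k(x)` the optimal value under model `k` alone and `V[x, q]` a
baseline optimum under uncertainty,

    EVPI(x, q) = Σ_k q(k) V*_k(x) − V[x, q].

The baseline is either the passive optimum (default, matching how the metric
is used in harvest management) or the active optimum. EVPXI for a factor is
computed two independent ways, whose algebraic identity is enforced in tests
to 1e-8:

- **direct**: average the within-level baseline optima (under conditional
  beliefs) over the factor marginal, minus the full-set baseline;
- **residual**: full-set EVPI minus the marginal-weighted within-level EVPIs.

`evpxi_single_model` applies the residual decomposition to the hierarchical
split {one model} vs {the rest}. `voi_vs_baseline` replaces the baseline
optimum with the belief-weighted true value of an arbitrary supplied policy;
since that value can only be lower than the active optimum, this metric
dominates active-baseline EVPI. `summarize_gain` reports a surface-weighted
percentage gain, `100 · mean(VOI) / mean(baseline value)`, and raises
`UndefinedGainError` on a zero reference mean.

### Ordering properties and their limits

With the **active** baseline, `EVPI ≥ 0` and `0 ≤ EVPXI ≤ EVPI` are theorems
at any horizon (the belief-MDP value is convex in `q`). With the **passive**
baseline they are not: the frozen-belief averaged model implicitly resamples
the model independently at every step, while the Σ q(k) V*_k term holds one
model fixed, and for horizons ≥ 3 the fixed-policy value is no longer linear
in the kernel. On random hypothesis families at horizon 3 the active optimum
falls below the passive value about half the time, with gaps up to ~1 % of
value; at horizon 2 the fixed-policy value *is* linear in the kernel, so
`active ≥ passive` (hence passive-baseline `EVPI ≥ 0`) is exact there, and
the acceptance test checks it on 100 random two-epoch families. Passive
baseline EVPI is reported raw — never clamped — and values below −1e-8 emit
a warning. On the structured goose family at its defaults, passive-baseline
EVPI is nonnegative everywhere on the state grid, which the tests verify as
an empirical property of that family, not as a theorem.

## The synthetic goose family

The demonstration family mimics the structure of migratory-goose harvest
management without using any fitted parameter values; every coefficient is
synthetic and chosen only for qualitative realism.

- **State**: (young, adults, spring-temperature category), young on
  0–30 thousand (step 2.5), adults on 0–120 thousand (step 10), temperature
  cold/average/warm with exogenous probabilities (0.25, 0.5, 0.25).
- **Actions**: harvest rates 0–20 % in 5 % steps; decision precedes the
  annual survival–reproduction cycle.
- **Objective**: harvested thousands × expected utility of next year's total
  population, with utility 1 at the 60-thousand goal, falling quadratically
  to 0 at ±40 thousand. Horizon 50 years, undiscounted.
- **Vital rates**: survival is logistic, reproduction log-linear, both in a
  *density pressure* term `softplus((N_post − 40)/10)·10` and the temperature
  anomaly. The softplus threshold form makes all hypotheses agree at low
  abundance — where every model shares the annual multiplier λ = s(1+r) =
  1.10, as models fitted to one growing time series would — while letting
  them disagree about regulation near and above the goal. Survival carries
  stronger density/temperature contrasts than reproduction: harvest acts on
  survival directly, and in long-lived birds survival variation dominates
  population growth.
- **Hypotheses**: each process is density independent, density dependent, or
  density and temperature dependent → a complete 3 × 3 cross of nine models
  with uniform initial weights.
- **Discretization**: the deterministic update is spread over the grids by a
  normal distribution (sd = 0.15 × mean + 0.5) whose bin masses are CDF
  differences at bin midpoints; edge bins absorb the tails, so kernels are
  exactly stochastic.

Consequences at default settings, verified by tests: density-dependent
survival models reach zero-harvest equilibria between 60 and 75 thousand
(inside the intended 60–90 band; density-independent survival cannot have an
interior equilibrium and grows to the grid cap); the EVPI surface peaks
exactly on the 60-thousand goal band; the EVPI over the (P(survival density
dependent), P(reproduction density dependent)) belief square is zero at the
four certainty corners and maximal strictly inside; survival EVPXI (3.3 %
gain) exceeds reproduction EVPXI (2.0 %), with overall EVPI near 5 %.
Zeroing all density/temperature coefficients collapses the nine models into
one and drives every metric to zero.

## Numerical conventions

- Kernel rows must be stochastic to 1e-9; model-state weights sum to 1 within
  1e-9.
- Reachable-belief memoization keys round beliefs to 12 decimals.
- Tie-breaking tolerance 1e-10; direct/residual EVPXI agreement enforced to
  1e-8; solver-vs-oracle agreement to 1e-9 or better.
- All CSV exports use `\n` line endings and fixed column orders, so repeated
  runs are byte-identical.

## Limitations

- `exact_reachable` is exponential in the horizon for generic kernels; use
  the grid mode (or accept the `max_nodes` guard) for long-horizon active
  analysis. Grid mode with ≥ 3 models uses nearest-neighbor projection,
  which converges slowly; its resolution is the accuracy knob.
- Passive-baseline metrics are not sign-guaranteed beyond two epochs (see
  above); interpret small negative values as a property of the frozen-belief
  construction.
- The goose family is a synthetic stand-in: qualitative patterns are
  meaningful, absolute magnitudes are not.
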