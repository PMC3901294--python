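# Methods

## Problem setting

A constraint-based metabolic model with `N` reactions and `M` metabolites
confines the flux vector `x` to the polytope

```
S = { x :  m_i <= x_i <= M_i ,   sum_i xi_{i,mu} x_i = gamma_mu }
```

where `xi` is the signed stoichiometric matrix (stored metabolites x
reactions; rows are constraints) and `gamma_mu` is the exchange rate of
species `mu` with the environment: exactly 0 for internal metabolites, a
fixed value, or uniformly distributed over a window `[m_mu, M_mu]`.
Reversibility is encoded purely through flux bounds; units are opaque and
never converted.  The package estimates the *marginal density* of every
flux (and the posterior of every windowed exchange rate) over the uniform
measure on `S`, by two independent routes.

## Weighted belief propagation (`wbp_engine`)

The bipartite reaction-metabolite graph is treated as locally tree-like.
Each directed edge reaction `i` -> metabolite `mu` carries a message
`P_{i->mu}`: the density of flux `i` with `mu`'s constraint removed.
Messages are represented as **weighted populations**: `Q` fixed, equispaced
support points spanning `[m_i, M_i]` whose *weights* evolve (positions never
move).  This representation is what makes flux ranges spanning orders of
magnitude harmless — no global binning is ever needed, and rescaling one
flux's bounds together with its stoichiometric column is a pure
reparameterisation.

One update evaluates, for every population point `x_q` of edge `(i, mu)`,

```
alpha_q  =  prod_{nu in i \ mu}  L_{nu->i}(x_q)
```

where `L_{nu->i}(x)` is the probability that metabolite `nu`'s balance
holds when flux `i` is pinned at `x`.  `L` is estimated by Monte Carlo with
the rejection-free sampler below: the remaining neighbours of `nu` are drawn
jointly under the single linear constraint, and the mean importance weight
over `n_draws` draws is the estimate.  Exchanged metabolites with a window
prior carry an explicit extra variable (coefficient -1, uniform population
on the window), so their posterior falls out of the recorded draws of the
final pass.  After the sweeps, the full marginal of flux `i` is the product
of *all* incoming `L` factors on the grid, normalised to integrate to one by
the trapezoid rule.

### Rejection-free weighted sampling (`constrained_sampling`)

To draw `(x_1 .. x_d)` under `sum_l c_l x_l = c`, one designated variable is
solved for; the others are sampled sequentially.  Before sampling variable
`l`, interval arithmetic over the not-yet-sampled variables gives the exact
range the remaining sum can cover; variable `l` is drawn from its population
*truncated to the feasible window* that keeps the constraint satisfiable,
and the window's share of the population mass multiplies the draw's weight.
The solved variable is then set exactly and contributes
`density(x_k)/|c_k|` (the Jacobian of the delta function).  No draw is ever
discarded: an unsatisfiable residual yields weight 0, which only happens
when the constraint itself is infeasible for the pinned value.  Interval
targets (exchange windows) sample *all* variables with windows guaranteeing
the final sum lands in the window.

Numerical choices:

* **Solved-variable density.**  The population has no intrinsic density, so
  the delta-function factor is evaluated on a piecewise-constant histogram
  of the population with `B = 50` equal-width bins over the support
  (configurable).  This is cheap and deterministic given the population.
* **Solved-variable choice.**  The scalar entry point picks, per draw, the
  variable with the widest feasible window (ties broken by largest
  |coefficient|, then declaration order).  The vectorised batch engine —
  the one the message-passing solver actually calls — fixes the solved
  variable for the whole batch as the largest-|coefficient| variable, which
  is the numerically safest divisor and lets the sequential windows
  vectorise across draws.
* **Sampling order.**  A fresh uniform random permutation of the non-solved
  variables per draw (the estimator is unbiased for any order; mixing
  orders symmetrises residual order effects on the weight distribution).
* **Emptiness tolerance.**  Windows are declared empty only below a 1e-12
  relative tolerance; float-thin windows collapse to their midpoint.
* Populations with equispaced support points use O(1) arithmetic window
  indexing instead of binary search.

### Protocol parameters

`WBPConfig` defaults are sized for benchmark-scale networks: `Q = 500`
points per message, 30 iterations, `1000*t` Monte Carlo draws per grid point
at iteration `t`, and 1e5 draws per edge for the final assembly.  Updates run
sequentially in a fixed edge order (reaction-major), so runs are exactly
reproducible from the seed; damping (default 0) and early stopping (default
off) are exposed for loopy instances.  A message whose weights all vanish
("starved") aborts with a diagnostic naming the edge — it indicates an
infeasible or near-infeasible instance, and silently renormalising would
hide that.

The test suite and the acceptance script run *reduced* schedules — e.g.
`Q = 150..200`, 2-6 iterations, `60*t`-`100*t` draws per point, 6000-8000
final draws — chosen so the whole suite completes in minutes.  Reducing
draw counts only adds Monte Carlo noise, so the fixed accuracy thresholds
in the tests are conservative with respect to the full protocol.  Problem
sizes used by each check are stated in the tests themselves.

## Kernel hit-and-run (`khr_sampler`)

The internal balances `S_int x = 0` (plus any *fixed* exchange rates and any
*pinned* fluxes `m_i = M_i`, which are folded into the same equality system
so the polytope stays full-dimensional) are eliminated exactly: an
orthonormal null-space basis `Phi` (N x K, SVD; rank counts singular values
above 1e-10 times the largest) gives `x = x_p + Phi y`, with `x_p` a
least-squares particular solution.  Every flux box and exchange window
becomes one row of the projected system `lo <= Psi y <= hi`.  Hit-and-run
then runs in `K` dimensions: an isotropic random direction, the exact
feasible chord through the current point, a uniform point on the chord.
Uniformity on a bounded convex body is a classical result, and the linear
lift preserves it.  Mixing time grows roughly as `K^3`, which is the point
of the reduction: `K = N - rank(S_int)` is typically far smaller than `N`
(12 instead of 46 for the human red-blood-cell benchmark shape).

Choices and safeguards:

* **Boundedness** is certified at construction by maximising each `+/- y_k`
  with an LP; finite flux boxes make genuine unboundedness impossible, so
  this doubles as an infeasibility check.  The same LPs detect
  implicit-equality (point) polytopes, which are returned as the unique
  solution rather than sampled.
* **Initial point**: MinOver-style relaxation (step along the inward normal
  of the worst row, step size `eta_0/(1 + t/1000)` with `eta_0` the
  polytope scale, plus 100 centering steps after feasibility) or the
  Chebyshev center by LP.  Chains started from the same point diverge
  during per-chain burn-in; results are averaged over chains.
* **Defaults**: burn-in 1e4 steps, thinning `10*K`, 3 chains.  The tests use
  shorter burn-in/thinning sized to their polytopes, validated by the
  uniformity checks themselves.
* **No enclosing box** is ever added; the exchange windows and flux boxes
  bound the projected polytope on their own.
* Every emitted sample is re-checked in flux space: internal balances to
  1e-8 relative, boxes and windows to 1e-9.
* No preconditioning/rounding of the polytope is applied; for very
  elongated polytopes the `10*K` default thinning may be optimistic.

## Synthetic instances (`synthetic_networks`)

Random bipartite ensembles emulate the scaling study's shape: `M = N/2`
metabolites, each processing `2 + Poisson(d-2)` reactions (mean exactly
`d`, default 3, minimum 2), signed unit or uniform(0.1, 2) coefficients with
at least one producer and one consumer per metabolite, flux bounds `[0, u]`
with `u = 10**U(-s, s)` (`s = 0` by default), and a fraction (default 0.25)
of metabolites exchanged through a `[-0.5, 0.5]` rate window.  Orphan
reactions are swapped into existing membership slots so the degree law is
preserved.  Instances are certified: full-row-rank internal stoichiometry,
bounded projected polytope, strictly positive Chebyshev radius — otherwise
regenerated, up to a retry cap.

What these instances do *not* emulate: realistic stoichiometric motifs
(cofactor coupling, compartments), correlated bounds from enzymatic rates,
and scale-free degree distributions.  Passing tests on them demonstrates
algorithmic correctness and scaling, not biological fidelity.

Small fixtures with known answers: `star_network(n, total)` (one internal
metabolite, n producers, a pinned drain — the flux polytope is a scaled
simplex, marginals are Beta laws), `chain_network(length, window)` (a linear
pathway whose metabolites have exchange windows; exact marginals by
dense-grid transfer integration in `reference`), and `toy_triangle()` (two
uniform variables and a solved third, density `2(1-x)`).

## Comparing estimates (`diagnostics`)

Agreement is quantified by total-variation distance (half the integrated
absolute density difference, both estimates linearly interpolated onto a
common refined grid) and Kolmogorov-Smirnov distance (max CDF gap).  Point
masses compare as 0/1 by location.  Fixing TV and KS (rather than a visual
overlay of density plots) as the agreement metrics, and the thresholds used
in the tests, are this package's choices.

## Known limitations

* On graphs with short loops the message-passing estimate is biased: the
  cavity factorisation double-counts shared neighbours.  On the random
  ensemble above (N = 40, M = 20) the *mean* per-flux TV against the
  certified uniform sampler is about 0.02, but single fluxes sitting on
  length-4 loops (two reactions sharing two metabolites — the synthetic
  analogue of currency metabolites) reach TV up to about 0.17, and this does
  not shrink with larger populations, more iterations, more draws, or
  damping.  This is a property of the approximation, not of the
  implementation; the uniform sampler is the ground truth in that regime.
* Convergence of the sweeps is not monitored beyond the max L1 weight
  change; loopy instances may oscillate (damping helps stability, not bias).
* The exchange-rate posterior is assembled from a single final pass; its
  resolution is the histogram bin count, not the population size.
* Volumes/entropies are out of scope: all densities are normalised per
  variable.
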