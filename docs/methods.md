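# Methods

## Model and assumptions

The community is a directed bipartite graph of N consumer populations and M
metabolites. The model is purely structural: it asks which presence states
are self-consistent under the rules "a consumer persists iff all its
required metabolites are present" and "a metabolite is present iff at least
one producer persists or it is externally supplied". There are no
abundances, no dynamics, no competition; a consumer producing its own
required metabolite is allowed and handled by the rules as-is.

The analytic layer works on the ensemble level. Requirements per consumer
and producers per metabolite are i.i.d. draws from degree distributions with
PGFs `C(x)` and `M(x)`; the persisting fractions solve
`c* = C(1 - M(1 - c*))`, `m* = 1 - M(1 - c*)`. This is exact in the
infinite, locally tree-like limit of the configuration model; on finite
networks loops and realised-degree fluctuations produce deviations that
shrink like `N^(-1/2)` (checked empirically in the test-suite at
N = 250…4000).

Degree-0 mass matters and is handled explicitly: consumers with no
requirements are unconditionally present and seed the upward cascade;
metabolites with no producers are absent unless supplied and seed the
downward one.

## Parameters

| parameter | meaning | default |
|---|---|---|
| `z_c` | mean requirements per consumer (Poisson) | user-set |
| `z_m` | mean producers per metabolite (Poisson) | user-set |
| `N`, `M` | consumers / metabolites in a simulated network | user-set |
| `sample_retention` (s) | probability a consumer is captured when sampling | 1.0 |
| `supply_fraction` (r) | probability a metabolite is supplied in culture | 0.0 |

All degrees are dimensionless counts. Arbitrary finite pmfs are accepted
wherever a Poisson is; the self-consistency machinery is
distribution-agnostic and only the parametric fold formulas are
Poisson-specific (non-Poisson folds are accessible through brute-force
fixed-point counting).

On the perturbation convention: with `s` the probability that a consumer is
*captured*, binomial thinning gives effective means `y_m = s·z_m` and
`y_c = (1 - r)·z_c`. Formulations that write `y_m = (1 - s)·z_m` are using
`s` for the *removed* fraction; the two are the same model under
`s -> 1 - s`. This package fixes the retention/supply-probability
convention because it makes the ensemble transform and the network-level
operation (delete consumers with probability `1 - s`; flag metabolites
supplied with probability `r`) provably consistent.

## Numerical choices

* **Root finding.** `find_fixed_points` scans `g(c) - c` on a uniform grid
  (default 10^4 points, vectorised through the PGFs) and refines each sign
  change with Brent's method to `tol = 1e-10`. The map is cheap, smooth and
  monotone, so robustness was preferred over continuation methods. Grid
  points that are roots to within `tol` are collected too, so tangencies at
  a fold are reported rather than silently merged; roots closer than twice
  the grid spacing are deduplicated.
* **Stability** is the slope of the discrete self-consistency map:
  `g'(c*) < 1` stable, `> 1` unstable, `|g' - 1| < 1e-6` marginal. The
  marginality band is deliberately far above the refinement tolerance so
  fold detection is explicit. This discrete-map notion matches the monotone
  percolation update used by the simulator.
* **Folds** use the parametric reduction of the Poisson fold conditions
  (`c ln c = -1/z_m`, then `z_c = exp(z_m c)/(z_m c)`), cross-checked in the
  tests against a derivation-free bisection on fixed-point-count changes to
  1e-6. `find_folds` raises rather than reports two folds whose colliding
  roots are closer than 1e-7 (only reachable within ~1e-14 of the cusp).
* **The cusp** is located in two honest stages: bisection on `z_m` for the
  onset of bistability (using the count-change oracle only), then a root
  solve of `g(c) = c`, `g'(c) = 1`, `g''(c) = 0` in `(c, z_c, z_m)`,
  accepted only if the residuals are below 1e-9.
* **Hysteresis sweeps** warm-start each parameter step from the previous
  converged `c*` (default step ~0.01 in `z_c`), mimicking quasi-static
  drift; jump locations are reported as the midpoint of the last pre-jump
  and first post-jump step, i.e. only to sweep resolution.
* **Percolation** sweeps nodes asynchronously in a fresh seeded random
  order per sweep and stops when a sweep changes nothing, with a defensive
  cap of `10(N + M)` sweeps. From the extreme initialisations monotonicity
  guarantees convergence in at most `N + M + 1` sweeps and
  order-independence of the result; the seeded order still makes
  intermediate (random-fraction) initialisations reproducible.
* **Generation** draws end-point degrees i.i.d. from the target
  distribution and partitions start points by an equal-probability
  multinomial conditioned on the realised link total — stub balance is then
  exact for any N, M without mean-degree algebra. Duplicate stub pairings
  (an O(1/N) fraction) are collapsed to simple edges; the presence rules do
  not see multiplicity.

## What the synthetic networks do and do not capture

The generator produces uncorrelated configuration-model networks with
Poisson (or user-supplied) degrees. It emulates the statistical ensemble the
analytics describe — which is the point: agreement between simulator and
analytics validates both implementations. It does not emulate real
communities: empirical requirement/production degrees are unknown and
plausibly heavy-tailed or correlated (generalists, hub metabolites), edges
carry no stoichiometry, and sampling/supply act independently per node.
Passing tests therefore demonstrate internal consistency of the theory and
code, not that any real microbiome sits at particular `(z_c, z_m)`.

## Degenerate inputs and tie-breaks

`z = 0` distributions, edgeless networks, empty consumer sets after total
sampling (`retention = 0`, reported as `c_hat = 0`), and metabolites both
supplied and produced are all well-defined and tested. When a bistable
system is initialised exactly at the unstable root the map iteration stays
there (it is a fixed point); the simulator cannot hit this measure-zero
state.

## Problem sizes

Analytic computations are effectively instantaneous. The simulation studies
use N = M = 2000 with 20 replicates for branch-agreement checks and
N = M = 1000 with 30 replicates per grid point for the sampling-and-culture
grid — sizes at which the binomial and realised-degree standard errors are
already far smaller than every effect being measured, while the whole suite
stays fast enough to run routinely. Exhaustive-enumeration validation of
the percolator uses 200 random networks with `N + M <= 12` (state spaces up
to 4096).

## Known limitations

* Correlated or jointly-distributed degrees are out of scope; the fold
  formulas further assume Poisson degrees.
* The warm-start culture path assumes quasi-static, order-deterministic
  assembly; real enrichment cultures have stochastic dynamics the structural
  model deliberately omits.
* Near the cusp the fold pair separates like the square root of the
  parameter offset, so fold locations within ~1e-7 of each other are
  reported as degenerate rather than resolved.
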