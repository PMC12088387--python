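# crossfeednet

Percolation analysis of microbial cross-feeding networks: how the structure
of metabolic interdependencies — who eats what, who secretes what — limits
the diversity a microbial community can sustain, and why that diversity can
collapse abruptly.

The package is for ecologists and microbiome researchers who want a
structural null model of community persistence: no population dynamics, no
competition terms, just the cascading constraint that consumers need their
required metabolites and metabolites need producers.

## The model

A community is a directed bipartite network of consumer populations and
metabolites. Consumption is a link from a metabolite to a consumer,
secretion a link from a consumer to a metabolite. Presence is determined by
two rules iterated to a fixed point:

* a consumer persists iff **all** the metabolites it requires are present;
* a metabolite is present iff **any** of its producers persists (or it is
  supplied externally).

For a random ensemble with requirement distribution `c_k` (PGF `C(x)`) and
producer distribution `m_k` (PGF `M(x)`), the persisting fractions solve the
self-consistency system

```
c* = C(m*),    m* = 1 - M(1 - c*)    =>    c* = C(1 - M(1 - c*))
```

and for Poisson degrees with means `z_c`, `z_m` this collapses to
`c* = exp(-z_c exp(-z_m c*))`. The map is monotone, so its extreme fixed
points are reached from all-present / all-absent initialisation — exactly as
in the network simulator.

Key structural results implemented here:

* **Tipping points.** For `z_m > e` the fixed-point equation folds: a stable
  and an unstable state collide at two saddle-node values of `z_c`
  (`find_folds`), producing discontinuous jumps in diversity and hysteresis
  (`hysteresis_sweep`). The fold curves meet and annihilate at a **cusp** at
  `z_c = z_m = e` (`find_cusp`); between them lies the bistable region
  (`phase_diagram`).
* **Sampling and culture.** Capturing each consumer with probability `s`
  thins producers to `y_m = s·z_m`; supplying each resource with probability
  `r` thins effective requirements to `y_c = (1-r)·z_c` (binomial thinning,
  Poisson in, Poisson out). The cultured community follows a warm-started
  path through parameter space (`culture_diversity`), which is how a culture
  gets trapped in a low-diversity state even when a high-diversity state
  exists.
* **Simulation.** Configuration-model network generation
  (`generate_network`), seeded asynchronous percolation (`percolate`),
  replicated ensembles (`ensemble_run`), and the staged sample-then-culture
  protocol (`culture_ensemble_run`) validate every analytic claim.

## Worked example

```
$ python examples/solve_diversity.py

z_c = 4.5, z_m = 4.0:
  c* = 0.0143  m* = 0.0554  g'(c*) = 0.242  [stable]
  c* = 0.3933  m* = 0.7926  g'(c*) = 1.468  [unstable]
  c* = 0.8711  m* = 0.9693  g'(c*) = 0.481  [stable]
```

At `z_c = 4.5, z_m = 4` the community is bistable: 87% of consumers persist
if the community assembled intact, but only 1.4% if it has to rebuild from
scratch — the middle root is the unstable threshold between the two basins.
The other examples print the folds (`z_c = 3.4260` and `5.8654` at
`z_m = 4`), the cusp (`z_c = z_m = 2.718282`), a bistable `N = M = 2000`
network whose two percolation fixed points land on both analytic branches
(`c_hat = 0.8725` vs `c* = 0.8711`; `0.0135` vs `0.0143`), and the
sampling/culture paths.

There is also a thin CLI mirroring the library:

```
crossfeednet solve --zc 4.5 --zm 4
crossfeednet folds --zm 4
crossfeednet cusp
crossfeednet generate --n 1000 --m 1000 --zc 3 --zm 4 --seed 1 --out net.tsv
crossfeednet percolate --net net.tsv --init all_present
crossfeednet culture --zc 4 --zm 4 --retention 0.3 --supply 0.9 --simulate
```

Network files are plain TSV: `#consumers`/`#metabolites` headers, optional
`#supplied <met_id>` flags, then `REQ <met> <cons>` and `PROD <cons> <met>`
rows.

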