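"""Iterative percolation of explicit cross-feeding networks.

Presence rules: a consumer is present when ALL the metabolites it requires
are present (vacuously true for requirement-free consumers); a metabolite is
present when ANY of its producers is present, or when it is externally
supplied (a producer-less, unsupplied metabolite is absent).  The percolator
sweeps all nodes in a seeded random order, updating presence asynchronously,
and stops when a full sweep changes no state.

Both rules are monotone, so from the all-present initialisation states only
ever flip present->absent and the process converges to the GREATEST fixed
point of the rules; from all-absent it converges to the LEAST fixed point.
At those extremes the converged state is independent of the update order;
order still matters for intermediate random initialisations, which is why
the sweep order is seeded and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network_gen import CrossFeedingNetwork, generate_network

__all__ = [
    "PercolationResult",
    "percolate",
    "ensemble_run",
    "ensemble_summary",
    "replicate_seeds",
]


@dataclass(frozen=True)
class PercolationResult:
    """Converged presence state and summary fractions."""

    c_hat: float
    m_hat: float
    n_sweeps: int
    consumer_state: np.ndarray  # bool, shape (N,)
    metabolite_state: np.ndarray  # bool, shape (M,)


def _initial_state(
    net: CrossFeedingNetwork, init, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    N, M = net.n_consumers, net.n_metabolites
    if isinstance(init, tuple) and len(init) == 2 and not isinstance(init[0], str):
        cons = np.array(init[0], dtype=bool).copy()
        mets = np.array(init[1], dtype=bool).copy()
        if cons.shape != (N,) or mets.shape != (M,):
            raise ValueError("explicit initial state has wrong shape")
        return cons, mets
    if init == "all_present":
        return np.ones(N, dtype=bool), np.ones(M, dtype=bool)
    if init == "all_absent":
        return np.zeros(N, dtype=bool), np.zeros(M, dtype=bool)
    if isinstance(init, str) and init.startswith("random:"):
        p = float(init.split(":", 1)[1])
    elif isinstance(init, tuple) and init[0] == "random":
        p = float(init[1])
    else:
        raise ValueError(f"unknown init specification: {init!r}")
    if not 0.0 <= p <= 1.0:
        raise ValueError("random init fraction must lie in [0, 1]")
    return rng.random(N) < p, rng.random(M) < p


def percolate(
    net: CrossFeedingNetwork,
    init="all_present",
    seed: int = 0,
    max_sweeps: int | None = None,
) -> PercolationResult:
    """Iterate the presence rules to a fixed point.

    ``init`` is "all_present", "all_absent", "random:p" (or ("random", p)),
    or an explicit (consumer_state, metabolite_state) boolean pair for
    warm-started continuation.  ``seed`` drives both the random
    initialisation (if requested) and the per-sweep node order.
    """
    N, M = net.n_consumers, net.n_metabolites
    rng = np.random.default_rng(seed)
    cons_state, met_state = _initial_state(net, init, rng)
    met_state |= net.supplied

    reqs = net.requirements_by_consumer()
    prods = net.producers_by_metabolite()
    supplied = net.supplied

    cap = max_sweeps if max_sweeps is not None else 10 * (N + M)
    n_nodes = N + M
    sweeps = 0
    while True:
        if sweeps >= cap:
            raise RuntimeError(f"percolation did not converge within {cap} sweeps")
        order = rng.permutation(n_nodes)
        changed = False
        for node in order:
            if node < N:
                new = all(met_state[m] for m in reqs[node])
                if new != cons_state[node]:
                    cons_state[node] = new
                    changed = True
            else:
                j = node - N
                new = bool(supplied[j]) or any(cons_state[c] for c in prods[j])
                if new != met_state[j]:
                    met_state[j] = new
                    changed = True
        sweeps += 1
        if not changed:
            break
    c_hat = float(cons_state.mean()) if N else 0.0
    m_hat = float(met_state.mean()) if M else 0.0
    return PercolationResult(c_hat, m_hat, sweeps, cons_state, met_state)


def replicate_seeds(seed: int, replicates: int) -> list[tuple[int, int]]:
    """Deterministic (network_seed, percolation_seed) pairs per replicate."""
    children = np.random.SeedSequence(seed).spawn(replicates)
    return [
        tuple(int(s) % 2**31 for s in child.generate_state(2)) for child in children
    ]


def ensemble_run(
    N: int,
    M: int,
    z_c: float,
    z_m: float,
    replicates: int,
    init="all_present",
    seed: int = 0,
) -> pd.DataFrame:
    """Percolate ``replicates`` independent random networks.

    Each replicate draws its own network and percolation seeds from a
    spawned seed sequence, so replicate r of an ensemble run reproduces a
    single generate+percolate call with the matching ``replicate_seeds``
    entry.  Returns one row per replicate (c_hat, m_hat, n_sweeps).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rows = []
    for rep, (net_seed, perc_seed) in enumerate(replicate_seeds(seed, replicates)):
        net = generate_network(N, M, z_c, z_m, net_seed)
        res = percolate(net, init=init, seed=perc_seed)
        rows.append(
            {"replicate": rep, "c_hat": res.c_hat, "m_hat": res.m_hat,
             "n_sweeps": res.n_sweeps}
        )
    return pd.DataFrame(rows)


def ensemble_summary(table: pd.DataFrame) -> dict[str, float]:
    """Ensemble means and standard errors of the persisting fractions."""
    n = len(table)
    out = {"replicates": float(n)}
    for col in ("c_hat", "m_hat"):
        out[f"mean_{col}"] = float(table[col].mean())
        out[f"se_{col}"] = float(table[col].std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return out
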