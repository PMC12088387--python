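"""Shared fixtures and independent oracles for the test-suite.

The brute-force fixed-point oracle enumerates every presence state of a
small network and checks the presence rules directly; it is deliberately
independent of the iterative percolator it validates.
"""

from __future__ import annotations

import numpy as np
import pytest

from crossfeednet.network_gen import CrossFeedingNetwork


def brute_force_fixed_states(net: CrossFeedingNetwork) -> np.ndarray:
    """All presence states fixed under the rules, by exhaustive enumeration.

    Returns a boolean array of shape (n_fixed, N + M) with consumers first.
    Feasible only for N + M <~ 16.
    """
    N, M = net.n_consumers, net.n_metabolites
    n = N + M
    R = np.zeros((N, M), dtype=bool)
    for met, cons in net.req_edges:
        R[cons, met] = True
    P = np.zeros((M, N), dtype=bool)
    for cons, met in net.prod_edges:
        P[met, cons] = True
    bits = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
    states = bits.astype(bool)
    cons_s, met_s = states[:, :N], states[:, N:]
    # consumer rule: present iff no required metabolite is absent
    required_absent = (~met_s).astype(np.int64) @ R.T.astype(np.int64)
    cons_rule = required_absent == 0
    # metabolite rule: present iff supplied or any producer present
    met_rule = net.supplied[None, :] | (
        cons_s.astype(np.int64) @ P.T.astype(np.int64) > 0
    )
    fixed = (cons_s == cons_rule).all(axis=1) & (met_s == met_rule).all(axis=1)
    return states[fixed]


def extreme_fixed_state(fixed_states: np.ndarray, which: str) -> np.ndarray:
    """Greatest or least element of the fixed-state lattice, with a check
    that it really dominates (is dominated by) every other fixed state."""
    sums = fixed_states.sum(axis=1)
    idx = int(np.argmax(sums) if which == "greatest" else np.argmin(sums))
    ext = fixed_states[idx]
    if which == "greatest":
        assert np.all(fixed_states <= ext[None, :]), "fixed states not a chain to max"
    else:
        assert np.all(fixed_states >= ext[None, :]), "fixed states not a chain to min"
    return ext


def random_small_network(rng: np.random.Generator, allow_supplied: bool = False):
    """A random dense-ish bipartite network with N + M <= 12."""
    N = int(rng.integers(1, 8))
    M = int(rng.integers(1, 13 - N))
    p_req = rng.uniform(0.0, 0.6)
    p_prod = rng.uniform(0.0, 0.6)
    req = [(m, c) for m in range(M) for c in range(N) if rng.random() < p_req]
    prod = [(c, m) for c in range(N) for m in range(M) if rng.random() < p_prod]
    supplied = (
        rng.random(M) < rng.uniform(0.0, 0.3) if allow_supplied else np.zeros(M, bool)
    )
    return CrossFeedingNetwork(
        n_consumers=N,
        n_metabolites=M,
        req_edges=np.array(req, dtype=np.int64).reshape(-1, 2),
        prod_edges=np.array(prod, dtype=np.int64).reshape(-1, 2),
        supplied=supplied,
    )


def poisson_gof_pvalue(degrees: np.ndarray, z: float) -> float:
    """Chi-square goodness of fit of observed degrees against Poisson(z).

    Upper tail cells are pooled so every expected count stays >= 5.
    """
    from scipy import stats

    n = len(degrees)
    kmax = int(stats.poisson.isf(1e-12, z))
    # smallest K whose pooled tail k >= K still has expected count >= 5
    K = kmax
    while K > 1 and n * stats.poisson.sf(K - 2, z) < 5.0:
        K -= 1
    obs = np.bincount(np.minimum(degrees, K), minlength=K + 1).astype(float)
    exp = np.append(stats.poisson.pmf(np.arange(K), z), stats.poisson.sf(K - 1, z)) * n
    exp *= obs.sum() / exp.sum()
    return float(stats.chisquare(obs, exp).pvalue)


@pytest.fixture()
def toy_self_loop():
    """One consumer that both requires and produces the single metabolite."""
    return CrossFeedingNetwork(
        n_consumers=1,
        n_metabolites=1,
        req_edges=np.array([[0, 0]]),
        prod_edges=np.array([[0, 0]]),
    )
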