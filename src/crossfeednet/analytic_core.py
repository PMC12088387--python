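"""Self-consistency analysis of the cross-feeding percolation model.

The fraction of consumers ``c*`` that can persist in an infinite random
cross-feeding network satisfies the fixed-point equation

    c* = g(c*),  g(c) = C(1 - M(1 - c)),

where ``C`` and ``M`` are the PGFs of requirements-per-consumer and
producers-per-metabolite.  A consumer persists only if *all* its required
metabolites are produced (probability ``C(m*)``); a metabolite is available
if *any* of its producers persists (``m* = 1 - M(1 - c*)``).  For Poisson
distributions with means ``z_c`` and ``z_m`` the map collapses to

    g(c) = exp(-z_c * exp(-z_m * c)).

The map g is non-decreasing on [0, 1] (PGFs have non-negative coefficients),
so at least one fixed point always exists and iteration from either end of
the interval converges monotonically to the extreme fixed points.  Stability
is classified by the slope of the map: ``g'(c*) < 1`` is stable under the
percolation update dynamics, ``> 1`` unstable, and ``|g' - 1|`` within a
marginality band flags a fold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .degree_models import CommunityEnsemble

__all__ = [
    "FixedPoint",
    "self_consistency_map",
    "map_derivative",
    "map_second_derivative",
    "map_residuals",
    "diversity_from_c",
    "classify_stability",
    "find_fixed_points",
    "iterate_map",
]

#: width of the band |g'(c*) - 1| < MARGINAL_TOL inside which a fixed point
#: is labelled marginal (at or indistinguishably near a fold)
MARGINAL_TOL = 1e-6

DEFAULT_SCAN_POINTS = 10_000


@dataclass(frozen=True)
class FixedPoint:
    """A solution of c = g(c) with its metabolite fraction and stability."""

    c_star: float
    m_star: float
    map_derivative: float
    stability: str  # "stable" | "unstable" | "marginal"


def self_consistency_map(ensemble: CommunityEnsemble, c: float) -> float:
    """g(c) = C(1 - M(1 - c)): expected consumer persistence given fraction c."""
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"c must lie in [0, 1]; got {c}")
    m = 1.0 - ensemble.metabolite_dist.pgf(1.0 - c)
    return ensemble.consumer_dist.pgf(m)


def map_derivative(ensemble: CommunityEnsemble, c: float) -> float:
    """g'(c) = C'(1 - M(1 - c)) * M'(1 - c)."""
    m = 1.0 - ensemble.metabolite_dist.pgf(1.0 - c)
    return ensemble.consumer_dist.pgf_derivative(m, 1) * ensemble.metabolite_dist.pgf_derivative(
        1.0 - c, 1
    )


def map_second_derivative(ensemble: CommunityEnsemble, c: float) -> float:
    """g''(c) = C''(.) M'(1-c)^2 - C'(.) M''(1-c)."""
    m = 1.0 - ensemble.metabolite_dist.pgf(1.0 - c)
    mp = ensemble.metabolite_dist.pgf_derivative(1.0 - c, 1)
    mpp = ensemble.metabolite_dist.pgf_derivative(1.0 - c, 2)
    cp = ensemble.consumer_dist.pgf_derivative(m, 1)
    cpp = ensemble.consumer_dist.pgf_derivative(m, 2)
    return cpp * mp * mp - cp * mpp


def map_residuals(ensemble: CommunityEnsemble, grid: np.ndarray) -> np.ndarray:
    """Vectorised g(c) - c over an array of c values (used by root scans)."""
    grid = np.asarray(grid, dtype=float)
    m = 1.0 - ensemble.metabolite_dist.pgf_vec(1.0 - grid)
    return ensemble.consumer_dist.pgf_vec(m) - grid


def diversity_from_c(ensemble: CommunityEnsemble, c_star: float) -> float:
    """Metabolite fraction m* = 1 - M(1 - c*) implied by a consumer fraction."""
    if not 0.0 <= c_star <= 1.0:
        raise ValueError(f"c_star must lie in [0, 1]; got {c_star}")
    return 1.0 - ensemble.metabolite_dist.pgf(1.0 - c_star)


def classify_stability(
    ensemble: CommunityEnsemble, c_star: float, marginal_tol: float = MARGINAL_TOL
) -> tuple[float, str]:
    """Slope of the map at a fixed point and its stability label."""
    slope = map_derivative(ensemble, c_star)
    if abs(slope - 1.0) < marginal_tol:
        label = "marginal"
    elif slope < 1.0:
        label = "stable"
    else:
        label = "unstable"
    return slope, label


def find_fixed_points(
    ensemble: CommunityEnsemble,
    tol: float = 1e-10,
    scan_points: int = DEFAULT_SCAN_POINTS,
    marginal_tol: float = MARGINAL_TOL,
) -> list[FixedPoint]:
    """All roots of g(c) - c on [0, 1], ordered by c_star.

    Dense uniform sign scan followed by bisection refinement.  g is monotone,
    cheap and smooth, so robustness wins over sophistication here.  Root
    pairs closer than the scan resolution (tangencies at a fold) are still
    reported: grid nodes that are roots to within ``tol`` are picked up even
    without a sign change.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    grid = np.linspace(0.0, 1.0, scan_points + 1)
    resid = map_residuals(ensemble, grid)

    roots: list[float] = []

    def _push(r: float) -> None:
        for existing in roots:
            if abs(existing - r) < 2.0 / scan_points:
                return
        roots.append(r)

    # exact-ish grid hits (covers endpoints and fold tangencies)
    for c, d in zip(grid, resid):
        if abs(d) < tol:
            _push(float(c))
    # sign changes, refined by brentq
    f = lambda c: self_consistency_map(ensemble, c) - c
    for i in range(scan_points):
        if resid[i] == 0.0 or resid[i] * resid[i + 1] >= 0:
            continue
        r = brentq(f, grid[i], grid[i + 1], xtol=tol, rtol=4 * np.finfo(float).eps)
        _push(float(r))

    roots.sort()
    out = []
    for r in roots:
        slope, label = classify_stability(ensemble, r, marginal_tol)
        out.append(FixedPoint(r, diversity_from_c(ensemble, r), slope, label))
    return out


def iterate_map(
    ensemble: CommunityEnsemble,
    c0: float,
    tol: float = 1e-12,
    max_iter: int = 100_000,
) -> float:
    """Iterate c <- g(c) from c0 to convergence.

    Because g is monotone the iteration converges monotonically to the fixed
    point adjacent to c0 in the direction of g(c0) - c0; this is the
    branch-following primitive used by hysteresis sweeps and the
    sampling-and-culture path.
    """
    c = float(c0)
    for _ in range(max_iter):
        nxt = self_consistency_map(ensemble, c)
        if abs(nxt - c) < tol:
            return nxt
        c = nxt
    raise RuntimeError(f"map iteration did not converge within {max_iter} steps")
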