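"""Tipping-point structure of the cross-feeding self-consistency map.

In the Poisson ensemble the fixed-point equation c = exp(-z_c exp(-z_m c))
undergoes fold (saddle-node) bifurcations: as z_c crosses a fold value a
stable and an unstable fixed point collide and annihilate, and the community
jumps discontinuously between high- and low-diversity states.  In the
(z_c, z_m) plane the folds form two curves that meet and annihilate at a
cusp; between them lies the bistable, history-dependent region.

At a fold the fixed-point and tangency conditions g(c) = c, g'(c) = 1 hold
simultaneously.  For the Poisson map these reduce to a parametric form: the
colliding fixed point satisfies c ln c = -1/z_m, and then
z_c = exp(z_m c)/(z_m c).  Since -c ln c peaks at 1/e (at c = 1/e), folds
exist only for z_m > e, and at z_m = e the two solutions merge: the cusp sits
at z_c = z_m = e with fixed point c = 1/e.  The parametric form is a
reconstruction, so a derivation-free oracle (bisection on the z_c at which
the fixed-point count changes) is provided alongside and cross-checked in
the test-suite to 1e-6.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, root

from .analytic_core import (
    find_fixed_points,
    iterate_map,
    map_derivative,
    map_residuals,
    map_second_derivative,
    self_consistency_map,
)
from .degree_models import CommunityEnsemble

__all__ = [
    "FoldPoint",
    "PhaseDiagram",
    "find_folds",
    "find_folds_scan",
    "count_fixed_points",
    "find_cusp",
    "phase_diagram",
    "hysteresis_sweep",
    "jump_location",
]


@dataclass(frozen=True)
class FoldPoint:
    """A saddle-node point: parameters plus the colliding fixed point."""

    z_c: float
    z_m: float
    c_fold: float


@dataclass(frozen=True)
class PhaseDiagram:
    """Fold curves, cusp, and per-cell fixed-point counts over a grid."""

    zc_values: np.ndarray
    zm_values: np.ndarray
    count_grid: np.ndarray  # shape (len(zm_values), len(zc_values))
    region_grid: np.ndarray  # "monostable" / "bistable" labels, same shape
    lower_fold_curve: list[FoldPoint]
    upper_fold_curve: list[FoldPoint]
    cusp: tuple[float, float]


def count_fixed_points(
    ensemble: CommunityEnsemble, scan_points: int = 20_000
) -> int:
    """Number of roots of g(c) - c on [0, 1] by dense sign scan.

    Derivation-free: counts sign changes (plus endpoint roots) on a uniform
    grid.  Exact tangencies are measure-zero in parameter space; near-fold
    pairs are resolved as long as their separation exceeds 1/scan_points.
    """
    grid = np.linspace(0.0, 1.0, scan_points + 1)
    resid = map_residuals(ensemble, grid)
    sign = np.sign(resid)
    sign[np.abs(resid) < 1e-13] = 0  # grid-node roots counted once, below
    count = int(np.sum(sign[:-1] * sign[1:] < 0))
    count += int(np.sum(sign == 0))
    return count


def find_folds(z_m: float, near_cusp_tol: float = 1e-7) -> list[FoldPoint]:
    """Fold values of z_c at fixed z_m for the Poisson ensemble.

    Solves c ln c = -1/z_m for the colliding fixed point(s) c and maps each
    to z_c = exp(z_m c)/(z_m c).  Returns an empty list below the cusp
    (z_m < e), a single degenerate point at the cusp, and two FoldPoints
    (ascending z_c) above it.

    Raises if z_m is so close to e that the two roots cannot be separated
    beyond ``near_cusp_tol`` — reported explicitly rather than merged.
    """
    if z_m <= 0:
        raise ValueError("z_m must be positive")
    e = np.e
    peak = 1.0 / e  # max of -c ln c, attained at c = 1/e
    target = 1.0 / z_m
    if target > peak:
        return []
    f = lambda c: c * np.log(c) + target
    if abs(target - peak) < 1e-15:
        return [FoldPoint(z_c=e, z_m=z_m, c_fold=1.0 / e)]
    c_lo = brentq(f, 1e-300, 1.0 / e, xtol=1e-15)
    c_hi = brentq(f, 1.0 / e, 1.0 - 1e-15, xtol=1e-15)
    if c_hi - c_lo < near_cusp_tol:
        raise ValueError(
            f"folds at z_m={z_m} are degenerate at the working resolution "
            f"(c separation {c_hi - c_lo:.2e}); z_m is at or within "
            "floating-point distance of the cusp"
        )
    zc = lambda c: np.exp(z_m * c) / (z_m * c)
    points = [
        FoldPoint(z_c=float(zc(c)), z_m=float(z_m), c_fold=float(c))
        for c in (c_lo, c_hi)
    ]
    points.sort(key=lambda p: p.z_c)
    return points


def find_folds_scan(
    z_m: float,
    zc_max: float = 50.0,
    tol: float = 1e-8,
    scan_points: int = 20_000,
) -> list[float]:
    """Derivation-free fold locator: bisection on fixed-point-count changes.

    Scans z_c for transitions in the number of fixed points of the Poisson
    map and refines each transition by bisection to ``tol``.  Independent of
    the parametric fold formulas; used to validate them.
    """
    count = lambda zc: count_fixed_points(
        CommunityEnsemble.poisson(zc, z_m), scan_points
    )
    coarse = np.linspace(0.05, zc_max, 400)
    counts = [count(z) for z in coarse]
    folds = []
    for i in range(len(coarse) - 1):
        if counts[i] != counts[i + 1]:
            lo, hi = coarse[i], coarse[i + 1]
            c_lo = counts[i]
            while hi - lo > tol:
                mid = 0.5 * (lo + hi)
                if count(mid) == c_lo:
                    lo = mid
                else:
                    hi = mid
            folds.append(0.5 * (lo + hi))
    return folds


def _cusp_conditions(v: np.ndarray) -> np.ndarray:
    c, z_c, z_m = v
    ens = CommunityEnsemble.poisson(z_c, z_m)
    return np.array(
        [
            self_consistency_map(ens, min(max(c, 0.0), 1.0)) - c,
            map_derivative(ens, c) - 1.0,
            map_second_derivative(ens, c),
        ]
    )


def find_cusp(zm_bracket: tuple[float, float] = (1.5, 4.0)) -> tuple[float, float]:
    """Locate the cusp of the Poisson ensemble in the (z_c, z_m) plane.

    Coarse stage: bisection on z_m for the onset of bistability (the value
    below which ``find_folds_scan`` finds no count change), giving a warm
    start.  Fine stage: Newton-type root solve of the simultaneous
    fixed-point, fold and degeneracy conditions g(c)=c, g'(c)=1, g''(c)=0
    in (c, z_c, z_m).
    """
    lo, hi = zm_bracket
    # coarse: onset of bistability in z_m
    has_fold = lambda zm: len(find_folds_scan(zm, zc_max=20.0, tol=1e-3,
                                              scan_points=4000)) >= 2
    if has_fold(lo) or not has_fold(hi):
        raise ValueError(f"zm_bracket {zm_bracket} does not bracket the cusp")
    while hi - lo > 1e-2:
        mid = 0.5 * (lo + hi)
        if has_fold(mid):
            hi = mid
        else:
            lo = mid
    zm0 = hi
    folds = find_folds_scan(zm0, zc_max=20.0, tol=1e-4, scan_points=4000)
    zc0 = float(np.mean(folds))
    # the colliding fixed point near the cusp: c where g'(c) is maximal ~ 1
    ens0 = CommunityEnsemble.poisson(zc0, zm0)
    cgrid = np.linspace(0.05, 0.95, 181)
    c0 = float(cgrid[np.argmin([abs(map_derivative(ens0, c) - 1) for c in cgrid])])
    sol = root(_cusp_conditions, x0=np.array([c0, zc0, zm0]), tol=1e-13)
    if not sol.success or np.max(np.abs(_cusp_conditions(sol.x))) > 1e-9:
        raise RuntimeError(f"cusp refinement failed: {sol.message}")
    _, z_c, z_m = sol.x
    return float(z_c), float(z_m)


def phase_diagram(
    zc_range: tuple[float, float] = (0.05, 8.0),
    zm_range: tuple[float, float] = (0.05, 8.0),
    resolution: int = 50,
    scan_points: int = 4000,
) -> PhaseDiagram:
    """Fixed-point-count grid plus traced fold curves meeting at the cusp."""
    if resolution < 2 or zc_range[0] <= 0 or zm_range[0] <= 0:
        raise ValueError("ranges must be positive and resolution >= 2")
    zc_vals = np.linspace(*zc_range, resolution)
    zm_vals = np.linspace(*zm_range, resolution)
    counts = np.empty((resolution, resolution), dtype=int)
    for i, zm in enumerate(zm_vals):
        for j, zc in enumerate(zc_vals):
            counts[i, j] = count_fixed_points(
                CommunityEnsemble.poisson(zc, zm), scan_points
            )
    region = np.where(counts >= 3, "bistable", "monostable")

    cusp = find_cusp()
    lower, upper = [], []
    for zm in zm_vals:
        if zm <= cusp[1]:
            continue
        try:
            pair = find_folds(zm)
        except ValueError:
            continue
        if len(pair) == 2:
            lower.append(pair[0])
            upper.append(pair[1])
    # both curves terminate at the cusp
    cusp_pt = FoldPoint(z_c=cusp[0], z_m=cusp[1], c_fold=1.0 / np.e)
    lower.insert(0, cusp_pt)
    upper.insert(0, cusp_pt)
    return PhaseDiagram(
        zc_values=zc_vals,
        zm_values=zm_vals,
        count_grid=counts,
        region_grid=region,
        lower_fold_curve=lower,
        upper_fold_curve=upper,
        cusp=cusp,
    )


def hysteresis_sweep(
    z_m: float,
    zc_from: float,
    zc_to: float,
    steps: int = 751,
    ensemble_factory=None,
    tol: float = 1e-12,
) -> list[tuple[float, float]]:
    """Quasi-static branch following along a monotone z_c path at fixed z_m.

    Starts on the high-diversity branch for increasing sweeps (iterate from
    c=1) and on the low branch for decreasing sweeps (iterate from c=0);
    each subsequent solve warm-starts from the previous converged c*, so the
    followed branch persists until it disappears at a fold and then jumps.

    ``ensemble_factory(z_c)`` may supply non-Poisson families along the path.
    """
    if steps < 2:
        raise ValueError("steps must be >= 2")
    factory = ensemble_factory or (lambda zc: CommunityEnsemble.poisson(zc, z_m))
    path = np.linspace(zc_from, zc_to, steps)
    increasing = zc_to >= zc_from
    c = iterate_map(factory(path[0]), 1.0 if increasing else 0.0, tol=tol)
    out = [(float(path[0]), float(c))]
    for zc in path[1:]:
        c = iterate_map(factory(zc), c, tol=tol)
        out.append((float(zc), float(c)))
    return out


def jump_location(
    sweep: list[tuple[float, float]], threshold: float = 0.1
) -> float | None:
    """Midpoint z_c of the largest discontinuity in a sweep, or None.

    Reported as the midpoint of the last pre-jump and first post-jump step;
    honest to the sweep resolution.
    """
    diffs = [abs(b[1] - a[1]) for a, b in zip(sweep, sweep[1:])]
    k = int(np.argmax(diffs))
    if diffs[k] < threshold:
        return None
    return 0.5 * (sweep[k][0] + sweep[k + 1][0])
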