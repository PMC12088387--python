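"""Folds, cusp, phase diagram and hysteresis."""

import numpy as np
import pytest

from crossfeednet.analytic_core import map_derivative, self_consistency_map
from crossfeednet.bifurcation import (
    count_fixed_points,
    find_cusp,
    find_folds,
    find_folds_scan,
    hysteresis_sweep,
    jump_location,
    phase_diagram,
)
from crossfeednet.degree_models import CommunityEnsemble

E = np.e


def test_no_folds_below_the_cusp_producer_degree():
    assert find_folds(2.0) == []
    assert find_folds(1.0) == []


def test_two_folds_at_zm_four_with_fold_conditions():
    lo, hi = find_folds(4.0)
    assert lo.z_c == pytest.approx(3.43, abs=0.01)
    assert hi.z_c == pytest.approx(5.87, abs=0.01)
    for p in (lo, hi):
        ens = CommunityEnsemble.poisson(p.z_c, p.z_m)
        assert self_consistency_map(ens, p.c_fold) == pytest.approx(p.c_fold, abs=1e-8)
        assert map_derivative(ens, p.c_fold) == pytest.approx(1.0, abs=1e-8)


def test_folds_coincide_at_the_cusp_value():
    pts = find_folds(E)
    assert len(pts) == 1
    assert pts[0].z_c == pytest.approx(E, abs=1e-9)
    assert pts[0].c_fold == pytest.approx(1 / E, abs=1e-9)


def test_near_cusp_degeneracy_is_reported_not_merged():
    # z_m a hair above e: the colliding roots sit ~1e-8 apart, below the
    # resolution at which reporting two distinct folds is honest
    with pytest.raises(ValueError, match="degenerate"):
        find_folds(E + 1e-14)


def test_parametric_folds_agree_with_count_change_oracle():
    """Closed-form fold locations vs derivation-free bisection, to 1e-6."""
    for zm in (3.5, 4.0, 6.0):
        parametric = [p.z_c for p in find_folds(zm)]
        scanned = find_folds_scan(zm, zc_max=30.0, tol=1e-8)
        assert len(scanned) == 2
        for a, b in zip(parametric, sorted(scanned)):
            assert a == pytest.approx(b, abs=1e-6)


def test_fixed_point_count_changes_across_each_fold():
    lo, hi = find_folds(4.0)
    for z_c, inside in [(lo.z_c - 0.01, False), (lo.z_c + 0.01, True),
                        (hi.z_c - 0.01, True), (hi.z_c + 0.01, False)]:
        n = count_fixed_points(CommunityEnsemble.poisson(z_c, 4.0))
        assert n == (3 if inside else 1)


def test_cusp_sits_at_e_e():
    zc, zm = find_cusp()
    assert zc == pytest.approx(E, abs=1e-3)
    assert zm == pytest.approx(E, abs=1e-3)


def test_phase_diagram_regions_and_curves():
    pd_ = phase_diagram((0.5, 8.0), (0.5, 8.0), resolution=16)
    assert set(np.unique(pd_.count_grid)) <= {1, 3}
    # bistable cells occur only above the cusp producer degree
    for i, zm in enumerate(pd_.zm_values):
        if zm <= E and (pd_.region_grid[i] == "bistable").any():
            raise AssertionError(f"bistable cell below z_m = e at zm={zm}")
    assert (pd_.region_grid != "bistable").all() is not np.True_  # some bistable cells
    # named cells
    i1 = np.argmin(abs(pd_.zm_values - 1)); j1 = np.argmin(abs(pd_.zc_values - 1))
    assert pd_.region_grid[i1, j1] == "monostable"
    i2 = np.argmin(abs(pd_.zm_values - 4)); j2 = np.argmin(abs(pd_.zc_values - 4.5))
    assert pd_.region_grid[i2, j2] == "bistable"
    # fold curves terminate at the cusp and bracket the bistable cells
    assert pd_.lower_fold_curve[0].z_c == pytest.approx(pd_.cusp[0], abs=1e-6)
    assert pd_.upper_fold_curve[0].z_c == pytest.approx(pd_.cusp[0], abs=1e-6)
    for lo_pt, hi_pt in zip(pd_.lower_fold_curve[1:], pd_.upper_fold_curve[1:]):
        assert lo_pt.z_c < hi_pt.z_c
        assert lo_pt.z_m == hi_pt.z_m > E


def test_phase_diagram_count_changes_match_parametric_folds():
    """Column-wise count transitions happen within one cell of the fold z_c."""
    zm = 4.0
    pd_ = phase_diagram((0.5, 8.0), (zm, zm + 0.1), resolution=96)
    row = pd_.count_grid[0]
    step = pd_.zc_values[1] - pd_.zc_values[0]
    changes = [0.5 * (pd_.zc_values[i] + pd_.zc_values[i + 1])
               for i in range(len(row) - 1) if row[i] != row[i + 1]]
    folds = [p.z_c for p in find_folds(zm)]
    assert len(changes) == 2
    for got, want in zip(changes, folds):
        assert got == pytest.approx(want, abs=step)


def test_hysteresis_jumps_at_the_folds():
    lo, hi = find_folds(4.0)
    up = hysteresis_sweep(4.0, 0.5, 8.0, steps=751)
    down = hysteresis_sweep(4.0, 8.0, 0.5, steps=751)
    step = 7.5 / 750
    assert jump_location(up) == pytest.approx(hi.z_c, abs=step)
    assert jump_location(down) == pytest.approx(lo.z_c, abs=step)


def test_no_hysteresis_below_the_cusp():
    up = hysteresis_sweep(2.0, 0.5, 8.0, steps=301)
    down = hysteresis_sweep(2.0, 8.0, 0.5, steps=301)
    assert jump_location(up) is None and jump_location(down) is None
    for (z1, c1), (z2, c2) in zip(up, reversed(down)):
        assert z1 == pytest.approx(z2, abs=1e-12)
        assert c1 == pytest.approx(c2, abs=1e-8)


def test_sweeps_follow_their_own_branch_between_folds():
    from crossfeednet.analytic_core import find_fixed_points

    lo, hi = find_folds(4.0)
    mid_zc = 0.5 * (lo.z_c + hi.z_c)
    up = dict(hysteresis_sweep(4.0, 0.5, 8.0, steps=751))
    down = dict(hysteresis_sweep(4.0, 8.0, 0.5, steps=751))
    z_probe = min(up, key=lambda z: abs(z - mid_zc))
    fps = find_fixed_points(CommunityEnsemble.poisson(z_probe, 4.0))
    assert up[z_probe] == pytest.approx(fps[-1].c_star, abs=1e-6)  # high branch
    assert down[z_probe] == pytest.approx(fps[0].c_star, abs=1e-6)  # low branch


def test_hysteresis_loop_area_positive_only_above_cusp():
    for zm, expect_area in [(2.0, False), (4.0, True)]:
        up = hysteresis_sweep(zm, 0.5, 8.0, steps=301)
        down = hysteresis_sweep(zm, 8.0, 0.5, steps=301)
        gap = sum(abs(u[1] - d[1]) for u, d in zip(up, reversed(down))) / len(up)
        assert (gap > 1e-3) == expect_area
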