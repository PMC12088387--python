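"""Sampling-and-culture perturbations: thinning, paths, network protocol."""

import numpy as np
import pytest
from scipy import stats

from crossfeednet.analytic_core import find_fixed_points
from crossfeednet.degree_models import CommunityEnsemble, FinitePMF, Poisson
from crossfeednet.network_gen import generate_network
from crossfeednet.percolation_sim import percolate
from crossfeednet.perturbation import (
    PerturbationParams,
    apply_perturbation_to_network,
    culture_diversity,
    culture_ensemble_run,
    effective_ensemble,
    sample_consumers,
    sample_culture_network_run,
    thin_distribution,
)

WILD = CommunityEnsemble.poisson(4.0, 4.0)


def test_params_validated():
    with pytest.raises(ValueError):
        PerturbationParams(sample_retention=1.2)
    with pytest.raises(ValueError):
        PerturbationParams(supply_fraction=-0.1)


def test_identity_perturbation_is_identity():
    eff = effective_ensemble(WILD, PerturbationParams())
    assert eff.y_c == 4.0 and eff.y_m == 4.0
    wild_fps = find_fixed_points(WILD)
    eff_fps = find_fixed_points(eff.ensemble)
    assert len(wild_fps) == len(eff_fps)
    for a, b in zip(wild_fps, eff_fps):
        assert abs(a.c_star - b.c_star) < 1e-12


def test_effective_means_follow_thinning():
    eff = effective_ensemble(WILD, PerturbationParams(supply_fraction=0.5))
    assert eff.y_c == pytest.approx(2.0)  # half the requirements supplied away
    eff = effective_ensemble(WILD, PerturbationParams(sample_retention=0.5))
    assert eff.y_m == pytest.approx(2.0)  # half the producers lost to sampling
    assert eff.y_c <= 4.0 and eff.y_m <= 4.0


def test_poisson_thinning_matches_simulated_thinning():
    """Binomial thinning of Poisson(4) at retention 0.5 is Poisson(2);
    checked against 1e5 simulated thinned draws."""
    rng = np.random.default_rng(6)
    raw = rng.poisson(4.0, 100_000)
    thinned = rng.binomial(raw, 0.5)
    d = thin_distribution(Poisson(4.0), 0.5)
    assert isinstance(d, Poisson) and d.z == pytest.approx(2.0)
    k = np.arange(12)
    emp = np.bincount(thinned, minlength=12)[:12] / len(thinned)
    assert np.max(np.abs(emp - stats.poisson.pmf(k, 2.0))) < 0.005


def test_finite_pmf_thinning_against_binomial_mixture():
    d = thin_distribution(FinitePMF({0: 0.2, 3: 0.8}), 0.25)
    # q_j = 0.8 * Binom(j; 3, 0.25) for j>0, plus the k=0 atom at j=0
    expect = {j: 0.8 * stats.binom.pmf(j, 3, 0.25) for j in range(4)}
    expect[0] += 0.2
    for j, q in expect.items():
        assert d.probs[j] == pytest.approx(q, abs=1e-12)


def test_thinning_composes_multiplicatively():
    once = thin_distribution(thin_distribution(Poisson(4.0), 0.6), 0.5)
    assert once.z == pytest.approx(4.0 * 0.3)
    a = thin_distribution(thin_distribution(FinitePMF({0: 0.5, 2: 0.5}), 0.6), 0.5)
    b = thin_distribution(FinitePMF({0: 0.5, 2: 0.5}), 0.3)
    for j in b.probs:
        assert a.probs[j] == pytest.approx(b.probs[j], abs=1e-12)


def test_identity_path_returns_wild_branch():
    out = culture_diversity(WILD, PerturbationParams())
    wild_high = find_fixed_points(WILD)[-1].c_star
    assert out.path.wild_c == pytest.approx(wild_high, abs=1e-9)
    assert out.path.cultured_c == pytest.approx(wild_high, abs=1e-9)


def test_severe_sampling_traps_culture_on_the_low_root():
    out = culture_diversity(WILD, PerturbationParams(sample_retention=0.2))
    fps = out.fixed_points
    assert out.path.cultured_c == pytest.approx(fps[0].c_star, abs=1e-9)
    assert out.path.cultured_c < 0.05


def test_full_supply_restores_everything():
    out = culture_diversity(
        WILD, PerturbationParams(sample_retention=0.5, supply_fraction=1.0)
    )
    assert out.path.cultured_c == pytest.approx(1.0, abs=1e-9)


def test_path_monotone_in_retention_and_supply():
    grid = np.linspace(0.05, 0.95, 10)
    for supply in (0.2, 0.6):
        vals = [
            culture_diversity(WILD, PerturbationParams(s, supply)).path.cultured_c
            for s in grid
        ]
        assert all(b >= a - 1e-9 for a, b in zip(vals, vals[1:]))
    for retention in (0.4, 0.8):
        vals = [
            culture_diversity(WILD, PerturbationParams(retention, r)).path.cultured_c
            for r in grid
        ]
        assert all(b >= a - 1e-9 for a, b in zip(vals, vals[1:]))


def test_identity_perturbation_leaves_network_unchanged():
    net = generate_network(100, 100, 2.0, 2.0, seed=4)
    assert apply_perturbation_to_network(net, PerturbationParams(), seed=1) == net


def test_zero_retention_empties_the_community():
    net = generate_network(400, 400, 4.0, 4.0, seed=4)
    pert = apply_perturbation_to_network(
        net, PerturbationParams(sample_retention=0.0, supply_fraction=0.3), seed=2
    )
    assert pert.n_consumers == 0
    res = percolate(pert, init="all_present", seed=2)
    assert res.c_hat == 0.0
    # only supplied metabolites remain, within a 3-sigma binomial band
    assert abs(res.m_hat - 0.3) < 3 * np.sqrt(0.3 * 0.7 / 400)


def test_sampling_thins_producer_degrees_binomially():
    """Post-sampling producer-degree histogram passes GOF against the
    thinned Poisson at the 1% level."""
    from conftest import poisson_gof_pvalue

    N = 10_000
    net = generate_network(N, N, 4.0, 4.0, seed=12)
    rng = np.random.default_rng(12)
    sampled, _ = sample_consumers(net, 0.5, rng)
    deg = np.bincount(sampled.prod_edges[:, 1], minlength=N)
    assert poisson_gof_pvalue(deg, 2.0) > 0.01


def test_staged_simulation_tracks_analytic_path():
    params = PerturbationParams(sample_retention=0.6, supply_fraction=0.6)
    analytic = culture_diversity(WILD, params).path
    tab = culture_ensemble_run(800, 800, 4.0, 4.0, params, replicates=12, seed=42)
    for col, target in [("wild_c", analytic.wild_c),
                        ("sampled_c", analytic.sampled_c),
                        ("cultured_c", analytic.cultured_c)]:
        mean, se = tab[col].mean(), tab[col].sem()
        assert abs(mean - target) < 4 * se, (col, mean, target, se)


def test_staged_run_is_reproducible():
    params = PerturbationParams(sample_retention=0.7, supply_fraction=0.4)
    a = sample_culture_network_run(300, 300, 4.0, 4.0, params, seed=9)
    b = sample_culture_network_run(300, 300, 4.0, 4.0, params, seed=9)
    assert a == b
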