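"""Sampling-and-culture perturbations of cross-feeding communities.

Two perturbations are modelled, mirroring what happens when a wild
community is sampled and grown in the lab:

* **Sampling** keeps each consumer independently with probability
  ``sample_retention``; a removed consumer takes its production edges with
  it.  At the ensemble level this is binomial thinning of the
  producers-per-metabolite distribution: Poisson(z_m) -> Poisson(s·z_m)
  with retention s.
* **Resource supply** marks each metabolite externally supplied with
  probability ``supply_fraction``; a supplied metabolite is present
  regardless of producers, so each consumer requirement is independently
  satisfied "for free" with that probability.  At the ensemble level this is
  binomial thinning of the requirements-per-consumer distribution:
  Poisson(z_c) -> Poisson((1-r)·z_c) with supply fraction r.

Because both perturbations map Poisson ensembles to Poisson ensembles, the
self-consistency analysis applies unchanged at the effective means
(y_c, y_m) = ((1-r)·z_c, s·z_m).  Whether the cultured community lands on
the high- or low-diversity branch is a *path* property: the community is
carried from the wild state through the sampling step and then the culture
step by warm-started iteration, which is how hysteresis can trap a culture
on the low branch even when a high-diversity state exists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .analytic_core import FixedPoint, find_fixed_points, iterate_map
from .degree_models import CommunityEnsemble, DegreeDistribution, FinitePMF, Poisson
from .network_gen import CrossFeedingNetwork, generate_network
from .percolation_sim import percolate, replicate_seeds

__all__ = [
    "PerturbationParams",
    "EffectiveEnsemble",
    "CulturePath",
    "CultureOutcome",
    "thin_distribution",
    "effective_ensemble",
    "culture_diversity",
    "sample_consumers",
    "flag_supplied",
    "apply_perturbation_to_network",
    "sample_culture_network_run",
    "culture_ensemble_run",
]


@dataclass(frozen=True)
class PerturbationParams:
    """Sampling retention and external resource-supply probabilities."""

    sample_retention: float = 1.0
    supply_fraction: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sample_retention", "supply_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]; got {v}")


@dataclass(frozen=True)
class EffectiveEnsemble:
    """Post-perturbation ensemble with its effective mean degrees."""

    y_c: float
    y_m: float
    ensemble: CommunityEnsemble


@dataclass(frozen=True)
class CulturePath:
    """Warm-start path: wild -> after sampling -> after culture."""

    wild_c: float
    sampled_c: float
    cultured_c: float


@dataclass(frozen=True)
class CultureOutcome:
    effective: EffectiveEnsemble
    fixed_points: list[FixedPoint]
    path: CulturePath


def thin_distribution(dist: DegreeDistribution, retention: float) -> DegreeDistribution:
    """Binomial thinning: keep each of the k units independently w.p. retention.

    Poisson(z) thins to Poisson(retention·z); a finite pmf thins to the
    binomial mixture q_j = sum_k p_k Binom(j; k, retention).
    """
    if not 0.0 <= retention <= 1.0:
        raise ValueError("retention must lie in [0, 1]")
    if isinstance(dist, Poisson):
        return Poisson(retention * dist.z)
    if isinstance(dist, FinitePMF):
        kmax = max(dist.probs)
        q = np.zeros(kmax + 1)
        for k, p in dist.probs.items():
            q[: k + 1] += p * stats.binom.pmf(np.arange(k + 1), k, retention)
        q /= q.sum()  # renormalise away pmf round-off
        return FinitePMF({j: float(q[j]) for j in range(kmax + 1)})
    raise TypeError(f"cannot thin distribution of type {type(dist).__name__}")


def effective_ensemble(
    ensemble: CommunityEnsemble, params: PerturbationParams
) -> EffectiveEnsemble:
    """Transformed ensemble after sampling and culture.

    Producers are thinned with retention ``sample_retention``; requirements
    are thinned with retention ``1 - supply_fraction`` (a supplied
    requirement drops out of the self-consistency condition).
    """
    cons = thin_distribution(ensemble.consumer_dist, 1.0 - params.supply_fraction)
    mets = thin_distribution(ensemble.metabolite_dist, params.sample_retention)
    return EffectiveEnsemble(
        y_c=cons.mean(), y_m=mets.mean(), ensemble=CommunityEnsemble(cons, mets)
    )


def culture_diversity(
    ensemble: CommunityEnsemble, params: PerturbationParams, tol: float = 1e-12
) -> CultureOutcome:
    """Fixed points of the effective ensemble plus the path-followed branch.

    The path warm-starts each stage from the previous converged state:
    wild high branch at the unperturbed ensemble, then the sampling step
    (requirements unchanged, producers thinned), then the culture step
    (requirements thinned too).
    """
    eff = effective_ensemble(ensemble, params)
    sampling_stage = CommunityEnsemble(
        ensemble.consumer_dist, eff.ensemble.metabolite_dist
    )
    wild_c = iterate_map(ensemble, 1.0, tol=tol)
    sampled_c = iterate_map(sampling_stage, wild_c, tol=tol)
    cultured_c = iterate_map(eff.ensemble, sampled_c, tol=tol)
    return CultureOutcome(
        effective=eff,
        fixed_points=find_fixed_points(eff.ensemble),
        path=CulturePath(wild_c, sampled_c, cultured_c),
    )


def sample_consumers(
    net: CrossFeedingNetwork, retention: float, rng: np.random.Generator
) -> tuple[CrossFeedingNetwork, np.ndarray]:
    """Remove each consumer independently w.p. 1 - retention.

    Retained consumers are renumbered consecutively; their production edges
    survive, removed consumers take theirs along.  Returns the sampled
    network and the boolean retention mask over original consumer ids.
    """
    mask = rng.random(net.n_consumers) < retention
    new_id = np.cumsum(mask) - 1
    req = net.req_edges[mask[net.req_edges[:, 1]]]
    req = np.column_stack([req[:, 0], new_id[req[:, 1]]]) if len(req) else req
    prod = net.prod_edges[mask[net.prod_edges[:, 0]]]
    prod = np.column_stack([new_id[prod[:, 0]], prod[:, 1]]) if len(prod) else prod
    sampled = CrossFeedingNetwork(
        n_consumers=int(mask.sum()),
        n_metabolites=net.n_metabolites,
        req_edges=req,
        prod_edges=prod,
        supplied=net.supplied.copy(),
    )
    return sampled, mask


def flag_supplied(
    net: CrossFeedingNetwork, supply_fraction: float, rng: np.random.Generator
) -> CrossFeedingNetwork:
    """Mark each metabolite externally supplied w.p. supply_fraction."""
    flags = net.supplied | (rng.random(net.n_metabolites) < supply_fraction)
    return CrossFeedingNetwork(
        n_consumers=net.n_consumers,
        n_metabolites=net.n_metabolites,
        req_edges=net.req_edges,
        prod_edges=net.prod_edges,
        supplied=flags,
    )


def apply_perturbation_to_network(
    net: CrossFeedingNetwork, params: PerturbationParams, seed: int
) -> CrossFeedingNetwork:
    """Sample consumers, then flag supplied metabolites; seeded, reproducible."""
    rng = np.random.default_rng(seed)
    sampled, _ = sample_consumers(net, params.sample_retention, rng)
    return flag_supplied(sampled, params.supply_fraction, rng)


def sample_culture_network_run(
    N: int,
    M: int,
    z_c: float,
    z_m: float,
    params: PerturbationParams,
    seed: int,
) -> dict[str, float]:
    """Simulated analogue of the warm-start sampling-and-culture path.

    Stage 1 percolates the wild network from all-present (wild high branch).
    Stage 2 removes sampled-out consumers and continues percolation from the
    wild converged state — a purely downward monotone cascade.  Stage 3 adds
    the supply flags and continues from the stage-2 state — purely upward.
    Fractions are reported over the retained consumers.
    """
    ss = np.random.SeedSequence(seed)
    net_seed, perc_seed, pert_seed, s2_seed, s3_seed = (
        int(s) % 2**31 for s in ss.generate_state(5)
    )
    wild = generate_network(N, M, z_c, z_m, net_seed)
    res_wild = percolate(wild, init="all_present", seed=perc_seed)

    rng = np.random.default_rng(pert_seed)
    sampled, mask = sample_consumers(wild, params.sample_retention, rng)
    if sampled.n_consumers:
        init2 = (res_wild.consumer_state[mask], res_wild.metabolite_state)
        res_sampled = percolate(sampled, init=init2, seed=s2_seed)
    else:
        res_sampled = percolate(sampled, init="all_absent", seed=s2_seed)

    cultured = flag_supplied(sampled, params.supply_fraction, rng)
    init3 = (res_sampled.consumer_state, res_sampled.metabolite_state)
    res_cult = percolate(cultured, init=init3, seed=s3_seed)
    return {
        "wild_c": res_wild.c_hat,
        "sampled_c": res_sampled.c_hat,
        "cultured_c": res_cult.c_hat,
        "cultured_m": res_cult.m_hat,
        "n_retained": float(sampled.n_consumers),
    }


def culture_ensemble_run(
    N: int,
    M: int,
    z_c: float,
    z_m: float,
    params: PerturbationParams,
    replicates: int,
    seed: int,
) -> pd.DataFrame:
    """Replicated sample-then-culture simulations; one row per replicate."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rows = []
    for rep, (child_seed, _) in enumerate(replicate_seeds(seed, replicates)):
        row = sample_culture_network_run(N, M, z_c, z_m, params, child_seed)
        row["replicate"] = rep
        rows.append(row)
    return pd.DataFrame(rows)
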