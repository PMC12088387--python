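"""Degree distributions and their probability generating functions.

A cross-feeding community is characterised statistically by two degree
distributions: the number of metabolites each consumer population requires,
and the number of consumer populations that produce each metabolite.  Both
are distributions over non-negative integers, and the analytics of the model
run entirely through their probability generating functions (PGFs)

    G(x) = sum_k p_k x^k,   0 <= x <= 1.

Two families are supported: Poisson with mean ``z`` (the random-network null
model, with closed-form PGF ``exp(z(x-1))``) and arbitrary finite pmfs, so
the self-consistency machinery can be exercised with any user-supplied
degree structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DegreeDistribution",
    "Poisson",
    "FinitePMF",
    "CommunityEnsemble",
    "pgf_eval",
    "pgf_derivative",
    "sample_degrees",
    "distribution_from_config",
]

_PMF_TOL = 1e-12


class DegreeDistribution:
    """Abstract degree distribution over non-negative integers."""

    def pgf(self, x: float) -> float:
        raise NotImplementedError

    def pgf_vec(self, x: np.ndarray) -> np.ndarray:
        """Vectorised PGF over an array of points in [0, 1]."""
        return np.array([self.pgf(float(v)) for v in np.asarray(x, dtype=float)])

    def pgf_derivative(self, x: float, order: int = 1) -> float:
        raise NotImplementedError

    def mean(self) -> float:
        raise NotImplementedError

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError


def _check_x(x: float) -> float:
    x = float(x)
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"PGF argument must lie in [0, 1]; got {x}")
    return x


def _check_order(order: int) -> int:
    if order not in (1, 2):
        raise ValueError(f"derivative order must be 1 or 2; got {order}")
    return order


@dataclass(frozen=True)
class Poisson(DegreeDistribution):
    """Poisson degree distribution with mean ``z >= 0``.

    PGF is the closed form ``exp(z(x-1))``; all derivatives follow by
    multiplying with powers of ``z``.
    """

    z: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.z) or self.z < 0:
            raise ValueError(f"Poisson mean must be finite and >= 0; got {self.z}")

    def pgf(self, x: float) -> float:
        x = _check_x(x)
        return float(np.exp(self.z * (x - 1.0)))

    def pgf_vec(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return np.exp(self.z * (x - 1.0))

    def pgf_derivative(self, x: float, order: int = 1) -> float:
        x = _check_x(x)
        order = _check_order(order)
        return float(self.z**order * np.exp(self.z * (x - 1.0)))

    def mean(self) -> float:
        return self.z

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.poisson(self.z, size=n)


@dataclass(frozen=True)
class FinitePMF(DegreeDistribution):
    """Finite-support pmf ``{degree: probability}``.

    Probabilities must be non-negative and sum to 1 within 1e-12.
    """

    probs: dict[int, float]
    _degrees: np.ndarray = field(init=False, repr=False, compare=False)
    _weights: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.probs:
            raise ValueError("pmf must have at least one entry")
        degrees = np.array(sorted(self.probs), dtype=np.int64)
        weights = np.array([self.probs[int(k)] for k in degrees], dtype=float)
        if (degrees < 0).any():
            raise ValueError("degrees must be non-negative integers")
        if (weights < -_PMF_TOL).any() or (weights > 1 + _PMF_TOL).any():
            raise ValueError("probabilities must lie in [0, 1]")
        total = weights.sum()
        if abs(total - 1.0) > _PMF_TOL:
            raise ValueError(f"probabilities must sum to 1; got {total!r}")
        object.__setattr__(self, "_degrees", degrees)
        object.__setattr__(self, "_weights", weights)

    def pgf(self, x: float) -> float:
        x = _check_x(x)
        return float(np.sum(self._weights * np.power(x, self._degrees)))

    def pgf_vec(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return np.power(x[:, None], self._degrees[None, :]) @ self._weights

    def pgf_derivative(self, x: float, order: int = 1) -> float:
        x = _check_x(x)
        order = _check_order(order)
        k = self._degrees.astype(float)
        if order == 1:
            coef = k
            expo = k - 1
        else:
            coef = k * (k - 1)
            expo = k - 2
        mask = coef > 0  # terms with k < order vanish identically
        with np.errstate(divide="ignore", invalid="ignore"):
            powers = np.where(mask, np.power(x, np.where(mask, expo, 0.0)), 0.0)
        return float(np.sum(self._weights * coef * powers))

    def mean(self) -> float:
        return float(np.sum(self._weights * self._degrees))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.choice(self._degrees, size=n, p=self._weights / self._weights.sum())


@dataclass(frozen=True)
class CommunityEnsemble:
    """Statistical ensemble of cross-feeding networks.

    ``consumer_dist`` is the distribution of requirements per consumer,
    ``metabolite_dist`` the distribution of producers per metabolite.
    """

    consumer_dist: DegreeDistribution
    metabolite_dist: DegreeDistribution

    @classmethod
    def poisson(cls, z_c: float, z_m: float) -> "CommunityEnsemble":
        return cls(Poisson(z_c), Poisson(z_m))

    @property
    def is_poisson(self) -> bool:
        return isinstance(self.consumer_dist, Poisson) and isinstance(
            self.metabolite_dist, Poisson
        )


def pgf_eval(dist: DegreeDistribution, x: float) -> float:
    """Evaluate the PGF ``sum_k p_k x^k`` at ``x`` in [0, 1]."""
    return dist.pgf(x)


def pgf_derivative(dist: DegreeDistribution, x: float, order: int = 1) -> float:
    """Evaluate the first or second derivative of the PGF at ``x``."""
    return dist.pgf_derivative(x, order)


def sample_degrees(dist: DegreeDistribution, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` i.i.d. degrees; identical seed gives identical output."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return dist.sample(n, rng)


def distribution_from_config(config: dict) -> DegreeDistribution:
    """Build a distribution from ``{family: poisson, mean: z}`` or
    ``{family: pmf, probs: {k: p_k, ...}}``."""
    family = config.get("family")
    if family == "poisson":
        return Poisson(float(config["mean"]))
    if family == "pmf":
        return FinitePMF({int(k): float(v) for k, v in config["probs"].items()})
    raise ValueError(f"unknown distribution family: {family!r}")
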