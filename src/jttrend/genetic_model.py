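"""Penetrance-based disease-model parameterization for a diallelic locus.

The model places the pair of genotype relative risks (lambda_1, lambda_2)
= (f1/f0, f2/f0) on a polar arc around the null point (1, 1):

    lambda_1 = 1 + lam * cos(theta),   lambda_2 = 1 + lam * sin(theta)

where ``lam >= 0`` is the distance from the null (effect size) and
``theta`` in [pi/4, pi/2] sweeps the mode of inheritance with respect to
the minor allele: theta = pi/4 gives the dominant model
(lambda_1 = lambda_2), theta = arctan(2) the additive model
(lambda_1 = (1 + lambda_2)/2), and theta = pi/2 the recessive model
(lambda_1 = 1).  lam = 0 is the null regardless of theta.

Given a population prevalence K and minor allele frequency q with
Hardy-Weinberg genotype proportions P(G) = ((1-q)^2, 2q(1-q), q^2), the
baseline penetrance is pinned by the law of total probability:

    f0 = K / [ (1-q)^2 + 2 lambda_1 q (1-q) + lambda_2 q^2 ],   f_i = lambda_i f0

and Bayes' rule gives the genotype distributions within cases and controls:

    tau_i = P(G_i) f_i / K,    upsilon_i = P(G_i) (1 - f_i) / (1 - K).

Both triples sum to one analytically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "GeneticModelSpec",
    "CellProbabilities",
    "InfeasibleModelError",
    "relative_risks",
    "cell_probabilities",
    "MODEL_THETAS",
    "theta_from_prime",
]

# Canonical angles for the three named modes of inheritance.
MODEL_THETAS = {
    "dominant": math.pi / 4,
    "additive": math.atan(2.0),
    "recessive": math.pi / 2,
}

_THETA_LO = math.pi / 4
_THETA_HI = math.pi / 2
_THETA_TOL = 1e-12


class InfeasibleModelError(ValueError):
    """Raised when a (K, q, lam, theta) combination implies a penetrance >= 1."""


def theta_from_prime(theta_prime: float) -> float:
    """Convert the normalized angle theta' = theta/pi (in [0.25, 0.5]) to radians."""
    return theta_prime * math.pi


def relative_risks(lam: float, theta: float) -> tuple[float, float]:
    """Genotype relative risks (lambda_1, lambda_2) from the polar parameters.

    Raises a ``ValueError`` for theta outside [pi/4, pi/2] or lam < 0.
    """
    if lam < 0:
        raise ValueError(f"lam must be >= 0, got {lam}")
    if not (_THETA_LO - _THETA_TOL <= theta <= _THETA_HI + _THETA_TOL):
        raise ValueError(
            f"theta must lie in [pi/4, pi/2] (dominant..recessive arc), got {theta}"
        )
    return 1.0 + lam * math.cos(theta), 1.0 + lam * math.sin(theta)


@dataclass(frozen=True)
class GeneticModelSpec:
    """Disease-model parameters (K, q, lam, theta).

    Parameters
    ----------
    K : float
        Disease prevalence, in (0, 1).
    q : float
        Minor allele frequency, in (0, 1).
    lam : float
        Effect distance from the null point (1, 1); lam = 0 is the null.
    theta : float
        Model angle in radians, in [pi/4, pi/2].  Use
        ``GeneticModelSpec.from_model`` or ``from_theta_prime`` for the
        named/normalized forms.
    """

    K: float
    q: float
    lam: float
    theta: float

    def __post_init__(self) -> None:
        if not 0.0 < self.K < 1.0:
            raise ValueError(f"prevalence K must be in (0, 1), got {self.K}")
        if not 0.0 < self.q < 1.0:
            raise ValueError(f"MAF q must be in (0, 1), got {self.q}")
        relative_risks(self.lam, self.theta)  # range validation

    @classmethod
    def from_model(cls, K: float, q: float, lam: float, model: str) -> "GeneticModelSpec":
        try:
            theta = MODEL_THETAS[model]
        except KeyError:
            raise ValueError(
                f"unknown model {model!r}; expected one of {sorted(MODEL_THETAS)}"
            ) from None
        return cls(K, q, lam, theta)

    @classmethod
    def from_theta_prime(cls, K: float, q: float, lam: float, theta_prime: float) -> "GeneticModelSpec":
        return cls(K, q, lam, theta_from_prime(theta_prime))

    @property
    def theta_prime(self) -> float:
        return self.theta / math.pi

    @property
    def is_null(self) -> bool:
        return self.lam == 0.0


@dataclass(frozen=True)
class CellProbabilities:
    """Derived quantities of a model spec: penetrances and cell probabilities.

    ``tau`` is the genotype distribution among cases, ``upsilon`` among
    controls; each sums to 1.  ``f`` holds the penetrances
    (f0, f1, f2) and ``lambdas`` the relative risks (lambda_1, lambda_2).
    """

    tau: tuple[float, float, float]
    upsilon: tuple[float, float, float]
    f: tuple[float, float, float]
    lambdas: tuple[float, float]


def cell_probabilities(spec: GeneticModelSpec) -> CellProbabilities:
    """Penetrances and case/control genotype probabilities for a model spec.

    Raises
    ------
    InfeasibleModelError
        If the implied f2 = lambda_2 * f0 reaches 1 (the prevalence/effect
        combination is not a valid penetrance model).
    """
    K, q = spec.K, spec.q
    l1, l2 = relative_risks(spec.lam, spec.theta)
    P = ((1.0 - q) ** 2, 2.0 * q * (1.0 - q), q**2)
    f0 = K / ((1.0 - q) ** 2 + 2.0 * l1 * q * (1.0 - q) + l2 * q**2)
    f = (f0, l1 * f0, l2 * f0)
    if f[2] >= 1.0:
        raise InfeasibleModelError(
            f"penetrance f2 = {f[2]:.4f} >= 1 for K={K}, q={q}, lam={spec.lam}, "
            f"theta={spec.theta:.4f}"
        )
    tau = tuple(Pi * fi / K for Pi, fi in zip(P, f))
    upsilon = tuple(Pi * (1.0 - fi) / (1.0 - K) for Pi, fi in zip(P, f))
    return CellProbabilities(tau=tau, upsilon=upsilon, f=f, lambdas=(l1, l2))
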