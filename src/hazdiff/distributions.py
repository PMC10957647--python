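"""Latent-variable laws for additive-hazard heterogeneity.

Two unobserved individual factors drive the model: a nonnegative frailty
``U0`` entering the baseline hazard and an effect modifier ``U1`` scaling the
additive exposure effect.  This module provides their marginal laws, the
Laplace transforms ``L(c) = E[exp(-c U1)]`` needed for survivor-conditional
means, and joint sampling of ``(U0, U1)`` coupled through a Gaussian copula
parameterized by Kendall's tau.

Gamma convention
----------------
``Gamma(shape, scale)`` throughout, with mean ``shape * scale``; the unit
case shape = scale = 1 is the standard exponential, for which both common
gamma conventions coincide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "BHNModifier",
    "ShiftedGammaModifier",
    "DegenerateModifier",
    "GammaFrailty",
    "CopulaSpec",
    "laplace",
    "laplace_derivative",
    "kendall_to_gaussian_rho",
    "sample_joint",
]


def _logsumexp_weighted(log_terms: np.ndarray, weights: np.ndarray) -> float:
    """sum_k w_k * exp(log_terms_k), stabilized by factoring out the max exponent."""
    m = np.max(log_terms)
    return float(math.exp(m) * np.sum(weights * np.exp(log_terms - m)))


@dataclass(frozen=True)
class BHNModifier:
    """Three-point Benefit/Harm/Neutral law of the effect modifier.

    ``U1 = mu1`` (benefit, <= 0) with probability ``p1``, ``mu2`` (harm, >= 0)
    with probability ``p2``, and 0 (neutral) otherwise.

    Parameters
    ----------
    p1, mu1 : probability and hazard-difference value of the benefit class.
    p2, mu2 : probability and hazard-difference value of the harm class.
    """

    p1: float
    mu1: float
    p2: float
    mu2: float

    def __post_init__(self) -> None:
        if self.p1 < 0 or self.p2 < 0 or self.p1 + self.p2 > 1 + 1e-12:
            raise ValueError("need p1 >= 0, p2 >= 0, p1 + p2 <= 1")
        if self.mu1 > 0:
            raise ValueError("benefit effect mu1 must be <= 0")
        if self.mu2 < 0:
            raise ValueError("harm effect mu2 must be >= 0")

    @property
    def p0(self) -> float:
        """Probability of the neutral class."""
        return 1.0 - self.p1 - self.p2

    def _atoms(self) -> tuple[np.ndarray, np.ndarray]:
        values = np.array([self.mu1, 0.0, self.mu2])
        probs = np.array([self.p1, self.p0, self.p2])
        return values, probs

    def mean(self) -> float:
        return self.p1 * self.mu1 + self.p2 * self.mu2

    def support_min(self) -> float:
        """Smallest support point carrying positive mass."""
        values, probs = self._atoms()
        return float(np.min(values[probs > 0]))

    def laplace(self, c: float) -> float:
        values, probs = self._atoms()
        return _logsumexp_weighted(-c * values, probs)

    def laplace_derivative(self, c: float) -> float:
        values, probs = self._atoms()
        return -_logsumexp_weighted(-c * values, probs * values)

    def ppf(self, q) -> np.ndarray:
        """Quantile function of the discrete three-point law."""
        values, probs = self._atoms()
        order = np.argsort(values, kind="stable")
        values, probs = values[order], probs[order]
        cum = np.cumsum(probs)
        idx = np.searchsorted(cum, np.asarray(q, dtype=float), side="left")
        return values[np.clip(idx, 0, 2)]


@dataclass(frozen=True)
class ShiftedGammaModifier:
    """Continuous modifier ``U1 = G - shift`` with ``G ~ Gamma(shape, scale)``.

    With shape = scale = 1 and shift ``l`` this is the unit-exponential
    modifier shifted so its support starts at ``-l``, mean ``1 - l``.
    """

    shape: float
    scale: float
    shift: float = 0.0

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("gamma shape and scale must be positive")

    def mean(self) -> float:
        return self.shape * self.scale - self.shift

    def support_min(self) -> float:
        return -self.shift

    def laplace(self, c: float) -> float:
        # L(c) = exp(c * shift) * (1 + c*scale)^(-shape); finite for c*scale > -1
        if c * self.scale <= -1:
            raise ValueError("Laplace transform diverges: need c * scale > -1")
        return math.exp(c * self.shift) * (1.0 + c * self.scale) ** (-self.shape)

    def laplace_derivative(self, c: float) -> float:
        if c * self.scale <= -1:
            raise ValueError("Laplace transform diverges: need c * scale > -1")
        # d/dc log L = shift - shape*scale/(1 + c*scale)
        return self.laplace(c) * (self.shift - self.shape * self.scale / (1.0 + c * self.scale))

    def ppf(self, q) -> np.ndarray:
        return stats.gamma.ppf(np.asarray(q, dtype=float), a=self.shape, scale=self.scale) - self.shift


@dataclass(frozen=True)
class DegenerateModifier:
    """Point mass at ``value``: the effect-homogeneous special case."""

    value: float

    def mean(self) -> float:
        return self.value

    def support_min(self) -> float:
        return self.value

    def laplace(self, c: float) -> float:
        return math.exp(-c * self.value)

    def laplace_derivative(self, c: float) -> float:
        return -self.value * math.exp(-c * self.value)

    def ppf(self, q) -> np.ndarray:
        return np.full_like(np.asarray(q, dtype=float), self.value)


@dataclass(frozen=True)
class GammaFrailty:
    """Nonnegative baseline frailty ``U0 ~ Gamma(shape, scale)``, mean shape*scale."""

    shape: float = 1.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("gamma shape and scale must be positive")

    def mean(self) -> float:
        return self.shape * self.scale

    def support_min(self) -> float:
        return 0.0

    def ppf(self, q) -> np.ndarray:
        return stats.gamma.ppf(np.asarray(q, dtype=float), a=self.shape, scale=self.scale)


@dataclass(frozen=True)
class DegenerateFrailty:
    """Point-mass frailty, for homogeneous-baseline configurations."""

    value: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("frailty must be nonnegative")

    def mean(self) -> float:
        return self.value

    def support_min(self) -> float:
        return self.value

    def ppf(self, q) -> np.ndarray:
        return np.full_like(np.asarray(q, dtype=float), self.value)


@dataclass(frozen=True)
class CopulaSpec:
    """Gaussian copula for (U0, U1), parameterized by Kendall's tau.

    The implied normal correlation is ``rho = sin(pi * tau / 2)``.  The
    boundaries tau = +/-1 are handled as deterministic monotone/antitone
    quantile couplings rather than a degenerate bivariate normal.
    """

    kendall_tau: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.kendall_tau) > 1:
            raise ValueError("Kendall tau must lie in [-1, 1]")

    @property
    def rho(self) -> float:
        return kendall_to_gaussian_rho(self.kendall_tau)


def laplace(modifier, c: float) -> float:
    """Laplace transform ``E[exp(-c U1)]`` of a modifier law; equals 1 at c = 0."""
    return modifier.laplace(c)


def laplace_derivative(modifier, c: float) -> float:
    """Derivative ``d/dc E[exp(-c U1)] = -E[U1 exp(-c U1)]``; equals -E[U1] at c = 0."""
    return modifier.laplace_derivative(c)


def kendall_to_gaussian_rho(tau: float) -> float:
    """Normal correlation implied by Kendall's tau for a Gaussian copula: sin(pi*tau/2)."""
    if abs(tau) > 1:
        raise ValueError("Kendall tau must lie in [-1, 1]")
    return math.sin(math.pi * tau / 2.0)


def sample_joint(
    frailty,
    modifier,
    copula: CopulaSpec,
    n: int,
    rng: np.random.Generator | int,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` pairs ``(u0, u1)`` with the given margins and copula.

    Uniform ranks are drawn from the Gaussian copula (independent normals for
    tau = 0, the comonotone/antitone coupling for tau = +/-1) and pushed
    through the marginal quantile functions.  Deterministic given the
    generator state.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    tau = copula.kendall_tau
    if tau == 0.0:
        v0 = rng.uniform(size=n)
        v1 = rng.uniform(size=n)
    elif abs(tau) == 1.0:
        v0 = rng.uniform(size=n)
        v1 = v0 if tau > 0 else 1.0 - v0
    else:
        rho = copula.rho
        z0 = rng.standard_normal(n)
        z1 = rho * z0 + math.sqrt(1.0 - rho * rho) * rng.standard_normal(n)
        v0 = stats.norm.cdf(z0)
        v1 = stats.norm.cdf(z1)
    return frailty.ppf(v0), modifier.ppf(v1)


def laplace_monte_carlo(modifier, c: float, n: int = 200_000, seed: int = 0) -> float:
    """Monte-Carlo estimate of the Laplace transform via the quantile transform.

    Generic cross-check for the closed forms; not used by any estimand path.
    """
    rng = np.random.default_rng(seed)
    u = modifier.ppf(rng.uniform(size=n))
    return float(np.mean(np.exp(-c * u)))
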