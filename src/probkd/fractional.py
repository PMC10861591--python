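"""Fractional-derivative extension of the mass-action machinery.

The Caputo power rule D^alpha x^beta = Gamma(beta+1)/Gamma(beta-alpha+1)
x^(beta-alpha) gives non-integer "weights" for the integer stoichiometry
numbers of a reaction vector; the weights slot into the mass-action
dissociation constant as real exponents, and the same derivative drives an
element-wise fractional gradient-descent update step.

Negative stoichiometry numbers raised to fractional powers would be
complex; the signed-magnitude convention sign(m) |m|^(beta-alpha) keeps
everything real while preserving the reactant/product polarity encoded in
the sign.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gamma

__all__ = [
    "FractionalSpec",
    "FractionalWeights",
    "caputo_monomial",
    "fractional_weights",
    "fractional_gd_step",
    "kd_from_weights",
]


@dataclass(frozen=True)
class FractionalSpec:
    """Order parameters for the fractional machinery.

    alpha in (beta - 1, beta) is the fractional order, beta a non-negative
    integer, gamma in (0, 1) the gradient-descent learning rate.
    """

    alpha: float
    beta: int
    gamma: float = 0.1

    def __post_init__(self) -> None:
        if self.beta < 0 or int(self.beta) != self.beta:
            raise ValueError("beta must be a non-negative integer")
        if not (self.beta - 1 < self.alpha < self.beta):
            raise ValueError(
                f"alpha={self.alpha} must lie strictly inside ({self.beta - 1}, {self.beta})"
            )
        if not (0 < self.gamma < 1):
            raise ValueError("learning rate gamma must lie in (0, 1)")


@dataclass(frozen=True)
class FractionalWeights:
    """Per-reactant real-valued weights omega_j for one reaction vector."""

    weights: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.weights)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=float)


def _caputo_factor(alpha: float, beta: int) -> float:
    return float(gamma(beta + 1) / gamma(beta - alpha + 1))


def caputo_monomial(alpha: float, beta: int, x: float) -> float:
    """Caputo fractional derivative of x^beta at x >= 0.

    Returns Gamma(beta+1)/Gamma(beta-alpha+1) * x^(beta-alpha); alpha must
    lie strictly inside (beta-1, beta).
    """
    if not (beta - 1 < alpha < beta):
        raise ValueError(f"alpha={alpha} outside ({beta - 1}, {beta})")
    if x < 0:
        raise ValueError("x must be non-negative; use the signed-magnitude helpers")
    return _caputo_factor(alpha, beta) * float(x) ** (beta - alpha)


def fractional_weights(
    r: Sequence[int] | np.ndarray, alpha: float, beta: int
) -> FractionalWeights:
    """Signed-magnitude Caputo weights for a stoichiometry reaction vector.

    omega_j = sign(m_j) * Gamma(beta+1)/Gamma(beta-alpha+1) * |m_j|^(beta-alpha),
    with omega_j = 0 where m_j = 0.
    """
    if not (beta - 1 < alpha < beta):
        raise ValueError(f"alpha={alpha} outside ({beta - 1}, {beta})")
    m = np.asarray(r, dtype=float)
    factor = _caputo_factor(alpha, beta)
    w = np.sign(m) * factor * np.abs(m) ** (beta - alpha)
    w[m == 0] = 0.0
    return FractionalWeights(tuple(float(x) for x in w))


def fractional_gd_step(
    r: Sequence[float] | np.ndarray, spec: FractionalSpec
) -> np.ndarray:
    """One element-wise fractional gradient-descent update.

    r' = r - gamma * D^alpha(r^beta), with the Caputo derivative evaluated
    under the signed-magnitude convention so negative components stay real.
    """
    m = np.asarray(r, dtype=float)
    factor = _caputo_factor(spec.alpha, spec.beta)
    grad = np.sign(m) * factor * np.abs(m) ** (spec.beta - spec.alpha)
    grad[m == 0] = 0.0
    return m - spec.gamma * grad


def kd_from_weights(
    concentrations: Sequence[float],
    weights: FractionalWeights,
    M: int | None = None,
) -> float:
    """Mass-action Kd with fractional weights as exponents.

    Species with negative weights (consumed, reactant side) contribute
    |omega| to the numerator; positive weights (produced, product side)
    contribute |omega| to the denominator of the printed reactants-on-top
    convention.  ``M`` may be given explicitly; by default the sign of each
    weight partitions the species.
    """
    conc = np.asarray(concentrations, dtype=float)
    w = weights.as_array()
    if conc.shape != w.shape:
        raise ValueError("concentrations and weights must align")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be strictly positive")
    if M is not None:
        if not 1 <= M < conc.size:
            raise ValueError("M must satisfy 1 <= M < J")
        reactant = np.zeros(conc.size, dtype=bool)
        reactant[:M] = True
    else:
        reactant = w < 0
    num = float(np.prod(conc[reactant] ** np.abs(w[reactant])))
    den = float(np.prod(conc[~reactant] ** np.abs(w[~reactant])))
    return num / den
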