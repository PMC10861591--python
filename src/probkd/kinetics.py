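"""Classical reaction-kinetics scaffolding.

Rate law and reaction order for a single reaction, the dissociation-constant
outcome classes (forward / reverse / equivalent / non-productive), rate
comparison within an outcome class, and the mass-action dissociation
constant evaluated from concentrations and exponents.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "RateLaw",
    "rate_law_eval",
    "classify_kd",
    "compare_reactions",
    "mass_action_kd",
]

KdLabel = Literal["forward", "reverse", "equivalent", "non-productive"]

DEFAULT_EPS_ONE = 0.05
DEFAULT_EPS_ZERO = 1e-6


@dataclass(frozen=True)
class RateLaw:
    """Rate-law quantities for one reaction.

    concentrations are per-species positive reals (arbitrary units);
    exponents are the per-species kinetic orders; the first ``n_reactants``
    species are reactants, the rest products.
    """

    concentrations: tuple[float, ...]
    exponents: tuple[float, ...]
    n_reactants: int
    rate: float

    @property
    def rate_constant(self) -> float:
        lam, _ = rate_law_eval(
            self.rate,
            self.concentrations[: self.n_reactants],
            self.exponents[: self.n_reactants],
        )
        return lam

    @property
    def order(self) -> float:
        return float(sum(self.exponents[: self.n_reactants]))


def rate_law_eval(
    R: float, concentrations: Sequence[float], exponents: Sequence[float]
) -> tuple[float, float]:
    """Rate constant lambda = R / prod([A_j]^l_j) and order psi = sum(l_j)."""
    if R <= 0:
        raise ValueError("rate must be strictly positive")
    conc = np.asarray(concentrations, dtype=float)
    ell = np.asarray(exponents, dtype=float)
    if conc.shape != ell.shape:
        raise ValueError("concentrations and exponents must align")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be strictly positive")
    lam = float(R / np.prod(conc ** ell))
    psi = float(ell.sum())
    return lam, psi


def classify_kd(
    Kd: float,
    eps_one: float = DEFAULT_EPS_ONE,
    eps_zero: float = DEFAULT_EPS_ZERO,
) -> KdLabel:
    """Four-way dissociation-constant outcome.

    non-productive at Kd ~ 0 (a complex forms but never resolves), then the
    usual trichotomy: equivalent near 1, forward above 1, reverse in (0, 1).
    """
    if Kd < 0:
        raise ValueError("Kd must be non-negative")
    if Kd <= eps_zero:
        return "non-productive"
    if abs(Kd - 1.0) <= eps_one:
        return "equivalent"
    return "forward" if Kd > 1.0 else "reverse"


def compare_reactions(
    kds: Sequence[float], labels: Sequence[str]
) -> list[int]:
    """Rank reactions of one shared outcome class by rate (1 = fastest).

    Forward class: larger Kd means faster; reverse class: smaller Kd means
    faster; equivalent class: all rates tied (every rank 1).
    """
    labels = list(labels)
    if len(set(labels)) != 1:
        raise ValueError("comparison defined within a class only")
    label = labels[0]
    kds = [float(k) for k in kds]
    if label == "equivalent":
        return [1] * len(kds)
    if label == "forward":
        order = sorted(range(len(kds)), key=lambda i: -kds[i])
    elif label == "reverse":
        order = sorted(range(len(kds)), key=lambda i: kds[i])
    else:
        raise ValueError(f"cannot rank class {label!r}")
    ranks = [0] * len(kds)
    for rank, i in enumerate(order, start=1):
        ranks[i] = rank
    return ranks


def mass_action_kd(
    concentrations: Sequence[float],
    exponents: Sequence[float],
    M: int,
    reactants_in_numerator: bool = True,
) -> float:
    """Mass-action dissociation constant from concentrations and exponents.

    Kd = prod_{j<=M} [A_j]^e_j / prod_{j>M} [A_j]^e_j with the first M
    species the reactants.  ``reactants_in_numerator`` keeps the printed
    convention (reactants on top); set it False for the common biochemical
    convention (products over reactants).
    """
    conc = np.asarray(concentrations, dtype=float)
    ell = np.asarray(exponents, dtype=float)
    if conc.shape != ell.shape:
        raise ValueError("concentrations and exponents must align")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be strictly positive")
    if not 1 <= M < conc.size:
        raise ValueError("M must satisfy 1 <= M < J")
    num = float(np.prod(conc[:M] ** ell[:M]))
    den = float(np.prod(conc[M:] ** ell[M:]))
    kd = num / den
    if not reactants_in_numerator:
        kd = 1.0 / kd
    return kd
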