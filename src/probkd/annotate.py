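"""Per-reaction outcome binning, the probable dissociation constant, and the
whole-network annotation loop.

Each reaction i corresponds to a row of the subspace A_u.  The row's terms
are characterised by their mean mu and population standard deviation sigma;
terms beyond mu + 2 sigma are binned into a forward subset F (positive
extremes) or a reverse subset B (negative extremes).  When F and B balance
in count and their sums cancel, the reaction is "equivalent" and the merged
alternating subset E carries the (near-zero) sum.  The populated subset's
sum phi is mapped into (0, inf):

    forward, B empty:      y_F = phi_F
    forward, B non-empty:  y_F = phi_F + exp(phi_B)
    reverse:               y_B = exp(phi_B)
    equivalent:            y_E = exp(phi_E) ~ 1

The p1-norm of the outcome vector (y_F, y_B, y_E) is the probable
dissociation constant eta; eta > 1 labels the reaction forward, eta in
(0, 1) reverse, eta ~ 1 equivalent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .stoich import StoichiometryMatrix, validate_network
from .subspace import (
    DEFAULT_MAX_SUBSPACE,
    DEFAULT_TOL_DUP,
    DEFAULT_TOL_ZERO,
    SubspaceState,
    combinatorial_sum,
    nullspace_basis,
    projected_candidate_count,
    screen_vectors,
)

__all__ = [
    "RowSequence",
    "OutcomeRecord",
    "AnnotationResult",
    "AnnotationConfig",
    "IncompleteAnnotationError",
    "row_stats",
    "bin_row",
    "map_outcome_sums",
    "probable_kd",
    "classify_eta",
    "annotate_network",
    "summarize",
]

_EXP_CLAMP = 700.0  # |exponent| beyond which exp() would over/underflow

Label = Literal["forward", "reverse", "equivalent"]
Case = Literal["forward", "reverse", "equivalent", "ambiguous"]


@dataclass(frozen=True)
class RowSequence:
    """One reaction's sequence of terms across all vectors of A_u."""

    reaction_id: str
    terms: np.ndarray
    phi: float
    mu: float
    sigma: float
    K: int

    @classmethod
    def from_terms(cls, reaction_id: str, terms: np.ndarray) -> "RowSequence":
        terms = np.asarray(terms, dtype=float)
        mu, sigma = row_stats(terms)
        return cls(
            reaction_id=reaction_id,
            terms=terms,
            phi=float(terms.sum()),
            mu=mu,
            sigma=sigma,
            K=terms.size,
        )


@dataclass
class OutcomeRecord:
    """Final annotation of one reaction."""

    reaction_id: str
    F: list[float]
    B: list[float]
    E: list[float]
    phi_F: float
    phi_B: float
    phi_E: float
    y_F: float
    y_B: float
    y_E: float
    eta: float
    label: Label
    iterations_used: int
    ambiguous: bool = False


@dataclass
class AnnotationConfig:
    """Tunable tolerances and enumeration caps for the annotation loop."""

    tol_zero: float = DEFAULT_TOL_ZERO
    tol_dup: float = DEFAULT_TOL_DUP
    eps_one: float = 0.05       # half-width of the equivalent band around eta = 1
    eps_equiv: float = 0.05     # relative cancellation tolerance for phi_F + phi_B ~ 0
    balance_tol: int | None = None  # |#F - #B| allowance; default max(1, ceil(0.1 (#F+#B)))
    max_iterations: int = 25
    max_subspace: int = DEFAULT_MAX_SUBSPACE
    max_subset_size: int | None = None

    def balance_allowance(self, nF: int, nB: int) -> int:
        if self.balance_tol is not None:
            return self.balance_tol
        return max(1, math.ceil(0.1 * (nF + nB)))


@dataclass
class AnnotationResult:
    """One OutcomeRecord per reaction plus run-level bookkeeping."""

    records: list[OutcomeRecord]
    summary: dict
    config: AnnotationConfig
    M: int | None = None
    iterations: int = 0
    cardinality_history: list[int] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        rows = []
        for r in self.records:
            rows.append(
                dict(
                    reaction_id=r.reaction_id,
                    eta=r.eta,
                    label=r.label,
                    phi_F=r.phi_F,
                    phi_B=r.phi_B,
                    phi_E=r.phi_E,
                    n_F=len(r.F),
                    n_B=len(r.B),
                    iterations_used=r.iterations_used,
                    ambiguous=r.ambiguous,
                )
            )
        return pd.DataFrame(rows)


class IncompleteAnnotationError(RuntimeError):
    """Raised when iteration/size caps are exhausted before every reaction
    carries an unambiguous label.  The partial result is attached."""

    def __init__(self, message: str, partial: AnnotationResult | None = None):
        super().__init__(message)
        self.partial = partial


def row_stats(terms: np.ndarray) -> tuple[float, float]:
    """Mean and population standard deviation (denominator K) of a row."""
    terms = np.asarray(terms, dtype=float)
    if terms.size < 1:
        raise ValueError("row must contain at least one term")
    mu = float(terms.mean())
    sigma = float(np.sqrt(np.mean((terms - mu) ** 2)))
    return mu, sigma


def bin_row(
    row: RowSequence,
    eps_equiv: float = 0.05,
    balance_tol: int | None = None,
) -> tuple[list[float], list[float], list[float], Case]:
    """Select extreme terms into the F/B subsets and decide the outcome case.

    F collects terms above mu + 2 sigma (and positive); B collects negative
    terms whose magnitude exceeds |mu + 2 sigma|.  The equivalent case holds
    when both subsets are populated, nearly balanced in count, and their
    sums cancel within ``eps_equiv`` relative tolerance; E is then the
    alternating merge of B and F.  An empty F u B yields the ambiguous case,
    which triggers further iterations upstream.
    """
    terms = row.terms
    thr = row.mu + 2.0 * row.sigma
    F = [float(a) for a in terms if a > thr and a > 0]
    B = [float(a) for a in terms if a < 0 and abs(a) > abs(thr)]
    if not F and not B:
        return F, B, [], "ambiguous"
    phi_F = sum(F)
    phi_B = sum(B)
    if F and B:
        allowance = (
            balance_tol
            if balance_tol is not None
            else max(1, math.ceil(0.1 * (len(F) + len(B))))
        )
        balanced = abs(len(F) - len(B)) <= allowance
        cancelling = abs(phi_F + phi_B) <= eps_equiv * (abs(phi_F) + abs(phi_B))
        if balanced and cancelling:
            E: list[float] = []
            for b, f in zip(B, F):
                E.extend((b, f))
            longer = F if len(F) > len(B) else B
            E.extend(longer[min(len(F), len(B)):])
            return F, B, E, "equivalent"
    net = phi_F + phi_B
    if net > 0:
        return F, B, [], "forward"
    if net < 0:
        return F, B, [], "reverse"
    return F, B, [], "ambiguous"


def map_outcome_sums(
    F: list[float], B: list[float], E: list[float], case: Case
) -> tuple[float, float, float]:
    """Map the populated subset sum into (0, inf); other components stay 0."""
    phi_F = sum(F)
    phi_B = sum(B)
    # exponents are clamped so the mapped component stays inside (0, inf)
    # in floating point even for strongly diverging sums
    if case == "forward":
        if B:
            return phi_F + math.exp(max(phi_B, -_EXP_CLAMP)), 0.0, 0.0
        return phi_F, 0.0, 0.0
    if case == "reverse":
        return 0.0, math.exp(max(phi_B, -_EXP_CLAMP)), 0.0
    if case == "equivalent":
        phi_E = phi_F + phi_B
        return 0.0, 0.0, math.exp(min(max(phi_E, -_EXP_CLAMP), _EXP_CLAMP))
    raise ValueError("ambiguous case cannot be mapped; iterate further instead")


def probable_kd(y_F: float, y_B: float, y_E: float) -> float:
    """p1-norm of the outcome vector: eta = y_F + y_B + y_E > 0."""
    eta = y_F + y_B + y_E
    if not eta > 0:
        raise ValueError(f"outcome vector maps to non-positive eta = {eta}")
    return eta


def classify_eta(eta: float, eps_one: float = 0.05) -> Label:
    """Trichotomy: equivalent within eps_one of 1, else forward (>1) or reverse."""
    if eta <= 0:
        raise ValueError("eta must be strictly positive")
    if abs(eta - 1.0) <= eps_one:
        return "equivalent"
    return "forward" if eta > 1.0 else "reverse"


def _annotate_rows(
    state: SubspaceState, reaction_ids: tuple[str, ...], config: AnnotationConfig
) -> list[OutcomeRecord] | None:
    """Bin every row of A_u; None when any reaction is still ambiguous."""
    rows = state.row_matrix()
    records: list[OutcomeRecord] = []
    for i, rid in enumerate(reaction_ids):
        seq = RowSequence.from_terms(rid, rows[i])
        F, B, E, case = bin_row(seq, config.eps_equiv, config.balance_tol)
        if case == "ambiguous":
            return None
        y_F, y_B, y_E = map_outcome_sums(F, B, E, case)
        eta = probable_kd(y_F, y_B, y_E)
        records.append(
            OutcomeRecord(
                reaction_id=rid,
                F=F,
                B=B,
                E=E,
                phi_F=sum(F),
                phi_B=sum(B),
                phi_E=sum(F) + sum(B) if case == "equivalent" else 0.0,
                y_F=y_F,
                y_B=y_B,
                y_E=y_E,
                eta=eta,
                label=classify_eta(eta, config.eps_one),
                iterations_used=state.u,
            )
        )
    return records


def _feasible_subset_size(K: int, config: AnnotationConfig) -> int | None:
    """Largest subset size whose cumulative candidate count fits the cap."""
    qcap = K if config.max_subset_size is None else min(K, config.max_subset_size)
    total = 0
    best = None
    for q in range(2, qcap + 1):
        total += math.comb(K, q)
        if total > config.max_subspace:
            break
        best = q
    return best


def annotate_network(
    S: StoichiometryMatrix, config: AnnotationConfig | None = None
) -> AnnotationResult:
    """Annotate every reaction of a validated network.

    Runs the null-space basis, then iterates combinatorial summation and
    screening until every row is resolved and binning is unambiguous for
    all reactions.  When a full-size enumeration would exceed the subspace
    cap, the subset size is reduced to the largest feasible value; when
    even pairwise sums do not fit, or ``max_iterations`` is exhausted, an
    IncompleteAnnotationError carrying the partial result is raised.
    """
    config = config or AnnotationConfig()
    report = validate_network(S)
    if not report.valid:
        raise ValueError(
            "invalid stoichiometry matrix: " + "; ".join(report.violations)
        )
    if report.removed_duplicate_reactions:
        keep = [r for r in S.reaction_ids if r not in report.removed_duplicate_reactions]
        S = S.select_reactions(keep)

    state = nullspace_basis(S, config.tol_zero)
    A = S.entries.astype(float)
    last_records: list[OutcomeRecord] | None = None
    for _ in range(config.max_iterations):
        q = _feasible_subset_size(state.K, config)
        if q is None:
            break
        candidates = combinatorial_sum(state, q, hard_cap=config.max_subspace)
        state = screen_vectors(
            state, candidates, tol_zero=config.tol_zero, tol_dup=config.tol_dup
        )
        residual = np.abs(A @ state.vectors.T).max()
        if residual > max(config.tol_zero, 1e-7 * state.K):
            raise RuntimeError(
                f"subspace closure violated: residual {residual:g} at u={state.u}"
            )
        if state.resolved is not None and bool(state.resolved.all()):
            records = _annotate_rows(state, S.reaction_ids, config)
            if records is not None:
                result = AnnotationResult(
                    records=records,
                    summary={},
                    config=config,
                    M=state.M,
                    iterations=state.u,
                    cardinality_history=list(state.cardinality_history),
                )
                result.summary = summarize(result)
                return result
            last_records = records

    unresolved = []
    if state.resolved is not None:
        unresolved = [
            S.reaction_ids[i] for i in range(S.I_bar) if not state.resolved[i]
        ]
    partial = AnnotationResult(
        records=[],
        summary={},
        config=config,
        M=state.M,
        iterations=state.u,
        cardinality_history=list(state.cardinality_history),
    )
    raise IncompleteAnnotationError(
        "incomplete annotation: caps exhausted"
        + (f"; unresolved rows: {', '.join(unresolved)}" if unresolved else
           "; all rows resolved but binning stayed ambiguous"),
        partial=partial,
    )


def summarize(result: AnnotationResult) -> dict:
    """Per-label counts and percentages, and the non-equivalent fraction."""
    n = len(result.records)
    counts = {"forward": 0, "reverse": 0, "equivalent": 0}
    for r in result.records:
        counts[r.label] += 1
    percentages = {k: (100.0 * v / n if n else 0.0) for k, v in counts.items()}
    return {
        "n_reactions": n,
        "counts": counts,
        "percentages": percentages,
        "non_equivalent_fraction": (
            (counts["forward"] + counts["reverse"]) / n if n else 0.0
        ),
    }
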