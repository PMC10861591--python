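"""Null-space generation, combinatorial subset summation and screening.

The algorithm treats every weighting v of the reactions with S.v = 0 as a
steady-state flux combination.  Starting from an orthonormal null-space
basis (iteration u = 0), each iteration combinatorially sums subsets of the
current vectors, unions the basis back in, and screens the result: vectors
that are numerically zero are dropped, groups of identical vectors keep a
single representative.  The survivors form the reduced-cardinality subspace
A_u whose rows (one per reaction) are the sequences later binned into
outcome subsets.

Because every subset of a set of K vectors of size q = 2..K is enumerated,
per-iteration work is O(2^K); the engine is therefore guarded by a
configurable maximum subset size and a hard cap on the candidate count, and
annotation stops at the first iteration whose rows are all resolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from math import comb

import numpy as np

from .stoich import StoichiometryMatrix

__all__ = [
    "SubspaceState",
    "SubspaceExplosionError",
    "TrivialNullSpaceError",
    "DegenerateSubspaceError",
    "sign_canon",
    "nullspace_basis",
    "combinatorial_sum",
    "projected_candidate_count",
    "screen_vectors",
    "partition_count",
    "theta_bar",
    "min_network_bounds",
    "row_resolved",
    "row_limit_diagnostic",
]

DEFAULT_TOL_ZERO = 1e-9
DEFAULT_TOL_DUP = 1e-9
DEFAULT_MAX_SUBSPACE = 500_000

_EXP_CLAMP = 700.0  # |exponent| beyond which exp() would over/underflow


class TrivialNullSpaceError(ValueError):
    """The stoichiometry matrix has full column rank: no non-trivial S.v = 0."""


class SubspaceExplosionError(RuntimeError):
    """Projected candidate count exceeds the configured hard cap."""


class DegenerateSubspaceError(RuntimeError):
    """Screening removed every candidate vector."""


@dataclass
class SubspaceState:
    """The iteration-u collection A_u of unique, non-trivial vectors.

    ``vectors`` has shape (K, I): row k is the k-th subspace vector.
    ``basis`` is the u = 0 orthonormal null-space basis, carried along so
    that later iterations can union it back into the candidate pool.
    """

    u: int
    vectors: np.ndarray
    basis: np.ndarray
    count_unique: int = 0
    count_identical_removed: int = 0
    count_trivial_removed: int = 0
    theta: int = 0
    resolved: np.ndarray | None = None
    M: int | None = None
    cardinality_history: list[int] = field(default_factory=list)

    @property
    def K(self) -> int:
        return self.vectors.shape[0]

    @property
    def I_bar(self) -> int:
        return self.vectors.shape[1]

    def row_matrix(self) -> np.ndarray:
        """Reactions-as-rows view of A_u (shape I x K)."""
        return self.vectors.T


def sign_canon(vectors: np.ndarray, copy: bool = True) -> np.ndarray:
    """Flip each vector so its largest-magnitude component is positive.

    Ties are broken by the lowest index (numpy argmax convention).  The
    canon makes duplicate detection insensitive to the arbitrary signs of
    an SVD basis and keeps runs reproducible.
    """
    v = np.array(vectors, dtype=float, copy=copy)
    if v.ndim == 1:
        v = v[None, :]
        idx = np.abs(v).argmax(axis=1)
        flip = v[np.arange(v.shape[0]), idx] < 0
        v[flip] *= -1.0
        return v[0]
    idx = np.abs(v).argmax(axis=1)
    flip = v[np.arange(v.shape[0]), idx] < 0
    v[flip] *= -1.0
    return v


def nullspace_basis(S: StoichiometryMatrix, tol_zero: float = DEFAULT_TOL_ZERO) -> SubspaceState:
    """Orthonormal basis of {v : S.v = 0} as the u = 0 state.

    The basis comes from a singular-value decomposition and is made
    deterministic by the sign canon (largest-magnitude component positive).
    """
    from scipy.linalg import null_space

    A = S.entries.astype(float)
    basis = null_space(A)
    if basis.shape[1] == 0:
        raise TrivialNullSpaceError(
            "trivial null space: the matrix has full column rank"
        )
    vectors = sign_canon(basis.T)
    residual = np.abs(A @ vectors.T).max()
    if residual > tol_zero:
        raise RuntimeError(f"null-space residual {residual:g} exceeds tol_zero")
    state = SubspaceState(u=0, vectors=vectors, basis=vectors.copy(),
                          count_unique=vectors.shape[0])
    state.cardinality_history.append(vectors.shape[0])
    return state


def projected_candidate_count(K: int, max_subset_size: int | None = None) -> int:
    """Number of subset sums of sizes 2..min(K, max_subset_size): sum of C(K, q)."""
    qmax = K if max_subset_size is None else min(K, max_subset_size)
    return sum(comb(K, q) for q in range(2, qmax + 1))


def combinatorial_sum(
    state: SubspaceState,
    max_subset_size: int | None = None,
    hard_cap: int = DEFAULT_MAX_SUBSPACE,
) -> np.ndarray:
    """Sum every subset of the current vectors of size q = 2..max_subset_size.

    Subsets are enumerated in deterministic lexicographic order, smallest
    size first.  The null space is closed under addition, so every candidate
    again satisfies S.v ~ 0.

    Raises
    ------
    SubspaceExplosionError
        If the projected candidate count exceeds ``hard_cap``; the caller
        should retry with a smaller ``max_subset_size`` or report the
        network as intractable for full enumeration.
    """
    K = state.K
    if K < 2:
        raise ValueError("combinatorial summation needs at least 2 vectors")
    qmax = K if max_subset_size is None else min(K, max_subset_size)
    if qmax < 2:
        raise ValueError("max_subset_size must be at least 2")
    total = projected_candidate_count(K, qmax)
    if total > hard_cap:
        raise SubspaceExplosionError(
            f"{total} candidate subset sums exceed the cap of {hard_cap}; "
            "reduce max_subset_size or accept that full enumeration is "
            "intractable for this network"
        )
    V = state.vectors
    out = np.empty((total, state.I_bar), dtype=float)
    pos = 0
    for q in range(2, qmax + 1):
        idx = np.fromiter(
            (i for combo in combinations(range(K), q) for i in combo),
            dtype=np.intp,
            count=comb(K, q) * q,
        ).reshape(-1, q)
        out[pos : pos + idx.shape[0]] = V[idx].sum(axis=1)
        pos += idx.shape[0]
    return out


def screen_vectors(
    previous: SubspaceState,
    candidates: np.ndarray,
    tol_zero: float = DEFAULT_TOL_ZERO,
    tol_dup: float = DEFAULT_TOL_DUP,
    include_basis: bool = True,
) -> SubspaceState:
    """Screen candidates into the next reduced-cardinality state A_{u+1}.

    The candidate pool is the union of the u = 0 basis and the subset sums.
    Vectors that are zero within ``tol_zero`` (infinity norm) are counted
    and dropped; groups of identical vectors (within ``tol_dup`` after sign
    canon) keep exactly one representative, the first in enumeration order.
    theta counts the collapsed identical groups.
    """
    pool = np.asarray(candidates, dtype=float)
    if pool.ndim != 2 or pool.shape[1] != previous.I_bar:
        raise ValueError("candidate array has wrong shape")
    if include_basis:
        pool = np.vstack([previous.basis, pool])

    nonzero = np.abs(pool).max(axis=1) > tol_zero
    n_trivial = int((~nonzero).sum())
    pool = pool[nonzero]
    if pool.shape[0] == 0:
        raise DegenerateSubspaceError("screening removed every candidate vector")

    # Tolerance dedup by quantising onto a tol_dup grid; exact duplicates of
    # floating-point sums land in the same cell.  The sign canon is applied
    # to the *keys only*, so v and -v count as one redundant direction while
    # the stored representative keeps its as-generated orientation (storing
    # the canon form would let the pool close on itself: v1 + v2 flipped to
    # -(v1 + v2) regenerates -v1 and -v2 and the iteration reaches a fixed
    # point instead of growing).
    keys = np.round(sign_canon(pool) / tol_dup).astype(np.int64)
    seen: dict[bytes, int] = {}
    keep: list[int] = []
    group_sizes: dict[int, int] = {}
    for k in range(pool.shape[0]):
        key = keys[k].tobytes()
        if key in seen:
            group_sizes[seen[key]] += 1
        else:
            seen[key] = k
            keep.append(k)
            group_sizes[k] = 1
    survivors = pool[keep]
    theta = sum(1 for sz in group_sizes.values() if sz > 1)
    n_dup = pool.shape[0] - survivors.shape[0]

    state = SubspaceState(
        u=previous.u + 1,
        vectors=survivors,
        basis=previous.basis,
        count_unique=survivors.shape[0],
        count_identical_removed=n_dup,
        count_trivial_removed=n_trivial,
        theta=theta,
        M=previous.M,
        cardinality_history=list(previous.cardinality_history),
    )
    state.cardinality_history.append(survivors.shape[0])
    rows = state.row_matrix()
    state.resolved = np.array([row_resolved(rows[i]) for i in range(rows.shape[0])])
    if state.M is None and bool(state.resolved.all()):
        state.M = state.u
    return state


def partition_count(n: int) -> int:
    """Number of ways to split n identical vectors off: 1 + sum_{t=2}^{n-2} C(n, t).

    Exact integer arithmetic; requires n >= 4 so the summation range is
    non-empty.
    """
    if n < 4:
        raise ValueError("summation range empty: need n >= 4")
    return 1 + sum(comb(n, t) for t in range(2, n - 1))


def theta_bar(J: int) -> int:
    """sum_{t=2}^{J-2} C(J, t): the master-partition count for J species."""
    return sum(comb(J, t) for t in range(2, J - 1))


def min_network_bounds() -> tuple[int, int]:
    """Smallest biochemically relevant network dimensions (J_min, I_min).

    J_min is the smallest J for which the summation range t = 2..J-2 is
    non-empty; I_min is theta_bar evaluated there.
    """
    J = 2
    while J - 2 < 2:  # range t = 2..J-2 empty
        J += 1
    return J, theta_bar(J)


def row_resolved(row: np.ndarray) -> bool:
    """True when a reaction's sequence of terms has escaped the unit interval.

    A row is resolved when its extremes diverge positively (max > 1),
    negatively (min < -1), or both (a mixed-sign alternating sequence with
    extremes beyond unit magnitude on both sides).  The u = 0 basis is
    always unioned back into each iteration's pool, so small-magnitude and
    structurally zero terms persist in every row forever; divergence is
    therefore judged on the extremes, not on every term.
    """
    row = np.asarray(row, dtype=float)
    if row.size == 0:
        raise ValueError("empty row")
    mn = float(row.min())
    mx = float(row.max())
    return mx > 1.0 or mn < -1.0


def row_limit_diagnostic(row: np.ndarray) -> tuple[float, float, float]:
    """Unit-limit diagnostics (forward, reverse, applicable) for a resolved row.

    forward = 1 + exp(min(row) - phi), reverse = 1 + exp(phi - max(row)),
    with phi the row sum; both approach 1 as |phi| grows.  Exponents are
    clamped to avoid overflow.
    """
    row = np.asarray(row, dtype=float)
    phi = float(row.sum())
    mn = float(row.min())
    mx = float(row.max())
    fwd = 1.0 + np.exp(np.clip(mn - phi, -_EXP_CLAMP, _EXP_CLAMP))
    rev = 1.0 + np.exp(np.clip(phi - mx, -_EXP_CLAMP, _EXP_CLAMP))
    if phi > 0:
        applicable = fwd
    elif phi < 0:
        applicable = rev
    else:
        applicable = min(fwd, rev)
    return float(fwd), float(rev), float(applicable)
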