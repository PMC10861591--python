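from itertools import combinations

import numpy as np
import pytest

from probkd import (
    StoichiometryMatrix,
    SubspaceExplosionError,
    TrivialNullSpaceError,
    combinatorial_sum,
    min_network_bounds,
    nullspace_basis,
    partition_count,
    projected_candidate_count,
    row_limit_diagnostic,
    row_resolved,
    screen_vectors,
    sign_canon,
    theta_bar,
)


def brute_force_screen(candidates, tol_zero=1e-9, tol_dup=1e-9):
    """Independent O(n^2) reference: drop near-zero vectors, then keep the
    first representative of every group equal within tol_dup after sign
    canon."""
    nonzero = [v for v in candidates if np.abs(v).max() > tol_zero]
    survivors = []
    for v in nonzero:
        cv = sign_canon(v)
        if not any(np.abs(cv - sign_canon(s)).max() <= tol_dup for s in survivors):
            survivors.append(v)
    return survivors


class TestNullspaceBasis:
    def test_t1_basis_size_and_closure(self, t1):
        state = nullspace_basis(t1)
        assert state.K == 3
        residual = np.abs(t1.entries.astype(float) @ state.vectors.T).max()
        assert residual <= 1e-10

    def test_t1_span_contains_cycle_combinations(self, t1):
        """The three independent cycles of the toy network (r1+r2-r5,
        r2+r3-r6, r1+r2+r3+r4) must lie in the basis span."""
        state = nullspace_basis(t1)
        B = state.vectors.T  # I x K
        for cycle in (
            [1, 1, 0, 0, -1, 0],
            [0, 1, 1, 0, 0, -1],
            [1, 1, 1, 1, 0, 0],
        ):
            c = np.array(cycle, dtype=float)
            proj = B @ np.linalg.lstsq(B, c, rcond=None)[0]
            assert np.abs(proj - c).max() <= 1e-9

    def test_full_column_rank_raises(self, full_column_rank_matrix):
        with pytest.raises(TrivialNullSpaceError):
            nullspace_basis(full_column_rank_matrix)

    def test_ag_basis_size_matches_nullity(self, ag):
        state = nullspace_basis(ag)
        rank = np.linalg.matrix_rank(ag.entries.astype(float))
        assert state.K == ag.I_bar - rank

    def test_sign_canon_deterministic(self, t1):
        a = nullspace_basis(t1).vectors
        b = nullspace_basis(t1).vectors
        assert np.array_equal(a, b)
        idx = np.abs(a).argmax(axis=1)
        assert (a[np.arange(a.shape[0]), idx] > 0).all()


class TestCombinatorialSum:
    @pytest.mark.parametrize("K, expected", [(2, 1), (3, 4)])
    def test_small_counts(self, t1, K, expected):
        state = nullspace_basis(t1)
        state.vectors = state.vectors[:K]
        cands = combinatorial_sum(state, hard_cap=10**6)
        assert cands.shape[0] == expected

    @pytest.mark.parametrize("K", range(2, 13))
    def test_candidate_count_matches_binomial_sum(self, K):
        """Unbounded per-iteration candidate count is sum_{q=2}^{K} C(K, q)."""
        from math import comb

        rng = np.random.default_rng(K)
        vecs = rng.normal(size=(K, 6))
        from probkd.subspace import SubspaceState

        state = SubspaceState(u=0, vectors=vecs, basis=vecs)
        cands = combinatorial_sum(state, hard_cap=10**6)
        expected = sum(comb(K, q) for q in range(2, K + 1))
        assert cands.shape[0] == expected == projected_candidate_count(K)

    def test_candidates_stay_in_null_space(self, t1):
        state = nullspace_basis(t1)
        cands = combinatorial_sum(state, hard_cap=10**6)
        residual = np.abs(t1.entries.astype(float) @ cands.T).max()
        assert residual <= 1e-9

    def test_explosion_guard(self, t1):
        state = nullspace_basis(t1)
        with pytest.raises(SubspaceExplosionError):
            combinatorial_sum(state, hard_cap=2)


class TestScreening:
    def test_duplicates_and_zeros_dropped(self, t1):
        state = nullspace_basis(t1)
        v = state.vectors[0]
        cands = np.vstack([v, v, np.zeros_like(v)])
        out = screen_vectors(state, cands, include_basis=False)
        assert out.count_trivial_removed == 1
        assert out.count_identical_removed == 1
        assert out.theta == 1
        assert out.K == 1

    def test_identity_screening(self, t1):
        state = nullspace_basis(t1)
        cands = combinatorial_sum(state, hard_cap=10**6)
        out = screen_vectors(state, cands, include_basis=False)
        assert out.theta == 0
        assert out.K == cands.shape[0]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, t1, seed):
        """Survivor set equals the O(n^2) tolerance-dedup reference on
        randomly corrupted candidate pools (duplicates, negations, zeros)."""
        state = nullspace_basis(t1)
        base = combinatorial_sum(state, hard_cap=10**6)
        rng = np.random.default_rng(seed)
        pool = [state.vectors[i] for i in range(state.K)] + [
            base[i] for i in range(base.shape[0])
        ]
        extra = []
        for v in pool:
            r = rng.random()
            if r < 0.3:
                extra.append(v.copy())       # duplicate
            elif r < 0.5:
                extra.append(-v)             # negated duplicate direction
            elif r < 0.6:
                extra.append(np.zeros_like(v))
        cands = np.vstack(pool + extra)
        out = screen_vectors(state, cands, include_basis=False)
        ref = brute_force_screen(list(cands))
        assert out.K == len(ref)
        for got, want in zip(out.vectors, ref):
            assert np.abs(got - want).max() <= 1e-12


class TestPartitionCount:
    @pytest.mark.parametrize("n", range(4, 13))
    def test_matches_subset_enumeration(self, n):
        """Theta(n) = 1 + number of subsets of sizes 2..n-2, by brute force."""
        enumerated = 1 + sum(
            1 for t in range(2, n - 1) for _ in combinations(range(n), t)
        )
        assert partition_count(n) == enumerated

    def test_known_values(self):
        assert partition_count(4) == 7
        assert partition_count(5) == 21

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError, match="summation range empty"):
            partition_count(3)


def test_min_network_bounds():
    j_min, i_min = min_network_bounds()
    assert j_min == 4
    assert i_min == 6
    assert theta_bar(5) == 20


class TestRowResolution:
    @pytest.mark.parametrize(
        "row, expected",
        [
            ((2.3, 5.1, 1.7), True),       # positive divergence
            ((-4.0, -1.5, -2.2), True),    # negative divergence
            ((-1.5, 2.0, 0.1), True),      # alternating, both extremes out
            ((0.5, 2.0, 3.0), True),       # max escaped the unit interval
            ((0.5, 0.9, -0.2), False),     # everything inside [-1, 1]
            ((0.0, 1.0, -1.0), False),     # extremes exactly on the boundary
        ],
    )
    def test_predicate(self, row, expected):
        assert row_resolved(np.array(row)) is expected

    def test_limit_diagnostics_approach_unity(self):
        row = np.full(25, 2.0)  # phi = 50, min = 2
        fwd, rev, app = row_limit_diagnostic(row)
        assert fwd == pytest.approx(1.0 + np.exp(-48.0))
        assert app == pytest.approx(1.0, abs=1e-6)
        row = np.full(25, -2.0)  # phi = -50, max = -2
        fwd, rev, app = row_limit_diagnostic(row)
        assert rev == pytest.approx(1.0 + np.exp(-48.0))
        assert app == pytest.approx(1.0, abs=1e-6)

    def test_limit_diagnostic_balanced_row(self):
        row = np.array([20.0, -20.0, 10.0, -10.0])  # phi = 0, extremes +-20
        _, _, app = row_limit_diagnostic(row)
        assert app == pytest.approx(1.0, abs=1e-6)

    def test_no_overflow_for_extreme_sums(self):
        row = np.array([1e4, -1e4, 5e3])
        fwd, rev, app = row_limit_diagnostic(row)
        assert np.isfinite([fwd, rev, app]).all()
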