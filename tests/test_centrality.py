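"""Matrix-free dominant patterns against dense eigendecomposition oracles.

Every implicit quantity (matvec, stationary basis, centered eigenpair) is
checked on small instances where the dense voxel x voxel matrix can be
formed explicitly.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dynparc.centrality import (DominantPattern, StationaryBasis,
                                centered_matvec, dominant_pattern,
                                make_windows, normalize_window, run_subject,
                                stationary_basis)


def dense_centered(Xw, basis):
    """Oracle: the centered matrix C_i - C_M formed explicitly."""
    C = Xw @ Xw.T
    if basis is not None:
        C = C - (basis.vectors * basis.eigenvalues) @ basis.vectors.T
    return C


class TestMakeWindows:
    @pytest.mark.parametrize("T,length,step", [
        (1190, 83, 5), (100, 60, 5), (400, 83, 5), (97, 30, 7)])
    def test_count_matches_enumeration_oracle(self, T, length, step):
        starts = [s for s in range(0, T, step) if s + length <= T
                  and s % step == 0]
        spec = make_windows(T, length, step)
        assert spec.n_windows == len(starts)
        np.testing.assert_array_equal(spec.window_starts, starts)

    def test_sixty_second_windows_of_full_length_run(self):
        # 1190 frames at TR 0.72 s, 83-TR windows stepping 5 TR
        assert make_windows(1190, 83, 5).n_windows == 222

    def test_window_equal_to_run_gives_one_window(self):
        spec = make_windows(83, 83, 5)
        assert spec.n_windows == 1

    def test_oversized_window_rejected(self):
        with pytest.raises(ValueError):
            make_windows(50, 60, 5)


class TestNormalizeWindow:
    def test_implicit_matrix_is_pearson_correlation(self, rng):
        Xw = normalize_window(rng.standard_normal((30, 83)))
        C = Xw @ Xw.T
        oracle = np.corrcoef(Xw)  # dense Pearson correlation oracle
        np.testing.assert_allclose(np.diag(C), 1.0, atol=1e-10)
        np.testing.assert_allclose(C, oracle, atol=1e-10)

    def test_rows_zero_mean_unit_norm(self, rng):
        Xw = normalize_window(rng.standard_normal((10, 40)) * 7 + 3)
        np.testing.assert_allclose(Xw.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(np.linalg.norm(Xw, axis=1), 1, atol=1e-10)

    def test_identical_rows_fully_correlated(self, rng):
        row = rng.standard_normal(50)
        Xw = normalize_window(np.vstack([row, row]))
        assert Xw[0] @ Xw[1] == pytest.approx(1.0, abs=1e-12)

    def test_constant_row_names_offending_voxel(self, rng):
        X = rng.standard_normal((5, 30))
        X[3] = 2.0
        with pytest.raises(ValueError, match="3"):
            normalize_window(X)


class TestStationaryBasis:
    def test_matches_dense_eigendecomposition(self, rng):
        X = normalize_window(rng.standard_normal((100, 300)))
        basis = stationary_basis(X, 10)
        dense_vals = np.linalg.eigvalsh(X @ X.T)[::-1][:10]
        np.testing.assert_allclose(basis.eigenvalues, dense_vals, atol=1e-8)
        # eigenvectors orthonormal and actually eigenvectors
        V = basis.vectors
        np.testing.assert_allclose(V.T @ V, np.eye(10), atol=1e-8)
        resid = (X @ (X.T @ V)) - V * basis.eigenvalues
        assert np.abs(resid).max() < 1e-7

    def test_full_rank_basis_reconstructs_stationary_matrix(self, rng):
        X = normalize_window(rng.standard_normal((20, 60)))
        basis = stationary_basis(X, 20)
        recon = (basis.vectors * basis.eigenvalues) @ basis.vectors.T
        np.testing.assert_allclose(recon, X @ X.T, atol=1e-8)

    def test_rank_beyond_numerical_rank_warns_and_truncates(self, rng):
        X = normalize_window(rng.standard_normal((30, 10)))  # rank <= 9
        with pytest.warns(RuntimeWarning):
            basis = stationary_basis(X, 20)
        assert basis.rank <= 9

    def test_eigenvalues_nonnegative_nonincreasing(self, rng):
        X = normalize_window(rng.standard_normal((50, 120)))
        basis = stationary_basis(X, 8)
        assert np.all(basis.eigenvalues >= 0)
        assert np.all(np.diff(basis.eigenvalues) <= 1e-12)


class TestCenteredMatvec:
    def test_matches_dense_oracle(self, rng):
        X = normalize_window(rng.standard_normal((40, 200)))
        Xw = normalize_window(rng.standard_normal((40, 30)) + 0.0)
        basis = stationary_basis(X, 5)
        w = rng.standard_normal(40)
        expected = dense_centered(Xw, basis) @ w
        np.testing.assert_allclose(centered_matvec(Xw, basis, w), expected,
                                   atol=1e-8)

    def test_window_equal_to_run_with_full_basis_is_null_operator(self, rng):
        X = normalize_window(rng.standard_normal((15, 50)))
        basis = stationary_basis(X, 15)
        for _ in range(3):
            w = rng.standard_normal(15)
            assert np.abs(centered_matvec(X, basis, w)).max() < 1e-8

    def test_no_basis_reduces_to_plain_window_operator(self, rng):
        Xw = normalize_window(rng.standard_normal((12, 25)))
        w = rng.standard_normal(12)
        np.testing.assert_allclose(centered_matvec(Xw, None, w),
                                   Xw @ (Xw.T @ w), atol=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        Xw = normalize_window(rng.standard_normal((12, 25)))
        with pytest.raises(ValueError):
            centered_matvec(Xw, None, np.ones(5))


class TestDominantPattern:
    def test_two_perfectly_correlated_voxels_closed_form(self, rng):
        z = rng.standard_normal(40)
        Xw = normalize_window(np.vstack([z, 2 * z + 1]))
        dp = dominant_pattern(Xw, None)
        assert dp.lam == pytest.approx(2.0, abs=1e-8)
        np.testing.assert_allclose(np.abs(dp.u), np.sqrt(0.5), atol=1e-8)

    def test_planted_rank_one_recovered(self, rng):
        n_v, n_t = 50, 83
        a = rng.standard_normal(n_v)
        a /= np.linalg.norm(a)
        z = rng.standard_normal(n_t)
        Xw = np.outer(a, z)  # rank-1, no normalization (would distort a)
        dp = dominant_pattern(Xw, None)
        assert abs(abs(a @ dp.u) - 1.0) < 1e-8

    def test_centered_eigenpair_matches_dense_oracle(self, rng):
        X = normalize_window(rng.standard_normal((50, 200)))
        Xw = normalize_window(rng.standard_normal((50, 83)))
        basis = stationary_basis(X, 5)
        dp = dominant_pattern(Xw, basis)
        C = dense_centered(Xw, basis)
        vals, vecs = np.linalg.eigh(C)
        top = np.argmax(np.abs(vals))
        assert dp.lam == pytest.approx(vals[top], abs=1e-6)
        assert abs(abs(vecs[:, top] @ dp.u)) == pytest.approx(1.0, abs=1e-6)

    def test_algebraic_mode_targets_largest_eigenvalue(self, rng):
        X = normalize_window(rng.standard_normal((30, 100)))
        Xw = normalize_window(rng.standard_normal((30, 40)))
        basis = stationary_basis(X, 10)
        dp = dominant_pattern(Xw, basis, eig_mode="algebraic")
        dense_max = np.linalg.eigvalsh(dense_centered(Xw, basis))[-1]
        assert dp.lam == pytest.approx(dense_max, abs=1e-6)

    def test_sign_convention_max_voxel_positive(self, rng):
        Xw = normalize_window(rng.standard_normal((20, 30)))
        dp = dominant_pattern(Xw, None)
        assert dp.u[np.argmax(np.abs(dp.u))] > 0

    def test_rank_one_is_best_in_frobenius_norm(self, rng):
        # one alternating-least-squares pass from a random start must not
        # beat the returned eigenpair
        Xw = normalize_window(rng.standard_normal((25, 40)))
        dp = dominant_pattern(Xw, None)
        C = Xw @ Xw.T
        best = np.linalg.norm(C - dp.lam * np.outer(dp.u, dp.u))
        for _ in range(5):
            a = rng.standard_normal(25)
            a /= np.linalg.norm(a)
            b = C @ a  # ALS update for the right factor (sigma absorbed)
            sigma = np.linalg.norm(b)
            b /= sigma
            competitor = np.linalg.norm(C - sigma * np.outer(b, a))
            assert best <= competitor + 1e-9


@settings(max_examples=15, deadline=None, derandomize=True)
@given(n_v=st.integers(5, 60), n_t=st.integers(6, 60),
       m=st.integers(0, 5), seed=st.integers(0, 10_000))
def test_matrix_free_equivalence_property(n_v, n_t, m, seed):
    """Implicit centered eigenpair always equals the dense one (up to sign)."""
    rng = np.random.default_rng(seed)
    X = normalize_window(rng.standard_normal((n_v, 3 * n_t)))
    Xw = normalize_window(rng.standard_normal((n_v, n_t)))
    basis = stationary_basis(X, m) if m > 0 else None
    dp = dominant_pattern(Xw, basis)
    C = dense_centered(Xw, basis)
    vals, vecs = np.linalg.eigh(C)
    top = np.argmax(np.abs(vals))
    gap = np.sort(np.abs(vals))
    if len(gap) > 1 and gap[-1] - gap[-2] < 1e-6 * gap[-1]:
        return  # numerically degenerate top pair: sign/direction undefined
    assert dp.lam == pytest.approx(vals[top], abs=1e-6 * max(1, abs(vals[top])))
    assert abs(vecs[:, top] @ dp.u) == pytest.approx(1.0, abs=1e-6)


class TestRunSubject:
    def test_single_state_noiseless_windows_agree(self):
        from dynparc import generate_dataset, preprocess_pipeline
        volumes, mask, truth = generate_dataset(
            n_subjects=1, n_states=1, T=200, snr=np.inf, seed=3)
        ts = preprocess_pipeline(volumes[0], mask, truth.affine, 0.72,
                                 n_discard=0, gsr=False)
        spec = make_windows(ts.n_timepoints, 83, 5)
        pats = run_subject(ts, spec, M=0, basis=StationaryBasis(
            np.empty(0), np.empty((ts.n_voxels, 0))))
        U = np.column_stack([p.u for p in pats])
        G = np.abs(U.T @ U)
        assert G.min() > 0.99  # constant structure across windows
        # per-window z-scoring flattens amplitudes, so the noiseless limit
        # recovers the planted pattern's sign structure exactly
        signs = np.sign(truth.patterns[0])
        for u in U.T:
            assert np.array_equal(np.sign(u) * np.sign(u @ signs), signs)
        assert np.abs(truth.patterns[0] @ U).min() > 0.9

    def test_consecutive_windows_sign_aligned(self, rng, small_dataset):
        from dynparc import preprocess_pipeline
        volumes, mask, truth = small_dataset
        ts = preprocess_pipeline(volumes[0], mask, truth.affine, 0.72)
        spec = make_windows(ts.n_timepoints, 83, 5)
        pats = run_subject(ts, spec, M=10)
        for prev, cur in zip(pats, pats[1:]):
            assert prev.u @ cur.u >= 0

    def test_empty_window_list_gives_empty_output(self, rng):
        data = rng.standard_normal((10, 50))
        from dynparc.centrality import WindowSpec
        spec = WindowSpec(30, 5, np.array([], dtype=int))
        assert run_subject(data, spec, M=2) == []

    def test_windows_track_planted_states(self):
        # a run long enough that every state accrues occupancy: with
        # balanced states the centered operator's top-magnitude direction
        # is the current state's pattern, not an absent state's deficit
        from dynparc import generate_dataset, preprocess_pipeline
        volumes, mask, truth = generate_dataset(
            n_subjects=1, n_states=3, T=900, snr=2.0, seed=17)
        ts = preprocess_pipeline(volumes[0], mask, truth.affine, 0.72)
        spec = make_windows(ts.n_timepoints, 83, 5)
        pats = run_subject(ts, spec, M=50)
        # account for the 10 discarded frames when locating window states
        states = truth.window_states(spec.window_starts + 10, 83, subject=0)
        seq = truth.states[0]
        purity = np.array([np.mean(seq[s + 10:s + 93] == st) for s, st in
                           zip(spec.window_starts, states)])
        U = np.column_stack([p.u for p in pats])
        cos = np.abs(truth.patterns @ U)  # n_states x n_windows
        # windows dominated by one state match that state's pattern best;
        # windows straddling a state switch are legitimately ambiguous
        pure = purity >= 0.8
        assert pure.sum() >= 30
        assert (np.argmax(cos, axis=0) == states)[pure].mean() > 0.9
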