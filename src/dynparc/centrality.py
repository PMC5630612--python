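"""Window-specific dominant patterns of dynamic functional connectivity.

A sliding window splits each subject's voxel x time matrix into windowed
submatrices X_i. After per-window normalization (z-score each voxel, divide
by the square root of the window length), the window's connectivity matrix

    C_i = X_i X_i^T

is the voxel x voxel Pearson correlation matrix; it is never formed
explicitly. Its leading eigenvector u_i (the dominant pattern, equal to the
eigenvector-centrality map) gives the best rank-1 approximation
C_i ~ lam_i u_i u_i^T. To keep only deviations from the subject's
stationary connectivity, a rank-M eigendecomposition of the full-run matrix
C = X X^T is subtracted implicitly:

    (C_i - C_M) w = X_i (X_i^T w) - sum_k mu_k v_k (v_k^T w)

so every operation is a matrix-vector product and peak extra storage is
O(N_V (M + N_T)), never O(N_V^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse.linalg import LinearOperator, eigsh

__all__ = [
    "WindowSpec", "StationaryBasis", "DominantPattern",
    "make_windows", "normalize_window", "stationary_basis",
    "centered_matvec", "dominant_pattern", "run_subject",
]


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window layout: length and step in samples.

    Window i covers samples [i*step, i*step + length); trailing samples
    that do not complete a window are dropped.
    """

    length: int
    step: int
    window_starts: np.ndarray

    @property
    def n_windows(self) -> int:
        return len(self.window_starts)


@dataclass(frozen=True)
class StationaryBasis:
    """Top-M eigenpairs of the full-run (stationary) correlation matrix.

    eigenvalues are nonnegative, non-increasing; eigenvectors are the
    corresponding orthonormal columns of `vectors` (N_V x M).
    """

    eigenvalues: np.ndarray
    vectors: np.ndarray

    @property
    def rank(self) -> int:
        return len(self.eigenvalues)


@dataclass(frozen=True)
class DominantPattern:
    """One window's leading eigenpair of the centered connectivity operator.

    `u` is the unit-norm spatial map (the implicit rank-1 connectome is
    lam * u u^T); `degenerate` flags a near-degenerate top eigenvalue pair.
    """

    u: np.ndarray
    lam: float
    window_index: int
    subject_id: str | int | None = None
    degenerate: bool = False


def make_windows(T: int, length: int, step: int) -> WindowSpec:
    """Window starts i*step with the last window fully inside [0, T)."""
    if length <= 0 or length > T:
        raise ValueError(f"window length {length} not in (0, T={T}]")
    if step < 1:
        raise ValueError("step must be >= 1")
    n_w = (T - length) // step + 1
    return WindowSpec(length, step, np.arange(n_w) * step)


def normalize_window(Xw: np.ndarray) -> np.ndarray:
    """Z-score each row and divide by sqrt(window length).

    Afterwards every row has mean 0 and unit Euclidean norm, so the
    implicit C = Xw Xw^T has unit diagonal and off-diagonal entries equal
    to Pearson correlations.
    """
    Xw = np.asarray(Xw, dtype=np.float64)
    n_t = Xw.shape[1]
    mu = Xw.mean(axis=1, keepdims=True)
    sd = Xw.std(axis=1, keepdims=True)  # population sd: rows get norm 1
    dead = np.flatnonzero(sd.ravel() == 0)
    if dead.size:
        raise ValueError(
            f"constant timecourse in window for voxel rows {dead[:10].tolist()}"
            " (degenerate correlation)")
    return (Xw - mu) / (sd * np.sqrt(n_t))


def stationary_basis(X: np.ndarray, M: int, tol: float = 1e-8) -> StationaryBasis:
    """Top-M eigenpairs of C = X X^T using only products X (X^T w).

    X must be the full-run matrix normalized with the same convention as
    windows (z-score + 1/sqrt(T)), so C is the stationary Pearson
    correlation matrix. Eigenvalues numerically at zero (below
    tol * largest) are dropped with a warning: the basis then has the
    achievable rank.
    """
    X = np.asarray(X, dtype=np.float64)
    n_v = X.shape[0]
    if M < 1:
        raise ValueError("M must be >= 1")
    if M > min(X.shape):
        warnings.warn(
            f"rank {M} exceeds min(N_V, T) = {min(X.shape)}; clamping",
            RuntimeWarning)
        M = min(X.shape)
    vals, vecs = _top_eigpairs(_gram_operator(X), n_v, M, which="LA")
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    vals = np.maximum(vals, 0.0)
    keep = vals > tol * max(vals[0], tol)
    if not keep.all():
        warnings.warn(
            f"requested rank {M} exceeds numerical rank; returning "
            f"{int(keep.sum())} eigenpairs", RuntimeWarning)
        vals, vecs = vals[keep], vecs[:, keep]
    return StationaryBasis(vals, vecs)


def centered_matvec(Xw: np.ndarray, basis: StationaryBasis | None,
                    w: np.ndarray) -> np.ndarray:
    """Apply the centered window operator (C_i - C_M) to a vector.

    Computed right-to-left as Xw (Xw^T w) - V (mu * (V^T w)); no
    N_V x N_V matrix is ever materialized. A ``None`` (or rank-0) basis
    reduces to the plain windowed operator.
    """
    w = np.asarray(w, dtype=np.float64)
    if w.shape[0] != Xw.shape[0]:
        raise ValueError(
            f"vector length {w.shape[0]} != N_V={Xw.shape[0]}")
    out = Xw @ (Xw.T @ w)
    if basis is not None and basis.rank > 0:
        if basis.vectors.shape[0] != Xw.shape[0]:
            raise ValueError("basis voxel dimension mismatch")
        out -= basis.vectors @ (basis.eigenvalues * (basis.vectors.T @ w))
    return out


def _gram_operator(X: np.ndarray,
                   basis: StationaryBasis | None = None) -> LinearOperator:
    n_v = X.shape[0]

    def mv(w):
        return centered_matvec(X, basis, w.ravel())

    return LinearOperator((n_v, n_v), matvec=mv, dtype=np.float64)


def _top_eigpairs(op: LinearOperator, n: int, k: int, which: str,
                  tol: float = 0.0, maxiter: int | None = None):
    """k extreme eigenpairs of a symmetric operator; dense fallback when
    ARPACK's k < n constraint cannot be met on tiny problems."""
    if k >= n:
        dense = op @ np.eye(n)
        vals, vecs = np.linalg.eigh(dense)
        if which in ("LA", "LM"):
            idx = np.argsort(vals if which == "LA" else np.abs(vals))[::-1][:k]
        else:
            idx = np.argsort(vals)[:k]
        return vals[idx], vecs[:, idx]
    # fixed start vector: ARPACK otherwise randomizes it, which would make
    # eigenvectors (and everything downstream) run-to-run nondeterministic
    v0 = np.random.default_rng(0).standard_normal(n)
    try:
        return eigsh(op, k=k, which=which, tol=tol, maxiter=maxiter, v0=v0)
    except Exception as exc:  # non-convergence carries iteration budget
        raise RuntimeError(
            f"eigensolver failed (k={k}, which={which}, "
            f"maxiter={maxiter}): {exc}") from exc


def dominant_pattern(Xw: np.ndarray, basis: StationaryBasis | None,
                     window_index: int = 0, subject_id=None, *,
                     tol: float = 1e-8, max_iter: int = 5000,
                     eig_mode: str = "magnitude") -> DominantPattern:
    """Leading eigenpair of the centered window operator.

    ``eig_mode='magnitude'`` (default) returns the eigenpair with largest
    absolute eigenvalue — the best rank-1 approximation in Frobenius norm
    of the centered, indefinite matrix. ``'algebraic'`` returns the
    algebraically largest. The sign of u is fixed so its maximum-|value|
    voxel is positive; a near-degenerate top pair sets ``degenerate``.
    """
    if eig_mode not in ("magnitude", "algebraic"):
        raise ValueError("eig_mode must be 'magnitude' or 'algebraic'")
    Xw = np.asarray(Xw, dtype=np.float64)
    n_v = Xw.shape[0]
    op = _gram_operator(Xw, basis)
    which = "LM" if eig_mode == "magnitude" else "LA"
    k = min(2, n_v)  # second pair only to diagnose degeneracy
    vals, vecs = _top_eigpairs(op, n_v, k, which=which, tol=tol,
                               maxiter=max_iter)
    key = np.abs(vals) if eig_mode == "magnitude" else vals
    best = int(np.argmax(key))
    lam = float(vals[best])
    u = vecs[:, best]
    degenerate = False
    if k == 2:
        other = 1 - best
        degenerate = abs(key[best]) - abs(key[other]) < tol * abs(key[best])
    u = u / np.linalg.norm(u)
    if u[np.argmax(np.abs(u))] < 0:
        u = -u
    return DominantPattern(u, lam, window_index, subject_id, degenerate)


def run_subject(ts, spec: WindowSpec, M: int = 50, *,
                basis: StationaryBasis | None = None,
                eig_mode: str = "magnitude", tol: float = 1e-8,
                max_iter: int = 5000, subject_id=None,
                progress=None) -> list[DominantPattern]:
    """All windows' dominant patterns for one (preprocessed) subject.

    Accepts a VoxelTimeseries or a bare N_V x T array. The stationary
    basis is computed from the full run unless supplied. Signs are aligned
    across consecutive windows (nonnegative cosine with the previous
    window's map) so that trajectories are smooth despite the inherent
    sign ambiguity of eigenvectors.
    """
    data = getattr(ts, "data", ts)
    data = np.asarray(data, dtype=np.float64)
    if spec.n_windows == 0:
        return []
    if basis is None:
        X_full = normalize_window(data)  # same convention, full run
        basis = stationary_basis(X_full, min(M, min(data.shape)))
    patterns: list[DominantPattern] = []
    prev_u = None
    for i, start in enumerate(spec.window_starts):
        Xw = normalize_window(data[:, start:start + spec.length])
        try:
            dp = dominant_pattern(Xw, basis, window_index=i,
                                  subject_id=subject_id, tol=tol,
                                  max_iter=max_iter, eig_mode=eig_mode)
        except Exception as exc:
            raise RuntimeError(f"window {i} (start {start}): {exc}") from exc
        if prev_u is not None and float(prev_u @ dp.u) < 0:
            dp = DominantPattern(-dp.u, dp.lam, dp.window_index,
                                 dp.subject_id, dp.degenerate)
        prev_u = dp.u
        patterns.append(dp)
        if progress is not None:
            progress(i, spec.n_windows)
    return patterns
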