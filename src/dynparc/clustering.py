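"""Representative dominant patterns via sign-invariant cosine k-means.

Dominant patterns are eigenvectors, so u and -u describe the same
connectivity (u u^T = (-u)(-u)^T). Clustering therefore uses the
sign-invariant cosine distance d(u, r) = 1 - |cos(u, r)|: each column's
working sign is flipped to agree with its centroid before the centroid
update, making the result invariant to arbitrary sign flips of the input.

The number of clusters K is chosen by 10-fold consensus: for each K, fit
on 9/10 of the columns, assign the held-out columns, and record the
worst-case (largest) per-cluster average test distance; K is where the
fold medians stop decreasing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["RDPSet", "ConsensusCurve", "concatenate_patterns",
           "cosine_kmeans", "consensus_select_K", "occupancy"]


@dataclass
class RDPSet:
    """K representative dominant patterns (cluster centroids) over voxels.

    centroids: N_V x K, unit-norm columns. assignments: cluster id per
    pooled (subject, window) column. occupancy: fraction of windows per
    cluster.
    """

    centroids: np.ndarray
    assignments: np.ndarray
    occupancy: np.ndarray
    inertia: float
    seed: int | None = None
    n_init: int = 1
    column_ids: list = field(default_factory=list)

    @property
    def K(self) -> int:
        return self.centroids.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.centroids.shape[0]


@dataclass
class ConsensusCurve:
    """Out-of-fold worst-case-cluster distances per candidate K."""

    K_values: np.ndarray
    fold_values: np.ndarray  # (len(K_values), folds), NaN for skipped folds
    selected_K: int

    def medians(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmedian(self.fold_values, axis=1)


def concatenate_patterns(per_subject_patterns, mask_check=None) -> tuple[np.ndarray, list]:
    """Stack per-subject dominant-pattern lists into the N_V x (N_W * N_S)
    matrix U.

    Column order is subject-major, window-minor; the (subject, window)
    identity of each column is returned alongside. All subjects must share
    the voxel dimension (same mask / row order).
    """
    cols, ids = [], []
    n_v = None
    for s_idx, patterns in enumerate(per_subject_patterns):
        for dp in patterns:
            u = np.asarray(getattr(dp, "u", dp), dtype=np.float64)
            if n_v is None:
                n_v = u.shape[0]
            elif u.shape[0] != n_v:
                sid = getattr(dp, "subject_id", s_idx)
                raise ValueError(
                    f"subject {sid!r} has {u.shape[0]} voxels, expected {n_v}")
            cols.append(u)
            ids.append((getattr(dp, "subject_id", s_idx),
                        getattr(dp, "window_index", len(ids))))
    if not cols:
        raise ValueError("no patterns to concatenate")
    return np.column_stack(cols), ids


def _unit_columns(U: np.ndarray) -> np.ndarray:
    U = np.asarray(U, dtype=np.float64)
    norms = np.linalg.norm(U, axis=0)
    if np.any(norms == 0):
        raise ValueError("zero column in pattern matrix")
    return U / norms


def _kmeanspp_init(U: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding under the sign-invariant cosine distance."""
    n = U.shape[1]
    centroids = np.empty((U.shape[0], K))
    centroids[:, 0] = U[:, rng.integers(n)]
    d = 1.0 - np.abs(centroids[:, :1].T @ U).ravel()
    for k in range(1, K):
        p = np.clip(d, 0, None)
        total = p.sum()
        if total <= 0:
            idx = rng.integers(n)
        else:
            idx = rng.choice(n, p=p / total)
        centroids[:, k] = U[:, idx]
        d = np.minimum(d, 1.0 - np.abs(centroids[:, k:k + 1].T @ U).ravel())
    return centroids


def _kmeans_once(U: np.ndarray, K: int, rng: np.random.Generator,
                 max_iter: int) -> tuple[np.ndarray, np.ndarray, float]:
    n = U.shape[1]
    C = _kmeanspp_init(U, K, rng)
    prev_obj = np.inf
    assign = np.zeros(n, dtype=np.intp)
    for _ in range(max_iter):
        S = C.T @ U                       # K x n cosine similarities
        A = np.abs(S)
        assign = np.argmax(A, axis=0)
        obj = float(np.sum(1.0 - A[assign, np.arange(n)]))
        # objective is non-increasing: assignment and update are both optimal
        assert obj <= prev_obj + 1e-9, "cosine k-means objective increased"
        if prev_obj - obj < 1e-12:
            break
        prev_obj = obj
        signs = np.sign(S[assign, np.arange(n)])
        signs[signs == 0] = 1.0
        newC = np.zeros_like(C)
        for k in range(K):
            members = assign == k
            if not members.any():
                # reseed empty cluster from the worst-fit column
                worst = int(np.argmin(A[assign, np.arange(n)]))
                logger.info("reseeding empty cluster %d from column %d",
                            k, worst)
                newC[:, k] = U[:, worst]
                continue
            m = U[:, members] @ signs[members]
            nrm = np.linalg.norm(m)
            newC[:, k] = m / nrm if nrm > 0 else U[:, int(np.argmax(members))]
        C = newC
    # final consistent assignment for the returned centroids
    S = C.T @ U
    A = np.abs(S)
    assign = np.argmax(A, axis=0)
    obj = float(np.sum(1.0 - A[assign, np.arange(n)]))
    return C, assign, obj


def cosine_kmeans(U: np.ndarray, K: int, *, n_init: int = 20,
                  max_iter: int = 300, seed: int | None = None,
                  column_ids=None) -> RDPSet:
    """Sign-invariant cosine k-means on pooled dominant patterns.

    Minimizes sum_i (1 - |cos(u_i, r_a(i))|) over assignments a and
    unit-norm centroids r_k; best of ``n_init`` k-means++ restarts.
    """
    U = _unit_columns(U)
    n = U.shape[1]
    if not 1 <= K <= n:
        raise ValueError(f"K={K} not in [1, n_columns={n}]")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_init):
        C, assign, obj = _kmeans_once(U, K, rng, max_iter)
        if best is None or obj < best[2]:
            best = (C, assign, obj)
    C, assign, obj = best
    return RDPSet(C, assign, occupancy(assign, K), obj, seed=seed,
                  n_init=n_init, column_ids=list(column_ids or []))


def _holdout_worst_distance(C: np.ndarray, U_test: np.ndarray) -> float:
    """Assign held-out columns to nearest centroid; return the largest
    per-cluster average sign-invariant cosine distance."""
    A = np.abs(C.T @ U_test)
    assign = np.argmax(A, axis=0)
    d = 1.0 - A[assign, np.arange(U_test.shape[1])]
    worst = 0.0
    for k in range(C.shape[1]):
        members = assign == k
        if members.any():
            worst = max(worst, float(d[members].mean()))
    return worst


def consensus_select_K(U: np.ndarray, K_range=range(1, 31), *,
                       folds: int = 10, seed: int | None = None,
                       n_init: int = 10, max_iter: int = 300,
                       rel_tol: float = 0.05) -> ConsensusCurve:
    """Choose K by out-of-fold consensus.

    The columns are partitioned once into `folds` random groups (reused
    across all K for comparability). For each K and fold, k-means is fit on
    the other folds and the held-out columns are scored by the worst-case
    per-cluster average distance. selected_K is the knee of the fold-median
    curve: the end of the initial decreasing run, where a step only counts
    as decreasing if it improves the median by at least ``rel_tol`` of the
    curve's total range (so plateau jitter past the knee does not extend
    the run).
    """
    U = _unit_columns(U)
    n = U.shape[1]
    K_values = np.asarray(sorted(K_range), dtype=int)
    if n < folds:
        raise ValueError(f"need at least {folds} columns, got {n}")
    rng = np.random.default_rng(seed)
    # balanced random partition: permute then split as evenly as possible
    perm = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, folds)):
        fold_of[chunk] = f
    values = np.full((len(K_values), folds), np.nan)
    for ki, K in enumerate(K_values):
        for f in range(folds):
            train = fold_of != f
            if train.sum() < K:
                warnings.warn(f"fold {f} has fewer training columns than "
                              f"K={K}; skipped", RuntimeWarning)
                continue
            fit = cosine_kmeans(U[:, train], K, n_init=n_init,
                                max_iter=max_iter,
                                seed=int(rng.integers(2 ** 31)))
            values[ki, f] = _holdout_worst_distance(fit.centroids,
                                                    U[:, fold_of == f])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(values, axis=1)
    finite = med[np.isfinite(med)]
    span = float(finite.max() - finite.min()) if finite.size else 0.0
    min_drop = rel_tol * span
    selected = K_values[0]
    for ki in range(1, len(K_values)):
        if np.isnan(med[ki]) or not med[ki] < med[ki - 1] - min_drop:
            break
        selected = K_values[ki]
    return ConsensusCurve(K_values, values, int(selected))


def occupancy(assignments: np.ndarray, K: int | None = None) -> np.ndarray:
    """Fraction of pooled (subject, window) columns per cluster."""
    assignments = np.asarray(assignments)
    if assignments.size == 0:
        raise ValueError("empty assignments")
    if K is None:
        K = int(assignments.max()) + 1
    counts = np.bincount(assignments, minlength=K)
    return counts / counts.sum()
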