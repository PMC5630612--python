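"""Reproducibility and similarity metrics.

Matched spatial correlation between two RDP sets (optimal assignment on
absolute Pearson correlation), partition agreement (AMI / RI / ARI),
inter-centroid cosine similarity, and a generic label-overlap table against
a reference parcellation. All metrics are invariant to label renumbering
and — where eigenvector maps are involved — to sign flips.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn import metrics as skm

from .parcellation import BACKGROUND, LabelVolume

__all__ = ["MatchResult", "match_rdp_sets", "partition_similarity",
           "intercluster_cosine", "label_overlap"]


@dataclass
class MatchResult:
    """Optimal pairing between two RDP sets.

    pairs[i] = (index in A, index in B); correlations are the per-pair
    absolute spatial Pearson correlations; the pairing maximizes their sum
    and is bijective on the smaller set.
    """

    pairs: list[tuple[int, int]]
    correlations: np.ndarray
    mean_correlation: float


def _centroid_matrix(rdps) -> np.ndarray:
    return np.asarray(getattr(rdps, "centroids", rdps), dtype=np.float64)


def match_rdp_sets(A, B) -> MatchResult:
    """Match two RDP sets by maximizing total |spatial correlation|.

    The absolute value makes the pairing insensitive to the arbitrary sign
    of each centroid. Requires both sets on the same mask/voxel order.
    """
    Ca, Cb = _centroid_matrix(A), _centroid_matrix(B)
    if Ca.shape[0] != Cb.shape[0]:
        raise ValueError("RDP sets are defined on different voxel sets")
    Za = (Ca - Ca.mean(axis=0)) / Ca.std(axis=0)
    Zb = (Cb - Cb.mean(axis=0)) / Cb.std(axis=0)
    corr = np.abs(Za.T @ Zb) / Ca.shape[0]
    row, col = linear_sum_assignment(-corr)
    vals = corr[row, col]
    pairs = list(zip(row.tolist(), col.tolist()))
    return MatchResult(pairs, vals, float(vals.mean()))


def _flatten_pair(X, Y) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(X, LabelVolume) and isinstance(Y, LabelVolume):
        if X.volume.shape != Y.volume.shape:
            raise ValueError("label volumes on different grids")
        joint = (X.volume != BACKGROUND) & (Y.volume != BACKGROUND)
        return X.volume[joint], Y.volume[joint]
    x = np.asarray(X).ravel()
    y = np.asarray(Y).ravel()
    if x.shape != y.shape:
        raise ValueError("partitions cover different voxel sets")
    return x, y


def partition_similarity(X, Y) -> tuple[float, float, float]:
    """(AMI, RI, ARI) between two labelings of the same voxels.

    RI counts agreeing voxel pairs; ARI corrects it for chance under the
    permutation model; AMI is mutual information normalized by the
    arithmetic mean of the entropies and chance-corrected. Accepts
    LabelVolumes (compared over their common mask) or flat label arrays.
    """
    x, y = _flatten_pair(X, Y)
    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        warnings.warn("degenerate single-label partition; metrics take "
                      "their defined limits", RuntimeWarning)
    ami = float(skm.adjusted_mutual_info_score(x, y,
                                               average_method="arithmetic"))
    ri = float(skm.rand_score(x, y))
    ari = float(skm.adjusted_rand_score(x, y))
    return ami, ri, ari


def intercluster_cosine(rdps) -> np.ndarray:
    """K x K matrix of |cosine| similarity between RDP centroids."""
    C = _centroid_matrix(rdps)
    if C.shape[1] < 2:
        raise ValueError("need at least two centroids")
    Cn = C / np.linalg.norm(C, axis=0)
    return np.abs(Cn.T @ Cn)


def label_overlap(X: LabelVolume, reference: LabelVolume) -> pd.DataFrame:
    """Fraction of each label's voxels falling in each reference label.

    Rows are labels of X, columns reference labels; entry (l, r) is
    |l ∩ r| / |l|. Background voxels are excluded on both sides, so rows
    sum to at most 1.
    """
    if X.volume.shape != reference.volume.shape:
        raise ValueError("grids differ; resample the reference first")
    sel = (X.volume != BACKGROUND) & (reference.volume != BACKGROUND)
    if not sel.any():
        warnings.warn("masks are disjoint; overlap table is empty",
                      RuntimeWarning)
        return pd.DataFrame(
            0.0, index=pd.Index(X.unique_labels(), name="label"),
            columns=pd.Index(reference.unique_labels(), name="reference"))
    x = X.volume[X.volume != BACKGROUND]
    # denominator: total voxels of each X label (inside X's own mask)
    sizes = pd.Series(x).value_counts().sort_index()
    tab = pd.crosstab(pd.Series(X.volume[sel], name="label"),
                      pd.Series(reference.volume[sel], name="reference"))
    tab = tab.reindex(sizes.index, fill_value=0)
    return tab.div(sizes, axis=0)
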