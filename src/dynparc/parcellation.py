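"""Sign-code parcellation from representative dominant patterns.

Every masked voxel n is assigned an integer label encoding its sign across
the K RDPs:

    label(n) = sum_k 2^(k-1) * (sign(r_k(n)) + 1) / 2

i.e. a K-bit code with bit k set where the voxel contributes positively to
RDP k. Voxels sharing a code share the same dynamics across all patterns;
a code's voxels are typically distributed across the brain (long-range
interactions). Splitting each code into contiguous components and pruning
the small ones yields the fine-scale parcellation.

Exact zeros of r_k(n) map to bit 0 (a measure-zero event; the rule is fixed
for determinism). Background (out-of-mask) is the reserved value -1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi

BACKGROUND = -1

__all__ = ["BACKGROUND", "LabelVolume", "Region", "Parcellation",
           "SymmetryReport", "assign_labels", "connected_components",
           "prune_small", "pattern_distances", "symmetry_index"]


@dataclass
class LabelVolume:
    """Per-voxel sign-code labels in [0, 2^K - 1] on a 3D grid.

    `volume` holds the label per voxel and BACKGROUND outside the mask.
    """

    volume: np.ndarray
    mask: np.ndarray
    affine: np.ndarray
    K: int

    @property
    def labels_in_mask(self) -> np.ndarray:
        """Masked labels in C-order row order."""
        return self.volume[self.mask]

    def unique_labels(self) -> np.ndarray:
        vals = np.unique(self.labels_in_mask)
        return vals[vals != BACKGROUND]


@dataclass
class Region:
    region_id: int
    parent_label: int
    voxels: np.ndarray         # (n, 3) voxel coordinates
    centroid_mm: np.ndarray    # (3,) world-mm centroid (unweighted)

    @property
    def voxel_count(self) -> int:
        return len(self.voxels)


@dataclass
class Parcellation:
    """Contiguous regions per sign-code label."""

    regions: list[Region]
    mask: np.ndarray
    affine: np.ndarray
    connectivity: int = 26
    K: int = 0
    min_size: int | None = None

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def region_volume(self) -> np.ndarray:
        """3D int volume of region ids (BACKGROUND elsewhere)."""
        out = np.full(self.mask.shape, BACKGROUND, dtype=np.int32)
        for r in self.regions:
            out[tuple(r.voxels.T)] = r.region_id
        return out

    def label_volume(self) -> LabelVolume:
        """Sign-code labels restricted to surviving regions."""
        out = np.full(self.mask.shape, BACKGROUND, dtype=np.int64)
        for r in self.regions:
            out[tuple(r.voxels.T)] = r.parent_label
        return LabelVolume(out, self.mask, self.affine, self.K)


@dataclass
class SymmetryReport:
    """Left/right voxel counts and symmetry index per label.

    SI = (#L - #R) / ((#L + #R) / 2) lies in [-2, 2]: 0 is a perfectly
    balanced label, +/-2 one lying entirely in a single hemisphere.
    """

    labels: np.ndarray
    n_left: np.ndarray
    n_right: np.ndarray
    si: np.ndarray
    fraction_within: float
    threshold: float = 1.0

    def si_of(self, label: int) -> float:
        idx = np.flatnonzero(self.labels == label)
        if idx.size == 0:
            raise KeyError(f"label {label} not present")
        return float(self.si[idx[0]])


def assign_labels(rdps, mask: np.ndarray, affine: np.ndarray) -> LabelVolume:
    """Sign-code label per masked voxel from the RDP centroids.

    `rdps` may be an RDPSet or a bare N_V x K centroid matrix whose rows
    follow the C-order scan of `mask`.
    """
    centroids = np.asarray(getattr(rdps, "centroids", rdps), dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    n_v, K = centroids.shape
    if n_v != int(mask.sum()):
        raise ValueError(f"centroids have {n_v} rows but mask has "
                         f"{int(mask.sum())} voxels")
    bits = (centroids > 0).astype(np.int64)   # sign(0) -> bit 0
    codes = bits @ (1 << np.arange(K, dtype=np.int64))
    vol = np.full(mask.shape, BACKGROUND, dtype=np.int64)
    vol[mask] = codes
    return LabelVolume(vol, mask, np.asarray(affine, float), K)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndi.generate_binary_structure(3, 1)
    if connectivity == 18:
        return ndi.generate_binary_structure(3, 2)
    raise ValueError("connectivity must be 6, 18 or 26")


def connected_components(labels: LabelVolume,
                         connectivity: int = 26) -> Parcellation:
    """Split every label into its maximal connected components.

    Region ids are assigned in a stable order: by parent label, then by
    descending voxel count (ties broken by first-voxel C-order position).
    """
    struct = _structure(connectivity)
    regions: list[Region] = []
    A = np.asarray(labels.affine, float)
    for lab in labels.unique_labels():
        comp, n_comp = ndi.label(labels.volume == lab, structure=struct)
        sizes = ndi.sum_labels(np.ones_like(comp), comp,
                               index=np.arange(1, n_comp + 1))
        order = np.argsort(-sizes, kind="stable")
        for c in order:
            vox = np.argwhere(comp == c + 1)
            ctr_vox = vox.mean(axis=0)
            ctr_mm = A[:3, :3] @ ctr_vox + A[:3, 3]
            regions.append(Region(len(regions), int(lab), vox, ctr_mm))
    return Parcellation(regions, labels.mask, A, connectivity, labels.K)


def prune_small(parc: Parcellation, min_size: int = 20) -> Parcellation:
    """Drop regions with fewer than `min_size` voxels.

    Removed voxels become background (they are not merged into neighbors);
    labels whose every region is removed disappear from the label set.
    Idempotent.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    kept = [r for r in parc.regions if r.voxel_count >= min_size]
    renumbered = [Region(i, r.parent_label, r.voxels, r.centroid_mm)
                  for i, r in enumerate(kept)]
    return Parcellation(renumbered, parc.mask, parc.affine,
                        parc.connectivity, parc.K, min_size)


def pattern_distances(parc: Parcellation, label: int):
    """Pairwise Euclidean distances (mm) between centroids of a label's
    contiguous regions; returns (mean, sd, list of (id_a, id_b, mm)).

    With fewer than two regions the result is empty (mean and sd NaN)."""
    regs = [r for r in parc.regions if r.parent_label == label]
    pairs = []
    for i in range(len(regs)):
        for j in range(i + 1, len(regs)):
            d = float(np.linalg.norm(regs[i].centroid_mm - regs[j].centroid_mm))
            pairs.append((regs[i].region_id, regs[j].region_id, d))
    if not pairs:
        return float("nan"), float("nan"), []
    dists = np.array([p[2] for p in pairs])
    return float(dists.mean()), float(dists.std()), pairs


def symmetry_index(labels: LabelVolume, threshold: float = 1.0) -> SymmetryReport:
    """Left/right balance of every label.

    Hemispheres are defined by world-mm x from the affine: left x < 0,
    right x > 0; voxels exactly on the midline count in neither. The
    report includes the fraction of covered voxels whose label has
    |SI| <= threshold (default 1, the conventional summary).
    """
    A = np.asarray(labels.affine, float)
    vox = np.argwhere(labels.volume != BACKGROUND)
    codes = labels.volume[tuple(vox.T)]
    world_x = vox @ A[0, :3] + A[0, 3]
    uniq = np.unique(codes)
    n_left = np.zeros(len(uniq), dtype=int)
    n_right = np.zeros(len(uniq), dtype=int)
    for i, lab in enumerate(uniq):
        sel = codes == lab
        n_left[i] = int(np.sum(world_x[sel] < 0))
        n_right[i] = int(np.sum(world_x[sel] > 0))
    tot = n_left + n_right
    with np.errstate(divide="ignore", invalid="ignore"):
        si = np.where(tot > 0, (n_left - n_right) / (tot / 2.0), 0.0)
    counts = np.array([np.sum(codes == lab) for lab in uniq])
    covered = counts.sum()
    within = counts[np.abs(si) <= threshold].sum()
    frac = float(within / covered) if covered else float("nan")
    return SymmetryReport(uniq, n_left, n_right, si, frac, threshold)
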