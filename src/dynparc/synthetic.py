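"""Synthetic multi-subject 4D datasets with planted switching states.

Each subject's voxel timecourses are a state-dependent mixture: during an
epoch in state k, every masked voxel gains a shared band-limited latent
timecourse weighted by pattern k's voxel value, plus i.i.d. Gaussian noise
at a configurable SNR. The planted spatial patterns are smooth, mutually
orthogonal, zero-mean unit-norm fields with near-saturated amplitudes
(soft-binarized smooth Gaussian fields), and the first pattern is
mirror-symmetric across the mid-sagittal plane — emulating the hemispheric
symmetry of resting-state networks. Ground-truth sign-code labels follow
from the patterns, so every downstream stage (dominant patterns, RDP
clustering, parcellation) has a known answer.

No hemodynamic response, physiological noise or motion is simulated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import nibabel as nib
import scipy.ndimage as ndi
from scipy import signal

from .parcellation import assign_labels, LabelVolume

__all__ = ["GroundTruth", "default_grid", "generate_dataset", "save_dataset",
           "load_dataset"]

DEFAULT_SHAPE = (20, 20, 16)
DEFAULT_VOXEL_MM = 2.0
WINDOW_STEP_TR = 5  # step used to convert dwell (windows) into samples


@dataclass
class GroundTruth:
    """Planted structure of a synthetic dataset.

    patterns: (n_states, N_V) unit-norm spatial maps over the mask
    (C-order row order). states: (n_subjects, T) per-sample state ids.
    labels: planted per-voxel sign-code LabelVolume implied by the
    patterns.
    """

    patterns: np.ndarray
    states: np.ndarray
    labels: LabelVolume
    mask: np.ndarray
    affine: np.ndarray
    tr: float
    dwell_windows: int

    @property
    def n_states(self) -> int:
        return self.patterns.shape[0]

    def window_states(self, window_starts: np.ndarray, length: int,
                      subject: int = 0) -> np.ndarray:
        """Majority planted state inside each window (per-window ids)."""
        seq = self.states[subject]
        out = np.empty(len(window_starts), dtype=int)
        for i, s in enumerate(window_starts):
            vals, counts = np.unique(seq[s:s + length], return_counts=True)
            out[i] = int(vals[np.argmax(counts)])
        return out


def default_grid(shape=DEFAULT_SHAPE, voxel_mm: float = DEFAULT_VOXEL_MM):
    """Centered grid: affine places the mid-sagittal plane at world x = 0."""
    shape = tuple(int(s) for s in shape)
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    affine[:3, 3] = -voxel_mm * (np.asarray(shape) - 1) / 2.0
    return shape, affine


def _ellipsoid_mask(shape) -> np.ndarray:
    center = (np.asarray(shape) - 1) / 2.0
    semi = 0.47 * np.asarray(shape)
    idx = np.indices(shape).astype(float)
    r2 = sum(((idx[d] - center[d]) / semi[d]) ** 2 for d in range(3))
    return r2 <= 1.0


def _mirror_x(field: np.ndarray) -> np.ndarray:
    return field[::-1, :, :]


def _smooth_field(shape, rng, sigma_vox=2.0) -> np.ndarray:
    return ndi.gaussian_filter(rng.standard_normal(shape), sigma=sigma_vox)


def _make_patterns(n_states: int, shape, mask: np.ndarray,
                   rng: np.random.Generator,
                   saturation: float = 2.0) -> np.ndarray:
    """Smooth, zero-mean, orthonormal, near-saturated planted patterns.

    Fields are smoothed white noise; the first is symmetrized across the
    mid-sagittal plane. Orthogonalization against the constant vector
    keeps every pattern zero-mean over the mask (so the global signal
    carries no planted structure); a soft binarization (tanh) flattens
    amplitudes so that the sign structure, not the amplitude profile,
    defines each pattern; a final orthogonalization restores exact
    orthogonality. Mirror symmetry of the first pattern survives every
    step because all the other operations commute with the reflection.
    """
    n_v = int(mask.sum())
    fields = []
    for k in range(n_states):
        f = _smooth_field(shape, rng)
        if k == 0:
            f = 0.5 * (f + _mirror_x(f))
        fields.append(f[mask])
    P = np.column_stack(fields)  # N_V x n_states

    def orthonormalize(P):
        ones = np.ones(n_v) / np.sqrt(n_v)
        Q = []
        for k in range(P.shape[1]):
            v = P[:, k] - (ones @ P[:, k]) * ones
            for q in Q:
                v = v - (q @ v) * q
            nrm = np.linalg.norm(v)
            if nrm < 1e-10:
                raise RuntimeError("degenerate planted pattern")
            Q.append(v / nrm)
        return np.column_stack(Q)

    P = orthonormalize(P)
    rms = np.sqrt(np.mean(P ** 2, axis=0))
    P = np.tanh(saturation * P / rms)
    P = orthonormalize(P)
    return P.T  # n_states x N_V


def _band_limited_latent(T: int, tr: float, rng: np.random.Generator,
                         low: float = 0.0167, high: float = 0.15) -> np.ndarray:
    """Unit-variance latent confined to the analysis band, so that the
    preprocessing band-pass does not destroy planted structure."""
    high = min(high, 0.99 * 0.5 / tr)
    sos = signal.butter(4, [low, high], btype="bandpass", fs=1.0 / tr,
                        output="sos")
    z = signal.sosfiltfilt(sos, rng.standard_normal(T + 200))[100:-100]
    return z / z.std()


def _state_sequence(T: int, n_states: int, dwell_samples: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Piecewise-constant Markov sequence: after each dwell epoch the state
    jumps uniformly to one of the other states."""
    seq = np.empty(T, dtype=int)
    state = int(rng.integers(n_states))
    t = 0
    while t < T:
        seq[t:t + dwell_samples] = state
        t += dwell_samples
        if n_states > 1:
            others = [s for s in range(n_states) if s != state]
            state = int(others[rng.integers(n_states - 1)])
    return seq


def generate_dataset(n_subjects: int = 4, grid=None, n_states: int = 3,
                     T: int = 600, TR: float = 0.72, dwell: int = 20,
                     snr: float = 2.0, seed: int | None = None,
                     baseline: float = 100.0):
    """Generate a multi-subject 4D dataset with planted switching states.

    Parameters
    ----------
    n_subjects, n_states, T, TR : counts / seconds
        Dataset dimensions. TR defaults to 0.72 s.
    grid : (shape, affine) or None
        Defaults to a 20 x 20 x 16 grid at 2 mm isotropic with an
        ellipsoidal mask (~2-4k voxels), mid-sagittal plane at x = 0.
    dwell : int
        Epoch length in analysis windows; one window advances by
        5 TR, so an epoch lasts ``dwell * 5`` samples.
    snr : float
        Ratio of per-voxel planted-signal RMS (averaged over the mask) to
        the i.i.d. noise standard deviation. ``np.inf`` gives noiseless
        data.
    seed : int
        Seeds all randomness; identical seeds give bit-identical output.

    Returns
    -------
    volumes : list of (nx, ny, nz, T) float64 arrays
    mask : 3D bool array
    truth : GroundTruth
    """
    if n_states < 1:
        raise ValueError("need at least one state")
    if not snr > 0:
        raise ValueError("snr must be positive")
    if T < 2:
        raise ValueError("T too short")
    if dwell < 1:
        raise ValueError("dwell must be >= 1 window")
    shape, affine = grid if grid is not None else default_grid()
    mask = _ellipsoid_mask(shape)
    n_v = int(mask.sum())
    if n_v < max(200, 10 * n_states):
        raise ValueError(
            f"mask has only {n_v} voxels; signals under-determined "
            f"(need >= {max(200, 10 * n_states)})")
    rng = np.random.default_rng(seed)
    patterns = _make_patterns(n_states, shape, mask, rng)
    labels = assign_labels(patterns.T, mask, affine)
    dwell_samples = dwell * WINDOW_STEP_TR
    noise_sd = 0.0 if np.isinf(snr) else 1.0 / snr
    amp = np.sqrt(n_v)  # unit average per-voxel signal variance

    volumes, states = [], []
    for _ in range(n_subjects):
        seq = _state_sequence(T, n_states, dwell_samples, rng)
        z = _band_limited_latent(T, TR, rng)
        data = baseline + amp * patterns[seq].T * z[None, :]
        if noise_sd > 0:
            data = data + noise_sd * rng.standard_normal((n_v, T))
        vol = np.zeros(shape + (T,))
        vol[mask] = data
        volumes.append(vol)
        states.append(seq)
    truth = GroundTruth(patterns, np.array(states), labels, mask, affine,
                        TR, dwell)
    return volumes, mask, truth


def save_dataset(out_dir, volumes, mask, truth: GroundTruth) -> dict:
    """Write gzipped NIfTI-1 volumes, the mask and the ground truth.

    Volumes are written as float32, the mask as uint8, and the ground
    truth as JSON with patterns stored as flat arrays over mask indices
    (C-order over the 3D grid).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"subjects": [], "mask": str(out / "mask.nii.gz"),
             "truth": str(out / "ground_truth.json")}
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), truth.affine),
             paths["mask"])
    for s, vol in enumerate(volumes):
        p = out / f"sub-{s:02d}.nii.gz"
        img = nib.Nifti1Image(vol.astype(np.float32), truth.affine)
        img.header.set_zooms((*img.header.get_zooms()[:3], truth.tr))
        nib.save(img, p)
        paths["subjects"].append(str(p))
    payload = {
        "tr": truth.tr,
        "dwell_windows": truth.dwell_windows,
        "mask_index_order": "C-order over the 3D grid",
        "affine": np.asarray(truth.affine).tolist(),
        "patterns": truth.patterns.tolist(),
        "states": truth.states.tolist(),
        "labels_in_mask": truth.labels.labels_in_mask.tolist(),
    }
    (out / "ground_truth.json").write_text(json.dumps(payload))
    return paths


def load_dataset(out_dir):
    """Inverse of :func:`save_dataset` (volumes come back float32)."""
    out = Path(out_dir)
    mask_img = nib.load(out / "mask.nii.gz")
    mask = np.asarray(mask_img.dataobj).astype(bool)
    payload = json.loads((out / "ground_truth.json").read_text())
    affine = np.asarray(payload["affine"])
    patterns = np.asarray(payload["patterns"])
    labels = assign_labels(patterns.T, mask, affine)
    truth = GroundTruth(patterns, np.asarray(payload["states"]), labels,
                        mask, affine, payload["tr"],
                        payload["dwell_windows"])
    volumes = []
    for p in sorted(out.glob("sub-*.nii.gz")):
        volumes.append(np.asarray(nib.load(p).dataobj))
    return volumes, mask, truth
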