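"""Voxelwise timecourse preparation.

Takes masked 4D resting-state data to the analysis-ready voxel x time
matrix: steady-state discard, polynomial detrending, nuisance regression,
band-pass filtering and global-signal regression, with an optional Gaussian
smoother applied to the 4D volume before masking.

All stages are linear operators on the time dimension, so the chain is
(approximately) idempotent; the band-pass is the only stage that is not
exactly a projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.ndimage as ndi
from scipy import signal


@dataclass
class VoxelTimeseries:
    """Masked voxel x time data matrix for one subject/session.

    Rows follow a C-order scan of the 3D mask (``np.flatnonzero`` of the
    mask raveled in C order), so the voxel <-> row mapping is a fixed
    function of the mask and maps are invertible.

    Attributes
    ----------
    data : (N_V, T) float array
        One row per masked voxel, arbitrary signal units.
    mask : (nx, ny, nz) bool array
        Analysis mask on the acquisition grid.
    affine : (4, 4) float array
        Voxel -> world-mm transform.
    tr : float
        Repetition time in seconds.
    history : tuple of str
        Names of the processing stages applied so far, in order.
    """

    data: np.ndarray
    mask: np.ndarray
    affine: np.ndarray
    tr: float
    history: tuple = field(default_factory=tuple)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (voxels x time)")
        if self.data.shape[0] != int(self.mask.sum()):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but mask has "
                f"{int(self.mask.sum())} voxels"
            )
        if self.data.shape[1] < 1:
            raise ValueError("need at least one timepoint")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    @property
    def mask_indices(self) -> np.ndarray:
        """(N_V, 3) voxel coordinates in row order (C-order scan)."""
        flat = np.flatnonzero(self.mask.ravel(order="C"))
        return np.column_stack(np.unravel_index(flat, self.mask.shape))

    def with_data(self, data: np.ndarray, stage: str) -> "VoxelTimeseries":
        return replace(self, data=data, history=self.history + (stage,))


def mask_volume(vol4d: np.ndarray, mask: np.ndarray, affine: np.ndarray,
                tr: float) -> VoxelTimeseries:
    """Extract the masked voxel x time matrix from a 4D volume.

    Row order is the C-order scan of the mask.
    """
    vol4d = np.asarray(vol4d)
    mask = np.asarray(mask, dtype=bool)
    if vol4d.shape[:3] != mask.shape:
        raise ValueError("4D volume and mask grids differ")
    data = vol4d[mask, :].astype(np.float64)  # boolean indexing is C-order
    return VoxelTimeseries(data, mask, np.asarray(affine, float), tr,
                           history=("mask",))


def unmask(values: np.ndarray, mask: np.ndarray,
           fill: float = 0.0) -> np.ndarray:
    """Scatter per-voxel values back into the 3D grid (C-order rows)."""
    mask = np.asarray(mask, dtype=bool)
    values = np.asarray(values)
    out = np.full(mask.shape + values.shape[1:], fill, dtype=values.dtype)
    out[mask] = values
    return out


def discard_initial(ts: VoxelTimeseries, n_discard: int) -> VoxelTimeseries:
    """Drop the first `n_discard` frames (pre-steady-state magnetization)."""
    if n_discard < 0:
        raise ValueError("n_discard must be nonnegative")
    if n_discard >= ts.n_timepoints:
        raise ValueError(
            f"cannot discard {n_discard} of {ts.n_timepoints} timepoints")
    return ts.with_data(ts.data[:, n_discard:], f"discard({n_discard})")


def _poly_basis(T: int, order: int) -> np.ndarray:
    # orthonormal polynomial basis over [-1, 1] for a stable projection
    t = np.linspace(-1.0, 1.0, T)
    P = np.vander(t, order + 1, increasing=True)
    Q, _ = np.linalg.qr(P)
    return Q


def detrend_poly(ts: VoxelTimeseries, order: int = 2) -> VoxelTimeseries:
    """Remove polynomial trends up to `order` (default: constant + linear
    + quadratic) from each voxel timecourse by least-squares projection."""
    T = ts.n_timepoints
    if T < order + 2:
        raise ValueError(f"T={T} too short to fit order-{order} trend")
    Q = _poly_basis(T, order)
    resid = ts.data - (ts.data @ Q) @ Q.T
    return ts.with_data(resid, f"detrend(order={order})")


def regress_confounds(ts: VoxelTimeseries,
                      confounds: np.ndarray | None) -> VoxelTimeseries:
    """Regress out nuisance time series (plus an implicit intercept).

    `confounds` is T x Q (e.g. motion parameters, WM/CSF signals); each
    voxel's row is replaced by its ordinary-least-squares residual.
    """
    T = ts.n_timepoints
    if confounds is None or (hasattr(confounds, "size") and confounds.size == 0):
        X = np.ones((T, 1))
    else:
        confounds = np.atleast_2d(np.asarray(confounds, dtype=np.float64))
        if confounds.shape[0] != T:
            raise ValueError(
                f"confounds have {confounds.shape[0]} rows, expected T={T}")
        if confounds.shape[1] >= T:
            raise ValueError("more confound columns than timepoints")
        X = np.column_stack([np.ones(T), confounds])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify collinear columns by incremental rank
        bad = []
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) == np.linalg.matrix_rank(X[:, :j]):
                bad.append(j - 1)  # confound column index (intercept excluded)
        raise ValueError(f"rank-deficient confounds: collinear columns {bad}")
    Q, _ = np.linalg.qr(X)
    resid = ts.data - (ts.data @ Q) @ Q.T
    return ts.with_data(resid, f"confounds(q={X.shape[1] - 1})")


def bandpass(ts: VoxelTimeseries, low: float = 0.0167,
             high: float = 0.15, order: int = 5) -> VoxelTimeseries:
    """Zero-phase Butterworth band-pass along time.

    Forward-backward filtering (``sosfiltfilt``) avoids phase distortion
    that would otherwise induce spurious window-to-window lag structure.
    Defaults retain the resting-state band [0.0167, 0.15] Hz.
    """
    nyq = 0.5 / ts.tr
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= nyq:
        raise ValueError(f"high={high} Hz at or above Nyquist ({nyq:.4f} Hz)")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=1.0 / ts.tr,
                        output="sos")
    filtered = signal.sosfiltfilt(sos, ts.data, axis=1)
    return ts.with_data(filtered, f"bandpass({low},{high})")


def global_signal_regress(ts: VoxelTimeseries) -> VoxelTimeseries:
    """Regress the across-voxel mean timecourse out of every voxel.

    Removal by per-voxel regression (not plain subtraction) so each output
    row is exactly orthogonal to the global signal.
    """
    if ts.n_voxels < 2:
        raise ValueError("need at least two voxels for a global signal")
    g = ts.data.mean(axis=0)
    X = np.column_stack([np.ones(ts.n_timepoints), g])
    # lstsq (not QR) so a degenerate all-zero global signal is a no-op
    beta, *_ = np.linalg.lstsq(X, ts.data.T, rcond=None)
    resid = ts.data - (X @ beta).T
    return ts.with_data(resid, "gsr")


def smooth_gaussian(vol4d: np.ndarray, affine: np.ndarray,
                    fwhm: float = 5.0) -> np.ndarray:
    """Per-frame 3D Gaussian smoothing with FWHM given in mm.

    Voxel sizes are read from the affine, so anisotropic grids get
    anisotropic kernels. ``fwhm=0`` is the identity.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be nonnegative")
    if fwhm == 0:
        return np.asarray(vol4d).copy()
    vol4d = np.asarray(vol4d, dtype=np.float64)
    voxsize = np.sqrt((np.asarray(affine, float)[:3, :3] ** 2).sum(axis=0))
    sigma_mm = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigma_vox = sigma_mm / voxsize
    out = np.empty_like(vol4d)
    for t in range(vol4d.shape[3]):
        out[..., t] = ndi.gaussian_filter(vol4d[..., t], sigma=sigma_vox)
    return out


def preprocess_pipeline(vol4d: np.ndarray, mask: np.ndarray,
                        affine: np.ndarray, tr: float, *,
                        n_discard: int = 10,
                        detrend_order: int = 2,
                        confounds: np.ndarray | None = None,
                        low: float = 0.0167, high: float = 0.15,
                        fwhm: float = 0.0,
                        gsr: bool = True) -> VoxelTimeseries:
    """Full preparation chain on a 4D volume.

    Order is fixed: (smooth) -> discard -> detrend -> confound regression ->
    band-pass -> mask -> global-signal regression; the per-stage history is
    recorded on the result. Smoothing operates on the unmasked volume; the
    time-domain stages act identically before or after masking, so they are
    applied to the masked matrix for efficiency. Voxels with zero variance
    inside the supplied mask are excluded (mask intersection with nonzero
    variance) and the effective mask is stored on the output.
    """
    if fwhm > 0:
        vol4d = smooth_gaussian(vol4d, affine, fwhm)
    mask = np.asarray(mask, dtype=bool)
    data4d = np.asarray(vol4d)
    # intersect mask with voxels of nonzero variance over the retained frames
    var = data4d[..., n_discard:].var(axis=3)
    eff_mask = mask & (var > 0)
    ts = mask_volume(data4d, eff_mask, affine, tr)
    ts = discard_initial(ts, n_discard)
    ts = detrend_poly(ts, detrend_order)
    if confounds is not None:
        conf = np.atleast_2d(np.asarray(confounds, dtype=np.float64))
        ts = regress_confounds(ts, conf[n_discard:])
    ts = bandpass(ts, low, high)
    if gsr:
        ts = global_signal_regress(ts)
    return ts
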