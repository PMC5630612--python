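"""Shared I/O: NIfTI volumes, HDF5 matrix containers and JSON sidecars.

Every container written by the pipeline carries the configuration hash so
that artifacts produced under different configurations are detected and
refused when mixed.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import nibabel as nib


def read_nifti(path):
    """Load a NIfTI file; returns (data, affine, tr_or_None)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    tr = None
    if data.ndim == 4:
        zooms = img.header.get_zooms()
        if len(zooms) >= 4 and zooms[3] > 0:
            tr = float(zooms[3])
    return data, img.affine, tr


def write_nifti(path, data, affine, tr: float | None = None) -> None:
    img = nib.Nifti1Image(np.asarray(data), np.asarray(affine))
    if tr is not None and data.ndim == 4:
        img.header.set_zooms((*img.header.get_zooms()[:3], tr))
    nib.save(img, str(path))


def save_matrix(path, name: str, matrix: np.ndarray, *, mask=None,
                affine=None, meta: dict | None = None) -> None:
    """Store a named matrix with mask geometry and JSON metadata in HDF5."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset(name, data=np.asarray(matrix))
        if mask is not None:
            fh.create_dataset("mask", data=np.asarray(mask, dtype=np.uint8))
        if affine is not None:
            fh.create_dataset("affine", data=np.asarray(affine, float))
        fh.attrs["meta"] = json.dumps(meta or {})


def load_matrix(path, name: str):
    """Inverse of :func:`save_matrix`; returns (matrix, mask, affine, meta)."""
    with h5py.File(path, "r") as fh:
        matrix = fh[name][()]
        mask = fh["mask"][()].astype(bool) if "mask" in fh else None
        affine = fh["affine"][()] if "affine" in fh else None
        meta = json.loads(fh.attrs.get("meta", "{}"))
    return matrix, mask, affine, meta


def check_config_hash(meta: dict, expected: str, what: str) -> None:
    found = meta.get("config_hash")
    if found is not None and found != expected:
        raise ValueError(
            f"{what} was produced under a different configuration "
            f"(hash {found} != {expected}); refusing to mix artifacts")


def read_confounds(path) -> np.ndarray:
    """Whitespace/TSV confound file with a header row -> T x Q array."""
    import pandas as pd

    df = pd.read_csv(path, sep=r"\s+")
    return df.to_numpy(dtype=float)


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True,
                                     default=_json_default))


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
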