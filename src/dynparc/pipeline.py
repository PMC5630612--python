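"""End-to-end driver: preprocess -> dominant patterns -> RDPs -> atlas.

Given one 4D run per subject and a common gray-matter mask, the pipeline
produces the representative dominant patterns (RDPs), the sign-code label
volume, the pruned contiguous-region parcellation, and the symmetry and
long-range distance reports. Every stage is deterministic given the
configuration seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import centrality, clustering, parcellation, preprocess
from .config import PipelineConfig
from .io import write_json, write_nifti, save_matrix

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    rdps: clustering.RDPSet
    consensus: clustering.ConsensusCurve | None
    labels: parcellation.LabelVolume
    parcellation: parcellation.Parcellation
    symmetry: parcellation.SymmetryReport
    distances: dict
    window_spec: centrality.WindowSpec
    per_subject_patterns: list
    config: PipelineConfig


def run_pipeline(volumes, mask, affine, config: PipelineConfig | None = None,
                 *, confounds=None, out_dir=None) -> PipelineResult:
    """Run the full voxelwise dFC parcellation on in-memory volumes.

    Parameters
    ----------
    volumes : list of 4D arrays
        One run per subject, all on the same grid as `mask`.
    confounds : list of T x Q arrays or None
        Optional per-subject nuisance time series.
    out_dir : path or None
        If given, all intermediates and reports are written there.
    """
    cfg = config or PipelineConfig()
    if len(volumes) == 0:
        raise ValueError("need at least one subject")
    mask = np.asarray(mask, dtype=bool)
    n_t_window = cfg.window_tr
    logger.info("window %.1f s -> %d TR (realized %.2f s); step %.1f s -> "
                "%d TR", cfg.window_sec, n_t_window,
                n_t_window * cfg.tr, cfg.step_sec, cfg.step_tr)

    per_subject = []
    spec = None
    eff_mask = None
    for s, vol in enumerate(volumes):
        try:
            conf = None if confounds is None else confounds[s]
            ts = preprocess.preprocess_pipeline(
                vol, mask, affine, cfg.tr, n_discard=cfg.n_discard,
                detrend_order=cfg.detrend_order, confounds=conf,
                low=cfg.band_low, high=cfg.band_high, fwhm=cfg.fwhm,
                gsr=cfg.gsr)
            if eff_mask is None:
                eff_mask = ts.mask
            elif not np.array_equal(eff_mask, ts.mask):
                raise ValueError("effective mask differs across subjects")
            if spec is None:
                spec = centrality.make_windows(ts.n_timepoints, n_t_window,
                                               cfg.step_tr)
            patterns = centrality.run_subject(
                ts, spec, M=cfg.rank_m, eig_mode=cfg.eig_mode, subject_id=s)
            per_subject.append(patterns)
            logger.info("subject %d: %d windows", s, len(patterns))
        except Exception as exc:
            raise RuntimeError(f"stage failed for subject {s}: {exc}") from exc

    U, column_ids = clustering.concatenate_patterns(per_subject)
    consensus = None
    if cfg.k_fixed is not None:
        K = cfg.k_fixed
    else:
        k_max = min(cfg.k_max, U.shape[1])
        consensus = clustering.consensus_select_K(
            U, range(cfg.k_min, k_max + 1), folds=cfg.folds,
            seed=cfg.seed, n_init=cfg.consensus_n_init)
        K = consensus.selected_K
        logger.info("consensus selected K=%d", K)
    rdps = clustering.cosine_kmeans(U, K, n_init=cfg.n_init, seed=cfg.seed,
                                    column_ids=column_ids)

    labels = parcellation.assign_labels(rdps, eff_mask, affine)
    parc = parcellation.connected_components(labels, cfg.connectivity)
    parc = parcellation.prune_small(parc, cfg.min_region_size)
    pruned_labels = parc.label_volume()
    symmetry = parcellation.symmetry_index(pruned_labels)
    distances = {}
    for lab in pruned_labels.unique_labels():
        mean, sd, pairs = parcellation.pattern_distances(parc, int(lab))
        distances[int(lab)] = {"mean_mm": mean, "sd_mm": sd,
                               "n_pairs": len(pairs)}

    result = PipelineResult(rdps, consensus, pruned_labels, parc, symmetry,
                            distances, spec, per_subject, cfg)
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(res: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    cfg = res.config
    chash = cfg.hash()
    cfg.to_yaml(out / "config.yaml")
    meta = {"config_hash": chash}

    mask = res.labels.mask
    save_matrix(out / "rdps.h5", "centroids", res.rdps.centroids,
                mask=mask, affine=res.labels.affine,
                meta={**meta, "K": res.rdps.K,
                      "occupancy": res.rdps.occupancy.tolist()})
    # one 3D map per RDP
    for k in range(res.rdps.K):
        vol = preprocess.unmask(res.rdps.centroids[:, k], mask)
        write_nifti(out / f"rdp-{k + 1:02d}.nii.gz", vol.astype(np.float32),
                    res.labels.affine)
    write_nifti(out / "labels.nii.gz",
                res.labels.volume.astype(np.int32), res.labels.affine)
    write_nifti(out / "regions.nii.gz",
                res.parcellation.region_volume().astype(np.int32),
                res.labels.affine)

    import pandas as pd

    rows = [{"region_id": r.region_id, "parent_label": r.parent_label,
             "n_voxels": r.voxel_count,
             "centroid_x_mm": r.centroid_mm[0],
             "centroid_y_mm": r.centroid_mm[1],
             "centroid_z_mm": r.centroid_mm[2]}
            for r in res.parcellation.regions]
    pd.DataFrame(rows).to_csv(out / "regions.tsv", sep="\t", index=False)

    report = {
        "config_hash": chash,
        "K": res.rdps.K,
        "occupancy": res.rdps.occupancy,
        "n_unique_labels": len(res.labels.unique_labels()),
        "n_regions": res.parcellation.n_regions,
        "symmetry": {
            "fraction_within_threshold": res.symmetry.fraction_within,
            "per_label": {int(l): float(s) for l, s in
                          zip(res.symmetry.labels, res.symmetry.si)},
        },
        "distances_mm": res.distances,
    }
    if res.consensus is not None:
        report["consensus"] = {
            "K_values": res.consensus.K_values,
            "medians": res.consensus.medians(),
            "selected_K": res.consensus.selected_K,
        }
    write_json(out / "report.json", report)
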