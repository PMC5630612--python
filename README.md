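# dynparc

Voxel-level **dynamic functional connectivity (dFC) parcellation** for
resting-state fMRI.

Conventional connectome analyses average BOLD signals inside a pre-defined
atlas because a voxel-by-voxel connectivity matrix (10^10 entries for
~10^5 gray-matter voxels) cannot be stored. `dynparc` sidesteps the atlas
choice: it represents each sliding window's voxelwise connectivity matrix
*implicitly* by its leading eigenvector, clusters these dominant patterns
across windows and subjects into a small set of representative dominant
patterns (RDPs), and derives a whole-brain parcellation from the voxels'
signs in the RDPs — capturing both long-range interactions and fine-scale
contiguous subdivisions, driven purely by connectivity dynamics.

It is aimed at researchers analysing multi-subject resting-state fMRI
(e.g. HCP-style acquisitions, TR ≈ 0.72 s) who want data-driven,
dynamics-aware parcellations without committing to an anatomical atlas.

## Method

For subject *s* with preprocessed voxel × time matrix **X**, each window
*i* (length *N*ᴛ = 83 TR ≈ 60 s, step Δ = 5 TR) is z-scored per voxel and
scaled by 1/√*N*ᴛ, so the windowed connectivity matrix is the Pearson
correlation matrix

&nbsp;&nbsp;**C**ᵢ = **X**ᵢ**X**ᵢᵀ ≈ λᵢ **u**ᵢ**u**ᵢᵀ,  **C**ᵢ**u**ᵢ = λᵢ**u**ᵢ,

whose leading eigenvector **u**ᵢ (the eigenvector-centrality map, or
*dominant pattern*) is the optimal rank-1 summary. To retain only
deviations from stationary connectivity, the rank-*M* (*M* = 50)
eigendecomposition of the full-run matrix **C** = Σₖ μₖ**v**ₖ**v**ₖᵀ is
subtracted implicitly:

&nbsp;&nbsp;(**C**ᵢ − **C**) **u** = **X**ᵢ(**X**ᵢᵀ**u**) − Σₖ μₖ**v**ₖ(**v**ₖᵀ**u**),

so every solver operation is a matrix–vector product and no *N*ᵥ × *N*ᵥ
matrix is ever formed. Dominant patterns pooled over windows and subjects
are clustered by sign-invariant cosine *k*-means (d = 1 − |cos|, since
**uu**ᵀ = (−**u**)(−**u**)ᵀ); the number of clusters *K* is chosen by
10-fold out-of-fold consensus on the worst-case per-cluster distance.
Each voxel *n* then receives the *K*-bit sign code

&nbsp;&nbsp;label(*n*) = Σₖ 2^(k−1) · (sign(**r**ₖ(*n*)) + 1)/2,

grouping voxels with identical dynamics (long-range patterns); splitting
each label into contiguous components and pruning regions under 20 voxels
gives the fine-scale parcellation. Diagnostics include the per-label
symmetry index SI = (#L − #R)/((#L + #R)/2), pairwise centroid distances,
matched spatial correlation between RDP sets, and AMI/RI/ARI between
parcellations.

## Worked example

No external data is needed: the built-in generator plants switching
network states with known patterns, state sequences and labels.

```python
import numpy as np
from dynparc import (PipelineConfig, generate_dataset,
                     partition_similarity, run_pipeline)

volumes, mask, truth = generate_dataset(
    n_subjects=4, n_states=3, T=600, snr=2.0, seed=101)
cfg = PipelineConfig(k_max=8, consensus_n_init=5, n_init=10, seed=202)
res = run_pipeline(volumes, mask, truth.affine, cfg)

print("selected K:", res.consensus.selected_K)
print("occupancy:", np.round(res.rdps.occupancy, 3))
print("unique labels:", len(res.labels.unique_labels()))
print("contiguous regions:", res.parcellation.n_regions)
print("fraction of voxels with |SI| <= 1:",
      round(res.symmetry.fraction_within, 3))
ami, ri, ari = partition_similarity(res.labels, truth.labels)
print("AMI/RI/ARI vs planted labels:",
      round(ami, 3), round(ri, 3), round(ari, 3))
```

Output:

```
selected K: 3
occupancy: [0.355 0.311 0.333]
unique labels: 8
contiguous regions: 19
fraction of voxels with |SI| <= 1: 1.0
AMI/RI/ARI vs planted labels: 0.977 0.996 0.982
```

Consensus clustering recovers the three planted states (K = 3) with
roughly equal occupancy; the sign code resolves all 2³ = 8 label
combinations into 19 contiguous regions; every label is hemispherically
balanced (|SI| ≤ 1); and the recovered parcellation agrees with the
planted one almost perfectly (ARI 0.98).

The same pipeline is available from the shell:

```bash
dynparc simulate --subjects 4 --states 3 --timepoints 600 --snr 2 \
    --seed 101 --out data/
dynparc run --data-dir data/ --seed 202 --out atlas/
```

with stage-wise subcommands (`preprocess`, `centrality`, `cluster`,
`parcellate`, `compare`) for real NIfTI data.

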