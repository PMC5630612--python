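# Methods notes

## Model and procedure

`dynparc` treats each subject's preprocessed gray-matter data as an
N_V × T matrix X and studies the time-resolved correlation structure
through sliding windows. Within a window, every voxel's timecourse is
z-scored (population standard deviation, so each row has exactly unit
Euclidean norm after division by √N_T); the windowed connectivity matrix
C_i = X_i X_iᵀ is then the voxel × voxel Pearson correlation matrix and is
summarized by its leading eigenpair (λ_i, u_i) — the eigenvector-centrality
map, optimal rank-1 approximation of C_i in Frobenius norm. Stationary
structure is removed by subtracting a rank-M eigendecomposition of the
full-run correlation matrix (normalized with the identical z-score + 1/√T
convention, so the subtracted object is the stationary Pearson matrix).
All operations are expressed as matrix–vector products
X_i(X_iᵀw) − Σ μ_k v_k(v_kᵀw); peak additional storage is O(N_V·(M + N_T))
and no N_V × N_V array is ever allocated.

Dominant patterns are pooled across windows and subjects (subject-major,
window-minor column order) and clustered with a sign-invariant cosine
k-means. K is selected by fold-based consensus; the final parcellation is
obtained from the sign code of the K centroids, split into connected
components and pruned.

Assumptions worth stating explicitly: windows are long enough for a
meaningful correlation estimate (dozens of samples); connectivity within a
window is well summarized by one eigenvector (the rank-1 assumption —
windowed correlation matrices are heavily information-limited, which is
what makes this representation usable); and all subjects are in a common
space sharing one mask. Upstream spatial preprocessing (registration,
distortion correction) is assumed done.

## Tunable parameters

| parameter | default | units | rationale |
|---|---|---|---|
| window length | 60 | s | trade-off between dynamic sensitivity and correlation reliability; 83 TR at TR = 0.72 s |
| window step | 3.6 | s | 5 TR; dense overlap for smooth trajectories |
| band-pass | 0.0167–0.15 | Hz | resting-state band; lower edge ≈ 1/window so within-window fluctuations are not dominated by unresolvable slow drift |
| centering rank M | 50 | — | captures the bulk of stationary correlation at modest cost |
| eig-mode | magnitude | — | the centered operator is indefinite; magnitude gives the best rank-1 approximation (see below) |
| K range / folds | 1–30 / 10 | — | consensus selection domain |
| k-means restarts | 20 (final), 10 (consensus folds) | — | restarts of k-means++ seeding |
| min region size | 20 | voxels | 0.16 cm³ at 2 mm isotropic; suppresses speckle regions |
| connectivity | 26 | — | face+edge+corner neighborhood; configurable to 6 or 18 |
| discarded frames | 10 | frames | pre-steady-state magnetization |

Durations are converted to integer TR counts by rounding to the nearest
TR; the realized duration is logged (60 s → 83 TR = 59.76 s).

## Numerical choices

- **Eigensolver.** ARPACK (`scipy.sparse.linalg.eigsh`) on a
  `LinearOperator`; tolerance 1e−8, budget 5000 matvecs. The start vector
  is fixed (seeded standard normal) because ARPACK otherwise randomizes
  it, which would make eigenvectors — and everything downstream —
  nondeterministic between runs. Problems too small for ARPACK's k < n
  constraint fall back to a dense `eigh` on the operator applied to the
  identity.
- **Magnitude vs algebraic.** The centered operator C_i − C_M is
  indefinite: a window can deviate from stationary connectivity by
  *lacking* a normally-present pattern (negative curvature) as much as by
  expressing an extra one. The magnitude-largest eigenpair is the best
  rank-1 approximation and is the default; `eig_mode="algebraic"` selects
  the largest positive eigenvalue instead. Note a consequence observed on
  synthetic data: when one planted state has near-zero occupancy in a
  run, its *deficit* in the stationary term can rival the current state's
  expression, and magnitude mode may return the absent pattern. With
  reasonably balanced state occupancy the current state dominates.
- **Sign conventions.** Eigenvector signs are arbitrary
  (uuᵀ = (−u)(−u)ᵀ). Within a subject, each window's map is flipped to
  nonnegative cosine with the previous window; the first window (and any
  standalone eigenvector) is oriented so its maximum-|value| voxel is
  positive. Clustering is sign-invariant by construction
  (d = 1 − |cos|, working signs realigned each iteration), so the
  convention affects presentation only. In the sign code, an exact zero
  centroid value maps to the negative bit — a measure-zero event needing
  only a deterministic rule.
- **k-means.** k-means++ seeding under the sign-invariant distance; the
  objective Σ(1 − |cos|) is asserted non-increasing every iteration
  (both steps are exact coordinate minimizations); empty clusters are
  reseeded from the worst-fit column; ties in argmax assignments resolve
  to the lowest cluster index (numpy convention).
- **Consensus K rule.** For each K and fold, the model is fit on 9/10 of
  the columns (the random partition is balanced and reused across K);
  held-out columns are assigned to the nearest centroid; the score is the
  worst-case per-cluster average distance. The selected K is the knee of
  the fold-median curve: the end of the initial decreasing run, where a
  step counts as decreasing only if it improves the median by at least 5%
  of the curve's total range. A strictly-monotone rule proved too fragile:
  past the true K the curve plateaus with tiny monotone jitter (splitting
  a tight cluster still reduces distances slightly), which a strict rule
  mistakes for continued improvement. `k_fixed` bypasses selection.
- **Band-pass.** Zero-phase forward–backward Butterworth (order 5 per
  direction); zero-phase filtering avoids inducing spurious
  window-to-window lag structure. The filter is only approximately a
  projection: reapplication changes a mid-band sinusoid by < 2%, but
  broadband input retains transition-band energy and can change by
  ~10–15% on a second pass. The detrending, confound and global-signal
  stages are exact projections (idempotent to machine precision); the
  global signal (across-voxel mean of masked timecourses) is removed by
  per-voxel regression, not subtraction.
- **Degenerate inputs.** Constant voxels within a window make the Pearson
  correlation undefined; `normalize_window` raises an error naming the
  offending rows, and the pipeline pre-emptively intersects the supplied
  mask with nonzero-variance voxels. A near-degenerate leading eigenpair
  (relative gap < tol) is flagged on the result rather than erroring. A
  requested stationary rank beyond the numerical rank is clamped with a
  warning.

## Synthetic data: what it does and does not emulate

The generator plants K_true switching covariance states on a 20 × 20 × 16
grid at 2 mm isotropic (ellipsoidal mask, ~2800 voxels, mid-sagittal
plane at world x = 0). Patterns are smoothed Gaussian fields,
orthogonalized against the constant vector (zero mean, so the global
signal carries no planted structure) and against each other, then
soft-binarized with tanh so each pattern's *sign structure* rather than
its amplitude profile carries the identity — mirroring the sign-code
labeling downstream — and re-orthogonalized. The first pattern is made
mirror-symmetric across hemispheres. State sequences are piecewise
constant: epochs of `dwell` windows (default 20 windows = 100 samples =
72 s, chosen so epochs outlast the 60 s analysis window and most windows
sample a single state), with uniform Markov jumps to one of the other
states. During an epoch in state k, voxel v receives
amp · p_k(v) · z(t) plus i.i.d. Gaussian noise, where z is a unit-variance
latent band-limited to 0.0167–0.15 Hz (so preprocessing does not destroy
the planted structure) and `snr` is the ratio of mask-average per-voxel
signal RMS to the noise standard deviation (default 2).

Because windows z-score each voxel, the noiseless dominant pattern equals
the planted pattern's *sign structure* with near-saturated amplitudes;
the cosine to the planted pattern is high (> 0.9) but not exactly 1. The
generator does not simulate hemodynamics, physiological noise, motion,
spatial noise correlations, or inter-subject spatial variability — so
passing recovery tests demonstrates the estimator's correctness under the
stated mixture model, not robustness to fMRI artifacts.

## Problem sizes used by the tests

The test suite and acceptance checks run on desk-scale problems chosen to
exercise every code path against dense oracles: ~2800-voxel grids, runs of
400–900 frames, 2–4 subjects, dense-oracle instances of N_V ≤ 200, and
consensus selection over K = 1…8. The full-scale setting the package
targets (10^5 voxels, 1190 frames, dozens of subjects, K up to 30) uses
identical code paths; only the matrix-free structure makes that scale
feasible.

## Known limitations

- One eigenvector per window: a rank-1 summary cannot represent multiple
  simultaneous connectivity deviations; higher-rank window
  representations would need a clustering notion for subspaces.
- Hard sign-code labels: voxels near a centroid's zero crossing flip
  labels under small perturbations; soft assignments or hierarchical
  aggregation of the binary codes (e.g. by Hamming distance) are natural
  extensions.
- The consensus-K knee rule has a tunable sensitivity (5% of range);
  on data without clear cluster structure the selected K is best treated
  as a suggestion and fixed K runs compared.
- Window-length effects are directional, not absolute: shorter windows
  resolve more labels on fast-switching data but estimate each window's
  correlation from fewer samples.
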