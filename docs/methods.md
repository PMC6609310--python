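# Methods

## Model and procedure

The package treats each resting-state scan as a matrix Y of N in-mask
voxels by T volumes, already co-registered to a common space (spatial
normalization is out of scope). The analysis chain is:

1. **Masking.** A subject-level gray-matter mask (density > 0.2, strict),
   a functional coverage mask (per-voxel temporal minimum above the 20th
   percentile of all minima, strict, linear-interpolation percentile), a
   group mask (voxel kept when present in ≥ 75% of subject masks,
   inclusive so the 3-of-4 case is well defined), and an intersection with
   optional exclusion masks (e.g. cerebellum, supplied as a file — the
   package does not derive it from an atlas). Affines must agree to 1e-4
   relative tolerance; resampled files commonly differ in last-digit
   header noise.
2. **Confound regression.** Per-voxel OLS on the demeaned motion
   parameters; the fitted motion contribution is subtracted, the intercept
   is kept, so voxel means survive and the operation is idempotent.
   Regression happens after masking, on extracted time series.
3. **Dynamic ECM.** For M requested maps, a window of W = T − M + 1
   volumes slides over all M positions (step one TR). Rows are demeaned
   and scaled to unit norm *within each window*, so the implicit
   connection matrix is exactly that window's correlation matrix plus one.
   The power step is evaluated matrix-free as
   `rows @ (rows.T @ v) + sum(v)` — the rank-one completion of the +1
   term — and never materializes an N×N matrix. Iteration starts at the
   uniform vector 1/√N (inside the Perron cone, so convergence to the
   nonnegative dominant eigenvector is guaranteed), and stops when the
   L2 change between normalized iterates falls below `tol` (default 1e-9,
   `max_iter` 1000; non-convergence returns a flagged result with a
   warning). Zero-variance voxels are kept in place with centrality 0 so
   indexing is stable across windows. Each map is rescaled so its mean is
   exactly the target (default 4500) — deterministic, invertible and
   order-preserving. W < 3 is rejected: with two samples all correlations
   are ±1.
4. **Dual regression.** Stage 1: spatial OLS of each centrality map on all
   K template Z-maps jointly, after spatially demeaning both. Stage 2:
   per-voxel temporal OLS on the K network courses plus an intercept.
   Stage-1 courses are variance-normalized (sample sd, ddof 1) by default
   so stage-2 coefficients are comparable across subjects; the flag can be
   disabled, and the network-curve summaries use the unnormalized courses
   so absolute centrality levels remain comparable across networks.
   Per-network test masks take template Z > 3.0 (configurable) within the
   analysis mask; a cerebellar template can simply be listed in
   `exclude_networks`.
5. **Inference.** Voxelwise GLM contrast t-statistics (group indicator
   ±1-coded, demeaned scan-length covariate when scan lengths vary,
   intercept); TFCE with E = 0.5, H = 2, dh = max|t|/100, 26-connectivity
   (the enhancement integrates component extent e(h)^E · h^H over
   thresholds below each voxel's statistic; negative values are enhanced
   on the negated map and re-signed); max-statistic permutation FWE with
   the Freedman–Lane scheme (data residualized on the nuisance columns,
   residual rows permuted, nuisance fit restored, full model re-fit) —
   plain label permutation is available as `scheme="labels"`. Corrected
   p = (1 + b)/(1 + n_perm) is never zero; with fewer distinct
   permutations than requested the space is enumerated exhaustively.
   Both contrast directions are run by default (the pipeline writes
   `_pos`/`_neg` outputs); each direction is its own test family. An
   optional Bonferroni layer divides α by the number of networks tested.
   Cluster tables keep components of {p < α} strictly larger than
   10 voxels. Statistics and TFCE run only inside each network's mask.
6. **Summaries.** Per-group mean EC maps (time-average per subject, then
   group mean) and per-network group curves: winsorized mean across
   subjects (⌊trim·n⌋ values per tail replaced by the nearest retained
   order statistic; trim 0.1) with the across-subject sd divided by 5 as
   a plotting ribbon (zero, with a warning, for singleton groups).

Median-split age groups put subjects at or above the median in the older
group, deterministically.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `n_maps` (M) | 100 (CLI), 60 (synthetic study) | window positions; W = T − M + 1 volumes |
| `target_mean` | 4500 | intensity scale of EC maps |
| `tol`, `max_iter` | 1e-9, 1000 | power-iteration convergence |
| `zthreshold` | 3.0 | template Z cut for network masks |
| TFCE E, H, dh | 0.5, 2, max/100 | enhancement exponents and step |
| `n_perm` | 10000 (library default), 500 in simulations | permutations |
| `alpha`, `min_cluster_size` | 0.05, 10 | reporting thresholds |

## Synthetic cohorts: what they emulate, and what they do not

`decm.synthetic` plants K Gaussian-blob "networks" (Z-scored over an
ellipsoidal brain mask) on a 20×20×12 grid of 3 mm voxels, 120 volumes at
TR 2.5 s. Each network k has a white unit-variance latent course s_k(t)
and a slowly drifting coupling c_k(t); voxel i carries
w_ik·(c_k s_k + √(1−c_k²) η_ik) summed over networks plus white
measurement noise (sd 0.3), so the instantaneous within-network
correlation tracks c_k(t)². The coupling drift is a random-sign monotone
trend plus a 15% smoothed-random-walk wobble, standardized to unit
temporal sd and scaled by the group's `coupling_sd` (defaults 0.18 vs
0.36 — a two-fold variability ratio planted in one network; means 0.55,
trajectories clipped to [0.05, 0.98]).

Two of these choices are deliberate and worth explaining. First, the
latent courses are white: a smooth latent course has a *randomly varying
realized variance inside each ~60-volume window*, which masquerades as
coupling dynamics and, at 10 subjects per group, buries a two-fold
variability ratio (measured effect size d ≈ 0.8). Second, the drift is
dominated by a monotone trend: windows of W ≈ T/2 low-pass any stationary
drift so heavily that a free random walk leaves the realized windowed
amplitude with roughly two degrees of freedom — a coefficient of
variation near 0.5 *between subjects with identical group parameters*.
The monotone trend survives windowing with a deterministic amplitude, so
every subject actually carries the group's planted variability (d ≈ 1.9).

Randomness follows a common-random-numbers design: templates, latent
courses, drift shapes and all noise are drawn from seed streams that do
not depend on the group parameters; `coupling_sd` only rescales the drift.
Changing the effect size therefore changes coupling trajectories and
nothing else, and a master seed reproduces a cohort byte for byte.

The generator does **not** emulate hemodynamic autocorrelation,
physiological noise, scanner drift, spatial noise correlations, realistic
head motion (only optional random-walk confound columns with linear
loadings), or between-subject anatomical variability. Passing the
simulation studies therefore shows that the estimator and the inference
machinery are correct and calibrated under the stated generative model —
not that effects of this size are detectable in real cohorts, where all
of the above inflate variance.

## Validation experiments and problem sizes

`decm.experiments` fixes the simulation conditions: the type-I calibration
uses 200 null cohorts (no group difference) of 8 subjects per group on a
14×14×10 grid, 60 volumes, 30 maps, two networks, 500 permutations, one
contrast direction per family; the recovery study uses 20 replicate
default cohorts (10 per group, 120 volumes, 60 maps) and counts a null
network as falsely flagged only when an FWE-significant cluster exceeds
10 voxels — the same cluster rule the reporting layer uses, under which a
correctly calibrated exact test flags a null network only rarely. These
sizes keep each experiment to a few minutes on one CPU.

## Numerical choices and degenerate inputs

Strict thresholds for density/percentile masks (exact-zero background is
excluded), inclusive for the group fraction. Degenerate (zero-variance)
rows are detected at norm ≤ 1e-10 relative to row scale. Clipping of
roundoff-negative centralities to 0 precedes the final renormalization.
Permutation inference fixes dh from the *observed* t-map so the null and
observed enhanced statistics share one scale. Voxels with zero residual
variance get t = 0 with a counted warning. Collinear designs, templates
or confounds raise errors naming the most correlated pair. The
`(1+b)/(1+m)` p-value estimator keeps the test exact-level and p > 0.

## Known limitations

Single whole-cohort exchangeability only (no exchangeability blocks, no
variance smoothing, no random-field or FDR alternatives); rectangular
windows with step one TR (no tapering, no DCC/HMM-style state models);
NIfTI-1 only; the CLI `dualreg` subcommand reconstructs a centrality
series from a saved ECM file without its window metadata. The sliding
window bounds the temporal resolution of any detected dynamics: only
fluctuations slower than roughly W volumes survive.
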