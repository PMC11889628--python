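# Methods

This note documents the statistical model behind `readcov`, the choices
made where the methodology was genuinely open, what the synthetic-data
generator does and does not emulate, and the package's known limitations.

## Structural covariance model

The unit of analysis is a subjects × regions table of mean grey-matter
volume (GMV), obtained either directly or by averaging spatially
normalized GMV maps over regions of interest (ROIs). For a group $g$ with
$n_g$ subjects, the structural covariance (SC) matrix is the Pearson
correlation matrix of the regional volumes across subjects, computed
*after* nuisance covariates have been regressed out.

**Residualization.** Each region is regressed (OLS, intercept included) on
the nuisance covariates — total intracranial volume (TIV) always; age and
nonverbal-IQ percentile for child-group comparisons — over the *pooled*
sample of the two groups being compared, and the residuals replace the
volumes. Pooled (rather than per-group) fitting is used because the
subsequent permutation test reassigns subjects across groups: fitting once
before permutation keeps the residualization identical under every
relabeling and avoids leakage of group information into the nuisance fit.
Residuals are exactly mean-zero and sample-orthogonal to every covariate.

**Correlation, not covariance.** SC is computed as Pearson correlation of
the residuals. Correlation is scale-free, is the dominant convention for
structural covariance networks, and keeps all entries on a common bounded
scale; raw covariance conveys region-specific variance that the group
comparison is not about. No Fisher z-transform is applied by default — the
tested statistic is then literally a difference of mean correlations; a
`fisher_z` flag applies the transform before averaging for users who want
variance stabilization.

## Permutation tests

**Overall test.** The statistic is the mean over the $R(R-1)/2$
upper-triangle entries of $SC_A - SC_B$, kept signed. The null is built by
randomly reassigning the pooled residualized subjects to two groups of the
original sizes and recomputing both correlation matrices; 1000 permutations
by default. The p value is two-sided via absolute values, with add-one
smoothing:

    p = (1 + #{ |T*| >= |T| }) / (1 + n_perm)

so p is never 0 and lies in [1/(1+n_perm), 1]. Signed-statistic,
two-sided testing was chosen because the scientific question ("do the
matrices differ?") is directionless; the sign of the observed statistic is
still reported so directionality can be read off.

**Pairwise post-hoc tests.** Per region pair, the statistic is
$SC_A[i,j] - SC_B[i,j]$ under the same reassignment scheme. All pairs share
one permutation stream (the same sequence of relabelings evaluated on every
pair), so the entire result set is reproducible from a single seed and
cross-pair comparisons are made on common resamples. The family of pairwise
p values is corrected with the Benjamini–Hochberg step-up procedure at
q = 0.05: sort ascending, find the largest k with p(k) ≤ k·q/m, reject the
k smallest.

**Calibration.** With both groups drawn from one covariance structure at
the default cohort sizes (110 vs 68), the overall test's rejection rate at
α = 0.05 is measured at 0.035 over 200 simulations (test suite and
acceptance script); with a planted single-pair difference of 0.7 vs 0.0 the
planted pair survives BH in 100 % of 100 simulations.

## Seed-based voxelwise GLM

For one seed ROI, each in-mask voxel's GMV across subjects is modelled as

    y_v = b0 + b1 * TIV + b2 * seed + e,

and the map of t statistics for $b_2$ is the seed covariance map. Design
columns are internally centred and unit-scaled (the t statistic is
invariant to per-column affine maps when an intercept is present), which
keeps the normal equations well conditioned for covariates in raw units
such as TIV in mm³. The default analysis mask keeps voxels whose values
vary across subjects; voxels with zero residual variance are dropped.

**Cluster-extent inference.** The t map is thresholded one-sided (positive)
at the voxel-level p < 0.001 quantile of t(df), and suprathreshold voxels
are grouped into clusters with 18-neighbour connectivity (faces + edges,
the convention of the classical VBM software family). Family-wise error is
controlled by a permutation null of the *maximum* cluster size: the seed
covariate's association is broken by Freedman–Lane permutation — the
nuisance-only model is fitted once, its residuals are row-permuted, and the
full model plus thresholding plus labeling is recomputed per permutation.
(Re-adding the nuisance fit after permuting is algebraically redundant
here: it lies in the column space of the full design and so changes neither
the seed coefficient nor the residual sum of squares.) Each observed
cluster's FWE p is the add-one proportion of permutations whose maximum
cluster is at least as large. This replaces the random-field-theory
cluster correction of classical VBM: RFT requires smoothness estimation
and Gaussian-field assumptions, while the permutation null is exact under
exchangeability of subjects, at the price of computation. One-sided
positive contrasts are the default because structural covariance seeds are
reported for positive coupling.

Measured behaviour at the simulated analysis scale (32³ voxel grid, n = 100,
500 permutations): a planted cluster with seed coupling 0.06 against voxel
noise 0.05 is detected at cluster-FWE p ≈ 0.002; under pure noise the
family-wise false-alarm rate over 100 simulations is 0.05–0.08 depending on
the seed stream, consistent with binomial noise around the nominal 0.05.

## Volumetric conventions

- **Sphere ROIs** use the voxel-centre rule: a voxel belongs to the sphere
  iff its centre's MNI position is within the radius (boundary included,
  with a 1e-9 mm² tolerance so exact-radius lattice points survive floating
  point). Centres are never snapped to the lattice. On a lattice-aligned
  1 mm grid a 4 mm sphere contains 257 voxels; on a 2 mm grid, 33 — counts
  are grid-dependent and should be reported, not assumed.
- **Smoothing** converts FWHM (mm) to a per-axis Gaussian σ in voxels via
  σ = FWHM/√(8 ln 2) and the voxel size; boundary mode is *reflect*, which
  keeps constant maps exactly constant and preserves the global mean.
  Sheared/oblique affines are rejected rather than mishandled.
- **No resampling**: all maps entering one analysis must share a grid and
  affine (spatial normalization is assumed done upstream); mismatches raise
  with the offending subject ids.
- Voxel indices are 0-based; world coordinates are RAS+ MNI millimetres via
  the affine.
- QC boundary: a quality rating of exactly 75 % is retained ("below 75 %"
  read strictly).
- Summary-statistics t-tests default to the pooled-variance Student form
  (df = n₁ + n₂ − 2, matching the df conventionally printed in demographic
  tables); Welch is available via a flag.

## Synthetic-data generator

The generator exists because subject-level data of this kind is restricted;
it gives every downstream stage a ground truth.

- **Phenotypes** emulate a school-age reading cohort: group sizes default
  to 110 typical / 68 poor readers; fluency percentiles are drawn inside
  each group's admissible band (truncated normal 59.35 ± 21.40 on [25, 100]
  for typical readers, uniform on (0, 16] for poor readers), so
  classification by the percentile rule reproduces the intended groups
  exactly; ages are uniform over each group's observed range; IQ
  percentiles are truncated normals (62 ± 17 / 56 ± 18); TIV is normal
  1.45×10⁶ ± 1.2×10⁵ mm³ truncated positive; MRI quality ratings cluster
  near 86–87 %; ADHD/dyscalculia flags are more prevalent in the poor
  group (15 % / 10 % vs 3 % / 2 %).
- **Regional volumes**: volume = mean + sd·z + β_TIV·(TIV − TIV_mean), with
  z ~ MVN(0, C_g) from the Cholesky factor of the group's target
  correlation matrix. Non-PSD targets are *rejected, not repaired* — a
  nearest-PSD projection would silently change the ground truth the tests
  recover against. Defaults: regional mean 0.55, sd 0.06 (GMV density
  units), β_TIV = 3×10⁻⁷ per mm³ (≈ 0.6 regional SD per TIV SD — a strong
  but not dominant confound), uniform off-diagonal SC 0.45 (typical) /
  0.25 (poor). Published SC matrices in this literature are typically
  displayed only as color maps without numeric values, so these magnitudes
  are the package's own realistic choices, not calibrated ones.
- **Voxel maps**: baseline 0.5 plus i.i.d. Gaussian voxel noise; a seed
  sphere carries a subject latent s ~ N(0,1) scaled by `seed_amp`; planted
  clusters add `coupling_strength`·s; the whole map is scaled by
  1 + κ·(TIV − TIV_mean)/TIV_sd (multiplicative, mimicking global-volume
  scaling). The default grid is 32³ at 2 mm isotropic with one shared
  affine, so full seed-GLM analyses run in seconds. Empirical correlation
  matrices of simulated volumes converge to the configured targets (max
  deviation < 0.05 at n = 5000 after TIV residualization; verified in the
  suite).

What the generator does **not** emulate: cortical anatomy and tissue
geometry, segmentation and registration artifacts, spatially correlated
scanner noise, site/scanner effects, non-linear TIV scaling, missing data.
Passing tests therefore demonstrate the *statistical machinery* —
calibration, power, invariances — under the assumed generating model, not
robustness to real-MRI artefacts.

## Numerical choices

- Permutations are generated with numpy's PCG64 `Generator`; every
  stochastic function takes an explicit seed and reproduces byte-identical
  serialized output under it. Simulation sub-streams (phenotypes, volumes,
  maps) are derived via `SeedSequence` spawning, so adding map simulation
  does not perturb the volume draws.
- Group-comparison permutations are vectorized in blocks of 128 to bound
  memory at large region counts (e.g. 140-region parcellations: ~0.2 GB
  peak rather than n_perm × n × R full materialization).
- The permutation loop of cluster inference runs in float32 (the design is
  standardized first, so conditioning is benign); observed t maps are
  float64.
- Degenerate-region detection uses a relative tolerance (sd ≤ 1e-12 ×
  max(|values|, 1)), so residuals that are floating-point dust around zero
  (a region exactly proportional to a covariate) are flagged rather than
  yielding correlation of noise.
- Correlation inputs are forced C-contiguous so identical data give
  bitwise-identical matrices regardless of DataFrame memory layout.
- Monte-Carlo p values use add-one smoothing throughout (permutation and
  cluster-FWE), guaranteeing p > 0 and exact validity of the test.

## Limitations

- Random-field-theory FWE, voxel-level FWE, and anatomical labeling of
  clusters are not implemented; cluster tables report peak MNI coordinates
  only.
- No resampling between grids: inputs must be pre-normalized to a common
  template space.
- The overall statistic (mean upper-triangle difference) can mask
  sign-cancelling pairwise differences; the pairwise tests exist precisely
  to localize effects, and the signed/absolute and pooled/per-group
  residualization choices are exposed as documented flags rather than
  silently fixed.
- Whole-brain parcellation analyses (≈140 regions, ~10⁴ pairs) are
  supported by the same code paths but BH correction at that scale is
  conservative relative to the 10-pair reading-network family; runtime
  remains minutes.
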