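# readcov

Structural covariance (SC) analysis of reading-related brain regions from
grey-matter-volume (GMV) data.

Structural covariance is the correlation, across subjects, of a structural
brain measure between pairs of regions — here the mean GMV of
reading-network regions of interest (ROIs) — and is read as evidence of
coordinated development of those regions. `readcov` implements the full
analysis path for comparing SC between groups of readers (e.g. typically
reading children vs children with poor reading skills, defined by a
reading-fluency percentile ≤ 16 vs ≥ 25):

1. **Cohort assembly** — MRI-quality filtering (ratings below 75 % excluded),
   reading-group classification from fluency percentiles, comorbidity
   (ADHD/dyscalculia) exclusion, and two-sample *t*-tests from summary
   statistics for demographic tables.
2. **Volumes** — Gaussian smoothing of GMV maps, spherical ROI construction
   at MNI coordinates (the six reading-network spheres — VWFA_lex, VWFA_per,
   STG, PCG, IFG, IPL — ship with the package), parcellation label images,
   and mean-GMV extraction into a subjects × regions table.
3. **Seed-based covariance GLM** — per voxel, GMV is regressed on an
   intercept, total intracranial volume (TIV, nuisance) and a seed ROI's
   mean GMV; the seed coefficient's *t*-map is thresholded (voxel
   *p* < 0.001, one-sided) and cluster extents are tested against a
   Freedman–Lane permutation null of the maximum cluster size
   (family-wise-error corrected).
4. **SC matrices** — per group, Pearson correlations of TIV-residualized
   (optionally age/IQ-residualized) regional volumes; group differences are
   tested by permutation (default 1000 permutations): overall (mean
   upper-triangle difference) and per region pair, with Benjamini–Hochberg
   FDR correction across pairs.
5. **Synthetic cohorts** — because subject-level MRI data of this kind is
   restricted, a first-class generator simulates phenotypes, regional
   volumes with known group-specific correlation structure and a TIV
   confound, and small voxel maps with planted covarying clusters, so every
   stage is testable against ground truth.

The core test statistic for the group comparison is, for groups $A$ and $B$
with SC matrices $R^A$ and $R^B$ (Pearson correlations of residualized
volumes),

$$T = \frac{2}{R(R-1)} \sum_{i<j} \left( R^A_{ij} - R^B_{ij} \right),$$

with a permutation null built by randomly reassigning the pooled subjects
to groups of the original sizes, and the two-sided Monte-Carlo p value
$p = \left(1 + \#\{|T^\*| \ge |T|\}\right) / (1 + n_\text{perm})$.

## Worked example

```python
from readcov import cohort, scmatrix, synthdata

# a synthetic two-group child cohort at the default group sizes
cfg = synthdata.SimulationConfig(
    n_per_group={"typical_child": 110, "poor_child": 68}, rng_seed=5
)
subjects = synthdata.simulate_phenotypes(cfg)
volumes = synthdata.simulate_roi_volumes(cfg, subjects)

# residualize on TIV, split by group, compare
resid = scmatrix.residualize(volumes, subjects.set_index("id")[["tiv"]])
a = resid.loc[subjects.loc[subjects.group == "typical_child", "id"]]
b = resid.loc[subjects.loc[subjects.group == "poor_child", "id"]]
result = scmatrix.compare_sc_overall(a, b, n_perm=1000, rng_seed=5)
print(f"observed mean SC difference: {result.observed:.3f}")
print(f"permutation p: {result.p:.4f}")

pairwise = scmatrix.compare_sc_pairwise(a, b, n_perm=1000, rng_seed=5)
print(pairwise.head(3).to_string(index=False))
```

prints

```
observed mean SC difference: 0.261
permutation p: 0.0020
region_i region_j  observed        p  rejected
VWFA_lex      STG  0.493714 0.001998      True
     STG      IPL  0.424361 0.002997      True
VWFA_per      IFG  0.340271 0.010989      True
```

The default generator gives typical readers a uniform inter-regional SC of
0.45 and poor readers 0.25, so the observed mean difference (~0.26) recovers
the planted gap of 0.2 (the excess reflects sampling noise at these group
sizes), and the strongest pairs survive BH-FDR.

A full end-to-end run (simulation → SC comparison → seed GLM with cluster
inference) is one command:

```sh
readcov demo --out demo_run --seed 5
```

which writes two SC matrices, the overall and pairwise comparison results,
a seed *t*-map with its cluster table, and a `runlog.json` whose exclusion
counts reconcile with the input row count.

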