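# Packaged synthetic demo: a small two-group child cohort with a stronger
# inter-regional correlation structure in typical readers, plus voxel maps
# containing one planted cluster covarying with the seed sphere.
simulation:
  n_per_group:
    typical_child: 40
    poor_child: 30
  map_grid:
    shape: [24, 24, 24]
    voxel_size: 2.0
  seed_roi:
    name: seed
    center: [-10.0, -10.0, 0.0]
    radius: 5.0
  cluster_rois:
    - name: planted
      center: [12.0, 12.0, 8.0]
      radius: 5.0
  seed_amp: 0.08
  coupling_strength: 0.06
  map_tiv_coupling: 0.02
  noise_sd: 0.05
analysis:
  covariates: [tiv]
  qc_threshold: 75.0
  n_perm: 200
  q: 0.05
  smoothing_fwhm: 0.0
  voxel_p: 0.001
  fwe_alpha: 0.05
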