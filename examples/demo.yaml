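# Desk-scale demo: three synthetic bundles, 19+19 subjects, one injected
# AFD effect. Run with:
#   tractoprofile run --config examples/demo.yaml --out results/demo --seed 7
metrics: [AFD, FA]
sh_order: 8
voxel_size_mm: 2.5
mesh_subdivisions: 3
stats:
  n_permutations: 1000
  alpha: 0.05
  n_metrics_bonferroni: 2
  cluster_extent_min: 5
cohort:
  n_per_group: 10         # raise to 19 for the full-size cohort
  noise_sd: 0.05
effect_windows:
  - bundle: arc
    metric: AFD
    segment_start: 40
    segment_stop: 60
    delta: 2.5
bundles:
  - name: arc
    centerline: [[-30, 0, 0], [-20, 18, 0], [0, 26, 2], [20, 18, 4], [30, 0, 4]]
    n_streamlines: 25
    radial_dispersion_mm: 1.5
  - name: sigmoid
    centerline: [[-30, -10, 20], [-10, -16, 21], [10, -4, 23], [30, -10, 24]]
    n_streamlines: 25
    radial_dispersion_mm: 1.5
  - name: ribbon
    centerline: [[-25, -28, -20], [0, -20, -16], [25, -28, -20]]
    n_streamlines: 25
    radial_dispersion_mm: 1.5
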