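# Demo pipeline configuration: a 300x300-pixel synthetic landscape of mixed
# wetland complexes over 40 years, six waterbird species with the bundled
# annual-cycle table, planted abundance drivers per species, and planted
# flood-probability trends on three functional classes.
seed: 7
output_dir: wetbird_demo_out

landscape:
  grid_height: 300
  grid_width: 300
  fine_cell_size: 30.0
  coarse_factor: 12
  years: [1984, 2023]
  coherence: independent
  random_patches:
    stochastic_profiles: true
    class_trends:
      managed: -0.25
      palustrine: -0.20
      rice: 0.30

hydro_window: [2008, 2022]
period1: [1984, 2003]
period2: [2004, 2023]
trend_alpha: 0.1

importance:
  n_tree_grid: [500]
  n_subsamples: 0
  node_size: 5

species:
  - name: american_avocet
    effects:
      - {covariate: wetland_area, shape: linear, magnitude: 1.0}
      - {covariate: semi_permanent, shape: linear, magnitude: 1.0}
      - {covariate: littoral_saline, shape: saturating, magnitude: 0.8}
    noise_sd: 0.15
  - name: black_necked_stilt
    effects:
      - {covariate: wetland_area, shape: linear, magnitude: 1.0}
      - {covariate: littoral_saline, shape: saturating, magnitude: 1.0}
      - {covariate: managed, shape: linear, magnitude: 0.6}
    noise_sd: 0.15
  - name: canvasback
    effects:
      - {covariate: wetland_area, shape: linear, magnitude: 1.0}
      - {covariate: semi_permanent, shape: linear, magnitude: 1.0}
      - {covariate: estuary, shape: linear, magnitude: 0.8}
    noise_sd: 0.15
  - name: cinnamon_teal
    effects:
      - {covariate: wetland_area, shape: linear, magnitude: 1.0}
      - {covariate: rice, shape: exponential, magnitude: 0.7}
      - {covariate: pond, shape: saturating, magnitude: 0.5}
    noise_sd: 0.15
  - name: northern_pintail
    effects:
      - {covariate: wetland_area, shape: linear, magnitude: 1.0}
      - {covariate: rice, shape: linear, magnitude: 0.9}
      - {covariate: managed, shape: linear, magnitude: 0.5}
    noise_sd: 0.15
  - name: wilsons_phalarope
    effects:
      - {covariate: wetland_area, shape: linear, magnitude: 1.0}
      - {covariate: littoral_saline, shape: saturating, magnitude: 1.2}
      - {covariate: semi_permanent, shape: linear, magnitude: 0.8}
    noise_sd: 0.15
    absent_cycles: [nonbreeding]
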