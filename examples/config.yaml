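# Example run configuration: a 2 km x 2 km six-stratum landscape with a
# dense systematic plot grid (the real survey uses 1-km spacing over a
# ~15,500 km^2 jurisdiction; at desk scale the spacing shrinks with the
# landscape so every stratum keeps enough plots for calibration).
seed: 7
landscape:
  extent_m: [2000, 2000]
  fine_cell_m: 2
  stratum_codes: [102, 103, 106, 118, 119, 121]
  n_domains: 10
  mean_height_m: [12, 10, 7, 11, 16, 9]
  height_cv: 0.45
  correlation_range_m: 150
  gap_fraction: [0.10, 0.15, 0.25, 0.10, 0.05, 0.30]
  agb_coefficient: 3.0
  agb_exponent: 1.4
  plot_noise_cv: 0.275
  plot_spacing_m: 100
  plot_radius_m: 25
  cover_min: 0.10
  cover_height_m: 4
experiment:
  resolutions_m: [10, 44, 100]   # 25 m needs fine_cell_m = 1 to tile exactly
  baseline_m: 44
  confidence: 0.95
  n_replicates: 200
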