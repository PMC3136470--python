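# Example end-to-end run: two sites, 4+4 replicates.
# symbioquant run --config example_run.yaml --out run_output
seed: 7

simulate:
  n_proteins: 300
  host_fraction: 0.25
  n_replicates: 4
  base_mean_low: 30.0
  base_mean_high: 150.0
  dispersion: 0.2
  fraction_differential: 0.4
  fc_sd: 1.0
  n_housekeeping: 10
  housekeeping_mean: 50.0
  dropout_rate: 0.1
  outlier_rate: 0.02
  outlier_magnitude: 5.0

respirometry_sim:
  substrate: ammonium
  site_slopes: {A: 0.01, B: 0.03}   # B responds 3-fold more steeply
  ambients: [10.0, 20.0, 30.0, 40.0]
  noise: 0.10
  n_points: 50

qc:
  max_ppm: 3.0
  fdr: 0.01
  scope: run

quantify:
  presence_scope: both
  min_unique: 3
  outlier_k: 2.0
  zero_floor: 0.2
  reference_site: A

summarize:
  top_n: 25
  direction_threshold: 0.0

respirometry:
  steady_fraction: 0.5
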