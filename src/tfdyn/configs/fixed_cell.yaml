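condition: fixed_cell
seed: 20140314
profile: full
motion:
  fraction_free: 0.0
  fraction_short: 0.0
  fraction_long: 1.0
  d_free: 1.31
  d_bound: 0.0
  tau_short: 0.5
  tau_long: 1000000000.0
frap_model:
  fraction_free: 0.0
  fraction_short: 0.0
  fraction_long: 1.0
  d_free: 1.31
  d_bound: 0.0
  tau_short: 0.5
  tau_long: 1000000000.0
regime:
  frame_lag_ms: 6.25
  second_lag_ms: 12.5
  frames_per_series: 8
  series_per_cell: 180
  n_cells: 20
  roi_pixels: 50
  pixel_size_um: 0.22
  localization_sigma_um: 0.04
  mean_peaks_per_frame: 1.5
  blink_off_rate: 0.0
  blink_on_rate: 0.0
  bleach_rate: 0.0
  axial_extent_um: 1.0
  detection_slab_um: null
frap_geometry:
  a_um: 6.0
  b_um: 4.0
  c_um: 2.5
  strip_width_um: 1.0
frap_protocol:
  n_prescans: 40
  scan_interval_s: 0.1
  bleach_duration_s: 0.1
  recovery_duration_s: 55.0
  bleach_survival: 0.16
  n_cells: 30
  n_particles: 20000
  sim_timestep_s: 0.05
  n_bleach_substeps: 5
search:
  n_fraction: 10
  n_tau_short: 5
  n_tau_long: 8
  refine_passes: 1
  candidate_particles: 3000
  final_particles: 120000
  stage2_pool: 40
  polish_pool: 15
pics:
  max_lag_ms: 37.5
  background_window_um2:
  - 1.0
  - 4.0
  min_pairs: 50
  n_groups: 3
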