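# Full pipeline configuration (all keys optional; defaults shown).
seed: 1

sim:
  n_animals_per_paradigm: 8     # animals per conditioning group
  n_cells: [50, 80]             # per-animal cell count (int or [lo, hi] range)
  fps: 2.3                      # imaging frame rate, frames/s
  duration_s: 80.0              # V2L test recording length, s
  stim_times_s: [20.0, 40.0, 60.0]  # three V2L repetitions per time point
  baseline_f0: 100.0            # arbitrary fluorescence units
  noise_sd: 0.02                # white noise sd, fraction of baseline
  drift_amplitude: 0.01         # slow sinusoidal drift, fraction of baseline
  drift_period_s: 90.0
  responder_fraction: 0.8       # probability a cell responds at all
  amplitude_mean: 0.12          # per-cell response amplitude, dF/F units
  amplitude_sd: 0.05
  rep_jitter_sd: 0.08           # repetition jitter sd at coupling 0
  # paradigm_effects:           # per paradigm/time point [gain, coupling];
  #   T1: {before: [1.0, 0.3], right_after: [1.125, 0.3],
  #        1hr: [1.25, 0.55], 2hr: [1.5, 0.8]}
  #   ...                       # omit for the default effect table
  vta_amplitude_mean: 0.3       # long (dopaminergic) transient amplitude
  vta_amplitude_sd: 0.1
  seed: 1

design:
  paradigms: [V2L_only, VTA_only, T1, T2]
  time_points: [before, right_after, 1hr, 2hr]
  n_repetitions: 3

dff_half_window_s: 2.5          # sliding-median half window for V2L responses
vta_dff_half_window_s: 40.0     # ... and for VTA responses
response_summary: peak          # per-cell response vector summary (peak|mean)
response_window_s: 5.0
occurrence_k_sd: 3.0            # occurrence threshold, baseline SD multiples
occurrence_binary_alpha: true   # Cronbach alpha on 0/1 occurrence (else graded)
responder_threshold: 0.2        # high-responder dF/F criterion
vta_sum_window_s: [30.0, 50.0]  # summed VTA response window, s
exclude_first_s: 10.0           # onset-artifact exclusion for display traces
alpha: 0.05
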