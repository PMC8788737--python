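# era3d default pipeline configuration.
#
# Every key shown here is recognized; unknown keys are rejected so typos
# fail loudly.  Command-line flags override config values, and the global
# --seed flag overrides master_seed.

master_seed: 0

io:
  delimiter: ","          # field delimiter of the ECG export
  decimal: "."            # decimal mark
  lead: "II"              # analysis lead (rhythm-strip convention)
  fs: null                # native sampling rate (Hz) when no time column exists

preprocess:
  fs_target: 125.0        # working sampling rate after resampling (Hz)
  filter_order: 4         # Butterworth low-pass order
  cutoff_hz: 40.0         # low-pass cut-off (Hz), applied zero-phase

annotator:
  low_dv_coef: 0.1        # "low dV" threshold, x SD(dV) over the segment
  high_dv_coef: 0.2       # "high dV" threshold, x SD(dV)
  run_length: 5           # samples per low/high run (and T-end settling run)
  t_search_start_frac: 0.125   # T search window start, fraction of beat duration
  t_search_end_frac: 0.5       # T search window end
  t_end_coef: 0.07        # T-end |dV| threshold, x SD(V); calibrated default
  refractory_s: 0.4       # minimum spacing between R onsets (s)
  q_window_s: 0.10        # Q search window before the R peak (s)
  r_window_s: 0.12        # R refinement window after the onset (s)

classifier:
  k: 13                   # neighbor count (odd) for `era3d classify`
  feature_set: RR_QT_TQ   # RR_QT | RR_TQ | QT_TQ | RR_QT_TQ
  k_smote: 5              # SMOTE minority-neighbor count

evaluation:
  n_runs: 1000            # repeated stratified subsampling runs
  n_train_control: 48     # training controls per run
  n_train_paf: 7          # training PAF subjects per run
  k_min: 3                # k grid: consecutive odd values k_min..k_max
  k_max: 41
  feature_sets: [RR_QT, RR_TQ, QT_TQ, RR_QT_TQ]

simulate:
  ecg:
    mean_hr_bpm: 40.0     # 25-90 bpm operating range
    rr_cv: 0.05           # RR coefficient of variation
    noise_sd_mv: 0.01     # additive white noise SD (mV)
    baseline_amp_mv: 0.05 # baseline-wander amplitude (mV)
    baseline_freq_hz: 0.25
    fs: 500.0             # recorder-native rate; the pipeline resamples to 125 Hz
    duration_s: 60.0
  cohort:
    n_control: 55
    n_paf: 10
    beats_min: 500        # usable beats per subject (range)
    beats_max: 800
    delta_sd: 0.0         # between-class shift in pooled within-class SDs
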