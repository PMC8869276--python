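# Full synthetic run: 8-subject default study scenario.
mode: synthetic
seed: 1
scenario:
  name: study_default
  n_subjects: 8
timeline:
  set_durations_s: [60.0, 50.0, 40.0]
  baseline_s: 300.0
  rest_s: 180.0
  recovery_s: 300.0
psd:
  segment_s: 150.0
  overlap: 0.5
  window: hann
  detrend: linear
stats:
  correction: gg
  alpha: 0.05
  rpe_agg: last
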