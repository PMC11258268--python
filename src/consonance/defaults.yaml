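# Canonical model and analysis constants, surfaced in one place.
# CLI flags and dataclass defaults mirror these values (asserted in tests).

dissonance:
  p: 0.096        # slow-beat boundary (critical-bandwidth units)
  q: 1.632        # slow-beat pleasantness strength
  r: 1.359        # amplitude exponent

composite:
  w_interference: -1.0
  w_harmonicity: 0.837

harmonicity:
  resolution: 1200       # pitch-class bins per octave
  smear_sd_cents: 6.83
  template_n_harmonics: 12
  template_roll_off: 3.0  # dB/octave

smoothing:
  bandwidth_interval_wide: 0.2     # semitones, 15-st ranges
  bandwidth_interval_tuning: 0.035 # semitones, 0.5-st ranges
  bandwidth_rolloff: 1.5           # dB/octave
  n_boot: 1000
  ci_mult: 1.96

peaks:
  merge_depth_alpha: 0.01
  sharpness_beta_behavioral: 0.01
  sharpness_beta_model: 0.05
  curvature_frac: 0.05             # 1/20 of range
  sharpness_window: 0.5            # semitones
  reliability_window: 0.5          # semitones
  reliability_threshold: 0.95

fitting:
  overlap_frac: 0.0267             # of the interval range
  bounds:
    p: [0.01, 0.5]
    q: [0.0, 5.0]
    r: [0.5, 3.0]
    w_harmonicity: [0.0, 3.0]

gsp:
  dim_low: 0.5                     # semitones, each triad dimension
  dim_high: 8.5
  n_chains: 200
  chain_length: 40
  kde_bandwidth: 0.375             # semitones
  model_kde_bandwidth: 0.1875
  out_grid: 500

stimuli:
  bass_midi_low: 55
  bass_midi_high: 65
  envelope:
    attack: 0.200
    attack_level: 1.0
    decay: 0.100
    decay_level: 0.8
    sustain: 0.030
    release: 1.0
  bonang_ratios: [1.0, 1.52, 3.46, 3.92]
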