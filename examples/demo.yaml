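# Small synthetic demo: two groups of 6, a -0.25 mm offset on "parent"
# from 10 s, compared one-tailed (parent lower).
seed: 42
out_dir: scratch/demo_run

sim:
  trial_length_s: 40.0
  phi: 0.7
  tonic_sd: 0.2
  noise_sd: 0.04
  blink_rate_hz: 0.2
  seed: 42

groups:
  - [parent, 6]
  - [child, 6]

effects:
  - group_label: parent
    onset_s: 10.0
    magnitude_mm: -0.25
    ramp_s: 1.0

comparisons:
  - group_a: parent
    group_b: child
    tail: A_less

stats:
  alpha_point: 0.1
  alpha_fw: 0.05
  n_sim: 2000
  seed: 42
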