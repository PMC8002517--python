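# Full self-relative evaluation on a synthetic cohort:
# 12 subjects with identity planted in the gamma band (30-50 Hz),
# a 2-order x 5-band configuration grid, and a 5-step enrollment
# simulation averaged over 3 label sequences.
seed: 2

pipeline:
  channel_set: [C0, C1, C2, C3, C4, C5]
  filter_order: 1
  band_hz: [30, 50]
  filter_variant: causal
  sampling_rate_hz: 160
  segment_length_s: 5
  overlap_fraction: 0.4
  ar_order: 12
  classifier: {kind: knn, neighbors: 1, distance: euclidean}
  kfold: 3
  duration_s: 30

sweep:
  orders: [1, 2]
  bands: [delta, theta, alpha, beta, gamma]

openness:
  first_size: 3
  last_size: 11
  n_steps: 5
  step_trials: 100
  step_prob: 0.04
  n_sequences: 3

cohort:
  n_subjects: 12
  n_channels: 6
  sampling_rate_hz: 160
  duration_s: 30
  identity_band_hz: [30, 50]
  separability: 1.0
  channel_labels: [C0, C1, C2, C3, C4, C5]
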