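# eegident

Self-relative evaluation of EEG-based person identification under
open-set enrollment.

## The problem

EEG-based biometric systems identify people from short segments of their
brain activity. Which preprocessing configuration — in particular which
frequency sub-band and band-pass filter order — extracts the most robust
identity information? Static benchmarks with a fixed subject pool cannot
tell: many configurations reach near-ceiling accuracy on a small closed
set. Real systems, however, are *open*: new subjects enroll over time,
and weak identity information shows up as accuracy that degrades as the
population grows.

`eegident` implements this self-relative evaluation for researchers in
EEG biometrics and biosignal processing. It provides:

* a parameterised identification pipeline — channel selection, common
  average referencing (CAR), Butterworth band-pass (causal or
  zero-phase), static overlapped segmentation, Burg autoregressive (AR)
  features, and plug-compatible classifiers (KNN, naive Bayes, decision
  tree, LDA);
* an openness simulator that enrolls subjects in random binomial
  increments, re-fitting and re-scoring the classifier at each step
  (repetitive batch learning with stratified k-fold cross-validation);
* self-relative degradation metrics that rank configurations;
* a synthetic-cohort generator with identity planted in a configurable
  frequency band, so the whole framework is testable without any data
  downloads (an EDF reader covers real recordings).

## Model and metrics

Each recording of duration *V* is referenced to the common average,
band-passed with a Butterworth filter of order *O* over sub-band *f*,
and cut into *N* = ⌊(V−v)/(v(1−α))⌋+1 windows of length *v* with overlap
α. Every window is summarised by the concatenated per-channel Burg AR(Q)
coefficients of

> x_t = a₁x_{t−1} + … + a_Q x_{t−Q} + e_t,

an ID vector of dimension d = H·Q for H channels. At the reference
parameterisation (H = 19, fs = 160 Hz, V = 60 s, v = 5 s, α = 0.4,
Q = 12) this gives N = 19 vectors of dimension d = 228 per subject.

The openness condition draws a subject-count sequence T₁ < … < T_R
(binomial step law, endpoints pinned) and M independent nested label
sequences L₁ ⊂ … ⊂ L_R. At each step the classifier is refit on the
enrolled subjects' vectors and scored by stratified k-fold
cross-validation; averaging the M accuracy trajectories gives the mean
openness accuracy OAm = (acc₁, …, acc_R). Configurations are compared
through:

* **LRL** (local relative loss, %): mean of (acc_{j−1} − acc_j)/acc_{j−1}
  over degrading steps (moving reference);
* **GRL** (global relative loss, %): mean of (acc₁ − acc_j)/acc₁ over
  degrading steps (fixed first-step reference);
* **Power** of a target parameter: max/min ratio of its marginal mean
  GRL — how strongly the parameter diversifies identity quality;
* **DMM**: acc_n · (1/GRL), maximised to select the configuration that is
  simultaneously accurate and stable under enrollment.

## Worked example

`examples/synthetic_run.yaml` describes a complete run on a synthetic
cohort: 12 subjects, 6 channels, 30 s at 160 Hz, identity planted in the
gamma band (30–50 Hz), a 2-order × 5-band grid, and a 5-step enrollment
ramp from 3 to 11 subjects averaged over 3 sequences.

```
$ eegident run-all --config examples/synthetic_run.yaml --out out/
{
 "best_config_id": "o1_b30-50",
 "best_filter_order": 1,
 "best_band_hz": [30.0, 50.0],
 "order_power": 1.1167144372849513,
 "band_power": 3.0142502060452276
}
```

The per-configuration table (`out/report/metrics.csv`) shows why the
gamma cell wins — every configuration starts near ceiling, but only the
planted band stays accurate as subjects enroll:

```
config_id  acc_first  acc_last  lrl_percent  grl_percent  dmm_last
o1_b0p5-4      1.000     0.751        6.802       19.416     0.039
  o1_b4-8      1.000     0.724        7.568       21.648     0.033
 o1_b8-13      1.000     0.717        7.918       20.018     0.036
o1_b13-30      0.988     0.700        8.452       22.687     0.031
o1_b30-50      0.988     0.892        3.035        7.649     0.117
o2_b0p5-4      0.951     0.633        9.552       25.244     0.025
  o2_b4-8      1.000     0.630       10.602       30.201     0.021
 o2_b8-13      0.975     0.734        6.827       17.412     0.042
o2_b13-30      0.951     0.684        8.544       19.679     0.035
o2_b30-50      0.975     0.865        2.908        9.552     0.091
```

The marginal mean GRL per band (`out/report/grl_by_band.csv`) is 8.6%
for 30–50 Hz against 18.7–25.9% elsewhere, a band Power of 3.0: the
sub-band parameter strongly diversifies identity quality, and the
framework picks the band where the identity actually lives.

Each stage is also exposed individually (`simulate-cohort`,
`simulate-openness`, `features`, `run-openness`, `report`), reading and
writing plain CSV/JSON so any stage can be replayed bit-exactly.

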