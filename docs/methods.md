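# Methods

## Pipeline

A recording is processed as channel selection → common average
referencing → Butterworth band-pass → static overlapped segmentation →
per-channel Burg AR features → classification.

**CAR.** The instantaneous cross-channel mean is subtracted from every
channel. It is a projection (idempotent) and, being a per-channel
identical linear time-invariant map, commutes with the band-pass filter.
By default the average is computed over the selected channel set; a
`car_over_selected` flag on the pipeline configuration computes it over
all channels present in the recording before selection instead, since
either convention is defensible when recordings carry more channels than
the pipeline uses.

**Band-pass.** One Butterworth design per (order, band) pair, realised
in second-order sections. The `causal` variant applies it in a single
forward pass and keeps the start-up transient (results are reported
as-is; tests that compare amplitudes trim explicitly). The `zero_phase`
variant applies the same design forward and backward, squaring the
magnitude response and cancelling phase. Orders are interpreted as the
design order of the low-pass prototype, so a band-pass of order O has 2O
poles.

**Segmentation.** Windows of v seconds with overlap fraction α start
every v(1−α) seconds; only complete windows are kept, giving
N = ⌊(V−v)/(v(1−α))⌋+1 segments. The floor convention matters: at the
reference parameterisation (V=60, v=5, α=0.4) the quotient is 55/3 and
only the floor reproduces the reference count N=19 without padding or
ragged windows. The hop must be a whole number of samples; a
non-integer hop is rejected with guidance rather than silently rounded.

**Burg AR features.** Coefficients follow the prediction convention
x_t = Σ aᵢ x_{t−i} + e_t. The recursion minimises the summed forward and
backward prediction-error power per stage with a Levinson-type
coefficient update. Burg's method estimates no intercept, so segments
are mean-centered before estimation; only the Q AR coefficients enter
the feature vector (no reflection coefficients or noise variance),
keeping d = H·Q exactly. The implementation agrees with the independent
Burg implementation in statsmodels to ~1e−13 relative error, which the
test suite asserts at 1e−8 over random series. Degenerate inputs
(n ≤ Q, zero variance) are rejected with the segment and channel named.

**Classifiers.** KNN (k=1, Euclidean) is the default; naive Bayes,
decision tree and LDA run through the identical contract. Evaluation is
stratified k-fold cross-validation with a seeded shuffle — with as few
as N=19 vectors per class, unstratified folds can lose whole classes
from a training split. The step accuracy is the mean of the fold
accuracies, each fold scored as the fraction correct from its pooled
confusion matrix. The classifier is refit from scratch at every step
and fold (repetitive batch learning); fold partitions are redrawn
independently at each (sequence, step) from sub-streams of one seed.

## Openness simulation

The subject count grows from T₁ to T_R in R steps. Increments are drawn
from Binomial(n, p); zeros are redrawn, since each step must enroll at
least one novel subject, and whole increment vectors are
rejection-sampled until they sum exactly to T_R − T₁ so both endpoints
are honoured. The label component draws, at each step, a uniformly
random combination of the newly enrolled subjects from those not yet in
the system, yielding nested label sets; M independent sequences are
generated, and requiring T_R < E (some subjects never enrolled) makes
sequence collisions combinatorially negligible. One master seed spawns
independent sub-streams for the sizes and for each sequence, so adding
sequences never perturbs earlier ones. Defaults reproduce a
5→97-subject ramp over 24 steps with Binomial(100, 0.04) increments for
a 108-subject population and M=10.

## Metrics

LRL and GRL are means of relative accuracy drops, against the previous
step and the first step respectively, reported in percent. Both
formulas carry an explicit degradation condition; non-degrading steps
contribute zero and the denominator stays at R−1 (all steps), keeping
values comparable across configurations with different numbers of
degrading steps. The alternative — averaging only over degrading
steps — is available via `mode="degrading_only"`. Both metrics are
ratios of accuracies and hence invariant to common rescaling of the
trajectory, and both are zero exactly when the trajectory is
nondecreasing.

Power is max/min over a parameter's marginal mean GRL values; it is
reported at full precision (display rounding to one decimal only) and
left undefined (NaN) for single-value marginals.

DMM divides a step's accuracy by GRL on the percent scale. On that
scale the best configurations of a well-performing system (last-step
accuracy near 1, GRL of order 1%) give DMM of order 1, which matches
the magnitudes this metric is reported at; the fraction scale would
inflate them a hundredfold. `dmm()` refuses GRL = 0 explicitly ("no
degradation — undefined") rather than returning infinity; the grid
report, which must still rank such cells, treats them as better than
every degrading cell and breaks ties by last-step accuracy — a
perfectly stable configuration is exactly what the selection is looking
for.

## Synthetic cohorts

The generator's purpose is to plant subject identity in a known
frequency band so that the band-selection behaviour of the framework
can be exercised end to end. Each channel of each subject sums four
stationary-in-law components:

1. **Background**: AR(1) with pole 0.9, identical in law across
   subjects — the 1/f-like low-frequency bulk of resting EEG.
2. **Identity resonance**: noise shaped, in the frequency domain, by
   the spectrum of an AR(2) pole pair (radius 0.98) whose frequency is
   drawn per subject inside `identity_band`, and set to exactly zero
   outside the band. Subject frequencies come from a jittered
   stratified draw (a random permutation of equal sub-intervals, plus a
   uniform position within each), which is random yet avoids
   near-collisions that no spectral feature could resolve; their
   dispersion scales with the separability δ, and δ = 0 collapses all
   subjects onto the band center — statistically identical cohorts.
   Channels share the subject's pole up to a small per-channel jitter
   (0.3 Hz s.d.) that is drawn once per cohort and reused for every
   subject, so CAR attenuates but cannot cancel the identity, and δ = 0
   cohorts remain exactly exchangeable.
3. **Wandering distractors** (3 per channel): unit-variance AR(2)
   rhythms, radius 0.95, whose pole frequency follows a reflected
   random walk (0.1 Hz per sample) across the frequencies below the
   identity band (1.5 Hz to 3 Hz under its lower edge; above it if the
   identity band sits too low). They are identical in law across
   subjects.
4. **White measurement noise**.

Component scales default to background 1.0, resonance 3.0, distractor
4.0 each, noise 1.0.

**Why exact band-limiting and distractors are necessary.** AR
coefficients are scale-free descriptors of spectral *shape*: a spectral
peak influences the fitted coefficients relative to the local spectral
floor, essentially regardless of its absolute power. Two consequences
drove the design. First, a time-domain AR(2) resonance has tails at all
frequencies, and those tails carry the pole position; features computed
from any sub-band read them easily, so the identity would not be
band-localised at all — hence the resonance is synthesised with exactly
zero out-of-band power. Second, a band-pass filter can only attenuate
the identity band, never remove it, and the attenuated copy in a
filter's stop band retains its full spectral shape; features from any
sub-band therefore still see the identity. The wandering distractors
break this: configurations whose pass band contains them produce
feature vectors that vary strongly from segment to segment (the rhythm
sits at a different frequency in every window), drowning the stop-band
copy of the identity, while the configuration matching the identity
band filters the distractors down to their own (weak, smeared)
stop-band copies. This mirrors real EEG, where task-unrelated rhythms
wax, wane and drift, and it is what makes identification accuracy
band-selective. The component scales were fixed while designing the
generator, by checking that nearest-neighbour identification separates
the planted band from the others across disjoint seed sets, and are not
adjusted per experiment.

**What the generator does not emulate.** Artifacts (blinks, EMG, line
noise), inter-session variability, volume-conduction mixing beyond the
shared-resonance-with-jitter construction, and amplitude-profile
identity (AR features are scale-invariant, so amplitude differences
would be invisible anyway). Two consequences for interpreting tests:
segments overlap by 40%, so same-recording feature vectors are
correlated and even a δ = 0 cohort scores above chance (the classifier
partially memorises the realisation, not the law) — the separability
property is therefore asserted as a δ = 1 vs δ = 0 dominance, not as
δ = 0 hitting chance; and the distractors make signals only piecewise
locally stationary, a deliberate deviation from a fully stationary
construction, without which band selection is provably unexercisable by
spectral-shape features. Passing tests show the framework ranks
configurations by the stability of their identity information under
enrollment; they do not certify performance on real EEG.

## Problem sizes in the test suite

Unit and property tests run on cohorts of 4–12 subjects with 4–6
channels and 10–30 s recordings. The planted-band selection check uses
the generator defaults at 12 subjects, 6 channels, 30 s, a 2-order ×
5-canonical-band grid, enrollment 3→11 in 5 steps, 3 sequences, and ten
seeded replicates, requiring the planted band to win the DMM selection
in at least 8; these sizes were chosen as the smallest at which the
selection is statistically stable. Reference-parameterisation checks
(19 segments, d = 228) run at the full 60 s, 19-channel geometry. The
acceptance script regenerates the segment-count quantity from scratch
at the reference parameterisation.
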