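# Methods

## The recognition problem

Level walking is cyclic. With the right heel strike anchoring the cycle,
four phases repeat in fixed order: the double-support phase opened by the
right heel strike (SU-RHS), the left swing phase (SW-L), the double-support
phase opened by the left heel strike (SU-LHS), and the right swing phase
(SW-R).  The package recognizes the current phase, at every sample, from a
20-sample sliding window of lower-limb joint angles measured by up to six
IMUs (left/right thigh, shank, foot) at 100 Hz.  Ground truth for training
comes from bilateral plantar ground-reaction force (GRF): a foot is in
contact when its force reaches 20 N, heel strike and toe-off are the rising
and falling edges of the two contact tracks, and each edge opens one phase.
Force exactly at the threshold counts as contact, which makes the condition
closed and deterministic on boundary samples; threshold conventions in the
gait literature specify only the strict inequalities, leaving the boundary
case open.

## The classifier

Each window (20 × C, C ∈ {2, 4, 6} channels depending on the sensor group)
passes through

    LSTM(128, full sequence) → LSTM(128, full sequence)
    → Conv1D(64, kernel 3, stride 1, 'same', ReLU) → MaxPool(2, stride 2)
    → Conv1D(128, kernel 3, stride 1, 'same', ReLU) → MaxPool(2, stride 1)
    → flatten → dense → softmax(4)

Both LSTM layers emit their full 20-step hidden sequence, so the 1×3
kernels convolve along time over 128-channel feature maps; the time axis
shrinks 20 → 10 → 9 through the two 'valid' poolings, leaving a 9 × 128
feature block for the single dense head.  Convolution padding, the dense
head width and all training hyperparameters are open choices in the source
description; we use 'same' padding (keeps ≥ 9 steps alive into the head), a
single dense layer to 4 logits, cross-entropy loss, and Adam at learning
rate 1e-3 (β₁ = 0.9, β₂ = 0.999).  Training holds out a seeded 15% window
fraction to monitor validation loss and stops when it has not improved by
`early_stop_min_delta` for `early_stop_patience` epochs, restoring the
best-validation weights.  The stack is implemented directly in NumPy
(float32), with hand-derived reverse-mode gradients for every layer; tests
check the forward passes against independent elementwise evaluation of the
gate/convolution equations and the full gradient against central
differences in float64.

Normalization is per channel, affine onto [−1, 1] by the training-set
minimum and maximum (Eq.-style min–max scaling); parameters are fitted on
training cycles only and applied frozen to test data, without clamping, so
out-of-range test values extrapolate linearly.  Dropped samples (packet
loss) are filled by linear interpolation between nearest present
neighbours before any windowing.

A window is labeled by the phase of its **final** sample.  The rule is
causal — in streaming use the label is the phase being entered — and a
majority rule is available as an option.  Because the double-support
phases last ~10% of a cycle (10–15 samples) while windows span 20 samples,
every double-support window necessarily contains samples of the preceding
swing phase; double-support windows are therefore intrinsically harder and
dominate the error mass of every model.

## Sensor groups and specialists

Seven channel subsets are studied: thighs, shanks, feet (2 IMUs each);
thighs+shanks, thighs+feet, shanks+feet (4 IMUs); and all six.  Three
fitted models get fixed roles: LSTM-CNN-1 (all six sites), LSTM-CNN-2
(shanks+feet, the SW-L specialist), LSTM-CNN-3 (thighs+shanks, the SU-LHS
specialist).  The source material is internally inconsistent about which
4-IMU group serves which phase; we follow the experiment sections (which
are mutually consistent) rather than the abstract, and the phase→model map
is configurable so either reading can be run.

## The DPF engine

Phases occur in a fixed cyclic order, so the successor of the current
phase is known.  The engine keeps a committed phase, routes incoming
windows to the committed phase's specialist, and watches that model's
predictions: when `debounce_k` (default 5) consecutive windows predict the
same new phase, the change is committed, the new phase's specialist takes
over, and the expected successor updates.  Debouncing suppresses isolated
mispredictions and costs exactly `debounce_k − 1` windows of commit
latency at each true transition.  Before the first commit the committed
phase is reported as undetermined and the full six-site model is active.
A commit that contradicts the expected successor is accepted, re-anchors
the state machine, and logs a warning — walking data should never produce
it, but a robust engine must resync.

Two per-window outputs are kept apart. The *prediction track* (the active
specialist's argmax each window) is what evaluation scores, so the
comparison against an always-on single model is like-for-like; the
*committed track* (the debounced phase) is what a downstream controller
would consume, and it necessarily lags truth by `debounce_k − 1` windows —
scoring it against per-window truth would charge the engine ~13% error
from latency alone at these cycle lengths, masking the model-routing
question the comparison is about.

## Synthetic cohort

No public recording of this modality pairs six joint angles with bilateral
GRF at 100 Hz, so the study conditions are emulated: 20 subjects (6 in the
desk-scale experiment plan) × three speeds (1.2 / 1.5 / 1.8 m/s) × 10
cycles, stance = 60% of the cycle with two symmetric 10% double supports,
cycle duration 1.8 m ÷ speed (a plausible fixed stride length; cadence
scaling is not specified by the source).  Joint angles are order-3
truncated Fourier series of the cycle phase with site-specific
coefficients, left sites offset by half a cycle, coefficients perturbed
±10% per subject, plus 0.5° Gaussian sensor noise and 1% independent
packet loss (endpoints always kept so interpolation is bounded).  GRF is a
raised-sine double bump scaled to a weight-dependent peak (~700 N ± 10%),
exactly equal to the 20 N threshold at the heel-strike sample, strictly
above it inside stance, zero in swing — so threshold labeling reproduces
the generator's truth exactly on noise-free output.

Two constructed disturbances make sensor sites differentially informative,
which is the condition the DPF comparison studies.  They emulate strap
slack accumulating over a session: around the SW-L onset the thigh
channels, and around the SU-LHS onset the foot channels, are smoothly
time-warped by an offset that ramps from 0 to 12% of a cycle across the
session's ten cycles (±2% per-cycle jitter, Gaussian warp zone of width 8%
of a cycle).  Because the cycle-level split trains on early cycles and
tests on later ones, models that read the affected channels mislocate
exactly that transition on held-out cycles, while models without them are
immune.  Design history that informed this choice: additive noise bursts
barely hurt a trained network; replay-style artifacts introduce
discontinuities that convolution layers exploit as a cue *for* the
affected phase; mean-zero smooth jitter leaves the channel a usable
unbiased boundary indicator.  A superset model can never be worse than a
subset model in Bayes terms, so any specialist advantage must come through
estimation error — here, a train/test shift that the split structure makes
systematic.

What the generator does **not** emulate: real sensor noise spectra,
biomechanically validated kinematics, turning/stopping, pathological gait,
inter-trial electrode/mounting variation beyond the slip model.  Passing
tests on this cohort show the pipeline's mechanics and the qualitative
protocol findings under the stated conditions; they do not certify
accuracy numbers on human data.

## Experiment protocol at desk scale

Each subject×speed trial of ten cycles splits 6 / 2 / 2 into training,
test, and validation cycles (the validation cycles are kept contiguous so
the engine sees an uninterrupted walking stream).  The source protocol's
70/30 train/test split plus a disjoint 20% validation set cannot all hold
exactly with ten cycles; 60/20/20 preserves the structure, and split
disjointness is asserted programmatically.  Training windows are cut at
stride 5 (reduces near-duplicate windows), test and validation windows at
stride 1 (streaming emulation).  The desk-scale training configuration is
batch 128, max 30 epochs, early stop after 3 epochs without a 1e-3
validation-loss improvement — pure-NumPy backpropagation is the throughput
bound, and on this separable cohort training converges in well under 30
epochs.  The full seven-group ablation plus the DPF comparison runs in
roughly 5 minutes on one CPU core.  All randomness (cohort, splits,
initialization, shuffling) derives from one master seed.

## Evaluation

All metrics derive from the 4×4 count matrix.  The confusion matrix is
row-normalized (each true-phase row sums to 1).  Precision, recall, F1 and
one-vs-rest accuracy are computed per phase; the macro aggregate takes
unweighted means of per-class precision and recall, and macro-F1 is the
harmonic mean of those two macro means — deliberately *not* the mean of
per-class F1s, which differs under asymmetric errors and is reported
alongside for comparison.  Zero denominators (a phase never predicted, or
absent from truth) yield 0 with a logged warning.  Argmax ties in decoding
resolve to the lowest cyclic index, logged.

## Known limitations

* The networks are CPU-bound NumPy; wall-clock, not statistics, caps the
  cohort size.
* Double-support recall is noisy (few hundred test windows per
  double-support phase at desk scale); per-phase differences of a few
  points between sensor groups are within run-to-run variation.
* The specialist advantage the DPF comparison demonstrates is constructed
  (see above); on real data its size and even its sign depend on the
  sensors' actual failure modes.
* The engine assumes walking continues; it has no explicit stop/stand
  state, and both-feet-off (running) input only produces held phases plus
  warnings.
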