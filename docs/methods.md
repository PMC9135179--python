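# Methods

This package implements two deep-learning EEG classifiers and the
evaluation protocol around them: **SASDL** (sparse autoencoder features,
swarm-based wrapper feature selection, softmax DNN) and **RBATQ** (a
Q-learning decision agent over BiLSTM-attention and Tree-LSTM state
representations).  Everything runs on synthetic EEG generated by the
package itself, so the full pipeline is testable without any data
download.

## Signal model of the synthetic generator

Single-channel ("Bonn-style") recordings are 4097 samples at 173.61 Hz.
The background class is unit-variance AR(2) noise whose resonance sits at
10 Hz (healthy scalp EEG is alpha-dominant), mixed with a small amount of
broadband noise.  The ictal-like class adds Poisson-timed 3–5 Hz
spike-wave bursts at 4× the background amplitude; each burst is a
sharpened sinusoid (a cubed-lobe "spike" riding the slow wave) under a
Tukey envelope.  The default burst rate (2.5/s) and duration (1–2 s) give
near-continuous discharge, reflecting that ictal recordings are
continuously abnormal; at these defaults ~2 % of one-second chunks of an
ictal-like recording still fall in a discharge gap, which bounds the
accuracy any classifier can reach on chunk labels.

Multichannel ("schizophrenia-style") data are latent AR(2) sources mixed
into 19 channels by a class-specific mixing matrix, so the class signal
lives in the cross-channel covariance; the canonical shape is 45 segments
× 5000 samples × 19 channels per subject.

What the generator deliberately does **not** model: artifacts (blinks,
EMG), non-stationary background drift, inter-subject variability, or any
physiological realism beyond class separability.  Passing tests therefore
demonstrate that the algorithms are implemented correctly and can exploit
class structure of the kind the real datasets contain — not that the
printed real-data accuracies would be reproduced.

Each 4097-sample recording is split into 23 contiguous chunks of
floor(4097/23) = 178 samples; the 3-sample tail is discarded.  Segments
are z-scored per segment before any model sees them, which removes the
amplitude cue and forces classifiers to use waveform shape and spectrum.

## Sparse autoencoder

Cost over a batch of N segments:

    J(W,b) = (1/N) Σ_i ½‖h_{W,b}(x^i) − x^i‖²
           + (λ/2) Σ (W^l_{ji})²
           + β Σ_j KL(p ‖ p̂_j),

with Bernoulli KL and p̂_j the batch-mean activation of bottleneck unit j.
Defaults: λ = 0.01, β = 4, p = 0.08, Adam, 50 iterations, batch 10.
Choices the cost sheet does not determine:

* Hidden units are ReLU; the decoder output layer is linear, because
  z-scored signals are negative-valued and a ReLU output could not
  reconstruct them.
* ReLU means p̂_j is unbounded, so p̂_j is clipped into [1e−8, 1−1e−8]
  inside the KL term; the clip's gradient is zero outside the interval.
  With minibatches of 10 the batch-mean p̂_j is noisy and the KL term
  equilibrates well above p; the sparsity-contrast test therefore uses
  full-batch training, where the penalty drives mean activation to p
  almost exactly.
* Encoder and decoder weights are untied (the per-layer sums in the cost
  read most naturally over independent layers).

The full-scale configuration uses a 9000-unit bottleneck (over-complete
for 4097-sample inputs).  The test profile uses a 178–96–64–96–178 stack:
the two-layer encoder matters on synthetic data because the class cue
after z-scoring is an envelope/spectral feature, and composing two ReLU
layers approximates rectified band-power detectors much better than one.

## Swarm wrapper selection

Continuous positions in R^d are decoded to masks by taking the top-m
coordinates (ties to the lowest index), which pins the feature count
exactly (9000 → 4500 at full scale).  Fitness of a mask is the validation
score of a small softmax DNN trained for 5 epochs on an inner stratified
80/20 split.  Two scores are available: plain validation accuracy, and a
smooth surrogate ("soft" — the mean predicted probability of the true
class).  The surrogate has far lower estimator variance on validation
splits of a few hundred samples; on subset-search benchmarks it is the
difference between stalling and recovering the informative features, and
the selection benchmarks use it.

Optimizer defaults follow the published parameterisations: PSO with
w = 0.64, c1 = c2 = 1.524, 30 particles × 30 generations; cuckoo search
with 20 nests, p_a = 0.45, α = 1.5, Lévy exponent 1.5 (Mantegna
construction); bat algorithm with 40 bats, frequencies in [0, 2],
A⁰ = 1, r⁰ = 0.5.  Implementation choices worth knowing:

* Cuckoo steps are scaled by the distance to the best nest
  (0.01·α·Lévy ⊕ (x−x_best), the canonical Mantegna/Yang scaling); a raw
  α ⊕ Lévy step of size O(1) never contracts and cannot approach an
  optimum to 1e−2.  Abandoned nests move by a biased random walk
  rand·(x_p − x_q), kept only when it improves the nest.
* The bat algorithm's local walk around the best solution has scale
  `local_step` × (init span) × mean loudness; loudness decays by 0.9 per
  accepted move down to a floor `loudness_min` (default 0).
* The sphere defaults (strong damping) converge fast on smooth
  objectives but collapse prematurely on the plateau landscape of top-m
  mask search, so the recovery benchmark runs each optimizer in an
  exploration-oriented configuration (PSO w = 0.9; CSO 120 generations;
  BA with slower loudness decay 0.97, floor 0.5, local step 0.2 and
  f_max = 0.5).  These are configurations of the same algorithms, not
  algorithm changes.

## Softmax DNN

Two ReLU hidden layers (2250, 500 at full scale), dropout after each
hidden layer (rate 0.5 by default; not fixed by the source
configuration), cross-entropy + L2 weight decay, Adam, 50 epochs at batch
10.  During the last 20 epochs only the softmax output layer is updated
("fine-tuning" = freezing the representation and polishing the head).
Ties in the argmax resolve to the lower class index.

## RBATQ

A segment is framed into T = ⌊178/11⌋ = 16 frames of 11 samples (test
profile; frame width is configurable) and fed to:

* a peephole BiLSTM (the printed gate equations, including the
  cell-to-gate terms and the c_{t−1} term inside the candidate
  activation) with per-direction parameters; state size 250 at full
  scale;
* additive attention over time producing s1 = Σ_t a_t [h_t ; h′_t]; the
  stage-1 class head applies the BiLSTM output-head weights to the
  attention-pooled states, so one cross-entropy trains BiLSTM, attention
  and head jointly;
* a child-sum Tree-LSTM over a balanced binary tree (depth 2) of
  contiguous sub-windows; leaves and internal nodes take the mean frame
  of their span as input; the root hidden state is s2 with its own
  softmax head.

The decision MDP: at s1 the agent commits (a1; predict the stage-1 head's
class; reward ±1) or defers (a2; reward +0.1); at s2 it predicts class 0
or 1 (a3/a4; reward ±1).  Rewards are a design choice (the source defines
their existence, not their values): symmetric ±1 terminal rewards and a
small positive deferral reward that prevents degenerate always-commit
policies without making deferral free.

Q(s, a) is an MLP on [state (s2 zero-padded to the width of s1) ;
state-kind one-hot ; action one-hot], one tanh hidden layer (100 at full
scale).  The training target is the running average
(1/t)·r + ((t−1)/t)·Q(s′, a′) with per-(state-kind, action) visit counts
t; for terminal transitions Q(s′, a′) is read as the current estimate
Q(s, a), which makes repeated visits under a constant reward converge to
that reward (the only reading under which the update has a sensible fixed
point).  Updates are RMSprop steps on the squared error; RMSprop's
scale-invariant steps mean converged values oscillate with amplitude of
order the learning rate.  ε-greedy exploration decays 0.5 → 0.05 over
training.  State builders are pre-trained with supervised cross-entropy
(Adam, max-norm 3 on weight matrices) and frozen during Q-learning by
default; with ``joint_updates=True`` each Q epoch is followed by one
further supervised builder epoch and the states are refreshed — an
alternating-minimisation scheme that keeps the representations adapting
without backpropagating the Q-loss into the recurrent networks.

## Evaluation protocol

Problems are composed by pooling labelled sets ("A-E" … "ABCD-E",
"schizophrenia").  Ten stratified folds (stratification stabilises the
small test runs and matches the balanced design in expectation); every
fitted component sees training folds only.  Metrics per fold from the
confusion counts; aggregate = unweighted fold mean.  GDR (good detection
rate) is reported as sensitivity and error rate as 100 − accuracy; both
are interpretive readings of underdefined plotted quantities.  Degenerate
denominators yield explicitly undefined (None) metrics, never NaN.

## Problem sizes used by the test suite and acceptance script

Cross-validated end-to-end runs use 20 synthetic recordings per class
(920 segments of 178 samples), the test profile's reduced widths
(bottleneck 64, 48 selected features, DNN 64/16 or 48/12, LSTM state 16),
and 10 folds.  The feature-recovery benchmark uses n = 500 samples,
d = 40, 8 informative features with ±0.6 sd mean shifts, 10 optimizer
seeds.  Sphere benchmarks run at d = 5.  These sizes were chosen so a
full run completes in minutes while every algorithmic property (learning,
selection, convergence, recovery) is still exercised at meaningful
signal-to-noise.

## Known limitations

* All networks are trained in float64 on CPU; the full-scale (9000-unit)
  profile is supported but not practical without hours of compute.
* The wrapper fitness is a single inner split — fast, but a noisy,
  slightly optimistic critic; the smooth surrogate mitigates variance,
  not bias.
* The synthetic classes are much cleaner than clinical EEG; reported
  synthetic accuracies say nothing quantitative about real-data
  performance.
* EDF support covers plain EDF reading (via mne) and a minimal writer
  for fixtures; EDF+ annotations and montage logic are out of scope.
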