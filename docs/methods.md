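# Methods

This note records the scientific choices, model parameters and problem
sizes implemented by `affectloop`. Everything below is a property of
this package; choices that are free parameters rather than forced by
the design are called out as such.

## Overview

The package simulates and evaluates a closed-loop emotion-induction
system: a music generator is driven by (valence, arousal) inputs on the
unit square, EEG recorded while a listener hears the music is decoded
into a predicted emotion, and a controller updates the generator input
during the piece to steer the listener toward a target emotion. Because
per-trial EEG from such experiments is rarely shareable, the package
ships a synthetic cohort generator whose programmed ground truth makes
every downstream claim testable.

## Synthetic cohort (`affectloop.cohort`)

Each participant owns, per frequency band, a gain matrix
(channels x 2) mapping felt emotion — centred at neutral (0.5, 0.5) —
to additive offsets of per-channel log band-power. A trial is 5 s of
silence followed by 20 s of listening; the EEG is a sum over the five
canonical bands (theta 4–7, alpha 8–13, low beta 14–21, high beta
22–29, gamma 30–45 Hz) of band-limited Gaussian noise whose variance
is:

    exp(baseline + gain @ (felt - 0.5) + noise)   while listening
    exp(baseline + gain @ (rest - 0.5) + noise)   before listening

The per-band/channel noise draws (sd `noise_scale`) are **independent
between the two periods**. This matters: a draw shared by both periods
would be removed exactly by the baseline correction of the feature
pipeline, so the independent draws are what make `noise_scale` genuine
feature noise.

The felt emotion is a clipped per-axis affine distortion of the
generator input (`felt = clip01(0.5 + affect_gain*(g-0.5) +
affect_offset)`): individuals do not feel exactly what the generator
intends. Self-reports are 9-level SAM quantizations of felt emotion
plus Gaussian report noise (sd `label_noise` = 0.05).

Stimulus grids: nested training sets of 5,
9, 13 and 25 generator inputs on the {0, .25, .5, .75, 1}² lattice, 16
held-out test pieces on the interleaved {.125, .375, .625, .875}²
lattice, and 5 induction targets.

Population-prior defaults (`PopulationPrior`) are free parameters of
the simulator, documented not inferred: gain population scale 1.0,
individual gain sd 1.0, affect gain 1.0 ± 0.15, affect offset sd 0.15,
noise_scale 0.2, resting emotion fixed at neutral by default.

## Features (`affectloop.features`)

Per trial: the last 3 pre-listening seconds and the 20 listening
seconds are cut into 23 non-overlapping 1-s windows; each window is
band-passed (4th-order Butterworth, zero-phase forward–backward) into
the five bands; the feature is the natural log of the variance of each
filtered window per channel and band (14 channels x 5 bands = 70
dimensions); the 20 listening windows are baseline-corrected by
subtracting the mean of the 3 pre-listening windows; each 70-vector is
scattered into a 6 x 6 x 5 scalp-topographic tensor (unmapped cells
exactly zero). The 14-channel montage and grid layout are a stand-in
subset of a Quick-30 headset; supply a mapping file to match a
concrete montage.

## Networks (`affectloop.nets`)

* **Grid CNN**: three blocks of (2x2 convolution, 8 channels, stride 1
  → batch normalization → ReLU) followed by a fully connected layer to
  2 outputs. Implemented on a small numpy reverse-mode autodiff engine
  (`affectloop.autodiff`) that supports double backward, which the
  second-order meta-gradient needs.
* **Fusion MLP**: input = (clipped CNN-predicted valence/arousal,
  generator-input valence/arousal) → 8 hidden units with ReLU and
  dropout 0.2 (training only) → 2 outputs.
* **Fusion initialisation** (a choice of this package): all four
  inputs lie in [0, 1], so ReLU units can route them unchanged. Each
  input passes through two redundant hidden units, and the CNN
  prediction reaches the output with weight 1/2 from each copy, so the
  untrained fusion network *is* the CNN predictor and training can only
  blend in the generator inputs. The two-fold redundancy halves the
  variance dropout injects on the routing units; without it, dropout
  noise at learning rate 0.1 measurably degrades the trained network
  below its own initialisation.
* Training is plain SGD on the mean squared error over both outputs.
  With validation data, training stops when the validation loss has
  not decreased for five consecutive checks and the best-validation
  parameters are returned.

## Subject adaptation (`affectloop.metalearn`)

Three training regimes for a target participant's CNN:

* **A (meta-learned)**: MAML pre-training on 10 participants (support
  set = 20 pieces per task, query = the rest), inner learning rate
  α ∈ {0.1, 0.01} chosen by the validation meta-loss on 9 held-out
  participants, outer rate β = 0.1; then 13 full-batch fine-tuning
  steps (lr 0.1) on the target's training pieces.
* **B (pooled)**: all pre-training participants' windows pooled,
  batch size 1024, lr ∈ {0.1, 0.01} by validation; then 10 fine-tuning
  steps.
* **C (scratch)**: 25 fine-tuning steps from a fresh initialisation.

Two implementation decisions deserve explanation:

* **Outer update uses the mean of task gradients.** With 10 tasks, a
  summed gradient times β = 0.1 is an effective step of 1.0, which
  empirically stalls SGD on a mean-prediction plateau for tens of
  iterations; the mean-gradient form converges in ~10 iterations.
* **Meta-training starts from a 0.3-scaled copy of the standard CNN
  init.** Under batch normalization the network function is invariant
  to the scale of the convolution weights, but the effective SGD step
  on the weight direction scales as 1/‖W‖²; the unit-gain start sits on
  the same plateau. The scale is applied only inside MAML pre-training;
  methods B and C keep the standard initialisation, so the comparison
  is not biased toward A.

**Iteration counts.** CNN fine-tuning iterations (13/10/25, lr 0.1)
are full-batch gradient steps — the natural continuation of the MAML
inner step, which is full-batch on the support set. The fusion
network's 100 iterations (lr 0.1) are epochs of shuffled minibatch SGD
(batch 32), since 100 full-batch steps cannot train this network from
cold and the fusion stage is trained to convergence.

Evaluation: per-piece prediction is the mean of the 20 window-level
predictions; performance is per-axis RMSE against the SAM labels over
the 16 held-out test pieces.

## Controller (`affectloop.controller`)

A 20-measure piece is generated in five 4-measure blocks (s_max = 5).
The silent-state emotion pred(0) is decoded by the CNN alone from 1 s
of EEG at 5–6 s of silence (baseline from 2–5 s); during each block the
fusion network decodes the current emotion from 1 s of EEG plus the
current generator input. Three update policies:

* **A (iso principle)**: intermediate targets interpolate from pred(0)
  to the target, `mid(s+1) = pred(0) + s*(target-pred(0))/(s_max-1)`
  (computed in convex-combination form so both endpoints are exact in
  floating point), with correction
  `input(s+1) = mid(s+1) + 0.5*(mid(s) - pred(s))`.
* **B (direct feedback)**: `input(s+1) = input(s) + 0.5*(target - pred(s))`,
  starting at the target.
* **C (fixed)**: always the target.

Every emitted input is clipped to [0, 1]²; intermediate targets are
stored unclipped so the interpolation reaches the target exactly. The
session score is the Euclidean distance between the target and the
final prediction pred(5).

## Replications (`affectloop.harness`)

**Method comparison**: leave-one-subject-out on 20-participant cohorts over 10
master seeds, with the target participant rotating across seeds; per
target, 10 pre-training and 9 validation participants are drawn
disjointly from the rest. Methods A/B/C are fine-tuned on 5/9/13/25
pieces and scored on the 16 test pieces; the fusion network is trained
on top of the method-A CNN.

The comparison runs on a deliberately heterogeneous cohort prior
(`METHOD_COMPARISON_PRIOR`: affect_gain_sd 0.35, affect_offset_sd 0.25,
gain_individual_sd 1.5, noise_scale 0.5). The comparison
presupposes (a) real between-subject heterogeneity — otherwise pooled
pre-training is optimal and meta-learning cannot help — and (b) an EEG
SNR regime in which the CNN's error leaves room for generator inputs
to add information. The default prior satisfies neither; the
experiment prior is calibrated to that regime and documented here
rather than silently baked into the simulator defaults.

**Policy comparison**: one 20-participant cohort pre-trains a MAML
initialisation;
10 fresh target participants (resting emotions spread with sd 0.15, so
the silent-state prediction has signal to recover) are fine-tuned on
the 13-piece training set; each runs 3 policies x 5 targets x 10
session-noise replicates (1,500 sessions). Summaries report mean and
population SD; Friedman and pairwise Wilcoxon tests (Bonferroni
corrected) are available for ordering claims.

## Problem sizes and budgets

On one CPU core: building and featurizing one 20 x 41 cohort takes
~15 s; a MAML pre-training run ~40 s; the full 10-seed method
comparison ~10–13 minutes; the policy comparison ~5 minutes.
`scripts/acceptance.py` runs reduced-scale versions of both (4 master
seeds / 6 target participants by default) plus the fast structural
checks, within ~10 minutes, using a single inner/pooled learning-rate
candidate (0.1) and validation checks every second meta-iteration.

## Known limitations

* No realistic EEG artifacts (blinks, EMG) beyond Gaussian band noise.
* The montage/grid layout is a stand-in; real recordings need a
  mapping file.
* The replications target qualitative orderings on synthetic cohorts;
  absolute RMSE/distance values depend on the simulator's free
  parameters and carry no empirical meaning.
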