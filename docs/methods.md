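# Methods

## The model

The classifier couples a conventional convolutional feature extractor with a
spiking head built from leaky integrate-and-fire (LIF) neurons.

**Backbone.** Input slices are 128×128×3 arrays in [0, 1] (grey-scale
sources are replicated across channels).  Two stages of 3×3 convolution
(stride 1, same padding; 16 then 32 channels) with batch normalisation,
ReLU and 2×2 max pooling reduce the image to 32×32×32 maps; 50 % dropout
and a dense layer map the flattened maps to a 128-d feature vector.  Conv
widths and kernel sizes are free design choices kept small enough that the
dense projection stays tractable; all are configurable.

**Spiking head.** The 128-d feature vector is injected *identically at each
of T = 25 time steps* as the synaptic current of a 64-neuron LIF layer,
whose spikes drive a 3-neuron output LIF layer.  The discrete membrane
update is `V_{t+1} = α V_t + (1 − α) I_t` with α = 0.95 (the forward-Euler
discretisation of the leaky integrator with Δt = 1; the membrane time
constant and resistance are absorbed into α and the learned synaptic
scales).  A neuron whose candidate potential reaches the threshold
V_th = 1 emits a spike and is hard-reset to V_reset = 0; comparison is `≥`,
and the order update → threshold → reset is fixed.  Class scores are the
per-class mean spike counts over the window — each a multiple of 1/T in
[0, 1] — and softmax converts them to probabilities.  Inference is fully
deterministic: spiking here is threshold-driven, not stochastic.

**Surrogate gradients.** The spike step has zero derivative almost
everywhere, so the backward pass substitutes the fast-sigmoid derivative
`1/(1 + k|u − V_th|)²` while the forward pass keeps hard {0, 1} spikes.
The hard reset is excluded from the gradient (treated as constant), which
is standard practice for stability.  For verification the head also runs in
a *relaxed* mode in which the hard step is replaced by the fast sigmoid
`x/(1 + k|x|)` itself and the reset is differentiated through it; the same
backward-through-time code is then the exact gradient of that relaxed
recurrence, so finite differences of the relaxation validate the production
backward pass to 1e-4.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| α (membrane decay) | 0.95 | – | per-step charge retention |
| V_th / V_reset | 1.0 / 0.0 | potential | threshold and hard-reset level |
| T (time steps) | 25 | steps | rate-coding window; scores are multiples of 1/T |
| surrogate slope k | 5 | – | see "Numerical choices" |
| learning rate / weight decay | 1e-4 / 1e-5 | – | Adam with classic L2 on weights (not biases) |
| epochs / patience | 30 / 5 | epochs | early stopping on validation loss, strict improvement, best-weight restore |
| batch size | 32 | images | conventional default |
| dropout | 0.5 | – | after the second pooling stage |
| loss | cross-entropy | – | on softmaxed rate scores; an MSE-on-rates option (targets one-hot, per-sample per-class loss bounded in [0, 1]) is provided behind `loss_kind` |

The loss choice deserves a note: descriptions of this training protocol
name both categorical cross-entropy and MSE; both are implemented, with
cross-entropy the default.

## Numerical choices

**Head initialisation.** With the `(1 − α) I` input scaling, a constant
current must exceed `V_th / (1 − α^T) ≈ 1.38` to produce even one spike in
25 steps, and ≈ 10 to fire every other step.  Plain He initialisation gives
currents of s.d. ≈ 0.7: the network is born silent, and a silent network
passes essentially no surrogate gradient.  Conversely, boosting weights by
the full `1/(1 − α) = 20` parks membranes many thresholds away from V_th,
where the surrogate also vanishes.  The spiking layers therefore initialise
at He × 3.5·V_th, placing initial currents a few thresholds wide — roughly
half the hidden units active at varied rates, membranes inside the
surrogate's responsive band.  This was chosen by analysing the firing
regime and confirmed with a small design sweep before the evaluation suite
was fixed.

**Surrogate slope.** The slope k = 25 often quoted for fast-sigmoid
surrogates assumes formulations whose membranes hover near threshold.
Here the `(1 − α)` attenuation spreads membrane potentials over several
units, and at k = 25 the surrogate is effectively non-zero only within
|u − V_th| < 0.04 — gradients become so sparse that the model cannot leave
chance accuracy within the 30-epoch budget at learning rate 1e-4.  k = 5
widens the responsive band about five-fold and trains reliably; it remains
a configuration key.

**Augmentation as expansion.** Training augmentation (zoom 0.9–1.1,
brightness 0.8–1.2, horizontal flip p = 0.5 — ranges include the identity)
is applied on the fly, with each training image presented 4 times per epoch
under independent draws.  At the package's desk scale (120 training images)
this yields ~15 optimiser steps per epoch, comparable to what the protocol
implies at realistic dataset sizes.  Validation data are never augmented
or oversampled.

**SMOTE.** Class imbalance is corrected on the training split only:
each minority class is raised to the majority count with interpolants
`x + u(x_nn − x)`, u ~ U(0, 1), between a minority sample and one of its 5
nearest same-class neighbours in flattened-pixel space.  Synthetic samples
record their parents' identifiers, and a run-time audit refuses any fold in
which a validation sample appears in training — directly or as a SMOTE
parent.

**Other conventions.** Zero-denominator metrics report 0 with a per-class
degenerate flag, never NaN.  Multi-class precision/recall/F1 are
one-vs-rest with unweighted macro averaging.  Salt-and-pepper corruption
splits corrupted pixels 50/50 between black and white and is decided per
spatial pixel (applied across channels, preserving grey-scale inputs).
Gaussian blur truncates its kernel at 4σ with reflect boundaries; σ = 0 is
an exact identity for every operator.  Attention maps are gradient-weighted
class activations at the last conv stage's post-ReLU maps: the rectified,
channel-summed product of feature maps with the target-class score gradient
(an exact first-order attribution), bilinearly upsampled and min-max
normalised; an identically zero map is returned as zeros with a flag rather
than divided by zero.  The classic variant that pools gradients into
per-channel weights assumes a global-average-pooled head; this backbone
flattens into a dense layer, where per-location gradients are exact — in
side-by-side runs on the hippocampus-only phantoms the element-wise form
localised the discriminative blob consistently across seeds while the
pooled-weight form was marginal.  Batch norm uses running
statistics (momentum 0.1, ε = 1e-5) at evaluation.  Label encoding is
fixed: AD = 0, CI = 1 (MCI accepted as a directory alias), CN = 2.

## The synthetic phantoms

`synth_phantoms` draws a simple axial "head": an elliptical parenchyma
(intensity 0.55) with a bright outer cortical ring (0.8), a central dark
ventricular ellipse (0.08), and a bright mid-lateral hippocampal blob
(0.9), plus Gaussian pixel noise (s.d. 0.05 by default) clipped to [0, 1].
Class effects mirror the disease's structural signatures: the AD class has
the largest ventricles (radius 16 px vs 11.5 / 7), the thinnest cortex
(3.5 px vs 6 / 8.5) and the smallest hippocampal blob (3.5 px vs 5.5 /
7.5); every structure's size and position is jittered ±10 % per sample.
The default geometry keeps the three classes non-overlapping in central
intensity, so a one-feature threshold classifier already exceeds 80 % on
noiseless phantoms — by construction the end-to-end learning task is
winnable, which is exactly what the training tests require.

For attention-localisation checks a second phantom family ties ventricle
and cortex across classes so that *only* the hippocampal blob
discriminates; a model trained on it must attend to the blob region, and
the test asserts that mean heatmap mass inside the blob exceeds the mean
outside.

What the phantoms do **not** emulate: real anatomical variability, scanner
physics (bias fields, Rician noise), partial-volume effects, registration
error, or the subtlety of early-stage atrophy.  Passing tests on phantoms
demonstrates that the architecture, training loop and harness work as
specified — not that the model reaches any particular accuracy on clinical
MRI.

## Problem sizes

The standard training task uses 150 phantoms (50 per class) at 128×128
with a stratified 80/20 split; the attention task uses 120
hippocampus-only phantoms at 64×64.  These sizes keep a full train +
ablation + robustness cycle within minutes on a single CPU while leaving
the classes learnable; they are the package's reference desk scale, not a
statement about the sizes the method supports.

## Known limitations

* The LIF input scaling `(1 − α) I` couples the effective learning signal
  to α; changing α far from 0.95 may require revisiting the head
  initialisation gain.
* Early stopping monitors validation loss only; with the bounded rate
  scores, plateaus of identical loss are common early in training, and a
  run that has not yet started spiking can be stopped by patience — the
  defaults avoid this, but aggressive patience values will not.
* SMOTE interpolates raw pixels; its synthetic samples are blurry averages
  and are only meaningful while classes are pixel-space clusters, as they
  are for phantoms.
* No 3-D convolution, pretrained backbones, adaptive thresholds,
  refractory periods or spike-timing-dependent plasticity; grey-scale
  inputs are handled by channel replication.
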