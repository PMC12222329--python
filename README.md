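# hybridsnn

Hybrid CNN–SNN classifier for 2-D brain-MRI slices.

Structural MRI carries the anatomical signatures of Alzheimer's disease —
ventricular enlargement, cortical thinning, hippocampal atrophy — and the
three-way diagnostic task (AD / mild cognitive impairment / cognitively
normal) is a standard slice-classification benchmark.  This package
implements a hybrid architecture for that task: a convolutional backbone
extracts spatial features, and a spiking neural network head processes them
through biologically inspired leaky integrate-and-fire (LIF) dynamics over
discrete time, with classification read out from spike rates.  Everything —
network, surrogate-gradient training, evaluation harness — is implemented in
NumPy, so the package runs anywhere scientific Python runs.

Because clinical MRI cannot be redistributed, the package ships a synthetic
phantom generator producing three visually separable classes with the same
kind of structural effects (ventricle size, cortical ring thickness,
hippocampal blob radius), so the full pipeline is exercisable end to end.

## Model

The backbone applies two stages of `conv (3×3) → batch-norm → ReLU →
max-pool (2×2)` to a 128×128×3 input in [0, 1], then 50 % dropout and a
dense projection to a 128-d feature vector *x*.

The spiking head injects *x* as a constant synaptic current at each of
*T* = 25 time steps.  With membrane decay *α* = 0.95, threshold
*V*<sub>th</sub> = 1 and hard reset to *V*<sub>reset</sub> = 0:

    I¹ = W₁x + b₁                       (synaptic projection, 128 → 64)
    V¹ₜ₊₁ = α V¹ₜ + (1 − α) I¹           (membrane update)
    S¹ₜ = 1[V¹ₜ₊₁ ≥ V_th]                (binary spikes, then reset)
    I²ₜ = W₂S¹ₜ + b₂                     (second projection, 64 → 3)
    ...same dynamics for the output layer...
    score_c = (1/T) Σₜ S²ₜ,c             (rate readout, multiples of 1/T)
    P(y) = softmax(score)

The threshold step is not differentiable; training backpropagates through
time using the **fast-sigmoid surrogate** d/dx [x/(1+k|x|)] = 1/(1+k|x|)²,
with the reset path detached.  The optimiser is Adam (lr 1e-4, L2 weight
decay 1e-5) with categorical cross-entropy, at most 30 epochs and patience-5
early stopping on validation loss with best-weight restore.  An ablation
baseline (`model_kind="cnn_only"`) replaces the spiking head with a plain
128 → 64 → 3 projection, trained under identical conditions.

The evaluation harness provides one-vs-rest precision/recall/F1 with macro
averaging, ROC-AUC, a nine-cell noise-robustness grid (speckle σ ∈ {0.1,
0.2, 0.3}, salt-and-pepper p ∈ {0.05, 0.1, 0.15}, Gaussian blur σ ∈ {0.2,
0.4, 0.6}) and gradient-weighted class-activation attention maps from the
CNN branch.

## Worked example

```python
import numpy as np
from hybridsnn import (AugmentConfig, HybridSNNClassifier, PhantomParams,
                       stratified_kfold, synth_phantoms)

dataset = synth_phantoms(PhantomParams(seed=1), n_per_class=50)
train_idx, val_idx = stratified_kfold(dataset, k=5, seed=1).split(0)

clf = HybridSNNClassifier(random_state=1, augment=AugmentConfig())
clf.fit(dataset.images[train_idx], dataset.labels[train_idx],
        dataset.images[val_idx], dataset.labels[val_idx])

print("stopped at epoch", clf.history_.stopped_epoch)
print("held-out accuracy", clf.score(dataset.images[val_idx],
                                     dataset.labels[val_idx]))
```

Output from this exact run:

```
stopped at epoch 27
held-out accuracy 1.0
```

The learning curve behind it (`clf.history_.val_accuracy`) climbs from
chance (0.33) through 0.97 around epoch 4 and holds 1.0 from epoch 11;
training stops when validation loss no longer improves for 5 epochs.  The
estimator is scikit-learn compatible (`get_params`, `clone`,
`predict_proba`), `transform` exports the penultimate 128-d features for
external embedding tools, and `save` / `from_checkpoint` round-trip the full
model.

A command-line interface wraps the same library:

```bash
hybridsnn synth --n-per-class 50 --seed 1 --out data/phantoms
hybridsnn train --data data/phantoms --out runs/hybrid
hybridsnn cv --data data/phantoms --k 5 --seed 1
hybridsnn robustness --model runs/hybrid/model.npz --data data/phantoms
hybridsnn attend --model runs/hybrid/model.npz --image img.png --target AD
hybridsnn ablate --data data/phantoms --seed 1
```

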