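"""Hybrid CNN-SNN network: convolutional backbone + spiking LIF head.

The backbone applies two [conv → batch-norm → ReLU → max-pool] stages, 50%
dropout, and a fully connected projection to a 128-d feature vector.  The
spiking head injects that vector as a constant synaptic current into a 64-unit
LIF layer and, from its spikes, into a 3-unit output LIF layer, for T discrete
time steps.  Class scores are the per-class mean spike counts over the window
(rate coding); softmax turns them into probabilities.

Training backpropagates through the spike threshold with the fast-sigmoid
surrogate; the hard reset is treated as constant during the backward pass.
A fully differentiable "relaxed" mode (soft spikes, differentiated reset) is
provided for finite-difference verification of the backward pass.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ._layers import (
    Adam,
    BatchNorm2D,
    Conv2D,
    Dense,
    Dropout,
    Flatten,
    Layer,
    MaxPool2D,
    ReLU,
    he_normal,
    softmax,
)
from .lif import LIFParams, SpikeTrain, fast_sigmoid, surrogate_gradient

__all__ = [
    "HybridConfig",
    "SNNHead",
    "MLPHead",
    "HybridNet",
    "cnn_forward",
    "snn_head_forward",
    "hybrid_forward",
    "capture_attention_inputs",
]


@dataclass(frozen=True)
class HybridConfig:
    """Architecture hyper-parameters.

    Defaults reproduce the reference architecture: 128x128x3 input, two conv
    stages, 50% dropout, 128-d features, 64-d spiking hidden layer, 3 classes.
    Conv widths/kernel are free choices (16/32 channels, 3x3 kernels) kept
    small enough that the flattened map (32*32*32) feeds a tractable dense
    projection.
    """

    input_shape: tuple[int, int, int] = (128, 128, 3)
    conv_channels: tuple[int, int] = (16, 32)
    kernel_size: int = 3
    pool_size: int = 2
    dropout_rate: float = 0.5
    feature_dim: int = 128
    hidden_dim: int = 64
    n_classes: int = 3
    lif: LIFParams = field(default_factory=LIFParams)

    def __post_init__(self) -> None:
        h, w, c = self.input_shape
        p2 = self.pool_size**2
        if h % p2 or w % p2:
            raise ValueError(
                f"input {h}x{w} must survive two {self.pool_size}x"
                f"{self.pool_size} pooling stages"
            )
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")

    @property
    def flat_dim(self) -> int:
        h, w, _ = self.input_shape
        p2 = self.pool_size**2
        return (h // p2) * (w // p2) * self.conv_channels[1]

    def to_dict(self) -> dict:
        return {
            "input_shape": list(self.input_shape),
            "conv_channels": list(self.conv_channels),
            "kernel_size": self.kernel_size,
            "pool_size": self.pool_size,
            "dropout_rate": self.dropout_rate,
            "feature_dim": self.feature_dim,
            "hidden_dim": self.hidden_dim,
            "n_classes": self.n_classes,
            "lif": self.lif.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HybridConfig":
        d = dict(d)
        d["input_shape"] = tuple(d["input_shape"])
        d["conv_channels"] = tuple(d["conv_channels"])
        d["lif"] = LIFParams.from_dict(d["lif"])
        return cls(**d)


class SNNHead(Layer):
    """Two-layer LIF head driven by a constant per-step synaptic current.

    Forward (hard mode): at each step t,
    ``I1 = W1 x + b1`` → hidden LIF → spikes ``S1_t`` →
    ``I2 = W2 S1_t + b2`` → output LIF → spikes ``S2_t``;
    the class score is ``mean_t S2_t`` (a multiple of 1/T in [0, 1]).

    ``relaxed=True`` replaces the hard step with the fast sigmoid
    ``s(x) = x / (1 + k|x|)`` and differentiates the reset through it, making
    the whole recurrence smooth; the shared backward pass is then the exact
    gradient of this relaxation, which is what finite differences check.
    """

    def __init__(self, feature_dim: int, hidden_dim: int, n_classes: int,
                 lif: LIFParams, rng: np.random.Generator) -> None:
        super().__init__()
        self.lif = lif
        # The membrane resistance of the continuous model is absorbed into
        # the synaptic scale: with the (1 - alpha) input attenuation a neuron
        # needs |I| ~ v_th / (1 - alpha^T) just to fire once, so plain He
        # init leaves the network silent (no surrogate gradient to follow),
        # while very large currents park membranes far from threshold where
        # the surrogate vanishes.  A gain of 3.5 puts initial currents at a
        # few thresholds' spread — a responsive, trainable firing regime.
        gain = 3.5 * lif.v_th
        self.params = {
            "W1": gain * he_normal(rng, (hidden_dim, feature_dim), feature_dim),
            "b1": np.zeros(hidden_dim, dtype=np.float32),
            "W2": gain * he_normal(rng, (n_classes, hidden_dim), hidden_dim),
            "b2": np.zeros(n_classes, dtype=np.float32),
        }
        self.decay = {"W1": True, "b1": False, "W2": True, "b2": False}
        self.relaxed = False
        self._cache: dict | None = None

    def _spike(self, x: np.ndarray) -> np.ndarray:
        if self.relaxed:
            return fast_sigmoid(x, self.lif.surrogate_slope)
        return (x >= 0.0).astype(x.dtype)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        p = self.lif
        W1, b1 = self.params["W1"], self.params["b1"]
        W2, b2 = self.params["W2"], self.params["b2"]
        B = x.shape[0]
        I1 = x @ W1.T + b1  # constant over time
        v1 = np.zeros((B, W1.shape[0]), dtype=x.dtype)
        v2 = np.zeros((B, W2.shape[0]), dtype=x.dtype)
        u1s, s1s, u2s, s2s = [], [], [], []
        for _ in range(p.n_steps):
            u1 = p.alpha * v1 + (1.0 - p.alpha) * I1
            s1 = self._spike(u1 - p.v_th)
            v1 = u1 * (1.0 - s1) + p.v_reset * s1
            I2 = s1 @ W2.T + b2
            u2 = p.alpha * v2 + (1.0 - p.alpha) * I2
            s2 = self._spike(u2 - p.v_th)
            v2 = u2 * (1.0 - s2) + p.v_reset * s2
            u1s.append(u1)
            s1s.append(s1)
            u2s.append(u2)
            s2s.append(s2)
        self._cache = {
            "x": x,
            "u1": u1s, "s1": s1s, "u2": u2s, "s2": s2s,
        }
        return np.stack(s2s).mean(axis=0)

    def spike_trains(self) -> tuple[SpikeTrain, SpikeTrain]:
        """Hidden- and output-layer spike records of the last forward pass
        (single-sample batches only)."""
        c = self._cache
        if c is None:
            raise RuntimeError("forward must run before spike_trains")
        hidden = np.stack([s[0] for s in c["s1"]])
        out = np.stack([s[0] for s in c["s2"]])
        return SpikeTrain(spikes=hidden.round()), SpikeTrain(spikes=out.round())

    def backward(self, dout: np.ndarray) -> np.ndarray:
        """Backprop-through-time with the fast-sigmoid surrogate.

        In hard mode the reset is detached (gradient flows through the
        carry-over factor ``1 - s`` only); in relaxed mode the reset term is
        differentiated exactly.
        """
        p = self.lif
        c = self._cache
        x = c["x"]
        W1, W2 = self.params["W1"], self.params["W2"]
        T = p.n_steps
        drate = dout / T

        dW1 = np.zeros_like(W1)
        db1 = np.zeros_like(self.params["b1"])
        dW2 = np.zeros_like(W2)
        db2 = np.zeros_like(self.params["b2"])
        dI1 = np.zeros((x.shape[0], W1.shape[0]), dtype=x.dtype)
        dv1 = np.zeros_like(dI1)
        dv2 = np.zeros((x.shape[0], W2.shape[0]), dtype=x.dtype)

        for t in reversed(range(T)):
            u1, s1 = c["u1"][t], c["s1"][t]
            u2, s2 = c["u2"][t], c["s2"][t]
            sur2 = surrogate_gradient(u2 - p.v_th, p.surrogate_slope)
            ds2 = drate.copy()
            if self.relaxed:
                ds2 += dv2 * (p.v_reset - u2)
            du2 = ds2 * sur2 + dv2 * (1.0 - s2)
            dI2 = (1.0 - p.alpha) * du2
            dW2 += dI2.T @ s1
            db2 += dI2.sum(axis=0)
            ds1 = dI2 @ W2
            sur1 = surrogate_gradient(u1 - p.v_th, p.surrogate_slope)
            if self.relaxed:
                ds1 += dv1 * (p.v_reset - u1)
            du1 = ds1 * sur1 + dv1 * (1.0 - s1)
            dI1 += (1.0 - p.alpha) * du1
            dv1 = p.alpha * du1
            dv2 = p.alpha * du2

        self.grads["W1"] = dI1.T @ x
        self.grads["b1"] = dI1.sum(axis=0)
        self.grads["W2"] = dW2
        self.grads["b2"] = db2
        return dI1 @ W1

    @property
    def surrogate_slope(self) -> float:
        return self.lif.surrogate_slope


class MLPHead(Layer):
    """Non-spiking ablation head: direct 128 → 64 → 3 projection.

    Contains no temporal loop and holds no LIF parameters; scores are plain
    logits.
    """

    def __init__(self, feature_dim: int, hidden_dim: int, n_classes: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.fc_hidden = Dense(feature_dim, hidden_dim, rng)
        self.act = ReLU()
        self.fc_out = Dense(hidden_dim, n_classes, rng)
        self._sub = [self.fc_hidden, self.act, self.fc_out]

    @property
    def sublayers(self) -> list[Layer]:
        return self._sub

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        h = self.fc_hidden.forward(x, training)
        h = self.act.forward(h, training)
        return self.fc_out.forward(h, training)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.fc_out.backward(dout)
        d = self.act.backward(d)
        return self.fc_hidden.backward(d)


class HybridNet:
    """The assembled network.

    ``model_kind`` selects the spiking head (``"hybrid"``) or the non-spiking
    ablation head (``"cnn_only"``).  Images enter as (B, H, W, 3) arrays in
    [0, 1] and are transposed to NCHW internally.
    """

    def __init__(self, config: HybridConfig, rng: np.random.Generator,
                 model_kind: str = "hybrid") -> None:
        if model_kind not in ("hybrid", "cnn_only"):
            raise ValueError(f"unknown model_kind {model_kind!r}")
        self.config = config
        self.model_kind = model_kind
        c1, c2 = config.conv_channels
        _, _, in_ch = config.input_shape
        k = config.kernel_size
        self.conv1 = Conv2D(in_ch, c1, k, rng)
        self.conv1.skip_input_grad = True
        self.bn1 = BatchNorm2D(c1)
        self.relu1 = ReLU()
        self.pool1 = MaxPool2D(config.pool_size)
        self.conv2 = Conv2D(c1, c2, k, rng)
        self.bn2 = BatchNorm2D(c2)
        self.relu2 = ReLU()
        self.pool2 = MaxPool2D(config.pool_size)
        self.dropout = Dropout(config.dropout_rate, rng)
        self.flatten = Flatten()
        self.fc1 = Dense(config.flat_dim, config.feature_dim, rng)
        self.backbone: list[Layer] = [
            self.conv1, self.bn1, self.relu1, self.pool1,
            self.conv2, self.bn2, self.relu2, self.pool2,
            self.dropout, self.flatten, self.fc1,
        ]
        if model_kind == "hybrid":
            self.head: Layer = SNNHead(
                config.feature_dim, config.hidden_dim, config.n_classes,
                config.lif, rng,
            )
        else:
            self.head = MLPHead(
                config.feature_dim, config.hidden_dim, config.n_classes, rng
            )
        # attention plumbing
        self.capture = False
        self._attn_maps: np.ndarray | None = None
        self._attn_grads: np.ndarray | None = None

    # ---- parameter plumbing -------------------------------------------------

    @property
    def layers(self) -> list[Layer]:
        head = (
            self.head.sublayers if isinstance(self.head, MLPHead)
            else [self.head]
        )
        return self.backbone + head

    def parameters(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for key, val in layer.params.items():
                out[f"layer{i}.{key}"] = val
        out["bn1.running_mean"] = self.bn1.running_mean
        out["bn1.running_var"] = self.bn1.running_var
        out["bn2.running_mean"] = self.bn2.running_mean
        out["bn2.running_var"] = self.bn2.running_var
        return out

    def set_parameters(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for key in layer.params:
                layer.params[key][...] = state[f"layer{i}.{key}"]
        self.bn1.running_mean = state["bn1.running_mean"].copy()
        self.bn1.running_var = state["bn1.running_var"].copy()
        self.bn2.running_mean = state["bn2.running_mean"].copy()
        self.bn2.running_var = state["bn2.running_var"].copy()

    def state_copy(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.parameters().items()}

    # ---- forward / backward -------------------------------------------------

    def _to_nchw(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images, dtype=np.float32)
        h, w, ch = self.config.input_shape
        if images.ndim == 3:
            images = images[None]
        if images.shape[1:] != (h, w, ch):
            raise ValueError(
                f"expected images of shape (B,{h},{w},{ch}), got {images.shape}"
            )
        if images.min() < -1e-6 or images.max() > 1 + 1e-6:
            raise ValueError("image intensities must lie in [0, 1]")
        return images.transpose(0, 3, 1, 2)

    def features(self, images: np.ndarray, training: bool = False) -> np.ndarray:
        """CNN backbone output: one 128-d feature vector per image."""
        x = self._to_nchw(images)
        for layer in self.backbone:
            x = layer.forward(x, training)
            if self.capture and layer is self.relu2:
                self._attn_maps = x.copy()
        return x

    def scores(self, images: np.ndarray, training: bool = False) -> np.ndarray:
        """Head output per image: spike rates (hybrid) or logits (cnn_only)."""
        feats = self.features(images, training)
        return self.head.forward(feats, training)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Class probabilities via normalised exponential of the scores."""
        return softmax(self.scores(images, training=False))

    def backward(self, dscores: np.ndarray) -> None:
        """Populate all layer gradients from the score-level gradient."""
        d = self.head.backward(dscores)
        for layer in reversed(self.backbone):
            d = layer.backward(d)
            if self.capture and layer is self.pool2:
                self._attn_grads = d.copy()

    # ---- attention capture --------------------------------------------------

    def capture_attention(self, image: np.ndarray,
                          target_class: int) -> tuple[np.ndarray, np.ndarray]:
        """Forward+backward on one image; return (feature maps, gradients).

        Gradients are of the target-class score with respect to the last
        conv stage's post-ReLU feature maps.  Shapes: (C2, H/2, W/2).
        """
        if not 0 <= target_class < self.config.n_classes:
            raise ValueError(f"target_class must be in [0, {self.config.n_classes})")
        self.capture = True
        try:
            s = self.scores(image[None] if image.ndim == 3 else image,
                            training=False)
            onehot = np.zeros_like(s)
            onehot[:, target_class] = 1.0
            self.backward(onehot)
        finally:
            self.capture = False
        if self._attn_maps is None or self._attn_grads is None:
            raise RuntimeError("attention capture failed: no cached maps")
        return self._attn_maps[0], self._attn_grads[0]

    # ---- checkpointing ------------------------------------------------------

    def save(self, path: str, seed: int | None = None) -> None:
        """Archive the config, all weights and the training seed."""
        meta = {
            "config": self.config.to_dict(),
            "model_kind": self.model_kind,
            "seed": seed,
        }
        np.savez(path, __meta__=np.array(json.dumps(meta)),
                 **self.parameters())

    @classmethod
    def load(cls, path: str) -> tuple["HybridNet", int | None]:
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            state = {k: data[k] for k in data.files if k != "__meta__"}
        config = HybridConfig.from_dict(meta["config"])
        net = cls(config, np.random.default_rng(0), meta["model_kind"])
        net.set_parameters(state)
        return net, meta["seed"]


# ---- thin functional wrappers (module-level API) ----------------------------

def cnn_forward(images: np.ndarray, net: HybridNet,
                training_mode: bool = False) -> np.ndarray:
    """CNN backbone features for a batch of images."""
    return net.features(images, training=training_mode)


def snn_head_forward(
    features: np.ndarray, head: SNNHead
) -> tuple[np.ndarray, tuple[SpikeTrain, SpikeTrain] | None]:
    """Run the spiking head on pre-computed features.

    Returns the per-class spike rates and, for single-sample input, the
    hidden/output spike trains.
    """
    feats = np.atleast_2d(np.asarray(features, dtype=np.float32))
    rates = head.forward(feats, training=False)
    trains = head.spike_trains() if feats.shape[0] == 1 else None
    return rates, trains


def hybrid_forward(images: np.ndarray, net: HybridNet) -> np.ndarray:
    """End-to-end class probabilities for a batch of images."""
    return net.predict_proba(images)


def capture_attention_inputs(net: HybridNet, image: np.ndarray,
                             target_class: int) -> tuple[np.ndarray, np.ndarray]:
    """Feature maps and target-class gradients for attention mapping."""
    return net.capture_attention(image, target_class)
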