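"""Compact convolutional network for encrypted-spectrogram classification.

The classifier is built from the three layer operators of the method —
convolution (computed as cross-correlation, no kernel flipping), max
pooling, and elementwise activation — followed by a fully connected softmax
head. The default model is deliberately small (two conv/pool blocks and one
FC layer) so that it trains in minutes on a CPU; the five large pretrained
backbones (AlexNet, Darknet-19, GoogLeNet, ResNet-50, SqueezeNet) are an
optional transfer-learning hook because their trained weights are not a
desk-scale artifact.

Everything is plain numpy: forward passes use im2col-style sliding windows,
training is seeded minibatch SGD on the cross-entropy loss. An ensemble of
such models is combined by soft fusion — a weighted average of the members'
class probabilities with weights in [0, 1] (tuned by the swarm optimizer in
:mod:`eegcrypt.hso`), renormalized so they need not sum to one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .features import SpectrogramImage

__all__ = [
    "ConvLayerSpec",
    "CNNModel",
    "FusionParams",
    "BackboneWeightsUnavailable",
    "BACKBONE_INPUT_SIDES",
    "conv2d_forward",
    "max_pool",
    "activate",
    "forward",
    "train",
    "ensemble_fuse",
    "load_pretrained_backbone",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ConvLayerSpec:
    """Shape of one convolution layer (odd square kernels)."""

    kernel_size: int
    n_kernels: int
    stride: int = 1
    padding: str = "valid"  # "valid" | "same"

    def __post_init__(self) -> None:
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd and >= 1")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.n_kernels < 1:
            raise ValueError("n_kernels must be >= 1")
        if self.padding not in ("valid", "same"):
            raise ValueError("padding must be 'valid' or 'same'")


# ---------------------------------------------------------------------------
# Layer operators (public, oracle-checked)
# ---------------------------------------------------------------------------

def conv2d_forward(
    inputs: np.ndarray,
    layer: ConvLayerSpec,
    weights: np.ndarray,
    bias: np.ndarray | None = None,
) -> np.ndarray:
    """Cross-correlate a (C, H, W) stack with (K, C, k, k) kernels.

    Output feature map f_k(p, q) = sum_c sum_{x,y} i_c(x, y) e_k(x, y):
    the kernel is slid, not flipped.
    """
    x = np.asarray(inputs, dtype=np.float64)
    if x.ndim == 2:
        x = x[None]
    w = np.asarray(weights, dtype=np.float64)
    if x.ndim != 3 or w.ndim != 4:
        raise ValueError("expected (C,H,W) input and (K,C,k,k) weights")
    k = layer.kernel_size
    if w.shape[1] != x.shape[0] or w.shape[2:] != (k, k) or w.shape[0] != layer.n_kernels:
        raise ValueError(
            f"weights {w.shape} incompatible with input {x.shape} and spec {layer}"
        )
    if layer.padding == "same":
        p = (k - 1) // 2
        x = np.pad(x, ((0, 0), (p, p), (p, p)))
    if x.shape[1] < k or x.shape[2] < k:
        raise ValueError("kernel larger than (padded) input")
    win = sliding_window_view(x, (k, k), axis=(1, 2))  # (C, Ho, Wo, k, k)
    win = win[:, :: layer.stride, :: layer.stride]
    out = np.tensordot(w, win, axes=([1, 2, 3], [0, 3, 4]))  # (K, Ho, Wo)
    if bias is not None:
        out += np.asarray(bias, dtype=np.float64)[:, None, None]
    return out


def max_pool(inputs: np.ndarray, window: int, stride: int | None = None) -> np.ndarray:
    """Max pooling over ``window`` x ``window`` patches of a (C, H, W) stack."""
    x = np.asarray(inputs, dtype=np.float64)
    if x.ndim == 2:
        x = x[None]
    if x.ndim != 3:
        raise ValueError("expected a (C,H,W) stack")
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > x.shape[1] or window > x.shape[2]:
        raise ValueError("pooling window larger than the input")
    stride = stride or window
    win = sliding_window_view(x, (window, window), axis=(1, 2))
    win = win[:, ::stride, ::stride]
    return win.max(axis=(3, 4))


def activate(inputs: np.ndarray, kind: str = "relu") -> np.ndarray:
    """Elementwise activation: relu, sigmoid or tanh."""
    x = np.asarray(inputs, dtype=np.float64)
    if kind == "relu":
        return np.maximum(x, 0.0)
    if kind == "sigmoid":
        return 1.0 / (1.0 + np.exp(-x))
    if kind == "tanh":
        return np.tanh(x)
    raise ValueError(f"unknown activation {kind!r}")


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# Internal trainable layers (batched, with backprop)
# ---------------------------------------------------------------------------

class _Conv:
    """Same-padded stride-1 conv block used by the compact model."""

    def __init__(self, c_in: int, c_out: int, ksize: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * ksize * ksize))
        self.w = rng.normal(0.0, scale, (c_out, c_in, ksize, ksize))
        self.b = np.zeros(c_out)
        self.k = ksize

    def forward(self, x: np.ndarray) -> np.ndarray:  # x: (B,C,H,W)
        p = (self.k - 1) // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        self._win = win  # (B,C,H,W,k,k)
        self._in_shape = x.shape
        out = np.tensordot(win, self.w, axes=([1, 4, 5], [1, 2, 3]))
        return out.transpose(0, 3, 1, 2) + self.b[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, H, W = self._in_shape
        p = (self.k - 1) // 2
        self.gw = np.tensordot(dy, self._win, axes=([0, 2, 3], [0, 2, 3]))
        self.gb = dy.sum(axis=(0, 2, 3))
        dxp = np.zeros((B, C, H + 2 * p, W + 2 * p))
        for i in range(self.k):
            for j in range(self.k):
                contrib = np.tensordot(dy, self.w[:, :, i, j], axes=([1], [0]))
                dxp[:, :, i : i + H, j : j + W] += contrib.transpose(0, 3, 1, 2)
        return dxp[:, :, p : p + H, p : p + W]


class _ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class _MaxPool2:
    """2x2 stride-2 max pooling; odd trailing rows/columns are cropped."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        B, C, H, W = x.shape
        H2, W2 = H // 2, W // 2
        x = x[:, :, : H2 * 2, : W2 * 2]
        xr = x.reshape(B, C, H2, 2, W2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(B, C, H2, W2, 4)
        self._idx = xr.argmax(axis=-1)
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, H, W = self._in_shape
        H2, W2 = H // 2, W // 2
        flat = np.zeros((B, C, H2, W2, 4))
        np.put_along_axis(flat, self._idx[..., None], dy[..., None], axis=-1)
        x = flat.reshape(B, C, H2, W2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        out = np.zeros((B, C, H, W))
        out[:, :, : H2 * 2, : W2 * 2] = x.reshape(B, C, H2 * 2, W2 * 2)
        return out


class _Flatten:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out))
        self.b = np.zeros(n_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.gw = self._x.T @ dy
        self.gb = dy.sum(axis=0)
        return dy @ self.w.T


class CNNModel:
    """Compact CNN: [conv(same) -> relu -> maxpool(2)] blocks + FC softmax.

    Parameters
    ----------
    input_side : int
        Square input image side; must be divisible by 2**len(conv_channels).
    n_classes : int
        2 (normal vs seizure) or 3 (adds preictal).
    conv_channels : tuple of int
        Kernels per conv block.
    kernel_size : int
        Odd kernel side for all conv blocks.
    standardize : bool
        Standardize each input image to zero mean / unit variance (after
        the /255 scaling) in both training and inference; stabilizes SGD.
    seed : int
        Weight-initialization seed.
    """

    def __init__(
        self,
        input_side: int = 32,
        n_classes: int = 3,
        conv_channels: Sequence[int] = (8, 16),
        kernel_size: int = 3,
        standardize: bool = True,
        seed: int = 0,
    ):
        if n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if input_side < 2 ** len(conv_channels):
            raise ValueError("input_side too small for the pooling stages")
        self.standardize = standardize
        self.input_side = input_side
        self.n_classes = n_classes
        self.conv_channels = tuple(conv_channels)
        self.kernel_size = kernel_size
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.layers: list = []
        c_in, side = 1, input_side
        for c_out in conv_channels:
            self.layers += [_Conv(c_in, c_out, kernel_size, rng), _ReLU(), _MaxPool2()]
            c_in, side = c_out, side // 2
        if side < 1:
            raise ValueError("input_side too small for the pooling stages")
        self.layers.append(_Flatten())
        self.layers.append(_Dense(c_in * side * side, n_classes, rng))

    # -- inference ----------------------------------------------------------

    @staticmethod
    def _as_batch(images) -> np.ndarray:
        if isinstance(images, SpectrogramImage):
            images = [images]
        if isinstance(images, (list, tuple)):
            arr = np.stack(
                [im.pixels if isinstance(im, SpectrogramImage) else np.asarray(im) for im in images]
            )
        else:
            arr = np.asarray(images)
            if arr.ndim == 2:
                arr = arr[None]
        return arr.astype(np.float64) / 255.0

    def _prepare(self, images) -> np.ndarray:
        x = self._as_batch(images)
        if self.standardize:
            mu = x.mean(axis=(1, 2), keepdims=True)
            sd = x.std(axis=(1, 2), keepdims=True)
            x = (x - mu) / (sd + 1e-8)
        return x

    def _forward_batch(self, x: np.ndarray) -> np.ndarray:
        h = x[:, None, :, :]  # (B,1,H,W)
        for layer in self.layers:
            h = layer.forward(h)
        return h  # logits (B, n_classes)

    def predict_proba(self, images) -> np.ndarray:
        """Class probabilities, rows summing to 1."""
        x = self._prepare(images)
        if x.shape[1] != self.input_side or x.shape[2] != self.input_side:
            raise ValueError(
                f"images must be {self.input_side} x {self.input_side}, got {x.shape[1:]}"
            )
        return _softmax(self._forward_batch(x))

    def predict(self, images) -> np.ndarray:
        return self.predict_proba(images).argmax(axis=1)

    def get_weights(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            if hasattr(layer, "w"):
                out += [layer.w.copy(), layer.b.copy()]
        return out

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        it = iter(weights)
        for layer in self.layers:
            if hasattr(layer, "w"):
                layer.w = np.array(next(it))
                layer.b = np.array(next(it))


def forward(model: CNNModel, image) -> np.ndarray:
    """Class-probability vector for one image (sums to 1)."""
    return model.predict_proba(image)[0]


def train(
    model: CNNModel,
    images,
    labels,
    epochs: int = 20,
    batch_size: int = 32,
    lr: float = 0.005,
    momentum: float = 0.9,
    seed: int = 0,
) -> list[dict]:
    """Seeded minibatch SGD (with classical momentum) on cross-entropy.

    Trains in place; returns the per-epoch history
    [{"epoch", "loss", "accuracy"}, ...]. ``labels`` are integer class
    indices in [0, n_classes).
    """
    x = model._prepare(images)
    y = np.asarray(labels, dtype=np.intp)
    if x.shape[0] == 0:
        raise ValueError("empty training set")
    if x.shape[0] != y.shape[0]:
        raise ValueError("images and labels length mismatch")
    if np.unique(y).size < 2:
        raise ValueError("training set must contain at least 2 classes")
    if y.min() < 0 or y.max() >= model.n_classes:
        raise ValueError("label index out of range for the model's classes")
    rng = np.random.default_rng(seed)
    n = x.shape[0]
    trainable = [layer for layer in model.layers if hasattr(layer, "w")]
    velocity = {id(l): (np.zeros_like(l.w), np.zeros_like(l.b)) for l in trainable}
    history = []
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            xb, yb = x[idx], y[idx]
            logits = model._forward_batch(xb)
            probs = _softmax(logits)
            eps = 1e-12
            losses.append(-np.mean(np.log(probs[np.arange(len(yb)), yb] + eps)) * len(yb))
            correct += int((probs.argmax(axis=1) == yb).sum())
            dlogits = probs.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits /= len(yb)
            grad = dlogits
            for layer in reversed(model.layers):
                grad = layer.backward(grad)
            for layer in trainable:
                vw, vb = velocity[id(layer)]
                vw *= momentum
                vw += layer.gw
                vb *= momentum
                vb += layer.gb
                layer.w -= lr * vw
                layer.b -= lr * vb
        history.append(
            {"epoch": epoch, "loss": float(np.sum(losses) / n), "accuracy": correct / n}
        )
    return history


# ---------------------------------------------------------------------------
# Ensemble soft fusion
# ---------------------------------------------------------------------------

@dataclass
class FusionParams:
    """Ensemble fusion parameters: member weights in [0,1] + feature mask."""

    weights: np.ndarray
    selected_features: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.ndim != 1 or self.weights.size < 1:
            raise ValueError("weights must be a non-empty vector")
        if np.any(self.weights < 0) or np.any(self.weights > 1):
            raise ValueError("weights must lie in [0, 1]")
        if self.selected_features is not None:
            self.selected_features = np.asarray(self.selected_features, dtype=bool)
            if self.selected_features.size and not self.selected_features.any():
                raise ValueError("feature mask must select at least one feature")


def ensemble_fuse(member_probs: Sequence[np.ndarray], params: FusionParams) -> np.ndarray:
    """Weighted average of member probability vectors, renormalized to sum 1.

    Weights need not sum to one (they are divided by their total), matching
    the optimizer's [0, 1] box constraint.
    """
    probs = [np.asarray(p, dtype=np.float64) for p in member_probs]
    if len(probs) != params.weights.size:
        raise ValueError("one weight per ensemble member required")
    shapes = {p.shape for p in probs}
    if len(shapes) != 1:
        raise ValueError("all members must produce the same class count")
    total = params.weights.sum()
    if total <= 0:
        raise ValueError("at least one fusion weight must be positive")
    fused = sum(w * p for w, p in zip(params.weights, probs)) / total
    norm = fused.sum(axis=-1, keepdims=True)
    return fused / norm


# ---------------------------------------------------------------------------
# Optional transfer-learning hook
# ---------------------------------------------------------------------------

#: Native input sides of the supported pretrained backbones.
BACKBONE_INPUT_SIDES = {
    "alexnet": 227,
    "darknet19": 256,
    "googlenet": 224,
    "resnet50": 224,
    "squeezenet": 227,
}


class BackboneWeightsUnavailable(RuntimeError):
    """Raised when pretrained backbone weights are not available locally."""


def load_pretrained_backbone(
    name: str,
    n_classes: int = 2,
    weights_path: str | Path | None = None,
    strict: bool = False,
) -> CNNModel:
    """Transfer-learning hook for the five named backbones.

    Real zoo weights are never downloaded. If ``weights_path`` points to a
    checkpoint saved by :func:`save_model` it is loaded with its final
    layer replaced for ``n_classes``. Otherwise the hook falls back to a
    compact CNN configured with the backbone's native input side (or, with
    ``strict=True``, raises :class:`BackboneWeightsUnavailable`).
    """
    if name not in BACKBONE_INPUT_SIDES:
        raise ValueError(
            f"unknown backbone {name!r}; expected one of {sorted(BACKBONE_INPUT_SIDES)}"
        )
    side = BACKBONE_INPUT_SIDES[name]
    if weights_path is not None and Path(weights_path).exists():
        model = load_model(weights_path)
        # swap the classification head for the requested class count
        rng = np.random.default_rng(0)
        head = model.layers[-1]
        model.layers[-1] = _Dense(head.w.shape[0], n_classes, rng)
        model.n_classes = n_classes
        return model
    if strict:
        raise BackboneWeightsUnavailable(
            f"optional feature: pretrained weights for {name!r} are not available "
            "locally; the pipeline falls back to the compact CNN"
        )
    # fallback: untrained compact model at the backbone's native input side
    return CNNModel(input_side=side, n_classes=n_classes)


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_model(model: CNNModel, path: str | Path) -> Path:
    """Single-file checkpoint: npz archive with a JSON architecture header."""
    path = Path(path)
    arch = {
        "input_side": model.input_side,
        "n_classes": model.n_classes,
        "conv_channels": list(model.conv_channels),
        "kernel_size": model.kernel_size,
        "seed": model.seed,
    }
    arrays = {f"param_{i}": w for i, w in enumerate(model.get_weights())}
    np.savez(path, arch=np.frombuffer(json.dumps(arch).encode(), dtype=np.uint8), **arrays)
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_model(path: str | Path) -> CNNModel:
    with np.load(path) as data:
        arch = json.loads(bytes(data["arch"]).decode())
        n_params = len([k for k in data.files if k.startswith("param_")])
        weights = [data[f"param_{i}"] for i in range(n_params)]
    model = CNNModel(
        input_side=arch["input_side"],
        n_classes=arch["n_classes"],
        conv_channels=tuple(arch["conv_channels"]),
        kernel_size=arch["kernel_size"],
        seed=arch["seed"],
    )
    model.set_weights(weights)
    return model
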