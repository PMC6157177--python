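"""The coding network: a small CNN whose penultimate activations serve as
learned high-level features (HF).

Default architecture (input 140 x 140 x 3, valid convolutions, stride 1):

====================  ================  ==================
layer                 patch size/stride  output size
====================  ================  ==================
convolution           11 x 11 / 1       130 x 130 x 32
convolution           11 x 11 / 1       120 x 120 x 32
max pool              5 x 5 / 2         58 x 58 x 32
convolution           9 x 9 / 1         50 x 50 x 64
max pool              5 x 5 / 2         23 x 23 x 64
convolution           8 x 8 / 1         16 x 16 x 128
convolution           9 x 9 / 1         8 x 8 x 256
convolution           8 x 8 / 1         1 x 1 x 256
rasterize (flatten + fully connected)   n_classes
softmax                                 n_classes
====================  ================  ==================

Every convolution is followed by (optional) batch normalization and a ReLU.
The 5x5/2 pooling is *overlapping* (window larger than stride) with floor
output arithmetic, so 120 -> 58.  The 1x1x256 post-ReLU activation is the
high-level feature vector; "rasterize" flattens it and maps it linearly to
the class scores, and softmax turns scores into probabilities.

A ``width_factor`` scales all channel counts (spatial shapes unchanged);
``width_factor=0.25`` is the reduced-width profile used for fast CPU runs,
giving a 64-dim HF.

Training is plain mini-batch SGD with momentum on the softmax cross-entropy,
with the learning rate multiplied by a decay factor after every epoch.  All
randomness (weight init, batch shuffling, dropout) is seeded, so identical
seed + data reproduce identical weights on one device.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _layers as L
from .preprocess import PatchSet, group_by_source

__all__ = [
    "LayerSpec",
    "NetworkSpec",
    "TrainConfig",
    "default_network_spec",
    "shape_propagate",
    "build_network",
    "CodingNetwork",
    "predict_patch_averaged",
]

_BASE_CHANNELS = (32, 32, 64, 128, 256, 256)
_CONV_KERNELS = (11, 11, 9, 8, 9, 8)


@dataclass(frozen=True)
class LayerSpec:
    """One architectural layer: conv, maxpool, rasterize or softmax."""

    kind: str
    patch_size: int = 0
    stride: int = 1
    out_channels: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("conv", "maxpool", "rasterize", "softmax"):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kind in ("conv", "maxpool") and self.patch_size < 1:
            raise ValueError(f"{self.kind} needs patch_size >= 1")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


@dataclass(frozen=True)
class NetworkSpec:
    """Ordered layer specs plus input size, class count and batch-norm flag."""

    layers: tuple[LayerSpec, ...]
    input_size: tuple[int, int, int] = (140, 140, 3)
    n_classes: int = 4
    batch_norm: bool = True

    def to_json(self) -> str:
        return json.dumps(
            {
                "layers": [vars(l) for l in self.layers],
                "input_size": list(self.input_size),
                "n_classes": self.n_classes,
                "batch_norm": self.batch_norm,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "NetworkSpec":
        d = json.loads(s)
        return cls(
            layers=tuple(LayerSpec(**l) for l in d["layers"]),
            input_size=tuple(d["input_size"]),
            n_classes=d["n_classes"],
            batch_norm=d["batch_norm"],
        )


def default_network_spec(n_classes: int = 4, width_factor: float = 1.0,
                         batch_norm: bool = True) -> NetworkSpec:
    """The standard architecture, with channel counts scaled by width_factor."""
    chans = [max(1, int(round(c * width_factor))) for c in _BASE_CHANNELS]
    layers = [
        LayerSpec("conv", _CONV_KERNELS[0], 1, chans[0]),
        LayerSpec("conv", _CONV_KERNELS[1], 1, chans[1]),
        LayerSpec("maxpool", 5, 2),
        LayerSpec("conv", _CONV_KERNELS[2], 1, chans[2]),
        LayerSpec("maxpool", 5, 2),
        LayerSpec("conv", _CONV_KERNELS[3], 1, chans[3]),
        LayerSpec("conv", _CONV_KERNELS[4], 1, chans[4]),
        LayerSpec("conv", _CONV_KERNELS[5], 1, chans[5]),
        LayerSpec("rasterize"),
        LayerSpec("softmax"),
    ]
    return NetworkSpec(layers=tuple(layers), n_classes=n_classes, batch_norm=batch_norm)


def shape_propagate(spec: NetworkSpec) -> list[tuple[int, ...]]:
    """Pure output-shape arithmetic per layer; no weights involved.

    conv: out = in - patch + 1 (stride 1, no padding);
    pool: out = floor((in - patch) / stride) + 1.
    Raises on any nonpositive intermediate dimension, naming the layer.
    """
    h, w, c = spec.input_size
    shapes: list[tuple[int, ...]] = []
    for i, layer in enumerate(spec.layers):
        if layer.kind == "conv":
            h, w = h - layer.patch_size + 1, w - layer.patch_size + 1
            c = layer.out_channels
        elif layer.kind == "maxpool":
            h = (h - layer.patch_size) // layer.stride + 1
            w = (w - layer.patch_size) // layer.stride + 1
        elif layer.kind == "rasterize":
            shapes.append((spec.n_classes,))
            continue
        elif layer.kind == "softmax":
            shapes.append((spec.n_classes,))
            continue
        if h < 1 or w < 1:
            raise ValueError(
                f"layer {i} ({layer.kind} {layer.patch_size}x{layer.patch_size}) "
                f"yields nonpositive spatial size {h}x{w}"
            )
        shapes.append((h, w, c))
    return shapes


@dataclass(frozen=True)
class TrainConfig:
    """SGD schedule: epochs, batch size, initial lr, per-epoch decay, seed."""

    epochs: int = 45
    batch_size: int = 16
    lr: float = 0.01
    decay: float = 0.9
    momentum: float = 0.9
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")
        if self.lr <= 0:
            raise ValueError(f"learning rate must be positive, got {self.lr}")
        if not 0 < self.decay <= 1:
            raise ValueError(f"decay must be in (0, 1], got {self.decay}")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


class CodingNetwork:
    """A built (possibly trained) coding network.

    Use :func:`build_network` or the constructor directly; ``seed`` controls
    weight initialization.
    """

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        shapes = shape_propagate(spec)
        # the last conv must collapse to 1x1 so the feature is a flat vector
        conv_shapes = [s for s, l in zip(shapes, spec.layers) if l.kind == "conv"]
        if not conv_shapes or conv_shapes[-1][:2] != (1, 1):
            raise ValueError(
                f"final conv layer must have 1x1 spatial extent, got {conv_shapes[-1][:2] if conv_shapes else None}"
            )
        self.spec = spec
        self.seed = seed
        self.feature_dim = conv_shapes[-1][2]
        rng = np.random.default_rng(seed)
        self._blocks: list[list[L.Layer]] = []  # one block per LayerSpec
        c_in = spec.input_size[2]
        self._dropout: L.Dropout | None = None
        first_conv = True
        for layer in spec.layers:
            if layer.kind == "conv":
                conv = L.Conv(layer.patch_size, c_in, layer.out_channels, rng)
                conv.first_layer = first_conv
                first_conv = False
                block: list[L.Layer] = [conv]
                if spec.batch_norm:
                    block.append(L.BatchNorm(layer.out_channels))
                block.append(L.ReLU())
                c_in = layer.out_channels
                self._blocks.append(block)
            elif layer.kind == "maxpool":
                self._blocks.append([L.MaxPool(layer.patch_size, layer.stride)])
            elif layer.kind == "rasterize":
                block = [L.Flatten()]
                self._dropout = L.Dropout(0.0, np.random.default_rng(rng.integers(2**31)))
                block.append(self._dropout)
                block.append(L.Dense(self.feature_dim, spec.n_classes, rng))
                self._blocks.append(block)
            else:  # softmax: applied in loss / predict, identity block here
                self._blocks.append([])
        self._layers = [l for block in self._blocks for l in block]
        self.history: list[dict] = []

    # -- forward passes ----------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a (batch, h, w, 3) float array of centered patches."""
        out = np.asarray(x, dtype=np.float32)
        for layer in self._layers:
            out = layer.forward(out, train)
        return out

    def forward_shapes(self, x: np.ndarray) -> list[tuple[int, ...]]:
        """Actual per-LayerSpec output shapes of an executed forward pass
        (batch axis stripped), for comparison with :func:`shape_propagate`."""
        out = np.asarray(x, dtype=np.float32)
        shapes: list[tuple[int, ...]] = []
        for spec_layer, block in zip(self.spec.layers, self._blocks):
            for layer in block:
                out = layer.forward(out, train=False)
            if spec_layer.kind == "softmax":
                out = L.softmax(out)
            shapes.append(tuple(out.shape[1:]))
        return shapes

    def predict_proba(self, patches: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Softmax probabilities per patch."""
        probs = []
        for i in range(0, len(patches), batch_size):
            probs.append(L.softmax(self.forward(patches[i : i + batch_size])))
        return np.concatenate(probs, axis=0)

    def features(self, patches: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Penultimate (post-ReLU, flattened final-conv) activations per patch."""
        rasterize_idx = [i for i, l in enumerate(self.spec.layers) if l.kind == "rasterize"][0]
        feats = []
        for i in range(0, len(patches), batch_size):
            out = np.asarray(patches[i : i + batch_size], dtype=np.float32)
            for block in self._blocks[:rasterize_idx]:
                for layer in block:
                    out = layer.forward(out, train=False)
            feats.append(out.reshape(out.shape[0], -1))
        return np.concatenate(feats, axis=0)

    def extract_high_level(self, patches_of_one_image: np.ndarray) -> np.ndarray:
        """HF for one source image: patch features averaged over its patches."""
        patches = np.asarray(patches_of_one_image)
        if patches.ndim == 3:
            patches = patches[None]
        if len(patches) == 0:
            raise ValueError("need at least one patch to extract a high-level feature")
        return self.features(patches).mean(axis=0)

    # -- training ----------------------------------------------------------

    def train(self, train_patches: PatchSet, val_patches: PatchSet | None,
              cfg: TrainConfig) -> list[dict]:
        """Mini-batch SGD on softmax cross-entropy; returns per-epoch history.

        ``history`` rows carry epoch, lr, train_loss, train_acc and (if a
        validation patch set is given) patch-averaged val_acc.
        """
        k = self.spec.n_classes
        labels = np.asarray(train_patches.labels)
        bad = labels[(labels < 1) | (labels > k)]
        if bad.size:
            raise ValueError(f"labels must lie in [1, {k}]; found {sorted(set(bad.tolist()))}")
        if self._dropout is not None:
            self._dropout.rate = cfg.dropout
        y = labels - 1
        x = np.asarray(train_patches.patches, dtype=np.float32)
        rng = np.random.default_rng(cfg.seed)
        n = len(x)
        lr = cfg.lr
        self.history = []
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            losses = []
            correct = 0
            for i in range(0, n, cfg.batch_size):
                idx = order[i : i + cfg.batch_size]
                logits = self.forward(x[idx], train=True)
                loss, dlogits = L.softmax_cross_entropy(logits, y[idx])
                losses.append(loss)
                correct += int(np.sum(logits.argmax(axis=1) == y[idx]))
                grad = dlogits
                for layer in reversed(self._layers):
                    grad = layer.backward(grad)
                L.sgd_momentum_step(self._layers, lr, cfg.momentum)
            row = {
                "epoch": epoch + 1,
                "lr": lr,
                "train_loss": float(np.mean(losses)),
                "train_acc": correct / n,
            }
            if val_patches is not None and len(val_patches):
                _, _, pred, true = predict_patch_averaged(self, val_patches, return_true=True)
                row["val_acc"] = float(np.mean(pred == true))
            self.history.append(row)
            lr *= cfg.decay
        return self.history

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        arrays = {}
        for i, layer in enumerate(self._layers):
            for j, p in enumerate(layer.params()):
                arrays[f"p_{i}_{j}"] = p["value"]
            if isinstance(layer, L.BatchNorm):
                arrays[f"rm_{i}"] = layer.running_mean
                arrays[f"rv_{i}"] = layer.running_var
        np.savez(path, manifest=np.bytes_(self.spec.to_json().encode()),
                 seed=np.int64(self.seed), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "CodingNetwork":
        with np.load(path) as data:
            spec = NetworkSpec.from_json(bytes(data["manifest"]).decode())
            net = cls(spec, seed=int(data["seed"]))
            for i, layer in enumerate(net._layers):
                for j, p in enumerate(layer.params()):
                    p["value"][...] = data[f"p_{i}_{j}"]
                if isinstance(layer, L.BatchNorm):
                    layer.running_mean[...] = data[f"rm_{i}"]
                    layer.running_var[...] = data[f"rv_{i}"]
        return net


def build_network(spec: NetworkSpec, seed: int = 0) -> CodingNetwork:
    """Build an initialized coding network from an architecture spec."""
    return CodingNetwork(spec, seed=seed)


def predict_patch_averaged(
    net: CodingNetwork, ps: PatchSet, return_true: bool = False
):
    """Per-source-image probabilities: mean of the image's patch softmaxes.

    Returns ``(source_ids, probs, labels)`` — predicted labels are 1-based
    argmaxes with ties broken toward the smaller label.  With
    ``return_true=True`` also returns the true label per source image.
    """
    groups = group_by_source(ps)
    patch_probs = net.predict_proba(ps.patches)
    ids = list(groups.keys())
    probs = np.stack([patch_probs[groups[sid]].mean(axis=0) for sid in ids])
    pred = probs.argmax(axis=1) + 1  # argmax takes the first max: smaller label wins ties
    if return_true:
        true = np.array([ps.labels[groups[sid][0]] for sid in ids])
        return ids, probs, pred, true
    return ids, probs, pred
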