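"""Fusing traditional features (LF) with coding-network features (HF).

Two strategies:

* **R feature fusion** — a fixed proportion lambda in [0, 1] weights the two
  standardized blocks, ``NF = (lambda * LF, (1 - lambda) * HF)``, and a
  softmax (multinomial logistic) head classifies NF.  Because LF (17) and HF
  (256 by default) have different lengths, the weighting is applied to the
  concatenated blocks rather than an elementwise sum.  lambda is chosen by a
  grid search on validation accuracy.

* **MLP fusion** — a one-hidden-layer perceptron
  ``RF = relu(W [LF; HF] + b)`` followed by a fully connected layer and
  softmax, trained end to end by cross-entropy.  The hidden layer learns the
  proportions between the feature groups instead of requiring a manual
  lambda, and the nonlinearity lets it exploit interactions that no single
  linear weighting can express.

Both expect LF and HF to be standardized (zero location, unit scale, fit on
training data): raw GLCM/moment magnitudes and ReLU activations differ by
orders of magnitude, and a fixed lambda would otherwise be meaningless.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression

from . import _layers as L

__all__ = [
    "r_fuse",
    "RFusionModel",
    "train_r_fusion",
    "MLPFusionModel",
    "mlp_fuse_train",
    "softmax_head",
    "xor_feature_task",
    "DEFAULT_LAMBDA_GRID",
]

DEFAULT_LAMBDA_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.0, 1.01, 0.1), 2))


def r_fuse(lf: np.ndarray, hf: np.ndarray, lam: float) -> np.ndarray:
    """Weighted concatenation ``(lam * LF, (1 - lam) * HF)``.

    Accepts single vectors or (n, d) matrices; the blocks keep their own
    lengths, so no feature is discarded.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    single = np.asarray(lf).ndim == 1
    lf = np.atleast_2d(np.asarray(lf, dtype=np.float64))
    hf = np.atleast_2d(np.asarray(hf, dtype=np.float64))
    if len(lf) != len(hf):
        raise ValueError(f"LF and HF sample counts differ: {len(lf)} vs {len(hf)}")
    fused = np.hstack([lam * lf, (1.0 - lam) * hf])
    return fused[0] if single else fused


def softmax_head(features: np.ndarray, labels: np.ndarray, seed: int = 0) -> LogisticRegression:
    """Multinomial logistic (= softmax) classifier over a feature matrix.

    Lightly regularized (C=10) so near-separable small samples still converge.
    """
    clf = LogisticRegression(C=10.0, max_iter=2000, random_state=seed)
    clf.fit(np.asarray(features, dtype=np.float64), np.asarray(labels))
    return clf


@dataclass
class RFusionModel:
    """Fixed-lambda fusion plus its fitted softmax head."""

    lam: float
    head: LogisticRegression
    grid_scores: dict[float, float] = field(default_factory=dict)

    def predict_proba(self, lf: np.ndarray, hf: np.ndarray) -> np.ndarray:
        fused = np.atleast_2d(r_fuse(lf, hf, self.lam))
        return self.head.predict_proba(fused)

    def predict(self, lf: np.ndarray, hf: np.ndarray) -> np.ndarray:
        probs = self.predict_proba(lf, hf)
        return self.head.classes_[_argmax_small_label(probs)]


def _argmax_small_label(probs: np.ndarray) -> np.ndarray:
    # np.argmax returns the first maximum, i.e. the smaller class index
    return probs.argmax(axis=1)


def train_r_fusion(
    lf_train: np.ndarray, hf_train: np.ndarray, y_train: np.ndarray,
    lf_val: np.ndarray, hf_val: np.ndarray, y_val: np.ndarray,
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID,
    seed: int = 0,
) -> RFusionModel:
    """Grid-search lambda on validation accuracy; ties go to the smaller lambda.

    One softmax head is fitted per grid point on the training features; the
    returned model carries the winning lambda, its head refitted on train,
    and the full grid of validation scores.
    """
    if len(lambda_grid) == 0:
        raise ValueError("lambda grid must be non-empty")
    for lam in lambda_grid:
        if not 0.0 <= lam <= 1.0:
            raise ValueError(f"lambda grid values must lie in [0, 1], got {lam}")
    scores: dict[float, float] = {}
    best_lam, best_score, best_head = None, -1.0, None
    for lam in sorted(lambda_grid):
        head = softmax_head(r_fuse(lf_train, hf_train, lam), y_train, seed=seed)
        acc = float(np.mean(head.predict(np.atleast_2d(r_fuse(lf_val, hf_val, lam))) == y_val))
        scores[lam] = acc
        if acc > best_score:  # strict: first (smallest) lambda wins ties
            best_lam, best_score, best_head = lam, acc, head
    return RFusionModel(lam=best_lam, head=best_head, grid_scores=scores)


class MLPFusionModel:
    """One-hidden-layer ReLU perceptron over the concatenated [LF; HF].

    The hidden activations are the fused representation RF; a dense layer
    plus softmax classifies it.  Trained by mini-batch SGD with momentum and
    per-epoch learning-rate decay, matching the coding network's schedule.
    """

    def __init__(self, n_lf: int, n_hf: int, hidden_width: int = 64,
                 n_classes: int = 2, seed: int = 0):
        if hidden_width < 1:
            raise ValueError(f"hidden_width must be >= 1, got {hidden_width}")
        self.n_lf, self.n_hf = n_lf, n_hf
        self.n_classes = n_classes
        self.hidden_width = hidden_width
        self.seed = seed
        rng = np.random.default_rng(seed)
        self._hidden = L.Dense(n_lf + n_hf, hidden_width, rng)
        self._relu = L.ReLU()
        self._out = L.Dense(hidden_width, n_classes, rng)
        self._layers = [self._hidden, self._relu, self._out]
        self.history: list[dict] = []

    def _check(self, lf: np.ndarray, hf: np.ndarray) -> np.ndarray:
        lf = np.atleast_2d(np.asarray(lf, dtype=np.float32))
        hf = np.atleast_2d(np.asarray(hf, dtype=np.float32))
        if lf.shape[1] != self.n_lf or hf.shape[1] != self.n_hf:
            raise ValueError(
                f"feature lengths ({lf.shape[1]}, {hf.shape[1]}) do not match "
                f"model ({self.n_lf}, {self.n_hf})"
            )
        return np.hstack([lf, hf])

    def fused_representation(self, lf: np.ndarray, hf: np.ndarray) -> np.ndarray:
        """RF = relu(W [LF; HF] + b), the learned fused feature."""
        x = self._check(lf, hf)
        return np.maximum(x @ self._hidden.W + self._hidden.b, 0.0)

    def predict_proba(self, lf: np.ndarray, hf: np.ndarray) -> np.ndarray:
        x = self._check(lf, hf)
        for layer in self._layers:
            x = layer.forward(x, train=False)
        return L.softmax(x)

    def predict(self, lf: np.ndarray, hf: np.ndarray) -> np.ndarray:
        return self.predict_proba(lf, hf).argmax(axis=1) + 1

    def fit(self, lf: np.ndarray, hf: np.ndarray, y: np.ndarray,
            epochs: int = 200, batch_size: int = 32, lr: float = 0.05,
            decay: float = 0.98, momentum: float = 0.9) -> "MLPFusionModel":
        x = self._check(lf, hf)
        y = np.asarray(y)
        bad = y[(y < 1) | (y > self.n_classes)]
        if bad.size:
            raise ValueError(f"labels must lie in [1, {self.n_classes}]")
        y_idx = y - 1
        rng = np.random.default_rng(self.seed + 1)
        self.history = []
        for epoch in range(epochs):
            order = rng.permutation(len(x))
            losses = []
            for i in range(0, len(x), batch_size):
                idx = order[i : i + batch_size]
                out = x[idx]
                for layer in self._layers:
                    out = layer.forward(out, train=True)
                loss, grad = L.softmax_cross_entropy(out, y_idx[idx])
                losses.append(loss)
                for layer in reversed(self._layers):
                    grad = layer.backward(grad)
                L.sgd_momentum_step(self._layers, lr, momentum)
            self.history.append({"epoch": epoch + 1, "lr": lr,
                                 "train_loss": float(np.mean(losses))})
            lr *= decay
        return self


def xor_feature_task(
    n: int = 400, noise: float = 0.15, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """A 2-class feature-level task where fusion *must* be nonlinear.

    The informative coordinate of LF carries a sign u = +-1, that of HF a
    sign v = +-1, and the label is the XOR of the signs (1 if u v > 0 else
    2); the second coordinate of each block is pure noise.  Neither block
    alone carries any label information, and no linear head on the
    concatenation can exceed 75% accuracy in expectation, while a small
    ReLU hidden layer separates the classes essentially perfectly.

    Returns (lf (n, 2), hf (n, 2), labels (n,)).
    """
    rng = np.random.default_rng(seed)
    u = rng.choice([-1.0, 1.0], size=n)
    v = rng.choice([-1.0, 1.0], size=n)
    lf = np.column_stack([u + noise * rng.standard_normal(n), rng.standard_normal(n)])
    hf = np.column_stack([v + noise * rng.standard_normal(n), rng.standard_normal(n)])
    y = np.where(u * v > 0, 1, 2)
    return lf, hf, y


def mlp_fuse_train(
    lf_train: np.ndarray, hf_train: np.ndarray, y_train: np.ndarray,
    hidden_width: int = 64, n_classes: int | None = None, seed: int = 0,
    epochs: int = 200, lr: float = 0.05, decay: float = 0.98,
    batch_size: int = 32,
) -> MLPFusionModel:
    """Train the MLP fusion head on standardized LF/HF matrices."""
    lf_train = np.atleast_2d(np.asarray(lf_train))
    hf_train = np.atleast_2d(np.asarray(hf_train))
    if len(lf_train) != len(hf_train) or len(lf_train) != len(y_train):
        raise ValueError("LF, HF and labels must have equal sample counts")
    if n_classes is None:
        n_classes = int(np.max(y_train))
    model = MLPFusionModel(lf_train.shape[1], hf_train.shape[1],
                           hidden_width=hidden_width, n_classes=n_classes, seed=seed)
    return model.fit(lf_train, hf_train, y_train, epochs=epochs, lr=lr,
                     decay=decay, batch_size=batch_size)
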