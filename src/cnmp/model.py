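"""CNMP as a fit-once modelling object.

:class:`CNMPModel` is built from a :class:`~cnmp.datasets.LabeledImageSet`
plus the pipeline configuration; :meth:`CNMPModel.fit` runs the whole
method — stratified 7:1:2 split, mean-RGB centering, patch augmentation,
coding-network training, traditional-feature extraction, both fusion heads —
and returns a :class:`CNMPResults` carrying test-set accuracies for the four
classifiers (traditional-only softmax, coding network alone, fixed-lambda
R fusion, MLP fusion), the annotated confusion matrix, ROC/AUC for binary
tasks, training history and the selected lambda.  ``results.summary()``
prints a readable report.

Example
-------
>>> from cnmp.datasets import tiny_spec, generate_dataset
>>> from cnmp.model import CNMPModel
>>> ds = generate_dataset(tiny_spec(seed=0))
>>> res = CNMPModel(ds, width_factor=0.25, epochs=5).fit(seed=0)
>>> print(res.summary())                                   # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .datasets import LabeledImageSet, split_dataset
from .evaluate import ConfusionMatrix, auc, confusion_matrix, roc_curve
from .features import Standardizer, extract_for_patchset, fit_standardizer
from .fusion import (DEFAULT_LAMBDA_GRID, MLPFusionModel, RFusionModel,
                     mlp_fuse_train, softmax_head, train_r_fusion)
from .network import (CodingNetwork, NetworkSpec, TrainConfig,
                      default_network_spec, predict_patch_averaged)
from .preprocess import (AugmentationConfig, FractionalCrop, PatchSet,
                         augment, group_by_source, subtract_mean_rgb)

__all__ = ["CNMPModel", "CNMPResults", "CLASSIFIERS"]

CLASSIFIERS = ("traditional", "coding_network", "r_fusion", "mlp_fusion")


def _per_image_hf(net: CodingNetwork, ps: PatchSet) -> tuple[list[str], np.ndarray]:
    """Patch-averaged high-level features per source image (ids sorted)."""
    groups = group_by_source(ps)
    feats = net.features(ps.patches)
    ids = list(groups.keys())
    return ids, np.stack([feats[groups[sid]].mean(axis=0) for sid in ids])


def _center(ps: PatchSet, mean_rgb: np.ndarray) -> PatchSet:
    """Subtract the training mean RGB from every patch.

    Channel-mean subtraction commutes with cropping, bilinear resizing and
    flips, so centering the patches equals centering the source images.
    """
    return PatchSet(
        patches=ps.patches - mean_rgb.astype(np.float32),
        source_ids=list(ps.source_ids),
        labels=ps.labels.copy(),
    )


@dataclass
class CNMPResults:
    """Fit results: per-classifier test metrics plus fitted components."""

    accuracies: dict[str, float]
    val_accuracies: dict[str, float]
    confusion: dict[str, ConfusionMatrix]
    aucs: dict[str, float]
    selected_lambda: float
    history: list[dict]
    n_train: int
    n_val: int
    n_test: int
    n_classes: int
    network: CodingNetwork = field(repr=False)
    r_fusion: RFusionModel = field(repr=False)
    mlp_fusion: MLPFusionModel = field(repr=False)
    mean_rgb: np.ndarray = field(repr=False, default=None)
    lf_standardizer: Standardizer = field(repr=False, default=None)
    hf_standardizer: Standardizer = field(repr=False, default=None)
    test_ids: list[str] = field(repr=False, default_factory=list)
    test_labels: np.ndarray = field(repr=False, default=None)
    test_probs: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    def summary(self) -> str:
        lines = [
            "CNMP classification results",
            "=" * 47,
            f"classes: {self.n_classes}   images: train {self.n_train} / "
            f"val {self.n_val} / test {self.n_test}",
            f"high-level feature dim: {self.network.feature_dim}   "
            f"selected lambda (R fusion): {self.selected_lambda:.2f}",
            "-" * 47,
            f"{'classifier':<24}{'val acc':>10}{'test acc':>12}",
        ]
        for name in CLASSIFIERS:
            lines.append(
                f"{name:<24}{self.val_accuracies[name]:>10.3f}{self.accuracies[name]:>12.3f}"
            )
        if self.aucs:
            lines.append("-" * 47)
            for name in CLASSIFIERS:
                lines.append(f"{name:<24}  AUC = {self.aucs[name]:.4f}")
        lines.append("=" * 47)
        return "\n".join(lines)


class CNMPModel:
    """The full pipeline as a model object.

    Parameters
    ----------
    dataset
        Labeled RGB images (the full dataset; splitting happens inside fit).
    augmentation
        Patch policy; defaults to m=2 fractional (2/3) crops resized to
        140 x 140 with both flips enabled.
    network_spec
        Coding-network architecture; defaults to the standard stack scaled by
        ``width_factor``.
    train_config
        SGD schedule for the coding network; defaults use ``epochs``/``lr``
        shortcuts below.
    width_factor, epochs, lr
        Convenience shortcuts when spec/config objects are not given.
    gray_levels
        Quantization levels for GLCM texture features (default 16).
    hidden_width, mlp_epochs
        MLP fusion head size and training length.
    lambda_grid
        Grid searched for the R-fusion weight.
    ratios
        Train/val/test split ratios (default 7:1:2).
    """

    def __init__(
        self,
        dataset: LabeledImageSet,
        augmentation: AugmentationConfig | None = None,
        network_spec: NetworkSpec | None = None,
        train_config: TrainConfig | None = None,
        width_factor: float = 1.0,
        epochs: int = 45,
        lr: float = 0.01,
        batch_norm: bool = True,
        gray_levels: int = 16,
        hidden_width: int = 64,
        mlp_epochs: int = 200,
        lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
        ratios: tuple[float, float, float] = (0.7, 0.1, 0.2),
    ):
        self.dataset = dataset
        self.classes = np.unique(dataset.labels)
        self.n_classes = int(self.classes.max())
        self.augmentation = augmentation or AugmentationConfig(
            m=2, crop_policy=FractionalCrop(), target_size=140
        )
        self.network_spec = network_spec or default_network_spec(
            n_classes=self.n_classes, width_factor=width_factor, batch_norm=batch_norm
        )
        self.train_config = train_config or TrainConfig(epochs=epochs, lr=lr)
        self.gray_levels = gray_levels
        self.hidden_width = hidden_width
        self.mlp_epochs = mlp_epochs
        self.lambda_grid = tuple(lambda_grid)
        self.ratios = ratios

    # -- pipeline ----------------------------------------------------------

    def fit(self, seed: int = 0) -> CNMPResults:
        train, val, test = split_dataset(self.dataset, self.ratios, seed)
        return self.fit_presplit(train, val, test, seed=seed)

    def fit_presplit(self, train: LabeledImageSet, val: LabeledImageSet,
                     test: LabeledImageSet, seed: int = 0) -> CNMPResults:
        """Run the pipeline on an externally provided split (used by CV)."""
        rng = np.random.default_rng(seed)
        aug_seeds = rng.integers(2**31, size=3)

        # raw patches per split (LF is computed on the raw intensity scale)
        ps = {
            name: augment(split, replace(self.augmentation, seed=int(s)))
            for (name, split), s in zip(
                (("train", train), ("val", val), ("test", test)), aug_seeds
            )
        }

        # traditional features per source image, standardized on train
        lf, y = {}, {}
        ids = {}
        for name in ("train", "val", "test"):
            ids[name], lf[name], y[name] = extract_for_patchset(ps[name], self.gray_levels)
        lf_std = fit_standardizer(lf["train"])
        lf_z = {name: lf_std.transform(lf[name]) for name in lf}

        # coding network on mean-centered patches
        _, mean_rgb = subtract_mean_rgb(train)
        centered = {name: _center(ps[name], mean_rgb) for name in ps}
        net = CodingNetwork(self.network_spec, seed=seed)
        train_cfg = replace(self.train_config, seed=seed)
        net.train(centered["train"], centered["val"], train_cfg)

        # high-level features per source image, standardized on train
        hf = {}
        for name in ("train", "val", "test"):
            hf_ids, hf[name] = _per_image_hf(net, centered[name])
            assert hf_ids == ids[name]  # both groupings sort by source id
        hf_std = fit_standardizer(hf["train"])
        hf_z = {name: hf_std.transform(hf[name]) for name in hf}

        # classifier heads
        trad_head = softmax_head(lf_z["train"], y["train"], seed=seed)
        r_model = train_r_fusion(
            lf_z["train"], hf_z["train"], y["train"],
            lf_z["val"], hf_z["val"], y["val"],
            lambda_grid=self.lambda_grid, seed=seed,
        )
        mlp_model = mlp_fuse_train(
            lf_z["train"], hf_z["train"], y["train"],
            hidden_width=self.hidden_width, n_classes=self.n_classes,
            seed=seed, epochs=self.mlp_epochs,
        )

        # per-classifier probabilities on val and test
        def probs_for(name: str) -> dict[str, np.ndarray]:
            _, cnn_probs, _ = predict_patch_averaged(net, centered[name])
            return {
                "traditional": trad_head.predict_proba(lf_z[name]),
                "coding_network": cnn_probs,
                "r_fusion": r_model.predict_proba(lf_z[name], hf_z[name]),
                "mlp_fusion": mlp_model.predict_proba(lf_z[name], hf_z[name]),
            }

        val_probs = probs_for("val")
        test_probs = probs_for("test")

        def acc(probs: np.ndarray, truth: np.ndarray) -> float:
            return float(np.mean(probs.argmax(axis=1) + 1 == truth))

        accuracies = {c: acc(test_probs[c], y["test"]) for c in CLASSIFIERS}
        val_accuracies = {c: acc(val_probs[c], y["val"]) for c in CLASSIFIERS}
        confusion = {
            c: confusion_matrix(y["test"], test_probs[c].argmax(axis=1) + 1,
                                self.n_classes)
            for c in CLASSIFIERS
        }
        aucs = {}
        if self.n_classes == 2:
            for c in CLASSIFIERS:
                aucs[c] = auc(roc_curve(test_probs[c][:, 0], y["test"], positive_label=1))

        return CNMPResults(
            accuracies=accuracies,
            val_accuracies=val_accuracies,
            confusion=confusion,
            aucs=aucs,
            selected_lambda=r_model.lam,
            history=net.history,
            n_train=len(train), n_val=len(val), n_test=len(test),
            n_classes=self.n_classes,
            network=net,
            r_fusion=r_model,
            mlp_fusion=mlp_model,
            mean_rgb=mean_rgb,
            lf_standardizer=lf_std,
            hf_standardizer=hf_std,
            test_ids=ids["test"],
            test_labels=y["test"],
            test_probs=test_probs,
        )
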