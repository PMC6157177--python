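"""Coding-network architecture arithmetic, forward semantics and training."""

import numpy as np
import pytest

from cnmp.datasets import ClassRecipe, SyntheticSpec, generate_dataset
from cnmp.network import (CodingNetwork, LayerSpec, NetworkSpec, TrainConfig,
                          build_network, default_network_spec,
                          predict_patch_averaged, shape_propagate)
from cnmp.preprocess import (AugmentationConfig, FractionalCrop, PatchSet,
                             augment, subtract_mean_rgb)

# output sizes of the standard architecture on a 140x140x3 input
TABLE_SHAPES = [
    (130, 130, 32), (120, 120, 32), (58, 58, 32), (50, 50, 64),
    (23, 23, 64), (16, 16, 128), (8, 8, 256), (1, 1, 256), (4,), (4,),
]


class TestShapePropagate:
    def test_default_architecture_shapes(self):
        assert shape_propagate(default_network_spec(4)) == TABLE_SHAPES

    def test_reduced_width_preserves_spatial_shapes(self):
        shapes = shape_propagate(default_network_spec(4, width_factor=0.25))
        assert [s[:2] for s in shapes[:8]] == [s[:2] for s in TABLE_SHAPES[:8]]
        assert shapes[7] == (1, 1, 64)

    def test_exact_fit_kernel(self):
        spec = NetworkSpec(layers=(LayerSpec("conv", 11, 1, 8),),
                           input_size=(11, 11, 3), n_classes=2)
        assert shape_propagate(spec) == [(1, 1, 8)]

    def test_kernel_larger_than_input_raises_naming_layer(self):
        spec = NetworkSpec(layers=(LayerSpec("conv", 11, 1, 8),),
                           input_size=(10, 10, 3), n_classes=2)
        with pytest.raises(ValueError, match="layer 0"):
            shape_propagate(spec)

    def test_overlapping_pool_uses_floor(self):
        # 120 -> floor((120 - 5) / 2) + 1 = 58
        spec = NetworkSpec(layers=(LayerSpec("maxpool", 5, 2),),
                           input_size=(120, 120, 8), n_classes=2)
        assert shape_propagate(spec) == [(58, 58, 8)]


def _small_spec(n_classes=2, input_size=(24, 24, 3), batch_norm=True):
    """A miniature architecture whose final conv is 1x1, for fast tests."""
    layers = (
        LayerSpec("conv", 5, 1, 4),
        LayerSpec("maxpool", 2, 2),
        LayerSpec("conv", 5, 1, 8),
        LayerSpec("conv", 6, 1, 12),
        LayerSpec("rasterize"),
        LayerSpec("softmax"),
    )
    return NetworkSpec(layers=layers, input_size=input_size,
                       n_classes=n_classes, batch_norm=batch_norm)


class TestBuildAndForward:
    def test_forward_shapes_match_arithmetic(self, rng):
        spec = _small_spec()
        net = build_network(spec, seed=0)
        x = rng.normal(size=(2, 24, 24, 3)).astype(np.float32)
        assert net.forward_shapes(x) == shape_propagate(spec)

    def test_softmax_simplex_and_uniform_for_zero_logits(self, rng):
        net = build_network(_small_spec(n_classes=3, batch_norm=False), seed=0)
        x = rng.normal(size=(4, 24, 24, 3)).astype(np.float32)
        probs = net.predict_proba(x)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs > 0).all()
        from cnmp._layers import softmax
        np.testing.assert_allclose(softmax(np.zeros((2, 5))), 0.2)

    def test_same_seed_identical_initial_weights(self):
        a = build_network(_small_spec(), seed=3)
        b = build_network(_small_spec(), seed=3)
        c = build_network(_small_spec(), seed=4)
        for la, lb in zip(a._layers, b._layers):
            for pa, pb in zip(la.params(), lb.params()):
                np.testing.assert_array_equal(pa["value"], pb["value"])
        assert any(
            not np.array_equal(pa["value"], pc["value"])
            for la, lc in zip(a._layers, c._layers)
            for pa, pc in zip(la.params(), lc.params())
        )

    def test_final_conv_must_be_1x1(self):
        layers = (LayerSpec("conv", 3, 1, 4), LayerSpec("rasterize"), LayerSpec("softmax"))
        spec = NetworkSpec(layers=layers, input_size=(8, 8, 3), n_classes=2)
        with pytest.raises(ValueError, match="1x1"):
            build_network(spec, seed=0)

    def test_save_load_roundtrip(self, tmp_path, rng):
        net = build_network(_small_spec(), seed=1)
        x = rng.normal(size=(3, 24, 24, 3)).astype(np.float32)
        net.save(tmp_path / "net.npz")
        back = CodingNetwork.load(tmp_path / "net.npz")
        np.testing.assert_array_equal(net.predict_proba(x), back.predict_proba(x))


class TestHighLevelFeature:
    def _net(self):
        return build_network(_small_spec(), seed=0)

    def test_single_patch_equals_its_activation(self, rng):
        net = self._net()
        p = rng.normal(size=(1, 24, 24, 3)).astype(np.float32)
        np.testing.assert_allclose(net.extract_high_level(p), net.features(p)[0])

    def test_duplicate_patch_idempotent(self, rng):
        net = self._net()
        p = rng.normal(size=(1, 24, 24, 3)).astype(np.float32)
        two = np.concatenate([p, p])
        np.testing.assert_allclose(net.extract_high_level(two),
                                   net.extract_high_level(p), atol=1e-6)

    def test_nonnegative_finite_and_sized(self, rng):
        net = self._net()
        hf = net.extract_high_level(rng.normal(size=(5, 24, 24, 3)).astype(np.float32))
        assert hf.shape == (net.feature_dim,)
        assert np.isfinite(hf).all() and (hf >= 0).all()

    def test_empty_patch_list_rejected(self):
        with pytest.raises(ValueError, match="at least one patch"):
            self._net().extract_high_level(np.empty((0, 24, 24, 3), dtype=np.float32))


class TestPatchAveragedPrediction:
    def test_mean_of_patch_probabilities(self):
        net = build_network(_small_spec(), seed=0)
        ps = PatchSet(patches=np.zeros((2, 24, 24, 3), dtype=np.float32),
                      source_ids=["a", "a"], labels=np.array([1, 1]))
        patch_probs = np.array([[0.6, 0.4], [0.2, 0.8]])
        net.predict_proba = lambda patches, batch_size=32: patch_probs  # type: ignore
        ids, probs, pred = predict_patch_averaged(net, ps)
        assert ids == ["a"]
        np.testing.assert_allclose(probs, [[0.4, 0.6]])
        assert pred.tolist() == [2]

    def test_identical_patches_give_patch_probability(self, rng):
        net = build_network(_small_spec(), seed=0)
        patch = rng.normal(size=(24, 24, 3)).astype(np.float32)
        ps = PatchSet(patches=np.stack([patch] * 3), source_ids=["x"] * 3,
                      labels=np.array([1] * 3))
        _, probs, _ = predict_patch_averaged(net, ps)
        np.testing.assert_allclose(probs[0], net.predict_proba(patch[None])[0], atol=1e-6)

    def test_exact_tie_goes_to_smaller_label(self):
        net = build_network(_small_spec(), seed=0)
        ps = PatchSet(patches=np.zeros((1, 24, 24, 3), dtype=np.float32),
                      source_ids=["a"], labels=np.array([1]))
        net.predict_proba = lambda patches, batch_size=32: np.array([[0.5, 0.5]])  # type: ignore
        _, _, pred = predict_patch_averaged(net, ps)
        assert pred.tolist() == [1]


class TestTraining:
    def test_config_validation(self):
        with pytest.raises(ValueError, match="epochs"):
            TrainConfig(epochs=0)
        with pytest.raises(ValueError, match="decay"):
            TrainConfig(decay=0.0)
        with pytest.raises(ValueError, match="rate"):
            TrainConfig(lr=-1.0)

    def test_label_outside_range_rejected_before_training(self, rng):
        net = build_network(_small_spec(n_classes=2), seed=0)
        ps = PatchSet(patches=rng.normal(size=(4, 24, 24, 3)).astype(np.float32),
                      source_ids=list("abcd"), labels=np.array([1, 2, 3, 1]))
        with pytest.raises(ValueError, match=r"\[1, 2\]"):
            net.train(ps, None, TrainConfig(epochs=1))

    def test_constant_lr_when_decay_one(self, rng):
        net = build_network(_small_spec(n_classes=2), seed=0)
        ps = PatchSet(patches=rng.normal(size=(6, 24, 24, 3)).astype(np.float32),
                      source_ids=list("abcdef"), labels=np.array([1, 2] * 3))
        hist = net.train(ps, None, TrainConfig(epochs=3, decay=1.0, lr=0.01))
        assert [h["lr"] for h in hist] == [0.01, 0.01, 0.01]

    def test_learning_rate_decays_each_epoch(self, rng):
        net = build_network(_small_spec(n_classes=2), seed=0)
        ps = PatchSet(patches=rng.normal(size=(4, 24, 24, 3)).astype(np.float32),
                      source_ids=list("abcd"), labels=np.array([1, 2, 1, 2]))
        hist = net.train(ps, None, TrainConfig(epochs=3, decay=0.5, lr=0.04))
        assert [h["lr"] for h in hist] == pytest.approx([0.04, 0.02, 0.01])

    def test_separable_two_class_fixture_reaches_95pct_train_accuracy(self):
        """40 noiseless color-separated images; a reduced-width network must
        fit them nearly perfectly within 30 epochs."""
        recipes = (
            ClassRecipe(1, "grating", period=8, amplitude=30.0,
                        color_mean=(180.0, 90.0, 90.0), count=20),
            ClassRecipe(2, "grating", period=8, amplitude=30.0,
                        color_mean=(90.0, 90.0, 180.0), count=20),
        )
        ds = generate_dataset(SyntheticSpec(recipes=recipes, image_size=(64, 64), seed=0))
        cfg = AugmentationConfig(m=1, crop_policy=FractionalCrop(), target_size=140, seed=0)
        centered, _ = subtract_mean_rgb(ds)
        ps = augment(centered, cfg)
        net = build_network(default_network_spec(2, width_factor=0.125), seed=0)
        hist = net.train(ps, None, TrainConfig(epochs=30, lr=0.01, decay=0.9, seed=0))
        assert hist[-1]["train_acc"] >= 0.95

    def test_training_is_deterministic_per_seed(self, rng):
        ps = PatchSet(patches=rng.normal(size=(8, 24, 24, 3)).astype(np.float32),
                      source_ids=list("abcdefgh"), labels=np.array([1, 2] * 4))
        hists = []
        nets = []
        for _ in range(2):
            net = build_network(_small_spec(n_classes=2), seed=5)
            hists.append(net.train(ps, None, TrainConfig(epochs=2, seed=5)))
            nets.append(net)
        assert hists[0] == hists[1]
        for la, lb in zip(nets[0]._layers, nets[1]._layers):
            for pa, pb in zip(la.params(), lb.params()):
                np.testing.assert_array_equal(pa["value"], pb["value"])
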