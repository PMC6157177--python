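"""Synthetic dataset generation, splitting and persistence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnmp.datasets import (ClassRecipe, SyntheticSpec, generate_dataset,
                           his_like_spec, isic_like_spec, load_image_set,
                           render_class_image, save_image_set, split_dataset,
                           tiny_spec)
from cnmp.features import extract_traditional


def _grating(count=0, **kw):
    defaults = dict(label=1, texture_kind="grating", period=8.0, amplitude=40.0)
    defaults.update(kw)
    return ClassRecipe(count=count, **defaults)


class TestRenderClassImage:
    def test_zero_amplitude_grating_is_constant_at_color_mean(self):
        r = _grating(amplitude=0.0, color_mean=(100.0, 150.0, 200.0))
        img = render_class_image(r, 32, 32, seed=0)
        assert img.shape == (32, 32, 3)
        assert (img[:, :, 0] == 100).all()
        assert (img[:, :, 1] == 150).all()
        assert (img[:, :, 2] == 200).all()

    def test_deterministic_per_seed(self):
        r = ClassRecipe(label=2, texture_kind="blob-noise", period=4.0,
                        color_spread=(10.0, 10.0, 10.0), color_skew=(1, 0, -1))
        a = render_class_image(r, 24, 24, seed=5)
        b = render_class_image(r, 24, 24, seed=5)
        c = render_class_image(r, 24, 24, seed=6)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_checkerboard_period2_tiles_8x8_cell_by_cell(self):
        # direct tiling enumeration: 16 alternating 2x2 cells
        r = ClassRecipe(label=1, texture_kind="checkerboard", period=2.0,
                        amplitude=50.0, color_mean=(128.0, 128.0, 128.0))
        img = render_class_image(r, 8, 8, seed=0).astype(int)
        for ci in range(4):
            for cj in range(4):
                cell = img[2 * ci : 2 * ci + 2, 2 * cj : 2 * cj + 2, 0]
                expected = 128 + 50 if (ci + cj) % 2 else 128 - 50
                assert (cell == expected).all(), (ci, cj)

    def test_grating_orientation_zero_varies_along_columns_only(self):
        r = _grating(orientation=0.0, amplitude=40.0)
        img = render_class_image(r, 16, 16, seed=0)
        assert (np.ptp(img[:, :, 0], axis=0) == 0).all()   # constant down each column
        assert np.ptp(img[0, :, 0]) > 0                     # varies across columns

    def test_unknown_texture_kind_rejected(self):
        with pytest.raises(ValueError, match="texture_kind"):
            ClassRecipe(label=1, texture_kind="plaid", count=1).validate()

    def test_image_smaller_than_period_rejected(self):
        with pytest.raises(ValueError, match="period"):
            render_class_image(_grating(period=64.0), 8, 8, seed=0)


class TestGenerateDataset:
    def test_counts_labels_and_ids(self):
        spec = SyntheticSpec(
            recipes=(_grating(count=3, label=1), _grating(count=2, label=2)),
            image_size=(16, 16), seed=0)
        ds = generate_dataset(spec)
        assert len(ds) == 5
        assert np.bincount(ds.labels)[1:].tolist() == [3, 2]
        assert len(set(ds.image_ids)) == 5

    def test_zero_count_recipe_gives_empty_class(self):
        spec = SyntheticSpec(recipes=(_grating(count=0, label=1),),
                             image_size=(16, 16), seed=0)
        assert len(generate_dataset(spec)) == 0

    def test_empty_recipe_list_rejected(self):
        with pytest.raises(ValueError, match="at least one recipe"):
            generate_dataset(SyntheticSpec(recipes=(), image_size=(16, 16)))

    def test_bit_identical_regeneration(self):
        spec = tiny_spec(n_per_class=3, noise_sd=5.0, seed=11)
        a, b = generate_dataset(spec), generate_dataset(spec)
        for ia, ib in zip(a.images, b.images):
            np.testing.assert_array_equal(ia, ib)

    def test_variable_resolution_draws_from_choice_set(self):
        spec = SyntheticSpec(
            recipes=(_grating(count=12, label=1),),
            image_size=((16, 20), (24, 28)), seed=3)
        sizes = {img.shape[:2] for img in generate_dataset(spec).images}
        assert sizes <= {(16, 20), (24, 28)}
        assert len(sizes) == 2

    @settings(max_examples=10, deadline=None)
    @given(count=st.integers(0, 4), seed=st.integers(0, 2**20), noise=st.floats(0, 20))
    def test_regeneration_property(self, count, seed, noise):
        spec = SyntheticSpec(
            recipes=(_grating(count=count, label=1), _grating(count=2, label=2)),
            image_size=(12, 12), noise_sd=noise, seed=seed)
        a, b = generate_dataset(spec), generate_dataset(spec)
        assert len(a) == count + 2
        for ia, ib in zip(a.images, b.images):
            np.testing.assert_array_equal(ia, ib)
            assert ia.dtype == np.uint8 and ia.min() >= 0 and ia.max() <= 255


def _split_size_oracle(class_counts, ratios):
    """Independent largest-remainder allocation, summed over classes."""
    totals = [0, 0, 0]
    for n in class_counts:
        target = [n * r for r in ratios]
        base = [int(np.floor(t)) for t in target]
        rem = n - sum(base)
        fracs = sorted(range(3), key=lambda j: (-(target[j] - base[j]), j))
        for j in fracs[:rem]:
            base[j] += 1
        for j in range(3):
            totals[j] += base[j]
    return tuple(totals)


class TestSplitDataset:
    def test_split_sizes_match_benchmark_class_counts(self):
        # per-class allocation of 1026/484/804/514 at 7:1:2 (independent oracle)
        counts = (1026, 484, 804, 514)
        expected = _split_size_oracle(counts, (0.7, 0.1, 0.2))
        assert sum(expected) == 2828
        labels = np.repeat([1, 2, 3, 4], counts)
        ds_like = _label_only_dataset(labels)
        tr, va, te = split_dataset(ds_like, (0.7, 0.1, 0.2), seed=0)
        assert (len(tr), len(va), len(te)) == expected == (1980, 282, 566)

    def test_split_is_stratified_partition(self, tiny_dataset):
        tr, va, te = split_dataset(tiny_dataset, (0.7, 0.1, 0.2), seed=3)
        ids = sorted(tr.image_ids + va.image_ids + te.image_ids)
        assert ids == sorted(tiny_dataset.image_ids)
        for part in (tr, va, te):
            assert set(part.labels) == {1, 2, 3, 4}

    def test_all_in_train_when_ratio_one(self, tiny_dataset):
        tr, va, te = split_dataset(tiny_dataset, (1.0, 0.0, 0.0), seed=0)
        assert len(tr) == len(tiny_dataset) and len(va) == len(te) == 0

    def test_same_seed_same_membership(self, tiny_dataset):
        a = split_dataset(tiny_dataset, (0.7, 0.1, 0.2), seed=9)
        b = split_dataset(tiny_dataset, (0.7, 0.1, 0.2), seed=9)
        for pa, pb in zip(a, b):
            assert pa.image_ids == pb.image_ids

    def test_class_too_small_raises_instead_of_dropping(self):
        labels = np.array([1] * 20 + [2] * 2)  # class 2 cannot reach all 3 splits
        with pytest.raises(ValueError, match="class 2"):
            split_dataset(_label_only_dataset(labels), (0.7, 0.1, 0.2), seed=0)


def _label_only_dataset(labels):
    from cnmp.datasets import LabeledImageSet
    img = np.zeros((2, 2, 3), dtype=np.uint8)
    return LabeledImageSet(images=[img] * len(labels), labels=labels,
                           image_ids=[f"i{k}" for k in range(len(labels))])


class TestFixtureSpecs:
    def test_benchmark_like_specs_declare_printed_counts(self):
        his = his_like_spec()
        assert [r.count for r in his.recipes] == [1026, 484, 804, 514]
        assert his.size_choices == ((480, 720),)
        isic = isic_like_spec()
        assert [r.count for r in isic.recipes] == [374, 1626]
        assert len(isic.size_choices) > 1

    def test_complementarity_by_nearest_centroid_probe(self, tiny_dataset):
        """Texture features alone and color features alone are each
        imperfect; their concatenation separates all four classes."""
        feats = np.array([extract_traditional(img) for img in tiny_dataset.images])
        y = tiny_dataset.labels

        def ncc_acc(x):
            sd = x.std(axis=0)
            sd[sd == 0] = 1.0
            z = (x - x.mean(axis=0)) / sd
            cents = np.stack([z[y == c].mean(axis=0) for c in (1, 2, 3, 4)])
            d = ((z[:, None, :] - cents[None]) ** 2).sum(axis=2)
            return float(np.mean(d.argmin(axis=1) + 1 == y))

        tex_acc, col_acc, cat_acc = ncc_acc(feats[:, :8]), ncc_acc(feats[:, 8:]), ncc_acc(feats)
        assert tex_acc < 1.0
        assert col_acc < 1.0
        assert cat_acc >= 0.99


class TestPersistence:
    def test_png_roundtrip(self, tmp_path):
        ds = generate_dataset(tiny_spec(n_per_class=2, seed=0))
        manifest = save_image_set(ds, tmp_path / "ds")
        assert manifest.exists()
        back = load_image_set(tmp_path / "ds")
        assert back.image_ids == ds.image_ids
        np.testing.assert_array_equal(back.labels, ds.labels)
        for a, b in zip(ds.images, back.images):
            np.testing.assert_array_equal(a, b)
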