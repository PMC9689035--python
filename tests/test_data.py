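"""Dataset I/O, the x20 augmentation policy, and balanced cropping."""

import numpy as np
import pytest
from PIL import Image

from rgcsnn.data import (
    AugmentPolicy, LabeledImage, augment_jitter, augment_noise,
    augment_transposition, balanced_windows, build_augmented_dataset,
    crop_and_resize, iter_augmented, load_dataset, save_dataset,
)


def make_item(size=32, seed=0):
    rng = np.random.default_rng(seed)
    img = rng.random((3, size, size))
    mask = np.ones((size, size), dtype=np.uint8)
    mask[size // 4: size // 2, size // 4: size // 2] = 0
    return LabeledImage(image=img, mask=mask, id="toy")


class TestLabeledImage:
    def test_non_binary_mask_rejected(self):
        with pytest.raises(ValueError):
            LabeledImage(image=np.zeros((3, 4, 4)), mask=np.full((4, 4), 2))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            LabeledImage(image=np.zeros((3, 4, 4)), mask=np.zeros((5, 4)))


class TestIO:
    def test_empty_directory(self, tmp_path):
        assert load_dataset(tmp_path) == []

    def test_save_load_round_trip(self, tmp_path):
        items = [make_item(seed=i) for i in range(3)]
        for i, it in enumerate(items):
            it.id = f"img{i}"
        save_dataset(items, tmp_path)
        loaded = load_dataset(tmp_path)
        assert len(loaded) == 3
        assert np.array_equal(loaded[0].mask, items[0].mask)
        # 8-bit quantisation on write
        assert np.allclose(loaded[0].image, items[0].image, atol=1 / 255)

    def test_missing_mask_named(self, tmp_path):
        (tmp_path / "images").mkdir()
        (tmp_path / "masks").mkdir()
        Image.new("RGB", (8, 8)).save(tmp_path / "images" / "a.png")
        with pytest.raises(FileNotFoundError, match="a.png"):
            load_dataset(tmp_path)

    def test_non_binary_mask_file_named(self, tmp_path):
        (tmp_path / "images").mkdir()
        (tmp_path / "masks").mkdir()
        Image.new("RGB", (8, 8)).save(tmp_path / "images" / "b.png")
        Image.fromarray(np.full((8, 8), 2, np.uint8)).save(
            tmp_path / "masks" / "b.png")
        with pytest.raises(ValueError, match="b.png"):
            load_dataset(tmp_path)


class TestTransposition:
    def test_five_outputs_first_is_original(self, rng):
        item = make_item()
        out = augment_transposition(item, AugmentPolicy(), rng)
        assert len(out) == 5
        assert np.array_equal(out[0].image, item.image)
        assert np.array_equal(out[0].mask, item.mask)

    def test_masks_stay_binary_under_rotation(self, rng):
        policy = AugmentPolicy(rotate_range=90, translate_range=8)
        for it in augment_transposition(make_item(), policy, rng):
            assert set(np.unique(it.mask)) <= {0, 1}

    def test_double_flip_is_identity(self):
        # flip_prob 1 with no rotation/translation flips both axes;
        # applying the same transform twice restores the original
        policy = AugmentPolicy(flip_prob=1.0, rotate_range=0.0,
                               translate_range=0)
        item = make_item()
        rng1 = np.random.default_rng(0)
        once = augment_transposition(item, policy, rng1)[1]
        rng2 = np.random.default_rng(0)
        twice = augment_transposition(once, policy, rng2)[1]
        assert np.allclose(twice.image, item.image)
        assert np.array_equal(twice.mask, item.mask)

    def test_image_mask_alignment_preserved(self, rng):
        # paint the lesion into a channel and check it tracks the mask
        size = 48
        mask = np.ones((size, size), np.uint8)
        mask[10:30, 14:34] = 0
        img = np.repeat((1 - mask)[None].astype(float), 3, axis=0)
        item = LabeledImage(image=img, mask=mask, id="aligned")
        policy = AugmentPolicy(rotate_range=45, translate_range=6)
        for it in augment_transposition(item, policy, rng)[1:]:
            assert np.abs(it.image[0] - (1 - it.mask)).mean() < 0.05


class TestJitter:
    def test_factor_one_is_identity(self, rng):
        item = make_item()
        out = augment_jitter(item, AugmentPolicy(), rng,
                             factors={k: 1.0 for k in
                                      ("brightness", "contrast",
                                       "saturation", "sharpness")})
        assert len(out) == 4
        for it in out:
            assert np.allclose(it.image, item.image, atol=1e-9)
            assert np.array_equal(it.mask, item.mask)

    def test_zero_brightness_is_black(self, rng):
        out = augment_jitter(make_item(), AugmentPolicy(), rng,
                             factors={"brightness": 0.0, "contrast": 1,
                                      "saturation": 1, "sharpness": 1})
        assert np.all(out[0].image == 0)

    def test_zero_saturation_is_grayscale(self, rng):
        out = augment_jitter(make_item(), AugmentPolicy(), rng,
                             factors={"brightness": 1, "contrast": 1,
                                      "saturation": 0.0, "sharpness": 1})
        img = out[2].image
        assert np.allclose(img[0], img[1]) and np.allclose(img[1], img[2])


class TestNoise:
    def test_zero_probs_unchanged(self, rng):
        item = make_item()
        policy = AugmentPolicy(salt_pepper_prob=0.0, mask_prob=0.0)
        out = augment_noise(item, policy, rng)
        assert np.array_equal(out.image, item.image)

    def test_full_salt_pepper_is_extreme(self, rng):
        policy = AugmentPolicy(salt_pepper_prob=1.0, mask_prob=0.0)
        out = augment_noise(make_item(), policy, rng)
        assert set(np.unique(out.image)) <= {0.0, 1.0}

    def test_corruption_fraction_matches_probability(self, rng):
        p = 0.05
        item = LabeledImage(image=np.full((3, 256, 256), 0.5),
                            mask=np.ones((256, 256), np.uint8), id="n")
        policy = AugmentPolicy(salt_pepper_prob=p, mask_prob=0.0)
        out = augment_noise(item, policy, rng)
        frac = (out.image[0] != 0.5).mean()
        sigma = np.sqrt(p * (1 - p) / 256 ** 2)
        assert abs(frac - p) < 3 * sigma

    def test_label_mask_untouched(self, rng):
        item = make_item()
        out = augment_noise(item, AugmentPolicy(salt_pepper_prob=0.5), rng)
        assert np.array_equal(out.mask, item.mask)


class TestOfflinePipeline:
    def test_multiplier_is_twenty(self):
        items = [make_item(seed=i) for i in range(3)]
        out = build_augmented_dataset(items, AugmentPolicy(seed=1))
        assert len(out) == 60

    def test_single_item_yields_twenty(self):
        out = list(iter_augmented([make_item()], AugmentPolicy(seed=2)))
        assert len(out) == 20
        for it in out:
            assert set(np.unique(it.mask)) <= {0, 1}

    def test_deterministic_under_seed(self):
        items = [make_item()]
        a = build_augmented_dataset(items, AugmentPolicy(seed=5))
        b = build_augmented_dataset(items, AugmentPolicy(seed=5))
        for x, y in zip(a, b):
            assert np.array_equal(x.image, y.image)
            assert np.array_equal(x.mask, y.mask)


class TestCropping:
    def test_small_image_resized_whole(self):
        out = crop_and_resize(make_item(32), target=16, crop_size=64)
        assert len(out) == 1
        assert out[0].image.shape == (3, 16, 16)

    def test_single_class_grid_fallback_disjoint(self):
        mask = np.ones((64, 64), np.uint8)
        wins = balanced_windows(mask, 32)
        assert wins == [(0, 0), (0, 32), (32, 0), (32, 32)]

    def test_balanced_windows_disjoint_and_mixed(self):
        mask = np.ones((96, 96), np.uint8)
        mask[:48, :] = 0  # top half lesion
        wins = balanced_windows(mask, 32)
        assert wins
        for i, (y1, x1) in enumerate(wins):
            for y2, x2 in wins[i + 1:]:
                assert abs(y1 - y2) >= 32 or abs(x1 - x2) >= 32
        # every chosen window straddles the class boundary
        for y, x in wins:
            sub = mask[y:y + 32, x:x + 32]
            assert 0 < sub.mean() < 1

    def test_output_masks_binary_after_resize(self):
        item = make_item(64)
        for it in crop_and_resize(item, target=16, crop_size=32):
            assert set(np.unique(it.mask)) <= {0, 1}
            assert it.image.shape == (3, 16, 16)
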