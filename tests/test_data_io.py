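"""Letterbox arithmetic, mask validation, augmentation contracts."""

import numpy as np
import pytest
from PIL import Image

from thyroseg.data_io import (
    AugmentationConfig,
    Sample,
    augment,
    invert_letterbox,
    letterbox,
    load_sample,
    save_sample,
)
from thyroseg.exceptions import InputError


def _sample(h, w, rng=None, mask=None):
    rng = rng or np.random.default_rng(0)
    image = rng.random((h, w)).astype(np.float32)
    if mask is None:
        mask = rng.integers(0, 3, size=(h, w)).astype(np.uint8)
    return Sample(image=image, mask=mask, id="s")


def test_letterbox_600x400_arithmetic():
    s, rec = letterbox(_sample(600, 400), side=512)
    assert s.image.shape == (512, 512)
    # 400 * 512/600 = 341.33 -> 341 (round half up); pads split 85/86
    assert rec.pad == (0, 0, 85, 86)
    assert rec.original_size == (600, 400)
    assert abs(rec.scale * 600 - 512) < 1e-9
    # the fill region is exactly zero
    assert s.image[:, :85].max() == 0.0 and s.image[:, -86:].max() == 0.0
    assert s.mask[:, :85].max() == 0 and s.mask[:, -86:].max() == 0


def test_letterbox_identity_when_already_square():
    orig = _sample(128, 128)
    s, rec = letterbox(orig, side=128)
    np.testing.assert_array_equal(s.mask, orig.mask)
    np.testing.assert_allclose(s.image, orig.image, atol=1e-6)
    assert rec.pad == (0, 0, 0, 0) and rec.scale == 1.0


def test_letterbox_mask_alphabet_never_grows():
    mask = np.zeros((100, 60), dtype=np.uint8)
    mask[10:40, 10:50] = 1
    mask[20:30, 20:30] = 2
    s, _ = letterbox(_sample(100, 60, mask=mask), side=64)
    assert set(np.unique(s.mask)) <= set(np.unique(mask)) | {0}


def test_invert_letterbox_roundtrip_identity_square():
    orig = _sample(128, 128)
    s, rec = letterbox(orig, side=128)
    np.testing.assert_array_equal(invert_letterbox(s.mask, rec), orig.mask)


def test_invert_letterbox_preserves_large_component_count():
    from scipy import ndimage

    mask = np.zeros((600, 400), dtype=np.uint8)
    mask[50:150, 50:150] = 1
    mask[300:420, 100:300] = 1
    mask[320:400, 150:250] = 2
    s, rec = letterbox(Sample(image=np.zeros((600, 400), np.float32), mask=mask, id="x"), 512)
    back = invert_letterbox(s.mask, rec)

    def ncomp(m, cls):
        return ndimage.label(m == cls, structure=np.ones((3, 3)))[1]

    for cls in (1, 2):
        assert ncomp(back, cls) == ncomp(mask, cls)


def test_invert_letterbox_empty_mask_stays_empty():
    s, rec = letterbox(_sample(90, 120, mask=np.zeros((90, 120), np.uint8)), side=64)
    assert invert_letterbox(s.mask, rec).max() == 0


def test_invert_letterbox_rejects_inconsistent_record():
    s, rec = letterbox(_sample(90, 120), side=64)
    with pytest.raises(InputError):
        invert_letterbox(np.zeros((32, 32), np.uint8), rec)


def test_degenerate_input_rejected():
    with pytest.raises(InputError):
        letterbox(Sample(np.zeros((0, 4), np.float32), np.zeros((0, 4), np.uint8), "z"))


class TestAugment:
    def test_zero_probabilities_identity(self):
        s = _sample(32, 32)
        out = augment(s, AugmentationConfig.identity(), np.random.default_rng(0))
        np.testing.assert_allclose(out.image, s.image, atol=1e-7)
        np.testing.assert_array_equal(out.mask, s.mask)

    def test_mirror_is_involution(self):
        cfg = AugmentationConfig.identity()
        cfg.p_mirror = 1.0
        s = _sample(16, 24)
        once = augment(s, cfg, np.random.default_rng(0))
        twice = augment(once, cfg, np.random.default_rng(0))
        np.testing.assert_allclose(twice.image, s.image)
        np.testing.assert_array_equal(twice.mask, s.mask)

    def test_seed_determinism_and_variation(self):
        cfg = AugmentationConfig(p_rotation=1.0)
        s = _sample(32, 32)
        a = augment(s, cfg, np.random.default_rng(7))
        b = augment(s, cfg, np.random.default_rng(7))
        c = augment(s, cfg, np.random.default_rng(8))
        np.testing.assert_array_equal(a.image, b.image)
        assert np.abs(a.image - c.image).max() > 1e-6

    def test_mask_alphabet_preserved_and_photometric_leaves_mask(self, rng):
        s = _sample(32, 32, rng)
        cfg = AugmentationConfig(
            p_brightness=1.0, p_contrast=1.0, p_mirror=0, p_rotation=0, p_crop=0, p_stretch=0
        )
        out = augment(s, cfg, np.random.default_rng(0))
        np.testing.assert_array_equal(out.mask, s.mask)
        geo = AugmentationConfig(
            p_brightness=0, p_contrast=0, p_mirror=1.0, p_rotation=1.0, p_crop=1.0, p_stretch=1.0
        )
        out2 = augment(s, geo, np.random.default_rng(1))
        assert set(np.unique(out2.mask)) <= set(np.unique(s.mask)) | {0}
        assert out2.image.min() >= 0.0 and out2.image.max() <= 1.0

    def test_probability_validation(self):
        with pytest.raises(InputError):
            AugmentationConfig(p_mirror=1.5)


class TestIO:
    def test_save_load_roundtrip(self, tmp_path, small_phantom):
        save_sample(small_phantom, tmp_path / "images", tmp_path / "masks")
        s = load_sample(
            tmp_path / "images" / f"{small_phantom.id}.png",
            tmp_path / "masks" / f"{small_phantom.id}.png",
        )
        np.testing.assert_array_equal(s.mask, small_phantom.mask)
        assert np.abs(s.image - small_phantom.image).max() < 1 / 255 + 1e-6

    def test_invalid_mask_labels_listed(self, tmp_path):
        Image.fromarray(np.zeros((8, 8), np.uint8), "L").save(tmp_path / "img.png")
        bad = np.zeros((8, 8), np.uint8)
        bad[0, 0] = 3
        bad[1, 1] = 7
        Image.fromarray(bad, "L").save(tmp_path / "mask.png")
        with pytest.raises(InputError, match=r"\[3, 7\]"):
            load_sample(tmp_path / "img.png", tmp_path / "mask.png")

    def test_rgb_image_collapsed_to_grayscale(self, tmp_path):
        rgb = np.random.default_rng(0).integers(0, 255, size=(10, 12, 3)).astype(np.uint8)
        Image.fromarray(rgb, "RGB").save(tmp_path / "img.png")
        Image.fromarray(np.zeros((10, 12), np.uint8), "L").save(tmp_path / "mask.png")
        s = load_sample(tmp_path / "img.png", tmp_path / "mask.png")
        assert s.image.shape == (10, 12)
        np.testing.assert_allclose(s.image, rgb.mean(axis=2) / 255.0, atol=1e-6)
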