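"""Volume I/O, resampling, slicing, augmentation and split hygiene."""

import numpy as np
import pytest

from vertebox.data_io import (
    SlicePair, VolumeMeta, augment, load_volume, normalize_intensity,
    resample_isotropic, resize_pair, save_volume, slice_and_resize,
    split_train_val,
)
from vertebox.errors import InvalidInputError
from vertebox.phantom import generate_dataset, generate_phantom_volume

RNG = np.random.default_rng(51)


class TestLoadSave:
    def test_round_trip_preserves_values_and_spacing(self, tmp_path):
        vol = RNG.standard_normal((6, 10, 12)).astype(np.float32)
        meta = VolumeMeta(spacing=(0.4, 0.4, 1.0))
        path = tmp_path / "vol.nii.gz"
        save_volume(vol, meta, path)
        loaded, labels, meta2 = load_volume(path)
        np.testing.assert_allclose(loaded, vol, rtol=1e-6)
        assert meta2.spacing == pytest.approx((0.4, 0.4, 1.0))
        assert labels is None

    def test_label_shape_mismatch_rejected(self, tmp_path):
        meta = VolumeMeta()
        save_volume(np.zeros((4, 8, 8), np.float32), meta, tmp_path / "img.nii.gz")
        save_volume(np.zeros((5, 8, 8), np.uint8), meta, tmp_path / "lab.nii.gz")
        with pytest.raises(InvalidInputError):
            load_volume(tmp_path / "img.nii.gz", tmp_path / "lab.nii.gz")

    def test_missing_file_rejected(self, tmp_path):
        with pytest.raises(InvalidInputError):
            load_volume(tmp_path / "nope.nii.gz")

    def test_phantom_volume_round_trip_is_isotropic(self, tmp_path):
        vol, labels, meta = generate_phantom_volume(3, seed=1)
        save_volume(vol, meta, tmp_path / "ph.nii.gz")
        _, _, meta2 = load_volume(tmp_path / "ph.nii.gz")
        assert meta2.spacing == pytest.approx((1.0, 1.0, 1.0))

    def test_nonpositive_spacing_rejected(self):
        with pytest.raises(InvalidInputError):
            VolumeMeta(spacing=(0.0, 1.0, 1.0))


class TestResample:
    def test_isotropic_input_unchanged(self):
        vol = RNG.standard_normal((5, 8, 8)).astype(np.float32)
        out, _, meta = resample_isotropic(vol, VolumeMeta())
        np.testing.assert_array_equal(out, vol)
        assert meta.spacing == (1.0, 1.0, 1.0)

    def test_constant_volume_stays_constant(self):
        vol = np.full((6, 20, 20), 7.0, dtype=np.float32)
        out, _, _ = resample_isotropic(vol, VolumeMeta(spacing=(0.5, 0.5, 1.0)))
        np.testing.assert_allclose(out, 7.0, rtol=1e-6)

    def test_half_millimetre_plane_halves_extent(self):
        vol = RNG.standard_normal((4, 100, 100)).astype(np.float32)
        labels = (RNG.random((4, 100, 100)) < 0.2).astype(np.uint8)
        out, out_labels, meta = resample_isotropic(
            vol, VolumeMeta(spacing=(0.5, 0.5, 1.0)), labels)
        assert out.shape == (4, 50, 50)
        assert out_labels.shape == (4, 50, 50)
        assert set(np.unique(out_labels)) <= {0, 1}
        assert meta.spacing == (1.0, 1.0, 1.0)


class TestSliceAndResize:
    def test_one_pair_per_axial_slice(self):
        vol = RNG.random((40, 64, 64)).astype(np.float32)
        labels = (RNG.random((40, 64, 64)) < 0.1).astype(np.uint8)
        pairs = slice_and_resize(vol, labels, size=128, volume_id="v0")
        assert len(pairs) == 40
        assert pairs[7].slice_index == 7 and pairs[7].volume_id == "v0"
        assert pairs[0].image.shape == (128, 128)

    def test_masks_stay_binary(self):
        labels = (RNG.random((5, 100, 100)) < 0.3).astype(np.uint8)
        pairs = slice_and_resize(np.zeros((5, 100, 100), np.float32), labels, size=256)
        for p in pairs:
            assert set(np.unique(p.mask)) <= {0, 1}

    def test_disk_area_scales_quadratically(self):
        yy, xx = np.mgrid[0:128, 0:128]
        disk = (((yy - 64) ** 2 + (xx - 64) ** 2) <= 30 ** 2).astype(np.uint8)
        pairs = slice_and_resize(disk[None].astype(np.float32), disk[None], size=256)
        big = pairs[0].mask.sum()
        assert abs(big - 4 * disk.sum()) / (4 * disk.sum()) < 0.05


class TestAugment:
    @pytest.fixture()
    def pair(self):
        pairs, _ = generate_dataset(1, profile="easy", seed=8)
        return resize_pair(pairs[0], 128)

    def test_deterministic_given_seed(self, pair):
        a = augment(pair, seed=123)
        b = augment(pair, seed=123)
        np.testing.assert_array_equal(a.image, b.image)
        np.testing.assert_array_equal(a.mask, b.mask)

    def test_noise_and_contrast_leave_mask_untouched(self, pair):
        # find a seed whose draw applies no rotation and no flip
        for seed in range(200):
            rng = np.random.default_rng(seed)
            rot, flip = rng.random() < 0.5, rng.random() < 0.5
            if not rot and not flip and (rng.random() < 0.5 or rng.random() < 0.5):
                out = augment(pair, seed=seed)
                np.testing.assert_array_equal(out.mask, pair.mask)
                return
        pytest.fail("no suitable seed found")

    def test_rotation_roundtrip_residual_small(self, pair):
        from skimage.transform import rotate as sk_rotate
        for seed in range(200):
            rng = np.random.default_rng(seed)
            if rng.random() < 0.5:  # rotation branch fires
                angle = float(np.degrees(rng.uniform(-0.1, 0.1)))
                if abs(angle) < 1.0:
                    continue  # want a visible rotation
                rotated = sk_rotate(pair.image, angle, order=1, preserve_range=True)
                back = sk_rotate(rotated, -angle, order=1, preserve_range=True)
                assert np.abs(back - pair.image).mean() < 0.02
                return
        pytest.fail("no suitable seed found")

    def test_output_image_clipped_to_unit_range(self, pair):
        out = augment(pair, seed=5)
        assert out.image.min() >= 0.0 and out.image.max() <= 1.0


class TestNormalize:
    def test_window_clip_and_unit_range(self):
        vol = np.array([[-500.0, -200.0], [500.0, 1400.0]], dtype=np.float32)
        out = normalize_intensity(vol)
        assert out.min() == 0.0 and out.max() == 1.0
        assert out[0, 0] == out[0, 1]  # both clipped to the window floor

    def test_fixed_affine_mapping_independent_of_content(self):
        # half-window intensity lands at 0.5 regardless of the rest of the volume
        a = normalize_intensity(np.array([300.0, 500.0], dtype=np.float32))
        b = normalize_intensity(np.array([300.0, 1200.0], dtype=np.float32))
        assert a[0] == b[0] == pytest.approx(500.0 / 1400.0)

    def test_phantom_hu_round_trips_to_unit_scale(self):
        vol, _, _ = generate_phantom_volume(2, seed=9)
        out = normalize_intensity(vol)
        assert out.min() >= 0.0 and out.max() <= 1.0


class TestSplit:
    def _pairs(self, n_per_volume=10, volumes=("a", "b", "c")):
        img = np.zeros((8, 8), np.float32)
        return [SlicePair(img, np.zeros((8, 8), np.uint8), vid, k)
                for vid in volumes for k in range(n_per_volume)]

    def test_four_to_one_ratio_within_each_volume(self):
        train, val = split_train_val(self._pairs(), seed=1)
        assert len(train) == 24 and len(val) == 6
        for vid in "abc":
            n_train = sum(p.volume_id == vid for p in train)
            assert abs(n_train - 8) <= 1

    def test_no_slice_in_both_lists(self):
        train, val = split_train_val(self._pairs(), seed=2)
        train_keys = {(p.volume_id, p.slice_index) for p in train}
        val_keys = {(p.volume_id, p.slice_index) for p in val}
        assert not train_keys & val_keys
        assert len(train_keys | val_keys) == 30

    def test_held_out_volume_never_leaks(self):
        pairs = self._pairs(volumes=("a", "b"))
        train, val = split_train_val(pairs, seed=3)
        assert all(p.volume_id in ("a", "b") for p in train + val)
        # a volume that was excluded from the input cannot appear downstream
        assert not any(p.volume_id == "test-volume" for p in train + val)

    def test_deterministic_given_seed(self):
        t1, v1 = split_train_val(self._pairs(), seed=4)
        t2, v2 = split_train_val(self._pairs(), seed=4)
        assert [(p.volume_id, p.slice_index) for p in t1] == \
               [(p.volume_id, p.slice_index) for p in t2]
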