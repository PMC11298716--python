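"""Synthetic corpus generation, preprocessing, augmentation, sampling, I/O."""

import numpy as np
import pytest
from scipy import stats

from semiseg.data import (Subject, SyntheticConfig, augment,
                          generate_synthetic_dataset, load_dataset,
                          normalize_image, random_crop, read_mask,
                          save_dataset, two_stream_batches, write_mask)


def small_config(**kwargs):
    defaults = dict(n_subjects=10, shape=(32, 32), n_classes=2,
                    labeled_proportion=0.2, noise_sd=0.3, min_radius=4,
                    max_radius=8, seed=1)
    defaults.update(kwargs)
    return SyntheticConfig(**defaults)


class TestSubject:
    def test_mask_hidden_when_unlabeled(self, rng):
        vol = rng.standard_normal((8, 8))
        mask = rng.integers(0, 2, (8, 8))
        s = Subject("a", vol, mask, labeled=False)
        assert s.mask is None
        assert np.array_equal(s.ground_truth, mask)

    def test_labeled_requires_mask(self, rng):
        with pytest.raises(ValueError):
            Subject("a", rng.standard_normal((4, 4)), None, labeled=True)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            Subject("a", rng.standard_normal((4, 4)),
                    np.zeros((5, 5), int), labeled=True)


class TestGenerator:
    def test_labeled_count_rounds(self):
        subjects = generate_synthetic_dataset(small_config())
        assert sum(s.labeled for s in subjects) == 2  # round(0.2 * 10)

    def test_subject_level_split(self):
        subjects = generate_synthetic_dataset(small_config())
        for s in subjects:
            assert (s.mask is not None) == s.labeled
            assert s.ground_truth is not None

    def test_deterministic_for_seed(self):
        a = generate_synthetic_dataset(small_config())
        b = generate_synthetic_dataset(small_config())
        for s, t in zip(a, b):
            assert np.array_equal(s.volume, t.volume)
            assert np.array_equal(s.ground_truth, t.ground_truth)

    def test_noiseless_threshold_recovers_mask_exactly(self):
        subjects = generate_synthetic_dataset(small_config(noise_sd=0.0))
        for s in subjects:
            fg_vals = np.unique(s.volume[s.ground_truth > 0])
            assert len(fg_vals) == 1  # one constant foreground intensity
            recovered = (s.volume > fg_vals[0] / 2).astype(int)
            assert np.array_equal(recovered, (s.ground_truth > 0).astype(int))

    def test_classes_non_overlapping_3class(self):
        subjects = generate_synthetic_dataset(small_config(n_classes=3))
        for s in subjects:
            assert set(np.unique(s.ground_truth)) == {0, 1, 2}

    def test_too_few_labeled_rejected(self):
        with pytest.raises(ValueError):
            small_config(n_subjects=5, labeled_proportion=0.1)

    def test_3d_generation(self):
        subjects = generate_synthetic_dataset(
            small_config(n_subjects=5, shape=(8, 16, 16), min_radius=2,
                         max_radius=4))
        assert subjects[0].volume.shape == (8, 16, 16)


class TestNormalize:
    def test_two_point_example(self):
        out = normalize_image(np.array([2.0, 4.0]))
        assert np.allclose(out, [-1.0, 1.0])

    def test_constant_volume_guard(self):
        assert np.array_equal(normalize_image(np.full((4, 4), 7.0)),
                              np.zeros((4, 4)))

    def test_output_moments(self, rng):
        out = normalize_image(rng.standard_normal((16, 16)) * 3 + 5)
        assert abs(out.mean()) < 1e-6
        assert abs(out.std() - 1.0) < 1e-6

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            normalize_image(np.array([]))


class TestRandomCrop:
    def test_identity_crop(self, rng):
        vol = rng.standard_normal((8, 8, 8))
        patch, _ = random_crop(vol, None, (8, 8, 8), rng)
        assert np.array_equal(patch, vol)

    def test_mask_cropped_identically(self, rng):
        vol = rng.standard_normal((16, 16))
        mask = (vol > 0).astype(int)
        patch, pm = random_crop(vol, mask, (8, 8), np.random.default_rng(0))
        assert pm.shape == (8, 8)
        assert np.array_equal((patch > 0).astype(int), pm)

    def test_oversized_patch_rejected(self, rng):
        with pytest.raises(ValueError):
            random_crop(np.zeros((4, 4)), None, (8, 8), rng)

    def test_offsets_uniform_chi2(self):
        """Offset histogram over repeated draws is consistent with uniform."""
        rng = np.random.default_rng(0)
        vol = np.zeros((12, 4))
        counts = np.zeros(9, int)  # offsets 0..8 along axis 0
        marks = np.arange(12.0)
        vol[:, 0] = marks
        n = 4000
        for _ in range(n):
            patch, _ = random_crop(vol, None, (4, 4), rng)
            counts[int(patch[0, 0])] += 1
        chi2 = ((counts - n / 9) ** 2 / (n / 9)).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=8)


class TestAugment:
    def test_flip_is_involution(self, rng):
        img = rng.standard_normal((8, 8))
        # draw a flip configuration, apply twice manually
        flipped = np.flip(img, axis=0)
        again = np.flip(flipped, axis=0)
        assert np.array_equal(again, img)

    def test_mask_label_set_preserved_and_geometry_shared(self, rng):
        img = rng.standard_normal((8, 8))
        mask = rng.integers(0, 3, (8, 8))
        out_img, out_mask = augment(img, mask, {"rotate", "flip"},
                                    np.random.default_rng(5))
        assert set(np.unique(out_mask)) <= set(np.unique(mask))
        assert out_img.shape == img.shape
        # same transform applied to both: positional correspondence survives
        src = np.argwhere(mask == mask.max())[0]
        assert (out_mask == mask.max()).sum() == (mask == mask.max()).sum()

    def test_jitter_changes_image_not_mask(self, rng):
        img = rng.standard_normal((8, 8))
        mask = rng.integers(0, 2, (8, 8))
        out_img, out_mask = augment(img, mask, {"jitter"}, np.random.default_rng(2))
        assert not np.array_equal(out_img, img)
        assert np.array_equal(out_mask, mask)

    def test_unknown_op_rejected(self, rng):
        with pytest.raises(ValueError):
            augment(np.zeros((4, 4)), None, {"zoom"}, rng)

    def test_rot90_exact_on_masks(self, rng):
        img = rng.standard_normal((6, 6))
        mask = rng.integers(0, 4, (6, 6))
        out_img, out_mask = augment(img, mask, {"rotate"}, np.random.default_rng(1))
        # find which k was applied from the image, check mask used the same
        for k in range(4):
            if np.array_equal(out_img, np.rot90(img, k)):
                assert np.array_equal(out_mask, np.rot90(mask, k))
                break
        else:
            pytest.fail("rotation was not a multiple of 90 degrees")


class TestTwoStream:
    def test_fixed_labeled_count_per_batch(self, rng):
        gen = two_stream_batches([f"l{i}" for i in range(4)],
                                 [f"u{i}" for i in range(20)],
                                 batch_size=6, n_labeled_per_batch=3, rng=rng)
        for _ in range(10):
            lab, unl = next(gen)
            assert len(lab) == 3 and len(unl) == 3

    def test_epoch_without_replacement(self, rng):
        """Every unlabeled id appears once before any repeats."""
        unl = [f"u{i}" for i in range(12)]
        gen = two_stream_batches(["l0"], unl, batch_size=4,
                                 n_labeled_per_batch=1, rng=rng, epochs=1)
        seen = []
        for lab, ub in gen:
            seen.extend(ub)
        assert sorted(seen) == sorted(unl)

    def test_duplication_mode_tiles_labeled_pool(self, rng):
        lab = [f"l{i}" for i in range(8)]
        unl = [f"u{i}" for i in range(72)]
        gen = two_stream_batches(lab, unl, batch_size=24,
                                 n_labeled_per_batch=0, rng=rng,
                                 mode="duplication", epochs=1)
        lab_seen = unl_seen = 0
        for lb, ub in gen:
            lab_seen += len(lb)
            unl_seen += len(ub)
        assert lab_seen + unl_seen == 144  # tiled labeled (72) + unlabeled (72)

    def test_empty_labeled_pool_rejected(self, rng):
        with pytest.raises(ValueError):
            next(two_stream_batches([], ["u0"], 2, 1, rng))

    def test_invalid_mix_rejected(self, rng):
        with pytest.raises(ValueError):
            next(two_stream_batches(["l0"], ["u0"], batch_size=4,
                                    n_labeled_per_batch=4, rng=rng))


class TestIO:
    def test_png_stack_mask_roundtrip(self, tmp_path, rng):
        mask = rng.integers(0, 3, size=(5, 8, 8))
        write_mask(tmp_path / "m", mask, format="png_stack")
        back = read_mask(tmp_path / "m", format="png_stack")
        assert back.shape == (5, 8, 8)
        assert np.array_equal(back, mask)

    def test_nifti_mask_roundtrip(self, tmp_path, rng):
        mask = rng.integers(0, 4, size=(4, 6, 6))
        write_mask(tmp_path / "m.nii.gz", mask, format="nifti")
        back = read_mask(tmp_path / "m.nii.gz", format="nifti")
        assert np.array_equal(back, mask)

    def test_float_mask_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_mask(tmp_path / "m", np.zeros((2, 2)), format="png_stack")

    def test_dataset_roundtrip_preserves_split_and_spacing(self, tmp_path):
        subjects = generate_synthetic_dataset(small_config(n_subjects=4,
                                                           labeled_proportion=0.5))
        subjects[0].spacing = (1.25, 2.5)
        save_dataset(subjects, tmp_path / "ds")
        back = load_dataset(tmp_path / "ds")
        assert [s.labeled for s in back] == [s.labeled for s in subjects]
        for orig, new in zip(subjects, back):
            assert np.allclose(orig.volume, new.volume, atol=1e-6)
            if orig.labeled:
                assert np.array_equal(orig.mask, new.mask)
        assert back[0].spacing == (1.25, 2.5)

    def test_mixed_slice_shapes_rejected(self, tmp_path):
        import imageio.v2 as imageio
        d = tmp_path / "stack"
        d.mkdir()
        imageio.imwrite(d / "0000.png", np.zeros((4, 4), np.uint8))
        imageio.imwrite(d / "0001.png", np.zeros((6, 6), np.uint8))
        with pytest.raises(ValueError):
            read_mask(d, format="png_stack")
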