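"""Phantom generator: reproducibility, anatomy/contrast structure, augmentation."""

import numpy as np
import pytest
from scipy.ndimage import binary_dilation, binary_fill_holes

from natseg.errors import InvalidConfigError, ShapeError
from natseg.metrics import evaluate_case
from natseg.phantom import (PhantomSpec, center_crop, generate_phantom,
                            make_dataset, random_rotate, random_warp)
from natseg.vocab import BACKGROUND, EDEMA, INFARCT, LV, MYO, NUM_CLASSES, RV

SPEC = PhantomSpec(image_size=96, seed=7)


class TestGenerate:
    def test_same_spec_and_seed_is_bit_identical(self):
        a = generate_phantom(SPEC, 3)
        b = generate_phantom(SPEC, 3)
        np.testing.assert_array_equal(a.label, b.label)
        for ia, ib in zip(a.images, b.images):
            np.testing.assert_array_equal(ia, ib)
        c = generate_phantom(SPEC, 4)
        assert not np.array_equal(a.label, c.label)

    def test_labels_partition_image_over_vocabulary(self):
        case = generate_phantom(SPEC, 0)
        assert case.label.shape == (96, 96)
        assert set(np.unique(case.label)) <= set(range(NUM_CLASSES))
        for k in (LV, RV, MYO, EDEMA, INFARCT):
            assert (case.label == k).any(), k

    def test_noiseless_modality_contrast_ordering(self):
        spec = PhantomSpec(image_size=96, seed=1, noise_sigma=0.0,
                           boundary_blur_sigma=0.0)
        case = generate_phantom(spec, 0)
        bssfp, lge, t2 = case.images
        infarct, myo = case.label == INFARCT, case.label == MYO
        edema = case.label == EDEMA
        assert lge[infarct].mean() > lge[myo].mean()       # LGE bright in infarct
        assert t2[edema].mean() > t2[myo].mean()           # T2 bright in edema
        blood = (case.label == LV) | (case.label == RV)
        assert abs(bssfp[blood].mean() - bssfp[myo].mean()) > 0.3  # bSSFP contrast

    def test_pathology_confined_to_annulus(self):
        case = generate_phantom(SPEC, 2)
        annulus = np.isin(case.label, (MYO, EDEMA, INFARCT))
        filled = binary_fill_holes(annulus)
        assert ((case.label == INFARCT) <= filled).all()
        # edema flanks the infarct inside the annulus
        assert (binary_dilation(case.label == INFARCT) & (case.label == EDEMA)).any()

    def test_self_evaluation_is_perfect(self):
        case = generate_phantom(SPEC, 5)
        res = evaluate_case(case.label, case.label)
        assert all(v == 1.0 for v in res.dice.values())

    def test_unfittable_geometry_rejected(self):
        with pytest.raises(InvalidConfigError):
            PhantomSpec(image_size=96, lv_radius=(0.3, 0.35), myo_thickness=(0.1, 0.15))

    def test_too_small_image_rejected(self):
        with pytest.raises(InvalidConfigError):
            PhantomSpec(image_size=32)


class TestCenterCrop:
    def test_equal_margins(self, rng):
        img = rng.random((320, 320))
        out = center_crop(img, 288)
        np.testing.assert_array_equal(out, img[16:304, 16:304])

    def test_crop_to_own_size_is_identity(self, rng):
        img = rng.random((64, 64))
        np.testing.assert_array_equal(center_crop(img, 64), img)

    def test_odd_margin_goes_low_side(self):
        img = np.arange(25).reshape(5, 5)
        out = center_crop(img, 4)
        np.testing.assert_array_equal(out, img[0:4, 0:4])

    def test_hot_pixel_survives_iff_inside_window(self):
        img = np.zeros((10, 10))
        img[1, 1] = 1.0
        assert center_crop(img, 8).sum() == 1.0   # window rows 1..8
        assert center_crop(img, 6).sum() == 0.0   # window rows 2..7

    def test_upscaling_rejected(self):
        with pytest.raises(ShapeError):
            center_crop(np.zeros((4, 4)), 8)


class TestRandomWarp:
    def test_zero_amplitude_is_identity(self, rng):
        img = rng.random((32, 32))
        lab = rng.integers(0, 6, (32, 32))
        wi, wl = random_warp(img, lab, amplitude=0.0, seed=0)
        np.testing.assert_allclose(wi, img, atol=1e-12)
        np.testing.assert_array_equal(wl, lab)

    def test_label_vocabulary_preserved(self, rng):
        lab = rng.integers(0, 6, (48, 48))
        img = rng.random((48, 48))
        _, wl = random_warp(img, lab, amplitude=4.0, seed=1)
        assert set(np.unique(wl)) <= set(np.unique(lab))

    def test_identical_seed_warps_image_and_label_consistently(self):
        case = generate_phantom(SPEC, 0)
        wi0, wl0 = random_warp(case.images[0], case.label, 4.0, seed=9)
        wi1, wl1 = random_warp(case.images[0], case.label, 4.0, seed=9)
        np.testing.assert_array_equal(wl0, wl1)
        np.testing.assert_array_equal(wi0, wi1)

    def test_topology_survives_small_warp_and_rotation(self):
        for case_seed in range(3):
            case = generate_phantom(SPEC, case_seed)
            _, lab = random_warp(case.images[0], case.label, 4.0, seed=case_seed)
            _, lab = random_rotate(case.images[0][:96, :96], lab, seed=case_seed)
            annulus = np.isin(lab, (MYO, EDEMA, INFARCT))
            filled = binary_fill_holes(annulus)
            infarct = lab == INFARCT
            assert infarct.any()
            assert (infarct <= filled).all()
            assert not (infarct & np.isin(lab, (LV, RV))).any()


class TestRandomRotate:
    def test_class_pixel_counts_invariant(self):
        case = generate_phantom(SPEC, 1)
        _, rl = random_rotate(case.images[0], case.label, seed=4)
        for k in range(NUM_CLASSES):
            assert (rl == k).sum() == (case.label == k).sum()

    def test_four_quarter_turns_compose_to_identity(self, rng):
        img = rng.random((8, 8))
        out = img
        for _ in range(4):
            out = np.rot90(out, 1)
        np.testing.assert_array_equal(out, img)

    def test_angles_drawn_uniformly(self):
        counts = {1: 0, 2: 0, 3: 0}
        img = np.zeros((4, 4))
        img[0, 1] = 1.0
        lab = np.zeros((4, 4), dtype=int)
        for seed in range(3000):
            ri, _ = random_rotate(img, lab, seed=seed)
            k = {(2, 0): 1, (3, 2): 2, (1, 3): 3}[tuple(np.argwhere(ri == 1.0)[0])]
            counts[k] += 1
        for k in counts:
            assert abs(counts[k] / 3000 - 1 / 3) < 0.03

    def test_non_square_rejected(self):
        with pytest.raises(ShapeError):
            random_rotate(np.zeros((4, 6)), np.zeros((4, 6), dtype=int), seed=0)


class TestMakeDataset:
    def test_four_to_one_split_of_25_cases(self):
        split = make_dataset(SPEC, 25, split_ratio=0.2, seed=0)
        assert len(split.train_idx) == 20
        assert len(split.test_idx) == 5
        assert sorted(split.train_idx + split.test_idx) == list(range(25))

    def test_folds_are_disjoint_and_cover_all_cases(self):
        split = make_dataset(SPEC, 25, seed=1)
        seen = [i for fold in split.folds for i in fold]
        assert sorted(seen) == list(range(25))
        assert len(split.folds) == 5

    def test_same_seed_reproduces_split(self):
        a = make_dataset(SPEC, 10, seed=3)
        b = make_dataset(SPEC, 10, seed=3)
        assert a.train_idx == b.train_idx and a.test_idx == b.test_idx
        assert a.folds == b.folds

    def test_fewer_cases_than_folds_rejected(self):
        with pytest.raises(InvalidConfigError):
            make_dataset(SPEC, 4)
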