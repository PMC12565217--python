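"""Losses and segmentation metrics against closed forms, brute-force set
arithmetic and library oracles (skimage SSIM, scipy distances)."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from ctprep.autodiff import Tensor
from ctprep.losses_metrics import (MaskVolume, boundary_points, dice2d,
                                   dice3d, dice_loss, dice_loss_t, hausdorff,
                                   iou3d, jaccard2d, loss_preproc,
                                   loss_preproc_t, metric_report, ssim,
                                   ssim_t, trimap_f)


def const_ssim(a: float, b: float) -> float:
    """Closed-form SSIM of two constant images (variance terms vanish)."""
    c1 = 0.01 ** 2
    return (2 * a * b + c1) / (a * a + b * b + c1)


class TestSSIM:
    def test_self_similarity_is_one(self, rng):
        a = rng.uniform(0, 1, (32, 32))
        assert ssim(a, a) == pytest.approx(1.0)

    def test_constant_images_closed_form(self):
        a = np.full((32, 32), 0.5)
        b = np.full((32, 32), 0.6)
        assert ssim(a, b) == pytest.approx(const_ssim(0.5, 0.6), abs=1e-12)
        assert const_ssim(0.5, 0.6) == pytest.approx(0.9836, abs=1e-4)

    def test_inverted_image_dissimilar(self, rng):
        a = rng.uniform(0, 1, (32, 32))
        assert ssim(a, 1 - a) < 1.0

    def test_symmetry_and_channel_triplication(self, rng):
        a = rng.uniform(0, 1, (24, 24))
        b = rng.uniform(0, 1, (24, 24))
        assert ssim(a, b) == pytest.approx(ssim(b, a), abs=1e-14)
        a3 = np.broadcast_to(a, (3, 24, 24))
        b3 = np.broadcast_to(b, (3, 24, 24))
        assert ssim(a3, b3) == pytest.approx(ssim(a, b), abs=1e-14)

    def test_matches_skimage_exactly(self, rng):
        from skimage.metrics import structural_similarity

        for _ in range(5):
            a = rng.uniform(0, 1, (48, 48))
            b = np.clip(a + rng.normal(0, 0.08, a.shape), 0, 1)
            ref = structural_similarity(a, b, gaussian_weights=True, sigma=1.5,
                                        use_sample_covariance=False,
                                        data_range=1.0)
            assert ssim(a, b) == pytest.approx(ref, abs=1e-12)

    def test_tensor_version_agrees_with_numpy(self, rng):
        a = rng.uniform(0, 1, (2, 3, 32, 32))
        b = np.clip(a + rng.normal(0, 0.05, a.shape), 0, 1)
        per_image = np.mean([ssim(a[i], b[i]) for i in range(2)])
        tensor_val = float(ssim_t(Tensor(a), Tensor(b)).data)
        assert tensor_val == pytest.approx(per_image, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ssim(np.zeros((16, 16)), np.zeros((16, 17)))


class TestRestorationLoss:
    def test_zero_for_identical(self, rng):
        a = rng.uniform(0, 1, (32, 32))
        assert loss_preproc(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_constant_images_hand_value(self):
        a = np.full((32, 32), 0.2)
        b = np.full((32, 32), 0.5)
        expected = 0.3 + (1 - const_ssim(0.2, 0.5))
        assert loss_preproc(a, b) == pytest.approx(expected, abs=1e-12)

    def test_nonnegative(self, rng):
        for _ in range(10):
            a = rng.uniform(0, 1, (24, 24))
            b = rng.uniform(0, 1, (24, 24))
            assert loss_preproc(a, b) >= 0

    def test_rejects_negative_weights(self):
        with pytest.raises(ValueError):
            loss_preproc(np.zeros((16, 16)), np.zeros((16, 16)), weight_ssim=-1)
        with pytest.raises(ValueError):
            loss_preproc_t(Tensor(np.zeros((1, 1, 16, 16))),
                           Tensor(np.zeros((1, 1, 16, 16))), weight_l1=-0.5)


class TestDiceLoss:
    def test_perfect_binary_prediction_near_zero(self):
        core = np.zeros((1, 8, 8), bool)
        core[0, 2:4, 2:4] = True
        pen = np.zeros((1, 8, 8), bool)
        pen[0, 5:7, 5:7] = True
        vol = MaskVolume(core, pen)
        pred = np.stack([core, pen, ~(core | pen)], axis=1).astype(float)
        assert dice_loss(pred, vol) == pytest.approx(0.0, abs=0.1)

    def test_empty_prediction_and_target(self):
        zeros = np.zeros((1, 3, 4, 4))
        target = np.zeros((1, 3, 4, 4))
        assert float(dice_loss_t(Tensor(zeros), Tensor(target)).data) \
            == pytest.approx(0.0)

    def test_hand_value_overlap_two_of_four(self):
        pred = np.zeros((1, 3, 4, 4))
        tgt = np.zeros((1, 3, 4, 4))
        pred[0, 0, 0, :4] = 1          # core: 4 px row
        tgt[0, 0, 0, 2:] = 1
        tgt[0, 0, 1, :2] = 1           # overlap 2, sizes 4/4
        pred[0, 1] = tgt[0, 1] = 0     # penumbra empty on both
        loss = float(dice_loss_t(Tensor(pred), Tensor(tgt)).data)
        core_dice = (2 * 2 + 1) / (4 + 4 + 1)
        pen_dice = 1.0                 # eps convention
        assert loss == pytest.approx(1 - 0.5 * (core_dice + pen_dice), abs=1e-12)


class TestOverlapMetrics:
    def test_identical_and_disjoint(self):
        a = np.zeros((6, 6), bool)
        a[1:3, 1:3] = True
        b = np.zeros((6, 6), bool)
        b[4:6, 4:6] = True
        assert dice2d(a, a) == 1.0 and jaccard2d(a, a) == 1.0
        assert dice2d(a, b) == 0.0 and jaccard2d(a, b) == 0.0

    def test_counting_example(self):
        p = np.zeros((4, 4), bool)
        t = np.zeros((4, 4), bool)
        p[0, :4] = True
        t[0, 2:] = True
        t[1, :2] = True
        assert dice2d(p, t) == pytest.approx(0.5)
        assert jaccard2d(p, t) == pytest.approx(1 / 3)

    def test_both_empty_convention(self):
        z = np.zeros((4, 4), bool)
        assert dice2d(z, z) == 1.0 and jaccard2d(z, z) == 1.0

    def test_volumetric_example(self):
        # slice A: overlap 2 of 4/4; slice B: disjoint 2/2
        p = np.zeros((2, 4, 4), bool)
        t = np.zeros((2, 4, 4), bool)
        p[0, 0, :4] = True
        t[0, 0, 2:] = True
        t[0, 1, :2] = True
        p[1, 0, :2] = True
        t[1, 3, :2] = True
        assert dice3d(p, t) == pytest.approx(2 * 2 / (6 + 6))
        assert iou3d(p, t) == pytest.approx(2 / 10)

    def test_dice_jaccard_identity_on_random_volumes(self, rng):
        for _ in range(100):
            p = rng.uniform(size=(4, 8, 8)) < 0.4
            t = rng.uniform(size=(4, 8, 8)) < 0.4
            d, j = dice3d(p, t), iou3d(p, t)
            assert d == pytest.approx(2 * j / (1 + j), abs=1e-12)

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError):
            dice2d(np.full((3, 3), 0.5), np.zeros((3, 3)))


class TestHausdorff:
    def test_identical_sets_zero(self):
        pts = np.array([[0, 0], [1, 2]])
        for mode in ("max", "hd95", "assd"):
            assert hausdorff(pts, pts, mode) == 0.0

    def test_euclidean_pair(self):
        assert hausdorff(np.array([[0, 0]]), np.array([[3, 4]])) == 5.0

    def test_spacing_converts_to_mm(self):
        a = np.zeros((1, 8, 8), bool)
        b = np.zeros((1, 8, 8), bool)
        a[0, 2, 2] = True
        b[0, 2, 4] = True   # 2 px apart in x at 0.5 mm/px
        assert hausdorff(a, b, "max", (5.0, 0.5, 0.5)) == pytest.approx(1.0)

    def test_symmetry_max_and_assd(self, rng):
        for _ in range(20):
            a = rng.uniform(size=(5, 8, 8)) < 0.3
            b = rng.uniform(size=(5, 8, 8)) < 0.3
            if not a.any() or not b.any():
                continue
            for mode in ("max", "assd"):
                assert hausdorff(a, b, mode) == pytest.approx(
                    hausdorff(b, a, mode))

    def test_hd95_bounded_by_max(self, rng):
        for _ in range(50):
            a = rng.uniform(size=(4, 8, 8)) < 0.3
            b = rng.uniform(size=(4, 8, 8)) < 0.3
            if not a.any() or not b.any():
                continue
            assert hausdorff(a, b, "hd95") <= hausdorff(a, b, "max") + 1e-12

    def test_monotone_under_dilation_away(self):
        from scipy import ndimage

        t = np.zeros((16, 16), bool)
        t[7:9, 7:9] = True
        prev = 0.0
        p = t.copy()
        for _ in range(3):
            p = ndimage.binary_dilation(p)
            d = hausdorff(p, t, "max")
            assert d >= prev
            prev = d

    def test_empty_set_is_defined_error(self):
        with pytest.raises(ValueError, match="undefined"):
            hausdorff(np.zeros((4, 4), bool), np.ones((4, 4), bool))

    def test_brute_force_distance_oracle(self, rng):
        for _ in range(20):
            a = rng.uniform(size=(3, 6, 6)) < 0.35
            b = rng.uniform(size=(3, 6, 6)) < 0.35
            if not a.any() or not b.any():
                continue
            sp = np.array([2.0, 0.7, 0.7])
            pa = boundary_points(a) * sp
            pb = boundary_points(b) * sp
            d = cdist(pa, pb)
            assert hausdorff(a, b, "max", sp) == pytest.approx(
                max(d.min(1).max(), d.min(0).max()))
            assert hausdorff(a, b, "assd", sp) == pytest.approx(
                (d.min(1).sum() + d.min(0).sum()) / (len(pa) + len(pb)))


class TestTrimapF:
    def test_perfect_prediction(self):
        t = np.zeros((16, 16), bool)
        t[5:11, 5:11] = True
        assert trimap_f(t, t) == 1.0

    def test_overdilated_prediction_penalized(self):
        from scipy import ndimage

        t = np.zeros((32, 32), bool)
        t[12:20, 12:20] = True
        p = ndimage.binary_dilation(t, iterations=7)
        assert trimap_f(p, t, band=5) < 1.0

    def test_band_saturation_equals_global_f(self, rng):
        t = rng.uniform(size=(10, 10)) < 0.4
        p = rng.uniform(size=(10, 10)) < 0.4
        if not t.any():
            t[0, 0] = True
        f_big = trimap_f(p, t, band=100)
        tp = (p & t).sum()
        if tp == 0:
            assert f_big == 0.0
        else:
            prec, rec = tp / p.sum(), tp / t.sum()
            assert f_big == pytest.approx(2 * prec * rec / (prec + rec))

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            trimap_f(np.ones((4, 4), bool), np.zeros((4, 4), bool))


class TestMetricReport:
    def test_report_fields_and_skip_counting(self, rng):
        core_t = rng.uniform(size=(3, 16, 16)) < 0.1
        pen_t = (rng.uniform(size=(3, 16, 16)) < 0.1) & ~core_t
        true = MaskVolume(core_t, pen_t)
        pred = MaskVolume(np.zeros_like(core_t), pen_t)   # misses all core
        rep = metric_report(pred, true)
        assert rep.dice3d["penumbra"] == 1.0
        assert rep.hd95["core"] is None or rep.hd95["core"] >= 0
        assert rep.skipped_empty["core"] in (0, 1)
        d = rep.to_dict()
        assert set(d) == {"dice2d", "jaccard2d", "dice3d", "iou3d", "hd3d",
                          "hd95", "assd", "trimap_f", "skipped_empty",
                          "z_interpolated"}
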