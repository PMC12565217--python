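"""Filter transforms vs independent brute-force oracles and hand-derived
values from the kernel definitions."""

import numpy as np
import pytest

from ctprep.autodiff import Tensor
from ctprep.filter_bank import (ContrastParam, GaussianSpec,
                                KernelBank, SHARPNESS_K, SHARPNESS_M,
                                brightness_apply, contrast_apply,
                                gaussian_blur, gaussian_kernel,
                                kernel_combo_apply, median_apply, residual,
                                sharpness_apply, sharpness_nu)


def dense_conv2d_oracle(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Brute-force dense 2-D correlation with reflect padding (pure loops
    over output pixels; independent of the engine's im2col path)."""
    k = kernel.shape[0] // 2
    pad = np.pad(img, k, mode="reflect")
    out = np.zeros_like(img)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            out[i, j] = (pad[i:i + 2 * k + 1, j:j + 2 * k + 1] * kernel).sum()
    return out


class TestGaussianKernel:
    def test_hand_evaluated_center_weight_sigma1(self):
        # G(0,0), G(±1,0), G(±1,±1) at sigma=1, then renormalized
        kern = gaussian_kernel(GaussianSpec(sigma=1.0, k=1))
        g0, g1, g2 = (np.exp(0) / (2 * np.pi),
                      np.exp(-0.5) / (2 * np.pi),
                      np.exp(-1.0) / (2 * np.pi))
        expected = g0 / (g0 + 4 * g1 + 4 * g2)
        assert kern[1, 1] == pytest.approx(expected, abs=1e-6)
        assert kern[1, 1] == pytest.approx(0.2042, abs=2e-4)

    def test_central_symmetry(self, rng):
        for _ in range(20):
            sigma = rng.uniform(0.05, 3.0)
            k = int(rng.integers(1, 4))
            kern = gaussian_kernel(GaussianSpec(sigma=sigma, k=k))
            assert np.allclose(kern, kern[::-1, ::-1])
            assert np.allclose(kern, kern.T)
            assert kern.sum() == pytest.approx(1.0, abs=1e-12)

    def test_tiny_sigma_approaches_delta(self):
        kern = gaussian_kernel(GaussianSpec(sigma=0.01, k=2))
        assert kern[2, 2] > 0.999

    def test_rejects_bad_sigma(self):
        with pytest.raises(ValueError):
            GaussianSpec(sigma=0.0)


class TestGaussianBlur:
    def test_constant_preserved(self):
        img = np.full((3, 9, 9), 0.4)
        out = gaussian_blur(img, GaussianSpec(sigma=0.8))
        assert np.allclose(out, 0.4)

    def test_single_bright_pixel_spreads_like_kernel(self):
        img = np.zeros((9, 9))
        img[4, 4] = 1.0
        out = gaussian_blur(img, GaussianSpec(sigma=1.0, k=2))
        kern = gaussian_kernel(GaussianSpec(sigma=1.0, k=2))
        assert np.allclose(out[2:7, 2:7], kern, atol=1e-12)

    def test_matches_dense_oracle(self, rng):
        img = rng.uniform(0, 1, (11, 11))
        spec = GaussianSpec(sigma=1.3, k=2)
        out = gaussian_blur(img, spec)
        assert np.abs(out - dense_conv2d_oracle(img, gaussian_kernel(spec))).max() <= 1e-6


class TestSharpness:
    def test_printed_matrix_sums(self):
        assert SHARPNESS_K.sum() == -256
        assert SHARPNESS_M.sum() == pytest.approx(21.0)
        assert sharpness_nu(0) == -256
        assert sharpness_nu(1) == -235
        assert sharpness_nu(-1) == -277

    def test_matrices_symmetric_under_rotation_and_transpose(self):
        for mat in (SHARPNESS_K, SHARPNESS_M):
            assert np.array_equal(mat, np.rot90(mat))
            assert np.array_equal(mat, mat.T)

    @pytest.mark.parametrize("q", [-1.0, -0.5, 0.0, 0.5, 1.0])
    def test_normalized_kernel_sums_to_one(self, q):
        kern = (SHARPNESS_K + SHARPNESS_M * q) / sharpness_nu(q)
        assert kern.sum() == pytest.approx(1.0, abs=1e-12)

    def test_constant_preserved_for_any_q(self, rng):
        img = np.full((3, 8, 8), 0.6)
        q = rng.uniform(-1, 1, 3)
        assert np.allclose(sharpness_apply(img, q), 0.6)

    def test_matches_dense_oracle(self, rng):
        img = rng.uniform(0, 1, (3, 9, 9))
        q = np.array([0.3, -0.7, 0.0])
        out = sharpness_apply(img, q)
        for c in range(3):
            kern = (SHARPNESS_K + SHARPNESS_M * q[c]) / sharpness_nu(q[c])
            assert np.abs(out[c] - dense_conv2d_oracle(img[c], kern)).max() <= 1e-6

    def test_rejects_out_of_range_q(self):
        with pytest.raises(ValueError):
            sharpness_apply(np.zeros((3, 5, 5)), np.array([1.5, 0, 0]))


class TestContrast:
    def test_identity_at_zero(self, rng):
        img = rng.uniform(0, 1, (6, 6))
        assert np.allclose(contrast_apply(img, 0.0), img)

    def test_hand_values_default_and_literal(self):
        img = np.full((2, 2), 0.75)
        assert np.allclose(contrast_apply(img, 0.5), 1.0)          # 0.5 + 0.25*2
        assert np.allclose(contrast_apply(img, 0.5, literal=True), 0.5)

    def test_negative_r_compresses(self):
        img = np.array([[0.0, 1.0]])
        out = contrast_apply(img, -0.5)   # scale 1.5 -> compress by 1.5? no: (1-r)=1.5
        assert np.allclose(out, 0.5 + (img - 0.5) * 1.5)

    def test_order_preserving_and_bijective_for_nonpositive_r(self, rng):
        img = np.sort(rng.uniform(0, 1, 16)).reshape(4, 4)
        for r in (-0.9, -0.3, 0.0):
            out = contrast_apply(img, r)
            assert np.all(np.diff(out.ravel()) >= 0)
        # r <= 0 keeps [0,1] inside [0,1]? scale (1-r) >= 1 expands... the
        # bijection claim is about invertibility of the affine map
        out = contrast_apply(img, -0.5)
        back = 0.5 + (out - 0.5) / 1.5
        assert np.allclose(back, img)

    def test_rejects_r_equal_one(self):
        with pytest.raises(ValueError):
            contrast_apply(np.zeros((2, 2)), 1.0)
        with pytest.raises(ValueError):
            ContrastParam(1.0)


class TestBrightnessAndMedian:
    def test_brightness_additive(self):
        img = np.full((4, 4), 0.4)
        assert np.allclose(brightness_apply(img, 0.2), 0.6)
        assert np.allclose(brightness_apply(img, 0.0), img)

    def test_brightness_preclip_value(self):
        out = brightness_apply(np.full((2, 2), 0.95), 0.2)
        assert np.allclose(out, 1.15)          # clip deferred to the pipeline
        assert np.allclose(np.clip(out, 0, 1), 1.0)

    def test_median_constant(self):
        assert np.allclose(median_apply(np.full((5, 5), 0.3)), 0.3)

    def test_median_is_fifth_order_statistic(self):
        img = np.array([[0, 0, 0], [0, 1, 1], [1, 1, 1]], dtype=float)
        assert median_apply(img)[1, 1] == 1.0

    def test_median_removes_salt_pixel(self):
        img = np.full((7, 7), 0.2)
        img[3, 3] = 1.0
        assert median_apply(img)[3, 3] == 0.2

    def test_median_matches_order_statistic_oracle(self, rng):
        img = rng.uniform(0, 1, (9, 9))
        out = median_apply(img)
        pad = np.pad(img, 1, mode="reflect")
        for i in range(9):
            for j in range(9):
                assert out[i, j] == np.sort(pad[i:i + 3, j:j + 3].ravel())[4]

    def test_median_rejects_even_window(self):
        with pytest.raises(ValueError):
            median_apply(np.zeros((5, 5)), window=4)


class TestKernelCombo:
    def test_delta_kernel_is_identity(self, rng):
        delta = np.zeros((5, 5))
        delta[2, 2] = 1.0
        bank = KernelBank([delta])
        img = rng.uniform(0, 1, (3, 8, 8))
        assert np.allclose(kernel_combo_apply(img, bank), img)

    def test_two_identical_kernels_collapse(self, rng):
        kern = rng.normal(size=(5, 5))
        img = rng.uniform(0, 1, (3, 8, 8))
        one = kernel_combo_apply(img, KernelBank([kern]))
        two = kernel_combo_apply(img, KernelBank([kern, kern],
                                                 np.array([2.0, -1.0])))
        assert np.allclose(one, two)

    def test_equal_logits_give_uniform_alphas(self):
        bank = KernelBank([np.eye(3)] * 3, np.zeros(3))
        assert np.allclose(bank.alphas, 1 / 3)

    def test_alphas_sum_to_one_at_extreme_logits(self):
        bank = KernelBank([np.eye(3)] * 3, np.array([50.0, -50.0, 0.0]))
        assert abs(bank.alphas.sum() - 1.0) <= 1e-9

    def test_matches_dense_oracle(self, rng):
        kernels = [rng.normal(size=(s, s)) for s in (5, 7)]
        logits = np.array([0.4, -0.2])
        bank = KernelBank(kernels, logits)
        img = rng.uniform(0, 1, (9, 9))
        out = kernel_combo_apply(img, bank)
        a = bank.alphas
        ref = sum(a[i] * dense_conv2d_oracle(img, kernels[i]) for i in range(2))
        assert np.abs(out - ref).max() <= 1e-6

    def test_empty_bank_rejected(self):
        with pytest.raises(ValueError):
            KernelBank([])

    def test_save_load_roundtrip(self, tmp_path, rng):
        bank = KernelBank([rng.normal(size=(5, 5)), rng.normal(size=(7, 7))],
                          np.array([0.3, -0.3]), manifest={"reduction": "x"})
        bank.save(tmp_path / "bank")
        back = KernelBank.load(tmp_path / "bank")
        assert all(np.array_equal(a, b)
                   for a, b in zip(bank.kernels, back.kernels))
        assert np.array_equal(bank.alpha_logits, back.alpha_logits)
        assert back.manifest["reduction"] == "x"


class TestResiduals:
    def test_neutral_residuals_vanish(self):
        img = np.random.default_rng(0).uniform(0, 1, (3, 8, 8))
        assert np.allclose(residual("brightness", img, np.array([0.0])), 0.0)
        assert np.allclose(residual("contrast", img, np.array([0.0])), 0.0)

    def test_constant_image_residuals_vanish(self):
        img = np.full((3, 8, 8), 0.5)
        assert np.allclose(residual("sharpen", img, np.zeros(3)), 0.0)
        assert np.allclose(residual("median filter", img, None), 0.0)
        assert np.allclose(residual("gaussian blur", img, np.array([0.5])), 0.0)

    def test_unknown_filter_rejected(self):
        with pytest.raises(KeyError):
            residual("nonexistent", np.zeros((3, 4, 4)), None)

    def test_filters_are_deterministic(self, rng):
        img = rng.uniform(0, 1, (3, 12, 12))
        q = np.array([0.2, -0.1, 0.4])
        a = sharpness_apply(img, q)
        b = sharpness_apply(img, q)
        assert np.array_equal(a, b)


def test_gradients_flow_through_trainable_filters(rng):
    """Every trainable parameter path has finite, nonzero gradients."""
    img = Tensor(rng.uniform(0.2, 0.8, (1, 3, 16, 16)))
    q = Tensor(np.array([0.1, 0.1, 0.1]), requires_grad=True)
    b = Tensor(np.array(0.05), requires_grad=True)
    r = Tensor(np.array(0.2), requires_grad=True)
    logits = Tensor(np.zeros(2), requires_grad=True)
    bank = KernelBank([rng.normal(size=(5, 5)), rng.normal(size=(7, 7))])
    out = sharpness_apply(img, q) + brightness_apply(img, b) \
        + contrast_apply(img, r) + kernel_combo_apply(img, bank, logits)
    out.mean().backward()
    for p in (q, b, r, logits):
        assert p.grad is not None and np.isfinite(p.grad).all()
        assert np.abs(p.grad).max() > 0
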