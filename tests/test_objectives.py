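"""Loss identities, Sobel correctness, overlap metric arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rst2g.objectives import (LossWeights, bce_loss, boundary_loss, dice_loss,
                              dsc, ji, rvd, sobel_gradients, total_loss,
                              SOBEL_X, SOBEL_Y)


class TestDiceLoss:
    def test_empty_vs_empty_is_zero(self):
        z = np.zeros((4, 4), dtype=np.float32)
        assert dice_loss(z, z).item() == 0.0

    def test_perfect_binary_prediction_is_zero(self):
        g = np.zeros((4, 4), dtype=np.float32)
        g[1:3, 1:3] = 1
        assert dice_loss(g, g).item() < 1e-6

    def test_half_overlap_arithmetic(self):
        # |P∩G|=2, |P|=4, |G|=4 -> 1 - (2*2+eps)/(8+eps) ~ 0.5
        p = np.zeros(8, dtype=np.float32); p[:4] = 1
        g = np.zeros(8, dtype=np.float32); g[2:6] = 1
        assert np.isclose(dice_loss(p, g).item(), 0.5, atol=1e-6)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            dice_loss(np.zeros(3), np.zeros(4))


class TestBCELoss:
    def test_uniform_half_probability_gives_ln2_for_any_target(self, rng):
        p = np.full((5, 5), 0.5, dtype=np.float32)
        for _ in range(3):
            g = (rng.uniform(size=(5, 5)) > 0.5).astype(np.float32)
            assert np.isclose(bce_loss(p, g).item(), np.log(2), atol=1e-6)

    def test_perfect_binary_prediction_is_near_zero(self):
        g = np.array([1.0, 0.0, 1.0], dtype=np.float32)
        # analytic bound is -log(1-clip) ~ clip; float32 rounding gives
        # the same order of magnitude
        assert bce_loss(g, g).item() <= 2e-7

    def test_hand_arithmetic(self):
        p = np.array([0.9, 0.1], dtype=np.float32)
        g = np.array([1.0, 0.0], dtype=np.float32)
        assert np.isclose(bce_loss(p, g).item(), -np.log(0.9), atol=1e-6)


class TestSobel:
    def test_kernels_sum_to_zero_and_transpose_relation(self):
        assert SOBEL_X.sum() == 0 and SOBEL_Y.sum() == 0
        assert np.array_equal(SOBEL_Y, SOBEL_X.T)

    def test_constant_image_has_zero_gradients(self):
        gx, gy = sobel_gradients(np.full((5, 7), 3.3))
        assert np.allclose(gx, 0, atol=1e-5) and np.allclose(gy, 0, atol=1e-5)

    def test_horizontal_ramp_interior_gx_is_eight(self):
        img = np.tile(np.arange(7, dtype=np.float32), (5, 1))
        gx, gy = sobel_gradients(img)
        assert np.allclose(gx[1:-1, 1:-1], 8.0, atol=1e-5)
        assert np.allclose(gy[1:-1, 1:-1], 0.0, atol=1e-5)

    def test_transposing_image_swaps_directions(self, rng):
        img = rng.normal(size=(6, 6)).astype(np.float32)
        gx, gy = sobel_gradients(img)
        gxt, gyt = sobel_gradients(img.T)
        assert np.allclose(gxt, gy.T, atol=1e-5)
        assert np.allclose(gyt, gx.T, atol=1e-5)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            sobel_gradients(np.zeros((2, 5)))


class TestBoundaryLoss:
    def test_identical_inputs_give_zero(self, rng):
        p = rng.uniform(size=(2, 1, 6, 6)).astype(np.float32)
        assert boundary_loss(p, p).item() == 0.0

    def test_constant_pair_gives_zero(self):
        p = np.full((1, 1, 5, 5), 0.8, dtype=np.float32)
        g = np.full((1, 1, 5, 5), 0.2, dtype=np.float32)
        assert np.isclose(boundary_loss(p, g).item(), 0.0, atol=1e-6)

    def test_single_edge_pixel_matches_convolution_oracle(self):
        from scipy.ndimage import correlate
        p = np.zeros((5, 5), dtype=np.float32); p[1:4, 1:4] = 1
        g = p.copy(); g[2, 3] = 0
        acc = 0.0
        for k in (SOBEL_X, SOBEL_Y):
            sp = correlate(p, k, mode="nearest")
            sg = correlate(g, k, mode="nearest")
            acc += np.abs(sp - sg).sum()
        assert np.isclose(boundary_loss(p, g).item(), acc / 25.0, atol=1e-5)

    def test_invariant_to_shared_constant_offset(self, rng):
        p = rng.uniform(size=(1, 1, 5, 5)).astype(np.float32)
        g = rng.uniform(size=(1, 1, 5, 5)).astype(np.float32)
        base = boundary_loss(p, g).item()
        shifted = boundary_loss(p + 0.7, g + 0.7).item()
        assert np.isclose(base, shifted, atol=1e-5)


class TestTotalLoss:
    def test_weighted_sum_arithmetic(self):
        # components (0.5, 0.2, 0.1) with lambda=0.5, beta=0.2 -> 0.62
        assert np.isclose(0.5 + 0.5 * 0.2 + 0.2 * 0.1, 0.62)

    def test_zero_components_give_zero_total(self):
        g = np.zeros((1, 1, 5, 5), dtype=np.float32)
        g[0, 0, 1:4, 1:4] = 1
        total, parts = total_loss(g, g)
        assert total.item() < 1e-6

    def test_monotone_in_each_component(self, rng):
        w = LossWeights()
        g = (rng.uniform(size=(1, 1, 6, 6)) > 0.6).astype(np.float32)
        good = np.clip(g * 0.98 + 0.01, 0, 1).astype(np.float32)
        bad = np.clip((1 - g) * 0.98 + 0.01, 0, 1).astype(np.float32)
        assert total_loss(good, g, w)[0].item() < total_loss(bad, g, w)[0].item()

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(lam=1.5)
        with pytest.raises(ValueError):
            LossWeights(beta=-0.1)
        with pytest.raises(ValueError):
            LossWeights(clip=0.7)


class TestOverlapMetrics:
    def test_identical_nonempty_masks(self):
        m = np.zeros((3, 3), dtype=np.float32); m[0, :] = 1
        assert dsc(m, m) == 1.0 and ji(m, m) == 1.0 and rvd(m, m) == 0.0

    def test_disjoint_nonempty_masks(self):
        p = np.array([1, 1, 0, 0], dtype=np.float32)
        g = np.array([0, 0, 1, 1], dtype=np.float32)
        assert dsc(p, g) == 0.0 and ji(p, g) == 0.0

    def test_hand_counted_set_arithmetic(self):
        # |P∩G|=1, |P|=|G|=2 -> DSC 0.5, JI 1/3
        p = np.array([1, 1, 0, 0], dtype=np.float32)
        g = np.array([0, 1, 1, 0], dtype=np.float32)
        assert np.isclose(dsc(p, g), 0.5)
        assert np.isclose(ji(p, g), 1 / 3)
        # |P|=6, |G|=4 -> RVD 0.5
        p6 = np.ones(6, dtype=np.float32)
        g4 = np.array([1, 1, 1, 1, 0, 0], dtype=np.float32)
        assert np.isclose(rvd(p6, g4), 0.5)

    def test_empty_vs_empty_defined_as_perfect(self):
        z = np.zeros(5, dtype=np.float32)
        assert dsc(z, z) == 1.0 and ji(z, z) == 1.0

    def test_rvd_requires_nonempty_truth(self):
        with pytest.raises(ValueError):
            rvd(np.ones(3, dtype=np.float32), np.zeros(3, dtype=np.float32))

    def test_non_binary_input_rejected(self):
        with pytest.raises(ValueError):
            dsc(np.array([0.5, 1.0]), np.array([0.0, 1.0]))

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_dice_jaccard_identity(self, seed):
        r = np.random.default_rng(seed)
        p = (r.uniform(size=20) > 0.5).astype(np.float32)
        g = (r.uniform(size=20) > 0.5).astype(np.float32)
        d, j = dsc(p, g), ji(p, g)
        assert np.isclose(d, 2 * j / (1 + j), atol=1e-12)

    def test_dice_loss_complements_dsc_on_binary_masks(self, rng):
        p = (rng.uniform(size=(6, 6)) > 0.5).astype(np.float32)
        g = (rng.uniform(size=(6, 6)) > 0.5).astype(np.float32)
        assert np.isclose(dice_loss(p, g, eps=1e-12).item() + dsc(p, g),
                          1.0, atol=1e-5)
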