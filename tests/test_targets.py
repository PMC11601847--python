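import numpy as np
import pytest

from bootseg import (
    AnnotationMask,
    LabelVolume,
    balance_weights,
    compute_lsds,
    labels_to_affinities,
    lsd_error_map,
    masked_weighted_mse,
    masked_weighted_mse_grad,
    open_error_mask,
)
from bootseg.targets import _lsds_nd
from oracles import affinity_oracle, lsd_oracle


# ------------------------------------------------------------ affinities


class TestAffinities:
    def test_single_object_all_connected(self):
        lab = LabelVolume(np.ones((2, 2, 2), np.uint8))
        affs = labels_to_affinities(lab)
        # in-bounds relations are 1; out-of-bounds stay 0
        assert affs.data[0, 0].all() and not affs.data[0, 1].any()
        assert affs.data[1, :, 0].all() and affs.data[2, :, :, 0].all()

    def test_boundary_between_two_labels(self):
        lab = LabelVolume(np.array([[[1, 1], [2, 2]]], dtype=np.uint8))
        affs = labels_to_affinities(lab)
        assert not affs.data[1].any()  # y interface 1|2
        assert affs.data[2][0, 0, 0] == 1 and affs.data[2][0, 1, 0] == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_oracle(self, seed):
        lab = np.random.default_rng(seed).integers(0, 5, size=(6, 6, 6))
        affs = labels_to_affinities(LabelVolume(lab.astype(np.uint8)))
        np.testing.assert_array_equal(
            affs.data, affinity_oracle(lab, affs.neighborhood)
        )

    def test_non_unit_offset_rejected(self):
        with pytest.raises(ValueError):
            labels_to_affinities(LabelVolume(np.ones((2, 2, 2), np.uint8)),
                                 neighborhood=((2, 0, 0),))


# ----------------------------------------------------------------- LSDs


class TestLSDs:
    def test_background_is_zero_vector(self):
        lab = np.zeros((8, 8, 8), np.uint8)
        lab[2:6, 2:6, 2:6] = 1
        lsds = compute_lsds(LabelVolume(lab, (8, 8, 8)), sigma=16.0)
        assert lsds.data.shape == (10, 8, 8, 8)
        assert not lsds.data[:, lab == 0].any()

    def test_ball_center_has_symmetric_mean_offset(self):
        from skimage.morphology import ball

        b = ball(9).astype(np.uint8)
        lsds = compute_lsds(LabelVolume(b, (8, 8, 8)), sigma=16.0)
        center = lsds.data[:3, 9, 9, 9]
        np.testing.assert_allclose(center, 0.5, atol=1e-6)

    def test_2d_square_matches_bruteforce_oracle(self):
        lab = np.zeros((16, 16), np.int32)
        lab[3:12, 4:13] = 1
        got = _lsds_nd(lab, 16.0, (8.0, 8.0))
        want = lsd_oracle(lab, 16.0, (8.0, 8.0))
        np.testing.assert_allclose(got, want, atol=1e-5)

    def test_3d_anisotropic_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(3)
        lab = np.zeros((12, 12, 12), np.int32)
        lab[2:10, 1:6, 2:11] = 1
        lab[2:10, 7:11, 2:11] = 2
        got = _lsds_nd(lab, 48.0, (40.0, 8.0, 8.0))
        want = lsd_oracle(lab, 48.0, (40.0, 8.0, 8.0))
        np.testing.assert_allclose(got, want, atol=1e-5)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            compute_lsds(LabelVolume(np.ones((4, 4, 4), np.uint8)), sigma=0.0)


# ----------------------------------------------------------------- loss


class TestMaskedLoss:
    def test_fully_masked_gives_zero_loss_and_gradient(self):
        p = np.random.default_rng(0).random((3, 4, 4))
        t = np.zeros_like(p)
        w = np.zeros_like(p)
        assert masked_weighted_mse(p, t, w) == 0.0
        assert not masked_weighted_mse_grad(p, t, w).any()

    def test_perfect_prediction_zero(self):
        p = np.random.default_rng(0).random((2, 3, 3))
        assert masked_weighted_mse(p, p, np.ones_like(p)) == 0.0

    def test_single_voxel_value(self):
        p = np.zeros((2, 2)); t = np.zeros((2, 2)); w = np.zeros((2, 2))
        p[0, 0] = 0.5; w[0, 0] = 1.0
        assert masked_weighted_mse(p, t, w) == pytest.approx(0.25)

    def test_invariant_to_changes_outside_mask(self, rng):
        p = rng.random((3, 5, 5)); t = rng.random((3, 5, 5))
        w = (rng.random((3, 5, 5)) > 0.5).astype(float)
        base = masked_weighted_mse(p, t, w)
        p2 = p.copy()
        p2[w == 0] = rng.random(int((w == 0).sum())) * 100
        assert masked_weighted_mse(p2, t, w) == pytest.approx(base, abs=1e-12)

    def test_gradient_matches_finite_difference(self, rng):
        p = rng.random((4, 4)); t = rng.random((4, 4)); w = rng.random((4, 4))
        w[w < 0.4] = 0.0
        g = masked_weighted_mse_grad(p, t, w)
        eps = 1e-6
        for idx in np.ndindex(p.shape):
            pp = p.copy(); pp[idx] += eps
            pm = p.copy(); pm[idx] -= eps
            fd = (masked_weighted_mse(pp, t, w) - masked_weighted_mse(pm, t, w)) / (2 * eps)
            assert g[idx] == pytest.approx(fd, abs=1e-6)
            if w[idx] == 0:
                assert g[idx] == 0.0

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            masked_weighted_mse(np.zeros((2, 2)), np.zeros((3, 3)), np.ones((2, 2)))


class TestBalanceWeights:
    def test_uniform_equals_mask(self):
        m = np.zeros((4, 4), bool); m[:2] = True
        w = balance_weights(np.zeros((4, 4)), m, "uniform")
        np.testing.assert_array_equal(w.data, m.astype(float))

    def test_balanced_classes_equal_total(self):
        t = np.zeros((10, 10)); t[0] = 1.0  # 10 ones / 90 zeros
        w = balance_weights(t, np.ones((10, 10), bool), "balanced")
        assert w.data[t == 1].sum() == pytest.approx(w.data[t == 0].sum())

    def test_empty_mask_zero_weights(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            w = balance_weights(np.ones((3, 3)), np.zeros((3, 3), bool))
        assert not w.data.any()
        assert any("empty" in r.message for r in caplog.records)

    def test_unknown_mode_raises(self):
        with pytest.raises(ValueError):
            balance_weights(np.ones((2, 2)), np.ones((2, 2), bool), "exotic")


# ----------------------------------------------------------- error maps


class TestLsdErrorMap:
    def test_identical_inputs_zero(self, rng):
        x = rng.random((6, 4, 4, 4))
        assert not lsd_error_map(x, x).any()

    def test_single_channel_single_voxel(self):
        a = np.zeros((6, 3, 3, 3)); b = a.copy()
        b[2, 1, 1, 1] = 0.3
        err = lsd_error_map(a, b)
        assert err[1, 1, 1] == pytest.approx(0.3)
        assert np.count_nonzero(err) == 1

    def test_matches_scalar_loop_oracle(self, rng):
        a = rng.random((5, 3, 3, 3)); b = rng.random((5, 3, 3, 3))
        err = lsd_error_map(a, b)
        for idx in np.ndindex((3, 3, 3)):
            want = np.sqrt(sum((a[(c,) + idx] - b[(c,) + idx]) ** 2 for c in range(5)))
            assert err[idx] == pytest.approx(want, abs=1e-12)

    def test_triangle_inequality_per_voxel(self, rng):
        x, y, z = (rng.random((4, 3, 3, 3)) for _ in range(3))
        assert (lsd_error_map(x, z) <= lsd_error_map(x, y) + lsd_error_map(y, z) + 1e-12).all()


class TestOpenErrorMask:
    def test_thin_shell_removed(self):
        err = np.zeros((9, 9, 9))
        err[2:7, 2:7, 2:7] = 1.0
        err[3:6, 3:6, 3:6] = 0.0  # 1-voxel shell of high error
        assert not open_error_mask(err, 0.5, 1).any()

    def test_solid_blob_survives(self):
        err = np.zeros((9, 9, 9))
        err[2:7, 2:7, 2:7] = 1.0
        opened = open_error_mask(err, 0.5, 1)
        assert opened.any() and opened[4, 4, 4]

    def test_radius_zero_is_pure_threshold(self, rng):
        err = rng.random((5, 5, 5))
        np.testing.assert_array_equal(open_error_mask(err, 0.3, 0), err > 0.3)
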