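import numpy as np
import pytest
from scipy import ndimage

from widif.image_io import Mask3D, TimeSeriesCurve
from widif.pvc import (
    PVCFactors,
    compute_pvc_factors,
    correct_blood_curve,
    gaussian_smooth,
    sleeve_tissue_mask,
    spillin_beta,
    spillout_alpha,
)

VOX = (0.98, 0.98, 2.79)


def _dense_gaussian_oracle(volume, fwhm_mm, voxel_size_mm):
    """Brute-force dense 3-D convolution with an explicitly built kernel.

    Independent of the separable implementation: constructs the sampled
    Gaussian kernel per axis (radius = int(4*sigma + 0.5)), forms the full
    3-D kernel by outer product, pads with edge replication, and sums.
    """
    sigmas = [(fwhm_mm / 2.3548200450309493) / v for v in voxel_size_mm]
    kernels = []
    for s in sigmas:
        r = int(4.0 * s + 0.5)
        x = np.arange(-r, r + 1)
        k = np.exp(-0.5 * (x / s) ** 2)
        kernels.append(k / k.sum())
    kern3 = (
        kernels[0][:, None, None] * kernels[1][None, :, None] * kernels[2][None, None, :]
    )
    radii = [len(k) // 2 for k in kernels]
    padded = np.pad(volume, [(r, r) for r in radii], mode="edge")
    out = np.zeros_like(volume, dtype=float)
    nx, ny, nz = volume.shape
    for i in range(kern3.shape[0]):
        for j in range(kern3.shape[1]):
            for k in range(kern3.shape[2]):
                out += kern3[i, j, k] * padded[i : i + nx, j : j + ny, k : k + nz]
    return out


def _random_interior_mask(rng, shape=(24, 24, 16)):
    m = np.zeros(shape, dtype=bool)
    n_seeds = rng.integers(1, 4)
    for _ in range(n_seeds):
        c = [rng.integers(6, s - 6) for s in shape]
        m[c[0], c[1], c[2]] = True
    m = ndimage.binary_dilation(m, iterations=int(rng.integers(1, 3)))
    return Mask3D(m.astype(int), VOX)


class TestGaussianSmooth:
    def test_constant_volume_unchanged(self):
        vol = np.full((8, 8, 8), 3.7)
        np.testing.assert_allclose(gaussian_smooth(vol, 2.1, VOX), vol, rtol=1e-12)

    def test_zero_fwhm_is_identity(self):
        vol = np.random.default_rng(0).random((6, 6, 6))
        np.testing.assert_array_equal(gaussian_smooth(vol, 0.0, VOX), vol)

    def test_impulse_centre_matches_kernel_construction(self):
        # isotropic 1 mm voxels, fwhm = 2.3548 mm -> sigma = 1 voxel
        vol = np.zeros((17, 17, 17))
        vol[8, 8, 8] = 1.0
        sm = gaussian_smooth(vol, 2.3548200450309493, (1.0, 1.0, 1.0))
        r = int(4.0 * 1.0 + 0.5)
        x = np.arange(-r, r + 1)
        k1 = np.exp(-0.5 * x**2)
        k1 /= k1.sum()
        assert sm[8, 8, 8] == pytest.approx(k1[r] ** 3, rel=1e-12)

    def test_matches_dense_convolution_oracle(self):
        vol = np.random.default_rng(1).random((12, 12, 8))
        got = gaussian_smooth(vol, 2.1, VOX)
        expected = _dense_gaussian_oracle(vol, 2.1, VOX)
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            gaussian_smooth(np.zeros((3, 3, 3)), -1.0, VOX)


class TestSpillFactors:
    def test_all_ones_mask_alpha_one_beta_zero(self):
        mask = Mask3D(np.ones((8, 8, 8), dtype=int), VOX)
        assert spillout_alpha(mask, 2.1) == pytest.approx(1.0, abs=1e-12)
        assert spillin_beta(mask, 2.1) == pytest.approx(0.0, abs=1e-12)

    def test_zero_fwhm_gives_alpha_one(self):
        m = np.zeros((8, 8, 8), dtype=int)
        m[3:5, 3:5, 3:5] = 1
        mask = Mask3D(m, VOX)
        assert spillout_alpha(mask, 0.0) == 1.0
        assert spillin_beta(mask, 0.0) == 0.0

    def test_alpha_plus_beta_is_one_for_interior_masks(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            mask = _random_interior_mask(rng)
            for fwhm in (2.0, 2.2, 2.4):
                a = spillout_alpha(mask, fwhm)
                b = spillin_beta(mask, fwhm)
                assert a + b == pytest.approx(1.0, abs=1e-6)

    def test_alpha_matches_dense_convolution_oracle(self):
        m = np.zeros((20, 20, 12), dtype=int)
        m[8:12, 8:13, 4:8] = 1  # tube-like block on the standard grid
        mask = Mask3D(m, VOX)
        a = spillout_alpha(mask, 2.1)
        sm = _dense_gaussian_oracle(m.astype(float), 2.1, VOX)
        expected = (sm * m).sum() / m.sum()
        assert a == pytest.approx(expected, abs=1e-6)

    def test_alpha_non_increasing_in_fwhm(self):
        m = np.zeros((16, 16, 10), dtype=int)
        m[6:10, 6:10, 4:7] = 1
        mask = Mask3D(m, VOX)
        alphas = [spillout_alpha(mask, f) for f in (0.0, 1.0, 2.0, 3.0, 4.0)]
        assert alphas[0] == 1.0
        assert all(a1 >= a2 for a1, a2 in zip(alphas, alphas[1:]))

    def test_empty_mask_rejected(self):
        mask = Mask3D(np.zeros((4, 4, 4), dtype=int), VOX)
        with pytest.raises(ValueError):
            spillout_alpha(mask, 2.1)
        with pytest.raises(ValueError):
            spillin_beta(mask, 2.1)

    def test_factor_invariants_enforced(self):
        with pytest.raises(ValueError):
            PVCFactors(alpha=0.0, beta=0.2, kernel_fwhm_mm=2.1)
        with pytest.raises(ValueError):
            PVCFactors(alpha=0.8, beta=1.0, kernel_fwhm_mm=2.1)


class TestSleeveMask:
    def test_single_voxel_l1_ball_counts(self):
        # 6-connected dilation of one voxel n times = L1 ball of radius n:
        # |ball(2)| - |ball(1)| = 25 - 7 = 18
        m = np.zeros((9, 9, 9), dtype=int)
        m[4, 4, 4] = 1
        sleeve = sleeve_tissue_mask(Mask3D(m, VOX), inner=1, outer=2)
        assert sleeve.n_voxels == 18

    def test_sleeve_disjoint_from_mask_and_inner_dilation(self):
        m = np.zeros((30, 30, 30), dtype=int)
        m[14:17, 14:16, 13:18] = 1
        mask = Mask3D(m, VOX)
        sleeve = sleeve_tissue_mask(mask, inner=3, outer=5)
        inner = ndimage.binary_dilation(
            m.astype(bool), ndimage.generate_binary_structure(3, 1), iterations=3
        )
        assert not (sleeve.voxels & inner).any()
        assert sleeve.n_voxels > 0

    def test_empty_mask_and_bad_radii_rejected(self):
        with pytest.raises(ValueError):
            sleeve_tissue_mask(Mask3D(np.zeros((4, 4, 4), dtype=int), VOX))
        m = np.zeros((20, 20, 20), dtype=int)
        m[10, 10, 10] = 1
        with pytest.raises(ValueError):
            sleeve_tissue_mask(Mask3D(m, VOX), inner=5, outer=5)


class TestCorrectBloodCurve:
    def test_identity_when_alpha_one_beta_zero(self):
        t = np.arange(5.0)
        tac = TimeSeriesCurve(t, [1.0, 5.0, 3.0, 2.0, 1.0])
        tissue = TimeSeriesCurve(t, np.zeros(5))
        out = correct_blood_curve(tac, tissue, PVCFactors(1.0, 0.0, 2.1))
        np.testing.assert_array_equal(out.value, tac.value)

    def test_direct_arithmetic(self):
        t = np.array([0.0, 1.0])
        tac = TimeSeriesCurve(t, [0.6, 0.6])
        tissue = TimeSeriesCurve(t, [0.2, 0.2])
        out = correct_blood_curve(tac, tissue, PVCFactors(0.5, 0.5, 2.1))
        np.testing.assert_allclose(out.value, [1.0, 1.0])

    def test_grid_mismatch_rejected(self):
        a = TimeSeriesCurve([0.0, 1.0], [1.0, 1.0])
        b = TimeSeriesCurve([0.0, 2.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            correct_blood_curve(a, b, PVCFactors(0.5, 0.5, 2.1))

    def test_uniform_background_exact_recovery(self):
        # measured image built as C_B*smooth(M) + C_T*smooth(1-M) with the
        # PVC kernel itself: the correction must return C_B exactly
        from widif.image_io import DynamicImage, FrameSchedule, frame_mid_times
        from widif.segmentation import extract_tac

        m = np.zeros((20, 20, 12), dtype=int)
        m[8:12, 9:12, 4:8] = 1
        mask = Mask3D(m, VOX)
        sched = FrameSchedule.from_durations([5.0] * 6)
        cb = np.array([0.0, 50.0, 400.0, 300.0, 120.0, 60.0])
        ct = np.array([0.0, 5.0, 30.0, 80.0, 100.0, 90.0])
        sm = gaussian_smooth(m.astype(float), 2.1, VOX)
        sm_inv = gaussian_smooth(1.0 - m, 2.1, VOX)
        img = DynamicImage(sm[..., None] * cb + sm_inv[..., None] * ct, VOX, sched)
        factors = compute_pvc_factors(mask, 2.1)
        carotid_tac = extract_tac(img, mask)
        tissue_tac = TimeSeriesCurve(frame_mid_times(sched), ct)
        out = correct_blood_curve(carotid_tac, tissue_tac, factors)
        np.testing.assert_allclose(out.value[1:], cb[1:], rtol=1e-6)

    def test_negative_early_auc_warns(self):
        t = np.array([0.0, 30.0, 60.0])
        tac = TimeSeriesCurve(t, [0.0, 0.1, 0.1])
        tissue = TimeSeriesCurve(t, [10.0, 10.0, 10.0])
        with pytest.warns(UserWarning, match="negative"):
            correct_blood_curve(tac, tissue, PVCFactors(0.5, 0.5, 2.1))
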