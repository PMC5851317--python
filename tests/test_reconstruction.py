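"""OP-OSEM update correctness, FBP, post-filtering and decay conversion."""

import numpy as np
import pytest

from dynapet.projection import (ProjectionGeometry, SinogramSet,
                                build_system_operator)
from dynapet.reconstruction import (
    ReconConfig,
    decay_correction_factor,
    default_recon_configs,
    fbp_reconstruct,
    frame_decay_factor,
    osem_reconstruct,
    post_filter,
    to_activity_concentration,
)


def _zero_sino(op):
    z = np.zeros(op.sinogram_shape)
    return z.copy(), z.copy(), z.copy()


def _phantom16():
    n = 16
    X, Y = np.meshgrid(2.0 * (np.arange(n) - (n - 1) / 2),
                       2.0 * (np.arange(n) - (n - 1) / 2))
    img = np.where(X**2 + Y**2 <= 10**2, 1.0, 0.0)
    img[(X + 4) ** 2 + Y**2 <= 3**2] = 3.0
    return img


class TestOSEM:
    def test_single_voxel_single_step(self):
        """With one effective unknown and p = 5 the update converges in one
        MLEM step to p / A."""
        op = build_system_operator(np.zeros((1, 1)), 1.0,
                                   ProjectionGeometry(n_angles=1, n_radial=1))
        p = np.full(op.sinogram_shape, 5.0)
        z = np.zeros_like(p)
        res = osem_reconstruct(SinogramSet(p, z, z), op,
                               ReconConfig("OSEM", 1, 1, 0))
        # A = voxel_size = 1 mm, so f = p / A = 5
        assert res.image[0, 0] == pytest.approx(5.0, rel=1e-12)

    def test_zero_prompts_drive_image_to_zero(self, op16):
        p, r, s = _zero_sino(op16)
        res = osem_reconstruct(SinogramSet(p, r, s), op16,
                               ReconConfig("OSEM", 1, 4, 0))
        assert np.all(res.image == 0.0)

    def test_noiseless_mlem_recovers_phantom(self, op16):
        """Noiseless data, 500 MLEM iterations: < 5% normalized RMSE."""
        img = _phantom16()
        trues = op16.forward(img) * 100.0
        z = np.zeros_like(trues)
        res = osem_reconstruct(SinogramSet(trues, z, z), op16,
                               ReconConfig("OSEM", 500, 1, 0))
        rec = res.image / 100.0
        mask = img > 0
        nrmse = np.sqrt(np.mean((rec[mask] - img[mask]) ** 2)) / img[mask].mean()
        assert nrmse < 0.05

    def test_fixed_point_of_consistent_data(self, op16_full, rng):
        """If forward(f) + r + s = p the update leaves f unchanged."""
        f = rng.random((16, 16)) + 0.1
        r = np.full(op16_full.sinogram_shape, 0.4)
        s = np.full(op16_full.sinogram_shape, 0.2)
        p = op16_full.forward(f) + r + s
        res = osem_reconstruct(SinogramSet(p, r, s), op16_full,
                               ReconConfig("TPSF", 1, 4, 0), initial=f)
        assert np.max(np.abs(res.image - f) / f) < 1e-10

    def test_iterates_nonnegative(self, op16, rng):
        img = _phantom16()
        trues = op16.forward(img) * 20.0
        p = rng.poisson(trues).astype(float)
        z = np.zeros_like(p)
        res = osem_reconstruct(SinogramSet(p, z, z), op16,
                               ReconConfig("OSEM", 5, 4, 0), keep_snapshots=True)
        for _, snap in res.snapshots:
            assert np.all(snap >= 0.0)

    def test_mlem_count_conservation(self, op16, rng):
        """Sensitivity-weighted image total equals the prompt total after
        every full MLEM iteration (r = s = 0, unit normalization)."""
        img = _phantom16()
        p = rng.poisson(op16.forward(img) * 50.0).astype(float)
        z = np.zeros_like(p)
        sens = op16.sensitivity(range(op16.n_angles))
        res = osem_reconstruct(SinogramSet(p, z, z), op16,
                               ReconConfig("OSEM", 3, 1, 0), keep_snapshots=True)
        for _, snap in res.snapshots:
            assert abs((sens * snap).sum() - p.sum()) / p.sum() < 1e-6

    def test_subsets_one_equals_mlem(self, op16, rng):
        """OSEM with a single subset is MLEM, iterate for iterate."""
        img = _phantom16()
        p = rng.poisson(op16.forward(img) * 30.0).astype(float)
        z = np.zeros_like(p)
        a = osem_reconstruct(SinogramSet(p, z, z), op16,
                             ReconConfig("OSEM", 4, 1, 0), keep_snapshots=True)
        # manual MLEM using the full-data update
        f = np.ones((16, 16))
        sens = op16.sensitivity(range(op16.n_angles))
        for _, snap in a.snapshots:
            proj = op16.forward(f)
            f = f * op16.back(p / np.maximum(proj, 1e-12)) / np.maximum(sens, 1e-12)
            np.testing.assert_allclose(snap, f, rtol=1e-10, atol=1e-12)

    def test_randoms_scatter_in_denominator_not_subtracted(self, op16):
        """With pure-background prompts (p = r + s) the image shrinks towards
        zero but never goes negative — the ordinary-Poisson behavior."""
        r = np.full(op16.sinogram_shape, 2.0)
        s = np.full(op16.sinogram_shape, 1.0)
        p = r + s
        res = osem_reconstruct(SinogramSet(p, r, s), op16,
                               ReconConfig("OSEM", 10, 4, 0))
        assert np.all(res.image >= 0.0)
        assert res.image.max() < 0.05  # activity estimate collapses

    def test_method_operator_validation(self, op16):
        p, r, s = _zero_sino(op16)
        with pytest.raises(ValueError, match="TOF"):
            osem_reconstruct(SinogramSet(p, r, s), op16,
                             ReconConfig("TOF", 1, 2, 0))


class TestFBP:
    def test_pure_background_gives_zero_image(self, op16):
        r = np.full(op16.sinogram_shape, 1.5)
        s = np.full(op16.sinogram_shape, 0.5)
        res = fbp_reconstruct(SinogramSet(r + s, r, s), op16)
        assert np.abs(res.image).max() < 1e-8

    def test_linearity(self, op16, rng):
        z = np.zeros(op16.sinogram_shape)
        p1, p2 = rng.random(z.shape), rng.random(z.shape)
        cfg = ReconConfig("FBP", 1, 1, 0)
        f1 = fbp_reconstruct(SinogramSet(p1, z, z), op16, cfg).image
        f2 = fbp_reconstruct(SinogramSet(p2, z, z), op16, cfg).image
        f12 = fbp_reconstruct(SinogramSet(2 * p1 + 3 * p2, z, z), op16, cfg).image
        np.testing.assert_allclose(f12, 2 * f1 + 3 * f2, rtol=1e-10, atol=1e-12)

    def test_uniform_disc_quantitative_recovery(self):
        """Noiseless 64x64 disc, 180 angles: interior mean within 5%."""
        n = 64
        X, Y = np.meshgrid(2.0 * (np.arange(n) - (n - 1) / 2),
                           2.0 * (np.arange(n) - (n - 1) / 2))
        disc = np.where(X**2 + Y**2 <= 30**2, 1.0, 0.0)
        op = build_system_operator(np.zeros((n, n)), 2.0,
                                   ProjectionGeometry(n_angles=180))
        trues = op.forward(disc)
        z = np.zeros_like(trues)
        res = fbp_reconstruct(SinogramSet(trues, z, z), op,
                              ReconConfig("FBP", 1, 1, 0, "ramp"))
        inner = X**2 + Y**2 <= 20**2
        assert res.image[inner].mean() == pytest.approx(1.0, rel=0.05)

    def test_tof_data_summed_before_reconstruction(self, op16_full, rng):
        img = _phantom16()
        trues = op16_full.forward(img)
        z = np.zeros_like(trues)
        res_tof = fbp_reconstruct(SinogramSet(trues, z, z), op16_full)
        nt = trues.sum(axis=2)
        # matching non-TOF operator for the summed sinogram
        from dynapet.projection import PSFConfig
        op_nt = build_system_operator(_mu16(), 2.0,
                                      ProjectionGeometry(n_angles=24),
                                      None, PSFConfig(4.0))
        res_nt = fbp_reconstruct(
            SinogramSet(nt, np.zeros_like(nt), np.zeros_like(nt)), op_nt)
        np.testing.assert_allclose(res_tof.image, res_nt.image, rtol=1e-8,
                                   atol=1e-10)


def _mu16():
    # same attenuation map as the conftest operators
    X, Y = np.meshgrid(2.0 * (np.arange(16) - 7.5), 2.0 * (np.arange(16) - 7.5))
    return np.where(X**2 + Y**2 <= 12**2, 0.096, 0.0)


class TestPostFilter:
    def test_zero_fwhm_identity(self, rng):
        img = rng.random((32, 32))
        out = post_filter(img, 0.0, 2.0)
        np.testing.assert_array_equal(out, img)

    def test_delta_response_is_sampled_gaussian(self):
        img = np.zeros((65, 65))
        img[32, 32] = 1.0
        out = post_filter(img, 5.0, 2.0)
        sig = 5.0 / 2.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        X, Y = np.meshgrid(np.arange(65) - 32, np.arange(65) - 32)
        g = np.exp(-(X**2 + Y**2) / (2 * sig**2))
        g /= g.sum()
        assert np.abs(out - g).max() < 1e-6 * g.max()

    def test_uniform_invariance_and_sum_preservation(self, rng):
        uni = np.full((24, 24), 3.3)
        np.testing.assert_allclose(post_filter(uni, 6.5, 2.0), 3.3, rtol=1e-12)
        img = rng.random((24, 24))
        out = post_filter(img, 6.5, 2.0)
        assert abs(out.sum() - img.sum()) / img.sum() < 1e-6

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            post_filter(np.zeros((4, 4)), -1.0, 2.0)


class TestDecayConversion:
    def test_doubling_time_equals_half_life(self):
        assert decay_correction_factor(20.0 * 60.0, 20.0) == pytest.approx(2.0)

    def test_short_frame_at_injection(self):
        assert frame_decay_factor(0.0, 1e-6, 20.0) == pytest.approx(1.0, abs=1e-6)

    def test_short_frame_at_half_life(self):
        f = frame_decay_factor(20.0 * 60.0 - 0.5, 1.0, 20.0)
        assert 1.0 / f == pytest.approx(2.0, rel=1e-3)

    def test_long_frame_closed_form(self):
        """[0, 1200 s] at 20 min half-life: mean decay (1 - e^-ln2)/ln2."""
        expected = (1.0 - np.exp(-np.log(2.0))) / np.log(2.0)
        assert frame_decay_factor(0.0, 1200.0, 20.0) == pytest.approx(
            expected, rel=1e-12)
        img = np.ones((4, 4)) * 1200.0 * expected
        out = to_activity_concentration(img, (0.0, 1200.0), 20.0, 1.0)
        np.testing.assert_allclose(out, 1.0, rtol=1e-12)

    def test_nonpositive_half_life_rejected(self):
        with pytest.raises(ValueError):
            frame_decay_factor(0.0, 10.0, 0.0)


def test_default_configs_match_protocol():
    cfgs = default_recon_configs()
    assert cfgs["OSEM"].em_equivalent == 200
    assert cfgs["TOF"].em_equivalent == 100
    assert cfgs["TPSF"].em_equivalent == 100
    assert cfgs["OSEM"].postfilter_fwhm_mm == 6.5
    assert cfgs["TOF"].postfilter_fwhm_mm == 5.0
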