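"""Forward-model physics: attenuation closed forms, planar and SPECT
projections, CT-number conversion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from replanar import (ActivityVolume, CTVolume, DetectorModel, GridGeometry,
                      MuMap, attenuation_path_factor, default_spect_angles,
                      hu_to_mu, simulate_planar, simulate_spect)
from replanar.projectors import anterior_attenuation_factors


def _uniform_mu(grid, value):
    return MuMap(np.full(grid.shape, value), grid)


class TestAttenuationPathFactor:
    def test_zero_mu_gives_unity(self, small_grid):
        mu = _uniform_mu(small_grid, 0.0)
        assert attenuation_path_factor(mu, (3, 7, 5)) == 1.0

    def test_uniform_slab_closed_form(self):
        """Voxel 10 steps below the anterior face under uniform mu:
        exp(-mu * step * 10.5), the half-step self term included."""
        grid = GridGeometry((16, 16, 16), voxel_size_mm=2.46)
        mu = _uniform_mu(grid, 0.01)
        got = attenuation_path_factor(mu, (4, 10, 8))
        assert got == pytest.approx(np.exp(-0.01 * 2.46 * 10.5), rel=1e-12)

    def test_anterior_face_half_step(self):
        grid = GridGeometry((16, 16, 16), voxel_size_mm=2.0)
        mu = _uniform_mu(grid, 0.02)
        assert attenuation_path_factor(mu, (0, 0, 0)) == pytest.approx(
            np.exp(-0.02 * 2.0 * 0.5), rel=1e-12)

    def test_outside_grid_rejected(self, small_grid):
        with pytest.raises(IndexError):
            attenuation_path_factor(_uniform_mu(small_grid, 0.0), (0, 99, 0))

    def test_vectorised_factors_match_scalar(self, small_phantom):
        _, mu, _ = small_phantom
        factors = anterior_attenuation_factors(mu.data, mu.grid.voxel_size_mm)
        for idx in [(0, 0, 0), (5, 9, 12), (15, 15, 15)]:
            assert factors[idx] == pytest.approx(
                attenuation_path_factor(mu, idx), rel=1e-12)

    @given(st.floats(0.0, 0.05), st.integers(0, 15))
    @settings(max_examples=25, deadline=None)
    def test_factor_in_unit_interval(self, mu_val, depth):
        grid = GridGeometry((8, 16, 8), voxel_size_mm=3.0)
        f = attenuation_path_factor(_uniform_mu(grid, mu_val), (2, depth, 3))
        assert 0.0 < f <= 1.0


class TestSimulatePlanar:
    def test_zero_activity_zero_image(self, small_grid):
        act = ActivityVolume(np.zeros(small_grid.shape), small_grid)
        img = simulate_planar(act, _uniform_mu(small_grid, 0.01))
        assert np.all(img.data == 0)

    def test_unattenuated_ray_sum(self, small_grid):
        rng = np.random.default_rng(0)
        act = ActivityVolume(rng.random(small_grid.shape), small_grid)
        img = simulate_planar(act, _uniform_mu(small_grid, 0.0))
        expected = small_grid.voxel_size_mm * act.data.sum(axis=1)
        np.testing.assert_allclose(img.data, expected, rtol=1e-12)

    def test_point_source_closed_form(self):
        grid = GridGeometry((16, 16, 16), voxel_size_mm=2.46)
        act = np.zeros(grid.shape)
        depth = 7
        act[8, depth, 5] = 1.0
        mu_val = 0.0154
        img = simulate_planar(ActivityVolume(act, grid), _uniform_mu(grid, mu_val))
        expected = 2.46 * np.exp(-mu_val * 2.46 * (depth + 0.5))
        assert img.data[8, 5] == pytest.approx(expected, rel=1e-12)
        assert np.count_nonzero(img.data) == 1

    def test_linearity(self, small_grid):
        rng = np.random.default_rng(1)
        a = rng.random(small_grid.shape)
        b = rng.random(small_grid.shape)
        mu = _uniform_mu(small_grid, 0.008)
        img_ab = simulate_planar(ActivityVolume(2 * a + 3 * b, small_grid), mu)
        img_a = simulate_planar(ActivityVolume(a, small_grid), mu)
        img_b = simulate_planar(ActivityVolume(b, small_grid), mu)
        np.testing.assert_allclose(img_ab.data, 2 * img_a.data + 3 * img_b.data,
                                   rtol=1e-10)

    def test_attenuation_monotonicity(self, small_grid):
        """Raising any mu voxel never raises any planar pixel."""
        rng = np.random.default_rng(2)
        act = ActivityVolume(rng.random(small_grid.shape), small_grid)
        mu_lo = rng.random(small_grid.shape) * 0.01
        mu_hi = mu_lo.copy()
        mu_hi[4, 8, 4] += 0.05
        img_lo = simulate_planar(act, MuMap(mu_lo, small_grid))
        img_hi = simulate_planar(act, MuMap(mu_hi, small_grid))
        assert np.all(img_hi.data <= img_lo.data + 1e-15)

    def test_count_conservation_without_attenuation(self, small_grid):
        rng = np.random.default_rng(3)
        act = ActivityVolume(rng.random(small_grid.shape), small_grid)
        det = DetectorModel(sensitivity=2.5)
        img = simulate_planar(act, _uniform_mu(small_grid, 0.0), det)
        assert img.data.sum() == pytest.approx(
            2.5 * small_grid.voxel_size_mm * act.data.sum(), rel=1e-12)

    def test_psf_preserves_counts_in_interior(self, small_grid):
        """The depth-dependent PSF redistributes, but barely changes, the
        total of a centred source."""
        act = np.zeros(small_grid.shape)
        act[8, 8, 8] = 100.0
        img_nopsf = simulate_planar(ActivityVolume(act, small_grid),
                                    _uniform_mu(small_grid, 0.0))
        img_psf = simulate_planar(ActivityVolume(act, small_grid),
                                  _uniform_mu(small_grid, 0.0),
                                  DetectorModel(psf=True))
        assert img_psf.data.sum() == pytest.approx(img_nopsf.data.sum(), rel=1e-6)
        assert img_psf.data.max() < img_nopsf.data.max()

    def test_poisson_seeded_reproducible(self, small_phantom):
        act, mu, _ = small_phantom
        img1 = simulate_planar(act, mu, seed=7, noiseless=False)
        img2 = simulate_planar(act, mu, seed=7, noiseless=False)
        img3 = simulate_planar(act, mu, seed=8, noiseless=False)
        assert np.array_equal(img1.data, img2.data)
        assert not np.array_equal(img1.data, img3.data)
        assert np.all(img1.data == np.round(img1.data))

    def test_grid_mismatch_rejected(self, small_grid):
        act = ActivityVolume(np.ones(small_grid.shape), small_grid)
        other = GridGeometry((16, 16, 16), voxel_size_mm=1.0)
        with pytest.raises(ValueError):
            simulate_planar(act, _uniform_mu(other, 0.0))


class TestSimulateSpect:
    def test_angle_zero_matches_planar(self, small_phantom):
        act, mu, _ = small_phantom
        proj = simulate_spect(act, mu, angles_deg=np.array([0.0, 90.0]))
        planar = simulate_planar(act, mu)
        np.testing.assert_allclose(proj.data[0], planar.data, rtol=1e-12)

    def test_rotational_symmetry(self):
        """A centred cylinder under uniform attenuation projects identically
        at every angle, within interpolation tolerance."""
        grid = GridGeometry((16, 16, 16), voxel_size_mm=10.0)
        d = grid.voxel_size_mm
        # rotation about the array centre ((n-1)/2 in index coordinates)
        yy, xx = np.meshgrid(*[np.arange(16) * d] * 2, indexing="ij")
        c = (16 - 1) * d / 2
        r2 = (yy - c) ** 2 + (xx - c) ** 2
        blob = np.exp(-r2 / (2 * (2.5 * d) ** 2))   # smooth radial profile
        act = ActivityVolume(np.broadcast_to(blob, grid.shape).copy(), grid)
        mu = MuMap(np.broadcast_to(blob * 0.001, grid.shape).copy(), grid)
        proj = simulate_spect(act, mu, angles_deg=default_spect_angles(12))
        ref = proj.data[0]
        for k in range(1, 12):
            assert np.abs(proj.data[k] - ref).max() < 0.02 * ref.max()

    def test_poisson_mean_matches_expectation(self, small_phantom):
        """Law of large numbers: the seeded Poisson realizations average to
        the noiseless expectation within 3 standard errors."""
        act, mu, _ = small_phantom
        angles = np.array([0.0, 120.0, 240.0])
        noiseless = simulate_spect(act, mu, angles_deg=angles).data
        pix = (1, 8, 8)
        mean_true = noiseless[pix]
        n_rep = 200
        draws = np.array([
            simulate_spect(act, mu, angles_deg=angles, seed=s,
                           noiseless=False).data[pix]
            for s in range(n_rep)])
        se = np.sqrt(mean_true / n_rep)
        assert abs(draws.mean() - mean_true) < 3 * se

    def test_too_few_angles_rejected(self, small_phantom):
        act, mu, _ = small_phantom
        with pytest.raises(ValueError):
            simulate_spect(act, mu, angles_deg=np.array([0.0]))


class TestHuToMu:
    def test_water_air_bone_anchors(self, small_grid):
        hu = np.zeros(small_grid.shape)
        hu[0, 0, 0] = -1000.0
        hu[0, 0, 1] = 1000.0
        mu = hu_to_mu(CTVolume(hu, small_grid))
        assert mu.data[1, 1, 1] == pytest.approx(0.0154)      # water
        assert mu.data[0, 0, 0] == pytest.approx(0.0)         # air
        # +1000 HU maps onto the package's 140-keV bone surrogate, which
        # standard attenuation tables put between trabecular (~0.022/mm)
        # and cortical (~0.030/mm) bone
        assert 0.020 < mu.data[0, 0, 1] < 0.031
        assert mu.data[0, 0, 1] == pytest.approx(0.025)

    def test_negative_hu_interpolates_linearly(self, small_grid):
        hu = np.full(small_grid.shape, -500.0)
        mu = hu_to_mu(CTVolume(hu, small_grid))
        np.testing.assert_allclose(mu.data, 0.0154 * 0.5, rtol=1e-12)

    def test_output_clipped_nonnegative(self, small_grid):
        hu = np.full(small_grid.shape, -1024.0)
        mu = hu_to_mu(CTVolume(hu, small_grid))
        assert np.all(mu.data >= 0)
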