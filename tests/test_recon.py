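"""Reconstruction tests: TEW arithmetic, MLEM properties, filters, summation."""

import numpy as np
import pytest

from qspect.phantom import empty_grid, make_sphere_source
from qspect.recon import (
    ReconConfig,
    gaussian_postfilter,
    osem_reconstruct,
    poisson_loglik,
    sum_photopeaks,
    tew_estimate,
)
from qspect.simulator import (
    AcquisitionConfig,
    EnergyWindow,
    acquire,
    photopeak_208,
)


def _small_acquisition(noise=False, seed=None, n_proj=12, windows=None):
    """A 16-ml sphere in air on a 32^3 grid, 12 angles."""
    grid = empty_grid(32, 32, 4.8)
    activity, mask = make_sphere_source(16.0, 1.0, grid)
    cfg = AcquisitionConfig(
        n_projections=n_proj,
        windows=windows or (photopeak_208(),
                            EnergyWindow(178.0, 0.05, "lower_scatter"),
                            EnergyWindow(214.0, 0.05, "upper_scatter")),
        orbit="circular", orbit_radius_mm=180.0,
    )
    ps = acquire(activity, None, cfg, seed=seed, noise=noise)
    return activity, mask, ps


class TestTEW:
    def _windows(self):
        pk = photopeak_208()
        low = EnergyWindow(178.0, 0.05, "lower_scatter")
        up = EnergyWindow(214.0, 0.05, "upper_scatter")
        return pk, low, up

    def test_zero_scatter_windows_zero_estimate(self):
        _, _, ps = _small_acquisition()
        pk, low, up = self._windows()
        ps.counts["sc178"][:] = 0
        ps.counts["sc214"][:] = 0
        assert np.all(tew_estimate(ps, pk, low, up) == 0)

    def test_equal_windows_identity(self):
        # equal widths and equal counts: the trapezoid returns C itself
        _, _, ps = _small_acquisition()
        w = 20.0 / (2 * 208.0)
        pk = EnergyWindow(208.0, w)
        low = EnergyWindow(178.0, 20.0 / (2 * 178.0), "lower_scatter")
        up = EnergyWindow(214.0, 20.0 / (2 * 214.0), "upper_scatter")
        c = 7.0
        ps.counts["sc178"][:] = c
        ps.counts["sc214"][:] = c
        est = tew_estimate(ps, pk, low, up)
        np.testing.assert_allclose(est, c, rtol=1e-12)

    def test_hand_computed_trapezoid(self):
        # C_low=100 in 17.8 keV, C_up=50 in 21.4 keV, peak width 41.6 keV
        _, _, ps = _small_acquisition()
        pk, low, up = self._windows()
        ps.counts["sc178"][:] = 100.0
        ps.counts["sc214"][:] = 50.0
        expected = 0.5 * (100.0 / 17.8 + 50.0 / 21.4) * 41.6
        est = tew_estimate(ps, pk, low, up)
        assert est.flat[0] == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(165.5, abs=0.1)

    def test_missing_window_rejected(self):
        _, _, ps = _small_acquisition(windows=(photopeak_208(),))
        pk, low, up = self._windows()
        with pytest.raises(KeyError, match="window"):
            tew_estimate(ps, pk, low, up)

    def test_estimate_unbiased_under_flat_density_model(self):
        # the default scatter model has a flat per-keV density, so TEW
        # should reproduce the true photopeak scatter in expectation
        _, _, ps = _small_acquisition()
        pk, low, up = self._windows()
        est = tew_estimate(ps, pk, low, up)
        truth = ps.components["pk208"]["scatter"]
        np.testing.assert_allclose(est.sum(), truth.sum(), rtol=1e-3)


class TestOSEM:
    def test_mlem_fixed_point(self):
        # an initial image whose forward projection equals the data exactly
        # is left unchanged by a full MLEM iteration (update factors = 1)
        from qspect.simulator import ScatterModel

        grid = empty_grid(32, 32, 4.8)
        conc = 0.8
        activity = grid.with_values(np.full(grid.shape, conc), "activity")
        cfg_acq = AcquisitionConfig(
            n_projections=6, windows=(photopeak_208(),),
            orbit="circular", orbit_radius_mm=180.0,
            scatter=ScatterModel(photopeak_fraction={208: 0.0}),
        )
        ps = acquire(activity, None, cfg_acq, noise=False)
        x0 = np.full(grid.shape, conc * grid.voxel_volume_ml * 10.0)
        cfg = ReconConfig(iterations=1, subsets=1, resolution_recovery=True)
        recon = osem_reconstruct(ps, None, cfg, initial=x0)
        np.testing.assert_allclose(recon.values, x0, rtol=5e-5)

    def test_mlem_likelihood_nondecreasing_on_poisson_data(self):
        activity, mask, ps = _small_acquisition(noise=True, seed=5)
        cfg = ReconConfig(iterations=8, subsets=1, scatter_correction="ideal",
                          resolution_recovery=True)
        recon = osem_reconstruct(
            ps, None, cfg, scatter_term=ps.components["pk208"]["scatter"],
            track_loglik=True,
        )
        ll = np.asarray(recon.info["loglik"])
        assert ll.size == 8
        diffs = np.diff(ll)
        assert np.all(diffs >= -1e-6 * np.abs(ll[:-1]))

    def test_all_zero_projections_give_zero_image(self):
        activity, mask, ps = _small_acquisition()
        for name in ps.counts:
            ps.counts[name] = np.zeros_like(ps.counts[name])
        cfg = ReconConfig(iterations=3, subsets=1)
        recon = osem_reconstruct(ps, None, cfg)
        assert recon.values.max() < 1e-9

    def test_uniform_cylinder_concentration_recovered(self):
        # noise-free, matched model, ideal scatter: voxel values inside a
        # uniform cylinder (away from the edges) within 5% of truth
        grid = empty_grid(32, 32, 4.8)
        x, y, z = grid.coords()
        cyl = ((x[:, None] ** 2 + y[None, :] ** 2) <= 40.0 ** 2)[:, :, None] & (
            np.abs(z) <= 50.0)[None, None, :]
        activity = grid.with_values(np.where(cyl, 1.0, 0.0), "activity")
        cfg_acq = AcquisitionConfig(
            n_projections=24, windows=(photopeak_208(),),
            orbit="circular", orbit_radius_mm=180.0,
        )
        ps = acquire(activity, None, cfg_acq, noise=False)
        cfg = ReconConfig(iterations=20, subsets=6, scatter_correction="ideal",
                          resolution_recovery=True)
        recon = osem_reconstruct(
            ps, None, cfg, scatter_term=ps.components["pk208"]["scatter"])
        expected = 1.0 * activity.voxel_volume_ml * 10.0  # cps per voxel
        from scipy.ndimage import binary_erosion
        core = binary_erosion(cyl, iterations=2)
        got = recon.values[core].mean()
        assert got == pytest.approx(expected, rel=0.05)

    def test_subset_count_must_divide_projections(self):
        activity, mask, ps = _small_acquisition()
        cfg = ReconConfig(iterations=1, subsets=7)
        with pytest.raises(ValueError, match="subset"):
            osem_reconstruct(ps, None, cfg)

    def test_negative_scatter_term_rejected(self):
        activity, mask, ps = _small_acquisition()
        cfg = ReconConfig(iterations=1, subsets=1)
        bad = -np.ones_like(ps.counts["pk208"])
        with pytest.raises(ValueError, match="nonnegative"):
            osem_reconstruct(ps, None, cfg, scatter_term=bad)

    def test_presubtraction_equivalent_for_zero_scatter(self):
        activity, mask, ps = _small_acquisition()
        zeros = np.zeros_like(ps.counts["pk208"])
        cfg_add = ReconConfig(iterations=2, subsets=2)
        cfg_pre = ReconConfig(iterations=2, subsets=2, presubtract_scatter=True)
        r1 = osem_reconstruct(ps, None, cfg_add, scatter_term=zeros)
        r2 = osem_reconstruct(ps, None, cfg_pre, scatter_term=zeros)
        np.testing.assert_allclose(r1.values, r2.values, rtol=1e-4,
                                   atol=1e-6 * r1.values.max())


class TestSumPhotopeaks:
    def test_sum_with_zero_volume_is_identity(self):
        activity, mask, ps = _small_acquisition()
        cfg = ReconConfig(iterations=2, subsets=2)
        r = osem_reconstruct(ps, None, cfg)
        z = type(r)(r.image.with_values(np.zeros_like(r.values)))
        s = sum_photopeaks([r, z])
        np.testing.assert_allclose(s.values, r.values)

    def test_commutative_and_additive(self):
        activity, mask, ps = _small_acquisition()
        cfg = ReconConfig(iterations=2, subsets=2)
        r = osem_reconstruct(ps, None, cfg)
        r2 = type(r)(r.image.with_values(0.5 * r.values))
        s12 = sum_photopeaks([r, r2])
        s21 = sum_photopeaks([r2, r])
        np.testing.assert_allclose(s12.values, s21.values)
        assert s12.values.sum() == pytest.approx(
            r.values.sum() + r2.values.sum(), rel=1e-3)


class TestPostfilter:
    def _delta_recon(self):
        from qspect.recon import ReconVolume
        from qspect.phantom import VoxelImage
        vals = np.zeros((33, 33, 33))
        vals[16, 16, 16] = 100.0
        img = VoxelImage(vals, (2.0, 2.0, 2.0), role="counts")
        return ReconVolume(img)

    def test_zero_fwhm_identity(self):
        r = self._delta_recon()
        out = gaussian_postfilter(r, 0.0)
        np.testing.assert_array_equal(out.values, r.values)

    def test_total_preserved(self):
        r = self._delta_recon()
        out = gaussian_postfilter(r, 8.0)
        assert out.values.sum() == pytest.approx(r.values.sum(), rel=1e-3)

    def test_delta_spreads_to_requested_fwhm(self):
        r = self._delta_recon()
        out = gaussian_postfilter(r, 8.0)
        profile = out.values[:, 16, 16]
        half = profile.max() / 2.0
        above = np.flatnonzero(profile >= half)
        # linear interpolation of the half-max crossings
        lo, hi = above[0], above[-1]
        x = np.arange(profile.size)
        left = np.interp(half, [profile[lo - 1], profile[lo]], [x[lo - 1], x[lo]])
        right = np.interp(half, [profile[hi + 1], profile[hi]], [x[hi + 1], x[hi]])
        fwhm_mm = (right - left) * 2.0
        assert fwhm_mm == pytest.approx(8.0, abs=0.5)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            gaussian_postfilter(self._delta_recon(), -1.0)


def test_poisson_loglik_maximised_at_data():
    y = np.array([3.0, 7.0, 0.0, 2.0])
    best = poisson_loglik(y, y + 1e-12)
    for scale in (0.5, 0.9, 1.1, 2.0):
        assert poisson_loglik(y, y * scale + 1e-12) <= best + 1e-9
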