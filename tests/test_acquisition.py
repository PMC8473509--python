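"""Projection physics: conservation, attenuation, windows, scatter, noise."""

import numpy as np
import pytest
from scipy.special import erf

from spectiq.acquisition import (
    AcquisitionConfig,
    EnergyWindowModel,
    add_poisson,
    count_scale,
    forward_project,
    make_projector,
    rebin_time,
    simulate,
    simulate_scatter,
    window_efficiency,
)
from spectiq.phantom import PhantomSpec, build_phantom, desk_spec
from spectiq.projector import PSFModel, RotationProjector


def point_source_phantom(value=1.0, grid=(33, 33, 9), voxel=4.0):
    spec = PhantomSpec(
        sphere_concentration=value, tb_ratio=32.0, spheres=(),
        voxel_size=(voxel,) * 3, grid_shape=grid,
    )
    ph = build_phantom(spec)
    ph.activity[:] = 0.0
    ph.mu_map[:] = 0.0
    ph.labels[:] = 0
    ph.activity[grid[0] // 2, grid[1] // 2, grid[2] // 2] = value
    return ph


class TestForwardProject:
    def test_zero_activity_gives_zero_sinogram(self):
        ph = point_source_phantom(0.0)
        acq = AcquisitionConfig(bin_size=4.0, n_views=8)
        assert not forward_project(ph, acq).any()

    def test_point_source_count_conservation_per_view(self):
        ph = point_source_phantom(2.0)
        acq = AcquisitionConfig(bin_size=4.0, n_views=12)
        sino = forward_project(ph, acq, with_attenuation=False, with_psf=False)
        expected = (
            2.0 * ph.spec.voxel_volume_ml * acq.sensitivity * acq.time_per_frame
            * window_efficiency(acq.window)
        )
        assert sino.sum(axis=(1, 2)) == pytest.approx(expected, rel=0.01)

    def test_beer_lambert_through_10cm_water(self):
        # point source with 100 mm of mu=0.154/cm water between it and the
        # detector along the 0-degree ray
        ph = point_source_phantom(1.0, grid=(33, 61, 9), voxel=4.0)
        iy = 30  # source row
        ph.mu_map[:] = 0.0
        ph.mu_map[:, iy + 1 : iy + 26, :] = 0.154  # 25 voxels * 4 mm = 100 mm
        acq = AcquisitionConfig(bin_size=4.0, n_views=1)
        free = forward_project(ph, acq, with_attenuation=False, with_psf=False)
        att = forward_project(ph, acq, with_attenuation=True, with_psf=False)
        assert att.sum() / free.sum() == pytest.approx(np.exp(-1.54), rel=1e-6)

    def test_linear_in_activity(self):
        ph = point_source_phantom(1.0)
        acq = AcquisitionConfig(bin_size=4.0, n_views=4)
        proj = make_projector(ph, acq)
        rng = np.random.default_rng(5)
        a = rng.random(ph.grid_shape)
        b = rng.random(ph.grid_shape)
        lhs = proj.forward(2.0 * a + b)
        rhs = 2.0 * proj.forward(a) + proj.forward(b)
        assert lhs == pytest.approx(rhs, abs=1e-10)

    def test_adjoint_matches_forward(self):
        ph = build_phantom(desk_spec(32.0, 0.2))
        proj = RotationProjector(
            ph.grid_shape, ph.spec.voxel_size, np.array([17.0, 211.0]),
            mu_map=ph.mu_map, attenuation=True, psf=PSFModel(),
        )
        rng = np.random.default_rng(1)
        x = rng.random(ph.grid_shape)
        y = rng.random((ph.grid_shape[0], ph.grid_shape[2]))
        for i in range(2):
            lhs = float((proj.forward_view(x, i) * y).sum())
            rhs = float((x * proj.adjoint_view(y, i)).sum())
            assert rhs == pytest.approx(lhs, rel=1e-12)


class TestWindowEfficiency:
    def test_wide_window_near_total(self):
        w = EnergyWindowModel(photopeak_halfwidth_frac=0.999)
        assert window_efficiency(w) == pytest.approx(1.0, abs=1e-12)

    def test_narrow_window_near_zero(self):
        w = EnergyWindowModel(photopeak_halfwidth_frac=1e-9)
        assert window_efficiency(w) == pytest.approx(0.0, abs=1e-6)

    def test_15pct_window_6pct_resolution_closed_form(self):
        w = EnergyWindowModel()  # 140 +/- 7.5%, 6% FWHM resolution
        sigma = 0.06 * 140.0 / (2 * np.sqrt(2 * np.log(2)))
        expected = erf(10.5 / (sigma * np.sqrt(2)))
        assert window_efficiency(w) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.9967, abs=5e-4)

    def test_wider_window_accepts_more(self):
        w15 = EnergyWindowModel()
        w20 = w15.with_width(0.10)
        assert window_efficiency(w20) >= window_efficiency(w15)
        assert w20.scatter_fraction > w15.scatter_fraction

    def test_scatter_fraction_must_grow_with_width(self):
        with pytest.raises(ValueError, match="scatter fraction"):
            EnergyWindowModel(scatter_fraction_by_window={0.075: 0.3, 0.10: 0.2})


class TestSimulateScatter:
    def test_zero_primary_zero_scatter(self):
        acq = AcquisitionConfig(bin_size=5.5)
        s_pp, s_win = simulate_scatter(np.zeros((4, 8, 8)), acq)
        assert not s_pp.any() and not s_win.any()

    def test_quarter_fraction_total(self):
        acq = AcquisitionConfig(bin_size=5.5)
        primary = np.full((4, 16, 16), 50.0)
        s_pp, _ = simulate_scatter(primary, acq)
        assert acq.window.scatter_fraction == 0.25
        assert s_pp.sum() == pytest.approx(primary.sum() / 3.0, rel=1e-9)

    def test_negative_primary_rejected(self):
        acq = AcquisitionConfig(bin_size=5.5)
        with pytest.raises(ValueError):
            simulate_scatter(np.full((1, 4, 4), -1.0), acq)


class TestAddPoisson:
    def test_zero_expectation_zero_counts(self):
        assert not add_poisson(np.zeros((10, 10)), 3).any()

    def test_reproducible_for_seed(self):
        lam = np.full((50, 50), 7.0)
        assert (add_poisson(lam, 11) == add_poisson(lam, 11)).all()

    def test_moments(self):
        lam = np.full(10_000, 50.0)
        draws = add_poisson(lam, 4)
        se = np.sqrt(50.0 / lam.size)
        assert abs(draws.mean() - 50.0) < 3 * se

    def test_negative_expectation_rejected(self):
        with pytest.raises(ValueError):
            add_poisson(np.array([-0.1]), 0)


class TestRebinTime:
    def _small_projections(self):
        ph = point_source_phantom(5.0)
        acq = AcquisitionConfig(bin_size=4.0, n_views=6, time_per_frame=120.0)
        return simulate(ph, acq, noise=True, scatter=False)

    def test_full_time_identity(self):
        full = self._small_projections()
        thin = rebin_time(full, 120.0, seed=0)
        assert (thin.photopeak_counts == full.photopeak_counts).all()

    def test_zero_time_zeroes(self):
        full = self._small_projections()
        thin = rebin_time(full, 0.0, seed=0)
        assert not thin.photopeak_counts.any()

    def test_longer_than_acquired_rejected(self):
        full = self._small_projections()
        with pytest.raises(ValueError):
            rebin_time(full, 121.0, seed=0)

    def test_binomial_moments_120_to_40(self):
        full = self._small_projections()
        n = full.photopeak_counts.sum()
        thin = rebin_time(full, 40.0, seed=2)
        p = 1.0 / 3.0
        sd = np.sqrt(n * p * (1 - p))
        assert abs(thin.photopeak_counts.sum() - n * p) < 3 * sd

    def test_composed_thinning_equivalent_in_distribution(self):
        full = self._small_projections()
        once, twice = [], []
        for s in range(50):
            once.append(rebin_time(full, 30.0, seed=s).photopeak_counts.sum())
            half = rebin_time(full, 60.0, seed=1000 + s)
            twice.append(rebin_time(half, 30.0, seed=2000 + s).photopeak_counts.sum())
        once, twice = np.array(once), np.array(twice)
        pooled_se = np.sqrt(once.var(ddof=1) / 50 + twice.var(ddof=1) / 50)
        assert abs(once.mean() - twice.mean()) < 3 * pooled_se


def test_simulate_determinism(desk_phantom, desk_acq):
    a = simulate(desk_phantom, desk_acq)
    b = simulate(desk_phantom, desk_acq)
    assert (a.photopeak_counts == b.photopeak_counts).all()
    assert (a.scatterwin_counts == b.scatterwin_counts).all()


def test_count_scale_inverts_sensitivity(desk_phantom, desk_acq):
    s = count_scale(desk_phantom, desk_acq)
    expected = (
        desk_phantom.spec.voxel_volume_ml * desk_acq.sensitivity
        * desk_acq.time_per_frame * window_efficiency(desk_acq.window)
    )
    assert s == pytest.approx(expected, rel=1e-12)
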