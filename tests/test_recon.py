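"""EM correctness on toy systems, DEW formula, filters, corrections plumbing."""

import numpy as np
import pytest

from spectiq.recon import (
    MatrixOperator,
    OSEMModel,
    ReconConfig,
    ReconVolume,
    dew_scatter_estimate,
    fwhm_to_sigma,
    gaussian_postfilter,
    osem,
    poisson_loglik,
    subset_views,
)


def reference_mlem(A, y, x0, n_iter):
    """Independent plain-numpy MLEM loop (no subsets, same guard rules)."""
    s = A.T @ np.ones(A.shape[0])
    mask = s > 1e-8 * s.max()
    x = x0.copy()
    for _ in range(n_iter):
        fp = A @ x
        ratio = np.divide(y, fp, out=np.zeros_like(fp), where=fp > 0)
        upd = np.divide(A.T @ ratio, s, out=np.ones_like(x), where=mask)
        x = np.where(mask, x * upd, x)
    return x


def random_system(n_bins, n_vox, seed):
    rng = np.random.default_rng(seed)
    A = rng.random((n_bins, n_vox))
    x_true = rng.random(n_vox) * 10
    y = rng.poisson(A @ x_true).astype(float)
    return A, x_true, y


class TestOsemCore:
    def test_one_subset_is_bitwise_mlem(self):
        A, _, y = random_system(24, 16, 0)
        x0 = np.ones(16)
        ref = reference_mlem(A, y, x0, 20)
        x, _ = osem(y, MatrixOperator(A), n_iterations=20, n_subsets=1, x0=x0)
        assert np.array_equal(x, ref)

    def test_mlem_loglik_nondecreasing_16x16(self):
        A, _, y = random_system(16, 16, 1)
        _, ll = osem(
            y, MatrixOperator(A), n_iterations=30, n_subsets=1,
            x0=np.ones(16), track_loglik=True,
        )
        diffs = np.diff(ll)
        assert (diffs > -1e-9).all()

    def test_2x2_matches_brute_force_em(self):
        A = np.array([[0.8, 0.2], [0.3, 0.7]])
        y = np.array([10.0, 5.0])
        # brute-force EM recursion written out elementwise
        x = np.array([1.0, 1.0])
        s = A.sum(axis=0)
        for _ in range(500):
            fp0 = A[0, 0] * x[0] + A[0, 1] * x[1]
            fp1 = A[1, 0] * x[0] + A[1, 1] * x[1]
            x = np.array([
                x[0] / s[0] * (A[0, 0] * y[0] / fp0 + A[1, 0] * y[1] / fp1),
                x[1] / s[1] * (A[0, 1] * y[0] / fp0 + A[1, 1] * y[1] / fp1),
            ])
        ours, _ = osem(y, MatrixOperator(A), n_iterations=500, n_subsets=1, x0=np.ones(2))
        assert ours == pytest.approx(x, abs=1e-8)
        # at the fixed point the model reproduces the data
        assert A @ ours == pytest.approx(y, rel=1e-6)

    def test_count_consistency_at_convergence(self):
        A, _, y = random_system(40, 25, 3)
        x, _ = osem(y, MatrixOperator(A), n_iterations=400, n_subsets=1, x0=np.ones(25))
        assert (A @ x).sum() == pytest.approx(y.sum(), rel=0.005)

    def test_nonnegativity_preserved(self):
        A, _, y = random_system(30, 20, 4)
        x, _ = osem(y, MatrixOperator(A), n_iterations=50, n_subsets=5, x0=np.ones(20))
        assert (x >= 0).all()

    def test_osem_with_scatter_term_converges_to_data(self):
        A, x_true, _ = random_system(30, 20, 5)
        s = np.full(30, 2.0)
        y = A @ x_true + s  # noiseless with known additive term
        x, _ = osem(y, MatrixOperator(A), n_iterations=8000, n_subsets=1,
                    x0=np.ones(20), scatter=s)
        assert A @ x + s == pytest.approx(y, rel=1e-3)


class TestSubsets:
    def test_stride_partition_covers_all_views(self):
        subs = subset_views(60, 20)
        assert len(subs) == 20
        assert sorted(np.concatenate(subs)) == list(range(60))

    def test_uneven_partition_sizes_differ_by_at_most_one(self):
        subs = subset_views(60, 7)
        sizes = {len(s) for s in subs}
        assert max(sizes) - min(sizes) <= 1
        assert sorted(np.concatenate(subs)) == list(range(60))


class TestDewEstimate:
    def test_zero_counts_zero_estimate(self):
        est = dew_scatter_estimate(np.zeros((3, 4)), 0.5, 21.0, 12.0)
        assert not est.values.any()

    def test_equal_widths_formula(self):
        est = dew_scatter_estimate(np.full(4, 100.0), 0.5, 12.0, 12.0)
        assert est.values == pytest.approx(50.0)

    def test_15pct_photopeak_vs_scatter_window(self):
        est = dew_scatter_estimate(np.array([100.0]), 0.5, 21.0, 12.0)
        assert est.values[0] == pytest.approx(87.5)

    def test_zero_width_rejected(self):
        with pytest.raises(ValueError):
            dew_scatter_estimate(np.ones(3), 0.5, 21.0, 0.0)


class TestFwhmSigma:
    @pytest.mark.parametrize(
        "fwhm,sigma", [(2.3548, 1.0000), (0.0, 0.0), (6.99, 2.9684)]
    )
    def test_closed_form(self, fwhm, sigma):
        assert fwhm_to_sigma(fwhm) == pytest.approx(sigma, abs=1e-4)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            fwhm_to_sigma(-1.0)


def _volume(values, voxel=1.0):
    return ReconVolume(values=values, voxel_size=(voxel,) * 3,
                       recon_config=ReconConfig(iterations=1, subsets=1))


class TestGaussianPostfilter:
    def test_delta_profile_fwhm(self):
        vol = np.zeros((41, 41, 41))
        vol[20, 20, 20] = 1.0
        f = 6.0
        out = gaussian_postfilter(_volume(vol), f).values
        profile = out[:, 20, 20]
        half = profile.max() / 2
        above = np.flatnonzero(profile >= half)
        measured = above[-1] - above[0] + 1
        assert abs(measured - f) <= 1.0  # voxel units = mm here

    def test_uniform_volume_unchanged(self):
        vol = np.full((16, 16, 16), 3.7)
        out = gaussian_postfilter(_volume(vol), 4.0).values
        assert out == pytest.approx(3.7, abs=1e-10)

    def test_mass_preserved(self):
        rng = np.random.default_rng(0)
        vol = np.zeros((32, 32, 32))
        vol[12:20, 12:20, 12:20] = rng.random((8, 8, 8))
        out = gaussian_postfilter(_volume(vol), 5.0).values
        assert out.sum() == pytest.approx(vol.sum(), rel=1e-3)

    def test_strictly_contractive_even_subvoxel(self):
        vol = np.zeros((24, 24, 24))
        vol[12, 12, 12] = 1.0
        p0 = gaussian_postfilter(_volume(vol, voxel=5.5), 0.7).values[12, 12, 12]
        p1 = gaussian_postfilter(_volume(vol, voxel=5.5), 2.0).values[12, 12, 12]
        assert p0 < 1.0
        assert p1 < p0


class TestReconConfig:
    def test_corrections_parser(self):
        cfg = ReconConfig.with_corrections("AC,SC,RR")
        assert cfg.corrections == frozenset({"AC", "SC", "RR"})
        assert ReconConfig.with_corrections("AC+RR").corrections_tag == "AC+RR"

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            ReconConfig(iterations=0)
        with pytest.raises(ValueError):
            ReconConfig(post_filter_fwhm=0.0)
        with pytest.raises(ValueError):
            ReconConfig.with_corrections("AC+XX")


class TestEndToEndRecon:
    def test_matched_model_short_run_recovers_large_sphere_shape(
        self, desk_phantom, noiseless_projections
    ):
        cfg = ReconConfig(iterations=8, subsets=12, corrections=frozenset({"AC", "RR"}))
        res = OSEMModel(
            noiseless_projections, desk_phantom.mu_map, cfg, desk_phantom.spec.voxel_size
        ).fit()
        assert (res.values >= 0).all()
        hot = res.values[desk_phantom.labels == 2].mean()
        bkg = res.values[desk_phantom.labels == 1].mean()
        assert hot > 5 * bkg  # 32:1 contrast mostly recovered
        assert "OSEM" in res.summary()

    def test_presubtraction_mode_runs_and_stays_nonnegative(
        self, desk_phantom, noisy_projections
    ):
        cfg = ReconConfig(iterations=2, subsets=12, presubtract_scatter=True)
        res = OSEMModel(
            noisy_projections, desk_phantom.mu_map, cfg, desk_phantom.spec.voxel_size
        ).fit()
        assert (res.values >= 0).all()
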