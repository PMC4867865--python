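"""Synthetic generators: 1D curves, phantom geometry/kinetics, metrics."""

import numpy as np
import pytest

import petfda as pf
from petfda.simulate import FWHM_TO_SIGMA, _survival_irf


class TestInputFunction:
    def test_starts_at_zero_and_positive(self):
        aif = pf.synthetic_input_function(tau=1000.0)
        assert aif(0.0) == 0.0
        assert np.all(aif.values[1:] > 0)

    def test_peak_location_and_amplitude(self):
        shape, scale, peak = 4.0, 15.0, 200.0
        aif = pf.synthetic_input_function(shape, scale, peak, tau=600.0,
                                          n_samples=6001)
        tmax = aif.times[np.argmax(aif.values)]
        assert tmax == pytest.approx((shape - 1) * scale, abs=0.5)
        assert aif.values.max() == pytest.approx(peak, rel=1e-6)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            pf.synthetic_input_function(shape=1.0)
        with pytest.raises(ValueError):
            pf.synthetic_input_function(scale=-5.0)


class TestSim1D:
    def test_dimensions_match_design(self):
        data = pf.simulate_1d_dataset(pf.Sim1DConfig(seed=0))
        assert data.noisy.shape == (200, 200)
        assert data.times.shape == (200,)

    def test_basis_normalization_constant(self):
        # c1 = (int_0^2000 sin^2(2 pi t/2000) dt)^{-1/2} = sqrt(2/2000)
        cfg = pf.Sim1DConfig()
        t = np.linspace(0, 2000, 20001)
        psi = cfg.basis(t)
        c1 = psi[0].max()
        assert c1 == pytest.approx(np.sqrt(2.0 / 2000.0), rel=1e-6)
        assert np.trapezoid(psi[0] ** 2, t) == pytest.approx(1.0, rel=1e-4)

    def test_mean_irf_at_origin(self):
        cfg = pf.Sim1DConfig()
        assert cfg.mean_irf(0.0) == pytest.approx(0.0049 + 0.0018)

    def test_noise_level_recovered_empirically(self):
        data = pf.simulate_1d_dataset(pf.Sim1DConfig(seed=5))
        sd = np.std(data.noisy - data.clean)
        assert sd == pytest.approx(2.0, rel=0.02)   # 40,000 draws

    def test_bitwise_reproducible(self):
        a = pf.simulate_1d_dataset(pf.Sim1DConfig(seed=42))
        b = pf.simulate_1d_dataset(pf.Sim1DConfig(seed=42))
        np.testing.assert_array_equal(a.noisy, b.noisy)
        np.testing.assert_array_equal(a.scores, b.scores)


class TestClosedFormVT:
    def test_region2_anchor(self):
        assert round(pf.closed_form_vt([0.0060], [0.0030]), 2) == 2.00

    def test_region5_anchor(self):
        assert round(pf.closed_form_vt([0.0007], [0.0377]), 2) == 0.02

    def test_finite_horizon(self):
        vt = pf.closed_form_vt([0.0060], [0.0030], tau=1000.0)
        assert vt == pytest.approx(2.0 * (1 - np.exp(-3.0)), rel=1e-12)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            pf.closed_form_vt([0.1], [0.0])


class TestPhantomLabels:
    def test_partition_every_pixel_once(self):
        cfg = pf.PhantomConfig()
        labels = pf.build_phantom_labels(cfg)
        counts = {r.label: r.size for r in cfg.regions}
        for lab, size in counts.items():
            assert (labels == lab).sum() == size
        assert (labels >= 0).all()

    def test_printed_region_sizes(self):
        labels = pf.build_phantom_labels(pf.PhantomConfig())
        sizes = [(labels == lab).sum() for lab in (1, 2, 3, 4, 5)]
        assert sizes == [9614, 5351, 3701, 414, 5704]

    def test_single_region_constant_inside(self):
        cfg = pf.PhantomConfig(grid_shape=(10, 10),
                               regions=[pf.RegionSpec(1, 100, alphas=(),
                                                      betas=())])
        labels = pf.build_phantom_labels(cfg)
        assert (labels == 1).all()

    def test_oversized_regions_rejected(self):
        cfg = pf.PhantomConfig(grid_shape=(8, 8),
                               regions=[pf.RegionSpec(1, 100, alphas=(),
                                                      betas=())])
        with pytest.raises(ValueError):
            pf.build_phantom_labels(cfg)


class TestPhantomScan:
    def test_fwhm_to_sigma_identity(self):
        # FWHM 6 mm at 2 mm pixels -> sigma ~ 1.274 px
        assert 6.0 * FWHM_TO_SIGMA / 2.0 == pytest.approx(1.274, abs=1e-3)

    def test_noise_free_unblurred_matches_analytic_convolution(self):
        # bolus input I = t e^{-at} gives a closed-form convolution oracle
        alpha, beta, a = 0.0060, 0.0030, 0.01
        region = pf.RegionSpec(2, 64, alphas=(alpha,), betas=(beta,),
                               vt_cv=0.0)
        cfg = pf.PhantomConfig(grid_shape=(8, 8), regions=[region],
                               psf_fwhm_mm=0.0, kappa=0.0, lam=0.0, seed=0,
                               m_fine=2000)
        tau = cfg.schedule.mid[-1]
        ts = np.linspace(0, tau, 4001)
        aif = pf.InputFunction(ts, ts * np.exp(-a * ts))
        scan, truth = pf.simulate_phantom_scan(cfg, aif)
        t = scan.frame_times
        c = a - beta
        exact = alpha * np.exp(-beta * t) * (1 - (1 + c * t) * np.exp(-c * t)) / c**2
        np.testing.assert_allclose(
            scan.curves, np.broadcast_to(exact, scan.curves.shape),
            rtol=5e-3, atol=5e-3)

    def test_vt_jitter_has_target_cv(self):
        region = pf.RegionSpec(2, 4000, alphas=(0.0060,), betas=(0.0030,))
        cfg = pf.PhantomConfig(grid_shape=(80, 80), regions=[region],
                               psf_fwhm_mm=0.0, kappa=0.0, seed=3,
                               m_fine=200)
        scan, truth = pf.simulate_phantom_scan(cfg)
        vt = truth.vt[scan.mask]
        cv = vt.std() / vt.mean()
        assert cv == pytest.approx(0.065, abs=0.01)

    def test_survival_irf_integrates_to_drawn_target(self):
        region = pf.RegionSpec(2, 50, kind="survival", weights=(0.7, 0.3),
                               gamma_shapes=(1.5, 10.0),
                               gamma_shape_sds=(0.05, 0.5),
                               gamma_scales=(2.0, 1.5),
                               gamma_scale_sds=(0.2, 0.1), vt_mean=1.97)
        cfg = pf.PhantomConfig(grid_shape=(8, 8), regions=[region],
                               psf_fwhm_mm=0.0, kappa=0.0, seed=1, m_fine=400)
        scan, truth = pf.simulate_phantom_scan(cfg)
        w = pf.trapezoid_weights(truth.grid.response_nodes)
        np.testing.assert_allclose(truth.irf @ w, truth.vt[scan.mask],
                                   rtol=1e-10)
        assert truth.vt[scan.mask].mean() == pytest.approx(1.97, rel=0.05)

    def test_survival_shape_is_decreasing_from_one(self):
        s = np.linspace(0, 5000, 200)
        S = _survival_irf(s, (0.7, 0.3), (1.5, 10.0), (2.0, 1.5))
        assert S[0] == pytest.approx(1.0)
        assert np.all(np.diff(S) <= 1e-12)

    def test_reproducible_given_seed(self):
        region = pf.RegionSpec(2, 60, alphas=(0.0060,), betas=(0.0030,))
        cfg = lambda: pf.PhantomConfig(grid_shape=(10, 10), regions=[region],
                                       seed=21, m_fine=150)
        s1, t1 = pf.simulate_phantom_scan(cfg())
        s2, t2 = pf.simulate_phantom_scan(cfg())
        np.testing.assert_array_equal(s1.values, s2.values)
        np.testing.assert_array_equal(t1.vt, t2.vt)

    def test_default_kappa_matches_target_snr(self):
        region = pf.RegionSpec(2, 60, alphas=(0.0060,), betas=(0.0030,))
        cfg = pf.PhantomConfig(grid_shape=(10, 10), regions=[region],
                               psf_fwhm_mm=0.0, seed=2, m_fine=150)
        scan, truth = pf.simulate_phantom_scan(cfg)
        assert truth.kappa > 0
        # noise sd at the median voxel ~ median signal / target_snr
        clean_cfg = pf.PhantomConfig(grid_shape=(10, 10), regions=[region],
                                     psf_fwhm_mm=0.0, kappa=0.0, seed=2,
                                     m_fine=150)
        clean, _ = pf.simulate_phantom_scan(clean_cfg)
        med = np.median(clean.curves.mean(1))
        assert np.sqrt(truth.kappa * med) == pytest.approx(med / 5.0, rel=1e-6)


class TestMetrics:
    def test_exact_estimate_zero_error(self, rng):
        t = np.linspace(0, 100, 50)
        M = rng.normal(0, 1, (4, 50))
        assert pf.mise(M, M, t) == 0.0

    def test_constant_offset_mise(self):
        t = np.linspace(0.0, 10.0, 101)
        M = np.zeros((3, 101))
        assert pf.mise(M + 0.5, M, t) == pytest.approx(0.25 * 10.0, rel=1e-9)

    def test_regional_vt_mse_constant_offset(self):
        labels = np.array([1, 1, 2, 2])
        vt_true = np.array([1.0, 1.0, 2.0, 2.0])
        mse = pf.vt_mse_by_region(vt_true + np.array([0.1, 0.1, 0.3, 0.3]),
                                  vt_true, labels)
        assert mse[1] == pytest.approx(0.01)
        assert mse[2] == pytest.approx(0.09)
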