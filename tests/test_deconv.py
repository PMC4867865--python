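"""Convolution operator, deconvolution solves, IRF/V_T assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import petfda as pf
from petfda.deconv import trapezoid_weights


def flat_input(tau=10.0):
    return pf.InputFunction(np.linspace(0, tau, 101), np.ones(101))


class TestOperator:
    def test_row_entries_unit_input_unit_spacing(self):
        grid = pf.QuadratureGrid(np.arange(0.0, 6.0))
        op = pf.build_convolution_operator(flat_input(), grid)
        # row for s_3: weights (s_1/2, s_2/2, (s_3 - s_1)/2) = (0.5, 1, 1)
        np.testing.assert_allclose(op.matrix[2, :3], [0.5, 1.0, 1.0])
        assert op.matrix[2].sum() == pytest.approx(2.5)

    def test_strictly_lower_triangular_above_diagonal_zero(self, gamma_aif):
        grid = pf.QuadratureGrid.uniform(2000.0, 40)
        op = pf.build_convolution_operator(gamma_aif, grid)
        assert np.all(op.matrix[np.triu_indices(40, k=1)] == 0.0)

    def test_positive_diagonal_makes_operator_invertible(self, gamma_aif):
        grid = pf.QuadratureGrid.uniform(2000.0, 50)
        op = pf.build_convolution_operator(gamma_aif, grid)
        assert np.all(np.diag(op.matrix) > 0)

    def test_grid_beyond_domain_rejected(self, gamma_aif):
        with pytest.raises(ValueError):
            pf.build_convolution_operator(gamma_aif,
                                          pf.QuadratureGrid.uniform(3000.0, 20))

    def test_grid_must_start_at_zero(self):
        with pytest.raises(ValueError):
            pf.QuadratureGrid(np.array([1.0, 2.0, 3.0]))


class TestForwardConvolve:
    def test_zero_in_zero_out(self, gamma_aif):
        op = pf.build_convolution_operator(gamma_aif,
                                           pf.QuadratureGrid.uniform(2000.0, 30))
        np.testing.assert_array_equal(pf.forward_convolve(np.zeros(30), op),
                                      np.zeros(30))

    def test_unit_input_unit_response_ramp(self):
        m = 8
        grid = pf.QuadratureGrid(np.arange(0.0, m + 1.0))
        op = pf.build_convolution_operator(flat_input(), grid)
        c = pf.forward_convolve(np.ones(m), op)
        np.testing.assert_allclose(c, np.arange(1, m + 1) - 0.5)

    def test_matches_closed_form_gamma_exponential_pair(self):
        # I = t e^{-at} (bolus, I(0)=0), M = e^{-bt}:
        # (I*M)(t) = e^{-bt} (1 - (1 + ct) e^{-ct}) / c^2, c = a - b
        a, b, tau = 0.05, 0.01, 100.0
        t_samp = np.linspace(0, tau, 501)
        aif = pf.InputFunction(t_samp, t_samp * np.exp(-a * t_samp))
        grid = pf.QuadratureGrid.uniform(tau, 400)
        op = pf.build_convolution_operator(aif, grid)
        conv = pf.forward_convolve(np.exp(-b * grid.response_nodes), op)
        t = grid.signal_nodes
        c = a - b
        exact = np.exp(-b * t) * (1 - (1 + c * t) * np.exp(-c * t)) / c**2
        # quadrature error ~3e-5 of the curve peak at this resolution
        assert np.max(np.abs(conv - exact)) < 1e-4 * exact.max()

    def test_length_mismatch_rejected(self, gamma_aif):
        op = pf.build_convolution_operator(gamma_aif,
                                           pf.QuadratureGrid.uniform(2000.0, 30))
        with pytest.raises(ValueError):
            pf.forward_convolve(np.zeros(29), op)


class TestDeconvolve:
    def test_round_trip_exact(self, gamma_aif, rng):
        grid = pf.QuadratureGrid.uniform(2000.0, 100)
        op = pf.build_convolution_operator(gamma_aif, grid)
        M = np.exp(-0.002 * grid.response_nodes) * (1 + 0.1 * rng.normal(size=100))
        rec = pf.deconvolve_curve(pf.forward_convolve(M, op), op)
        np.testing.assert_allclose(rec, M, atol=1e-9)

    def test_ramp_deconvolves_to_unit_derivative(self):
        grid = pf.QuadratureGrid(np.arange(0.0, 21.0))
        op = pf.build_convolution_operator(flat_input(25.0), grid)
        f = grid.signal_nodes.astype(float)   # f(s_j) = s_j
        rec = pf.deconvolve_curve(f, op)
        np.testing.assert_allclose(rec[1:-1], np.ones(18), atol=1e-8)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(a=st.floats(-3, 3), b=st.floats(-3, 3), seed=st.integers(0, 5))
    def test_linearity(self, a, b, seed):
        aif = flat_input(30.0)
        grid = pf.QuadratureGrid.uniform(20.0, 15)
        op = pf.build_convolution_operator(aif, grid)
        r = np.random.default_rng(seed)
        f, g = r.normal(size=15), r.normal(size=15)
        lhs = pf.deconvolve_curve(a * f + b * g, op)
        rhs = a * pf.deconvolve_curve(f, op) + b * pf.deconvolve_curve(g, op)
        np.testing.assert_allclose(lhs, rhs, atol=1e-8)

    def test_ridge_shrinks_solution_norm(self, gamma_aif):
        grid = pf.QuadratureGrid.uniform(2000.0, 60)
        op = pf.build_convolution_operator(gamma_aif, grid)
        f = pf.forward_convolve(np.exp(-0.001 * grid.response_nodes), op)
        plain = pf.deconvolve_curve(f, op)
        shrunk = pf.deconvolve_curve(f, op, ridge=1e3)
        assert np.linalg.norm(shrunk) < np.linalg.norm(plain)


class TestResample:
    def test_constant_extension_below_first_frame(self):
        grid = pf.QuadratureGrid.uniform(100.0, 10)
        vals = np.array([7.0, 8.0, 9.0])
        times = np.array([35.0, 60.0, 100.0])
        out = pf.resample_to_grid(vals, times, grid)
        assert np.all(out[grid.signal_nodes < 35.0] == 7.0)
        assert out[-1] == 9.0


class TestIrfVt:
    def _basis(self, gamma_aif):
        grid = pf.QuadratureGrid.uniform(2000.0, 80)
        op = pf.build_convolution_operator(gamma_aif, grid)
        t = np.linspace(20, 2000, 50)
        mean_vals = 0.005 * np.exp(-0.001 * t)
        phis = np.stack([np.sin(np.pi * t / 2000), np.cos(np.pi * t / 2000)])
        return pf.deconvolve_basis(mean_vals, phis, t, op)

    def test_mean_only_voxel(self, gamma_aif):
        basis = self._basis(gamma_aif)
        res = pf.estimate_irf_vt(basis, a0=[1.0], scores=[[0.3, 0.4]],
                                 n_components=[0], return_irf=True)
        assert res.vt[0] == pytest.approx(basis.v0)
        np.testing.assert_allclose(res.irf[0], basis.mu_d)

    def test_vt_linear_form_exact(self, gamma_aif, rng):
        basis = self._basis(gamma_aif)
        a0 = rng.normal(1, 0.1, 6)
        sc = rng.normal(0, 1, (6, 2))
        res = pf.estimate_irf_vt(basis, a0, sc, np.full(6, 2))
        np.testing.assert_allclose(
            res.vt, a0 * basis.v0 + sc @ basis.vk, rtol=1e-14)

    def test_excess_components_rejected(self, gamma_aif):
        basis = self._basis(gamma_aif)
        with pytest.raises(ValueError):
            pf.estimate_irf_vt(basis, [1.0], [[0.0, 0.0]], [3])

    def test_noise_free_single_exponential_vt(self):
        # full basis-deconvolution path vs the closed-form finite integral
        alpha, beta, tau = 0.006, 0.003, 2000.0
        aif = pf.synthetic_input_function(tau=tau)
        fine = pf.QuadratureGrid.uniform(tau, 800)
        op_f = pf.build_convolution_operator(aif, fine)
        C = pf.forward_convolve(alpha * np.exp(-beta * fine.response_nodes), op_f)
        frame_t = np.linspace(10, tau, 60)
        c_frames = np.interp(frame_t, fine.signal_nodes, C)
        grid = pf.QuadratureGrid.uniform(tau, 250)
        op = pf.build_convolution_operator(aif, grid)
        basis = pf.deconvolve_basis(c_frames, np.zeros((0, 60)), frame_t, op)
        truth = pf.closed_form_vt([alpha], [beta], tau)
        assert basis.v0 == pytest.approx(truth, rel=0.02)


class TestOperatorConsistency:
    def test_error_shrinks_quadratically_with_m(self):
        # I(0) = 0 input (physical bolus); the discretization is then
        # second-order.  With I(0) > 0 it degrades to first order because
        # the quadrature rule omits the I(0) M(s_j) endpoint triangle.
        a, b, tau = 0.05, 0.01, 200.0
        t_samp = np.linspace(0, tau, 2001)
        aif = pf.InputFunction(t_samp, t_samp * np.exp(-a * t_samp))
        c = a - b
        errs = []
        for m in (125, 250, 500):
            grid = pf.QuadratureGrid.uniform(tau, m)
            op = pf.build_convolution_operator(aif, grid)
            conv = pf.forward_convolve(np.exp(-b * grid.response_nodes), op)
            t = grid.signal_nodes
            exact = np.exp(-b * t) * (1 - (1 + c * t) * np.exp(-c * t)) / c**2
            errs.append(np.max(np.abs(conv - exact)))
        assert errs[0] / errs[1] > 3.0
        assert errs[1] / errs[2] > 3.0


def test_trapezoid_weights_integrate_linear_exactly():
    x = np.array([0.0, 1.0, 3.0, 7.0])
    w = trapezoid_weights(x)
    assert w @ x == pytest.approx(np.trapezoid(x, x))
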