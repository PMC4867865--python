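"""Comparator methods: curve-by-curve deconvolution and spectral analysis.

Curve-by-curve (CC) applies the same triangular least-squares
deconvolution used on the FPCA basis, but independently to every voxel
curve — the brute-force alternative whose noise amplification the
functional approach avoids.

Spectral analysis expands each decay-corrected curve on input-convolved
decaying exponentials ``(I * e^{-beta_g t})`` with nonnegative
coefficients (the compartmental-model-compatible basis), solved by NNLS;
V_T follows in closed form from the coefficients.  Applied to raw
curves it mimics conventional PET spectral analysis; applied to
presmoothed curves it is the "preprocessed" variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .datamodel import InputFunction
from .deconv import (ConvolutionOperator, QuadratureGrid,
                     build_convolution_operator, deconvolve_curve,
                     forward_convolve, resample_to_grid, trapezoid_weights)


def curvewise_deconvolve(curves: np.ndarray, frame_times: np.ndarray,
                         operator: ConvolutionOperator, ridge: float = 0.0
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel deconvolution: returns (IRFs (n, m), V_T (n,)).

    Curves are decay-corrected values on the frame grid; each is linearly
    interpolated to the quadrature grid and solved independently.
    """
    curves = np.atleast_2d(np.asarray(curves, float))
    on_grid = resample_to_grid(curves, frame_times, operator.grid)
    irf = deconvolve_curve(on_grid.T, operator, ridge=ridge).T
    w = trapezoid_weights(operator.grid.response_nodes)
    return irf, irf @ w


@dataclass(frozen=True)
class SpectralBasisConfig:
    """Grid of decay rates beta_g (1/s) for the exponential basis."""

    rates: np.ndarray = None

    def __post_init__(self):
        rates = self.rates
        if rates is None:
            rates = np.logspace(-5, 0, 64)
        rates = np.asarray(rates, float)
        if np.any(rates <= 0) or np.any(np.diff(rates) <= 0):
            raise ValueError("rates must be positive and strictly increasing")
        object.__setattr__(self, "rates", rates)

    @property
    def n_rates(self) -> int:
        return len(self.rates)


def spectral_basis_matrix(input_function: InputFunction, frame_times: np.ndarray,
                          config: SpectralBasisConfig,
                          grid: QuadratureGrid | None = None) -> np.ndarray:
    """Basis (p, G): (I * e^{-beta_g .}) evaluated at the frame times."""
    frame_times = np.asarray(frame_times, float)
    if grid is None:
        grid = QuadratureGrid.uniform(input_function.tau)
    op = build_convolution_operator(input_function, grid)
    E = np.exp(-config.rates[None, :] * grid.response_nodes[:, None])  # (m, G)
    conv = forward_convolve(E, op)                                     # (m, G)
    out = np.empty((len(frame_times), config.n_rates))
    for g in range(config.n_rates):
        out[:, g] = np.interp(frame_times, grid.signal_nodes, conv[:, g])
    return out


def spectral_nnls(curves: np.ndarray, input_function: InputFunction,
                  frame_times: np.ndarray, tau: float,
                  config: SpectralBasisConfig | None = None,
                  grid: QuadratureGrid | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """NNLS spectral analysis of decay-corrected curves.

    Returns (theta (n, G) >= 0, V_T (n,)) with
    ``V_T = sum_g theta_g (1 - e^{-beta_g tau}) / beta_g``.
    """
    if config is None:
        config = SpectralBasisConfig()
    curves = np.atleast_2d(np.asarray(curves, float))
    if not np.all(np.isfinite(curves)):
        raise ValueError("curves must be finite")
    B = spectral_basis_matrix(input_function, frame_times, config, grid)
    theta = np.empty((len(curves), config.n_rates))
    for i, c in enumerate(curves):
        theta[i], _ = nnls(B, c)
    vt_weights = (1.0 - np.exp(-config.rates * tau)) / config.rates
    return theta, theta @ vt_weights


class CurveByCurveDeconvolver:
    """sklearn-style wrapper: fit builds the operator, predict returns V_T."""

    def __init__(self, input_function: InputFunction = None, frame_times=None,
                 m: int = 250, ridge: float = 0.0, tau: float | None = None):
        self.input_function = input_function
        self.frame_times = frame_times
        self.m = m
        self.ridge = ridge
        self.tau = tau

    def fit(self, X=None, y=None):
        t = np.asarray(self.frame_times, float)
        tau = self.tau if self.tau is not None else float(t[-1])
        self.grid_ = QuadratureGrid.uniform(tau, self.m)
        self.operator_ = build_convolution_operator(self.input_function, self.grid_)
        return self

    def predict(self, X):
        """V_T of each decay-corrected curve (rows of X)."""
        _, vt = curvewise_deconvolve(X, np.asarray(self.frame_times, float),
                                     self.operator_, ridge=self.ridge)
        return vt

    def deconvolve(self, X):
        irf, _ = curvewise_deconvolve(X, np.asarray(self.frame_times, float),
                                      self.operator_, ridge=self.ridge)
        return irf

    def get_params(self, deep=True):
        return {k: getattr(self, k) for k in
                ("input_function", "frame_times", "m", "ridge", "tau")}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self


class SpectralNNLS:
    """sklearn-style wrapper for NNLS spectral analysis."""

    def __init__(self, input_function: InputFunction = None, frame_times=None,
                 rates=None, m: int = 250, tau: float | None = None):
        self.input_function = input_function
        self.frame_times = frame_times
        self.rates = rates
        self.m = m
        self.tau = tau

    def fit(self, X=None, y=None):
        t = np.asarray(self.frame_times, float)
        self.tau_ = self.tau if self.tau is not None else float(t[-1])
        self.config_ = SpectralBasisConfig(None if self.rates is None
                                           else np.asarray(self.rates, float))
        self.grid_ = QuadratureGrid.uniform(self.input_function.tau, self.m)
        self.basis_ = spectral_basis_matrix(self.input_function, t,
                                            self.config_, self.grid_)
        return self

    def predict(self, X):
        theta = self.coefficients(X)
        rates = self.config_.rates
        return theta @ ((1.0 - np.exp(-rates * self.tau_)) / rates)

    def coefficients(self, X):
        X = np.atleast_2d(np.asarray(X, float))
        theta = np.empty((len(X), self.config_.n_rates))
        for i, c in enumerate(X):
            theta[i], _ = nnls(self.basis_, c)
        return theta

    def get_params(self, deep=True):
        return {k: getattr(self, k) for k in
                ("input_function", "frame_times", "rates", "m", "tau")}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self
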