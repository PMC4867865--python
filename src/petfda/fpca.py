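"""Multiplicative-random-effect functional PCA for voxel time courses.

The decay-corrected concentration curves are modelled with a modified
Karhunen-Loeve expansion

    C_i(t) = A_i0 mu(t) + sum_k A_ik phi_k(t),

where the voxel-specific scalar A_i0 (mean 1) captures multiplicative
amplitude variation — the natural effect of spatially varying receptor
density on otherwise similarly shaped kinetics — and the phi_k are the
eigenfunctions of the covariance of the residual C_i - A_i0 mu.

Estimation details that matter:

* the mean is the *unsmoothed* cross-sectional average of the measured
  (decayed) data, decay-corrected pointwise: smoothing before the
  exponential decay correction would bias it;
* A_i0 is the quadrature regression coefficient of the (smoothed) voxel
  curve on the mean, so residuals are exactly orthogonal to the mean;
* the residual covariance is the plain second moment (no re-centering),
  which keeps it positive semi-definite;
* the per-voxel number of components L is chosen by an R^2 increment
  rule with threshold 0.025 on the measured scale.

All functional inner products use composite-trapezoid quadrature on the
frame-time grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from sklearn.base import BaseEstimator, TransformerMixin

from .datamodel import DynamicScan, X_SCALE
from .deconv import trapezoid_weights

DEFAULT_KMAX = 10
DEFAULT_R2_THRESHOLD = 0.025
EIGENVALUE_FLOOR = 1e-10  # relative to the leading eigenvalue
ORTHONORMALITY_TOL = 1e-8


@dataclass
class MeanFunction:
    """Mean concentration curve on the frame grid, linear between knots."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.values = np.asarray(self.values, float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal shape")

    def __call__(self, t):
        t = np.asarray(t, float)
        if np.any(t < self.times[0] - 1e-9) or np.any(t > self.times[-1] + 1e-9):
            raise ValueError("mean function defined only on [t_1, t_p]")
        return np.interp(t, self.times, self.values)


def estimate_mean(scan: DynamicScan) -> MeanFunction:
    """Cross-sectional mean of the raw data, decay-corrected at each frame.

    mu_hat(t_j) = mean_i(Y_ij) * exp(lambda t_j); exactly unbiased at the
    frame times.  The scan must be the raw (unsmoothed) X-scale data.
    """
    if scan.scale != X_SCALE:
        raise ValueError("estimate_mean expects the raw X-scale scan")
    if scan.n_voxels == 0:
        raise ValueError("empty mask")
    t = scan.frame_times
    ybar = scan.curves.mean(axis=0)
    return MeanFunction(t, ybar * np.exp(scan.lam * t))


def estimate_a0(curves: np.ndarray, mean: MeanFunction,
                times: np.ndarray | None = None) -> np.ndarray:
    """Multiplicative coefficients A_i0 = <C_i, mu> / <mu, mu> (trapezoid).

    ``curves`` is (n, p) of decay-corrected curves on the frame grid.
    """
    times = mean.times if times is None else np.asarray(times, float)
    w = trapezoid_weights(times)
    mu = mean(times)
    denom = float(w @ (mu * mu))
    if denom <= 0:
        raise ValueError("mean function has zero quadrature norm")
    curves = np.atleast_2d(np.asarray(curves, float))
    return (curves * mu) @ w / denom


@dataclass
class ResidualCovariance:
    """Second-moment matrix of the residuals C_i - A_i0 mu on the frame grid."""

    matrix: np.ndarray
    times: np.ndarray


@dataclass
class EigenSystem:
    """Quadrature-orthonormal eigenfunctions of the residual covariance."""

    eigenvalues: np.ndarray     # (K,), non-increasing
    eigenfunctions: np.ndarray  # (K, p) function values on the frame grid
    times: np.ndarray
    weights: np.ndarray         # trapezoid weights on the frame grid

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)

    def gram(self) -> np.ndarray:
        """Quadrature Gram matrix <phi_k, phi_l>_w (identity when orthonormal)."""
        return (self.eigenfunctions * self.weights) @ self.eigenfunctions.T


def estimate_eigensystem(curves: np.ndarray, a0: np.ndarray, mean: MeanFunction,
                         kmax: int = DEFAULT_KMAX,
                         eigenvalue_floor: float = EIGENVALUE_FLOOR,
                         ) -> tuple[ResidualCovariance, EigenSystem]:
    """Residual covariance (second moment, Gamma = R'R/n) and its eigensystem.

    The eigenproblem is symmetrized with the quadrature weights:
    eigenvectors of diag(sqrt(w)) Gamma diag(sqrt(w)) are rescaled by
    1/sqrt(w) to function values, which makes the eigenfunctions
    orthonormal in the quadrature inner product.  Eigenvalues below
    ``eigenvalue_floor`` times the leading one are dropped; at most
    ``kmax`` components are kept.  Sign convention: the entry of largest
    magnitude of each eigenfunction is positive.
    """
    curves = np.atleast_2d(np.asarray(curves, float))
    a0 = np.asarray(a0, float)
    n, p = curves.shape
    if n == 0:
        raise ValueError("no curves")
    t = mean.times
    mu = mean.values
    R = curves - a0[:, None] * mu[None, :]
    if not np.all(np.isfinite(R)):
        raise ValueError("non-finite residuals")
    gamma = (R.T @ R) / n
    w = trapezoid_weights(t)
    sw = np.sqrt(w)
    sym = sw[:, None] * gamma * sw[None, :]
    evals, evecs = eigh(sym)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # numerically-zero systems: compare against the curves' own scale so
    # that exactly-reconstructed samples yield an empty eigensystem
    data_scale = float(w @ (curves * curves).mean(axis=0))
    if evals[0] > 1e-14 * max(data_scale, 1e-300):
        keep = evals >= eigenvalue_floor * evals[0]
    else:
        keep = np.zeros(p, bool)
    keep &= evals > 0
    keep[min(kmax, p):] = False
    evals = evals[keep]
    phi = (evecs[:, keep] / sw[:, None]).T
    # sign convention for reproducibility
    for k in range(len(phi)):
        j = np.argmax(np.abs(phi[k]))
        if phi[k, j] < 0:
            phi[k] = -phi[k]
    cov = ResidualCovariance(gamma, t)
    return cov, EigenSystem(evals, phi, t, w)


def estimate_scores(curves: np.ndarray, a0: np.ndarray, mean: MeanFunction,
                    eigensystem: EigenSystem) -> np.ndarray:
    """Component scores A_ik = <C_i - A_i0 mu, phi_k> by quadrature."""
    curves = np.atleast_2d(np.asarray(curves, float))
    if curves.shape[1] != len(eigensystem.times):
        raise ValueError("curve grid does not match the eigensystem grid")
    R = curves - np.asarray(a0, float)[:, None] * mean.values[None, :]
    return (R * eigensystem.weights) @ eigensystem.eigenfunctions.T


def fitted_curves(a0: np.ndarray, scores: np.ndarray, mean: MeanFunction,
                  eigensystem: EigenSystem, n_components: int) -> np.ndarray:
    """C_i(t, L) = A_i0 mu(t) + sum_{k<=L} A_ik phi_k(t) on the frame grid."""
    a0 = np.asarray(a0, float)
    fit = a0[:, None] * mean.values[None, :]
    if n_components:
        fit = fit + scores[:, :n_components] @ eigensystem.eigenfunctions[:n_components]
    return fit


def r2_paths(raw_curves: np.ndarray, a0: np.ndarray, scores: np.ndarray,
             mean: MeanFunction, eigensystem: EigenSystem, lam: float) -> np.ndarray:
    """R^2(i, L) for L = 0..K against the measured (X-scale) curves.

    R^2(i, L) = 1 - var{Y_i - C_i(., L) exp(-lambda .)} / var{Y_i}, with
    population variances across the p frame times.
    """
    Y = np.atleast_2d(np.asarray(raw_curves, float))
    t = mean.times
    decay = np.exp(-lam * t)
    vary = Y.var(axis=1)
    if np.any(vary <= 0):
        raise ValueError("var{Y_i(t)} = 0 for some voxel; handle flat voxels "
                         "before computing R^2")
    K = eigensystem.n_components
    out = np.empty((len(Y), K + 1))
    for L in range(K + 1):
        resid = Y - fitted_curves(a0, scores, mean, eigensystem, L) * decay[None, :]
        out[:, L] = 1.0 - resid.var(axis=1) / vary
    return out


def select_components(r2: np.ndarray,
                      threshold: float = DEFAULT_R2_THRESHOLD) -> np.ndarray:
    """Smallest L with R^2(L+1) - R^2(L) < threshold, else K (the cap).

    ``r2`` is (n, K+1) of R^2 paths for L = 0..K.
    """
    r2 = np.atleast_2d(np.asarray(r2, float))
    n, kp1 = r2.shape
    K = kp1 - 1
    L = np.full(n, K, int)
    gains = np.diff(r2, axis=1) < threshold   # (n, K)
    for i in range(n):
        hit = np.flatnonzero(gains[i])
        if hit.size:
            L[i] = hit[0]
    return L


class MultiplicativeFPCA(BaseEstimator, TransformerMixin):
    """Multiplicative-mean functional PCA of a sample of curves.

    Parameters
    ----------
    times : array-like of shape (p,)
        Observation times (s) of the curve values.
    lam : float, default 0
        Radioactive decay constant (1/s).  The raw curves handed to
        :meth:`fit` are on the measured (decayed) scale; the model is
        fitted to the decay-corrected curves.
    kmax : int, default 10
        Maximum number of retained eigenfunctions.
    r2_threshold : float, default 0.025
        Increment threshold of the per-curve component-count rule.

    After ``fit(Y, C=...)`` (Y raw curves, C optional presmoothed
    decay-corrected curves; default C = Y * exp(lam t)):

    - ``mean_`` : MeanFunction
    - ``a0_`` : (n,) multiplicative coefficients
    - ``covariance_`` : ResidualCovariance
    - ``eigensystem_`` : EigenSystem (``eigenvalues_``/``eigenfunctions_``
      expose its fields)
    - ``scores_`` : (n, K)
    - ``r2_path_`` : (n, K+1), ``n_components_`` : (n,) selected L per curve
    """

    def __init__(self, times=None, lam: float = 0.0, kmax: int = DEFAULT_KMAX,
                 r2_threshold: float = DEFAULT_R2_THRESHOLD):
        self.times = times
        self.lam = lam
        self.kmax = kmax
        self.r2_threshold = r2_threshold

    def _corrected(self, curves):
        t = np.asarray(self.times, float)
        return np.atleast_2d(np.asarray(curves, float)) * np.exp(self.lam * t)[None, :]

    def fit(self, Y, y=None, C=None):
        if self.times is None:
            raise ValueError("times must be provided")
        t = np.asarray(self.times, float)
        Y = np.atleast_2d(np.asarray(Y, float))
        if Y.shape[1] != len(t):
            raise ValueError("curves and times disagree in length")
        ybar = Y.mean(axis=0)
        self.mean_ = MeanFunction(t, ybar * np.exp(self.lam * t))
        Cc = self._corrected(Y) if C is None else np.atleast_2d(np.asarray(C, float))
        self.a0_ = estimate_a0(Cc, self.mean_)
        self.covariance_, self.eigensystem_ = estimate_eigensystem(
            Cc, self.a0_, self.mean_, kmax=self.kmax)
        self.scores_ = estimate_scores(Cc, self.a0_, self.mean_, self.eigensystem_)
        flat = Y.var(axis=1) <= 0
        self.flat_voxels_ = flat
        if flat.all():
            self.r2_path_ = np.zeros((len(Y), self.eigensystem_.n_components + 1))
            self.n_components_ = np.zeros(len(Y), int)
        else:
            r2 = np.zeros((len(Y), self.eigensystem_.n_components + 1))
            r2[~flat] = r2_paths(Y[~flat], self.a0_[~flat], self.scores_[~flat],
                                 self.mean_, self.eigensystem_, self.lam)
            self.r2_path_ = r2
            L = np.zeros(len(Y), int)
            L[~flat] = select_components(r2[~flat], self.r2_threshold)
            self.n_components_ = L
        return self

    @property
    def eigenvalues_(self):
        return self.eigensystem_.eigenvalues

    @property
    def eigenfunctions_(self):
        return self.eigensystem_.eigenfunctions

    def transform(self, Y, C=None):
        """Scores of new raw curves under the fitted mean/eigensystem."""
        Cc = self._corrected(Y) if C is None else np.atleast_2d(np.asarray(C, float))
        a0 = estimate_a0(Cc, self.mean_)
        return estimate_scores(Cc, a0, self.mean_, self.eigensystem_)
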