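"""Quadrature-discretized deconvolution against a known input function.

The tissue concentration obeys ``C(t) = (I * M)(t) = int_0^t I(t-s) M(s) ds``
with a known, positive input function I.  On a grid ``0 = s_0 < ... < s_m``
the integral becomes a lower-triangular matrix A acting on the values of M
at ``s_0..s_{m-1}``: row j (for time s_j) has entries ``I(s_j - s_{k-1})``
times composite trapezoid weights ``s_1/2, s_2/2, (s_k - s_{k-2})/2 ...``.
Positivity of I on (0, tau] makes every diagonal entry positive, so A is
invertible and deconvolution is a plain (triangular) least-squares solve.

The decisive economy of the functional approach is that this solve is
applied only to the mean curve and a handful of eigenfunctions, never
voxel by voxel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular, lstsq

from .datamodel import InputFunction

DEFAULT_M = 250


def trapezoid_weights(x: np.ndarray) -> np.ndarray:
    """Composite-trapezoid quadrature weights on arbitrary nodes x."""
    x = np.asarray(x, float)
    w = np.empty_like(x)
    w[0] = (x[1] - x[0]) / 2
    w[-1] = (x[-1] - x[-2]) / 2
    if len(x) > 2:
        w[1:-1] = (x[2:] - x[:-2]) / 2
    return w


@dataclass(frozen=True)
class QuadratureGrid:
    """Nodes s_0 = 0 < s_1 < ... < s_m = tau for the convolution operator."""

    nodes: np.ndarray

    def __post_init__(self):
        nodes = np.asarray(self.nodes, float)
        object.__setattr__(self, "nodes", nodes)
        if nodes.ndim != 1 or len(nodes) < 2:
            raise ValueError("grid needs at least two nodes")
        if abs(nodes[0]) > 1e-12:
            raise ValueError("grid must start at s_0 = 0")
        if np.any(np.diff(nodes) <= 0):
            raise ValueError("grid nodes must be strictly increasing")

    @classmethod
    def uniform(cls, tau: float, m: int = DEFAULT_M) -> "QuadratureGrid":
        if m < 2:
            raise ValueError("m must be >= 2")
        return cls(np.linspace(0.0, float(tau), m + 1))

    @property
    def m(self) -> int:
        return len(self.nodes) - 1

    @property
    def tau(self) -> float:
        return float(self.nodes[-1])

    @property
    def equispaced(self) -> bool:
        d = np.diff(self.nodes)
        return bool(np.allclose(d, d[0], rtol=1e-9, atol=0))

    @property
    def response_nodes(self) -> np.ndarray:
        """Nodes s_0..s_{m-1} where deconvolved functions live."""
        return self.nodes[:-1]

    @property
    def signal_nodes(self) -> np.ndarray:
        """Nodes s_1..s_m where convolved signals live."""
        return self.nodes[1:]


def _column_weights(nodes: np.ndarray) -> np.ndarray:
    # weights for columns k = 1..m (value nodes s_0..s_{m-1}):
    # w_1 = s_1/2, w_2 = s_2/2, w_k = (s_k - s_{k-2})/2 for k >= 3
    m = len(nodes) - 1
    w = np.empty(m)
    w[0] = nodes[1] / 2
    if m > 1:
        w[1] = nodes[2] / 2
    if m > 2:
        w[2:] = (nodes[3 : m + 1] - nodes[1 : m - 1]) / 2
    return w


@dataclass
class ConvolutionOperator:
    """Lower-triangular discretization A of convolution with I on a grid."""

    matrix: np.ndarray
    grid: QuadratureGrid
    input_function: InputFunction = field(repr=False, default=None)

    @property
    def m(self) -> int:
        return self.grid.m

    def __matmul__(self, values):
        return self.matrix @ np.asarray(values, float)


def build_convolution_operator(input_function: InputFunction,
                               grid: QuadratureGrid) -> ConvolutionOperator:
    nodes = grid.nodes
    if grid.tau > input_function.tau + 1e-9:
        raise ValueError(
            f"grid extends to {grid.tau} s beyond the input-function domain "
            f"[0, {input_function.tau}]"
        )
    m = grid.m
    w = _column_weights(nodes)
    # lag matrix: row j (time s_{j+1}), col k (response node s_k), j,k 0-based
    lags = nodes[1:, None] - nodes[None, :-1]
    tri = lags >= -1e-12
    A = np.zeros((m, m))
    A[tri] = input_function(np.clip(lags[tri], 0.0, None))
    A *= w[None, :]
    A = np.tril(A)
    return ConvolutionOperator(A, grid, input_function)


def forward_convolve(values: np.ndarray, operator: ConvolutionOperator) -> np.ndarray:
    """Approximate (I * M)(s_j), j = 1..m, from M at s_0..s_{m-1}.

    ``values`` may be (m,) or (m, n_curves); the operator acts columnwise.
    """
    values = np.asarray(values, float)
    if values.shape[0] != operator.m:
        raise ValueError(f"expected {operator.m} values, got {values.shape[0]}")
    return operator.matrix @ values


def deconvolve_curve(values: np.ndarray, operator: ConvolutionOperator,
                     ridge: float = 0.0, cond_warn: float = 1e12) -> np.ndarray:
    """Least-squares inverse of :func:`forward_convolve`.

    ``values`` holds a curve (or columns of curves) at s_1..s_m; the result
    lives at s_0..s_{m-1}.  With an invertible lower-triangular A this is an
    exact triangular solve; an optional ridge penalty (default 0) is offered
    for noisy per-voxel use.
    """
    values = np.asarray(values, float)
    if values.shape[0] != operator.m:
        raise ValueError(f"expected {operator.m} values, got {values.shape[0]}")
    A = operator.matrix
    diag = np.abs(np.diag(A))
    if ridge > 0:
        AtA = A.T @ A + ridge * np.eye(operator.m)
        return np.linalg.solve(AtA, A.T @ values)
    if diag.min() <= 0 or diag.max() / max(diag.min(), 1e-300) > cond_warn:
        warnings.warn(
            "convolution operator is ill-conditioned; returning a "
            "pseudo-inverse (least-squares) solution",
            RuntimeWarning,
        )
        sol, *_ = lstsq(A, values)
        return sol
    return solve_triangular(A, values, lower=True)


def resample_to_grid(values: np.ndarray, times: np.ndarray,
                     grid: QuadratureGrid, where: str = "signal") -> np.ndarray:
    """Linearly interpolate frame-time values onto the quadrature grid.

    Values at grid nodes below the first frame time are held constant at the
    first observed value (curves are only measured from t_1 > 0, but the
    operator needs the full [0, tau] support); nodes beyond the last frame
    time hold the last value.  ``where`` selects the signal (s_1..s_m) or
    response (s_0..s_{m-1}) node set.
    """
    values = np.asarray(values, float)
    times = np.asarray(times, float)
    nodes = grid.signal_nodes if where == "signal" else grid.response_nodes
    if values.ndim == 1:
        return np.interp(nodes, times, values)
    return np.stack([np.interp(nodes, times, v) for v in values])


@dataclass
class DeconvolvedBasis:
    """Deconvolved mean and eigenfunctions with their [0, tau] integrals."""

    grid: QuadratureGrid
    mu_d: np.ndarray            # (m,) at s_0..s_{m-1}
    phi_d: np.ndarray           # (K, m)
    v0: float
    vk: np.ndarray              # (K,)
    extended_below_t1: bool = True  # frame curves were held constant on [0, t_1)

    @property
    def n_components(self) -> int:
        return self.phi_d.shape[0]


def deconvolve_basis(mean_values: np.ndarray, eigenfunctions: np.ndarray,
                     frame_times: np.ndarray, operator: ConvolutionOperator,
                     ridge: float = 0.0) -> DeconvolvedBasis:
    """Deconvolve the mean and each eigenfunction once (1 + K solves)."""
    grid = operator.grid
    mu_on_grid = resample_to_grid(mean_values, frame_times, grid)
    mu_d = deconvolve_curve(mu_on_grid, operator, ridge=ridge)
    K = len(eigenfunctions)
    if K:
        phi_on_grid = resample_to_grid(np.asarray(eigenfunctions), frame_times, grid)
        phi_d = deconvolve_curve(phi_on_grid.T, operator, ridge=ridge).T
    else:
        phi_d = np.zeros((0, grid.m))
    w = trapezoid_weights(grid.response_nodes)
    v0 = float(w @ mu_d)
    vk = phi_d @ w
    return DeconvolvedBasis(grid, mu_d, phi_d, v0, vk)


@dataclass
class VTResult:
    """Per-voxel IRF expansion and volume of distribution.

    ``vt[i] = a0[i] * v0 + sum_{k <= L_i} scores[i, k] * vk[k]`` exactly.
    """

    vt: np.ndarray              # (n,)
    a0: np.ndarray              # (n,)
    scores: np.ndarray          # (n, K)
    n_components: np.ndarray    # (n,) selected L_i
    r2_path: np.ndarray | None = None   # (n, K+1)
    irf: np.ndarray | None = None       # (n, m) optional


def estimate_irf_vt(basis: DeconvolvedBasis, a0: np.ndarray, scores: np.ndarray,
                    n_components: np.ndarray, r2_path: np.ndarray | None = None,
                    return_irf: bool = False) -> VTResult:
    """Assemble voxelwise IRFs and V_T from the deconvolved basis.

    ``M_i(t, L) = a0_i mu_d(t) + sum_{k<=L_i} score_ik phi_d_k(t)`` and
    V_T is its [0, tau] integral, which is linear in the scores.
    """
    a0 = np.asarray(a0, float)
    scores = np.asarray(scores, float)
    L = np.asarray(n_components, int)
    K = basis.n_components
    if scores.ndim != 2 or scores.shape[1] != K:
        raise ValueError("scores must be (n_voxels, K) matching the basis")
    if np.any(L < 0) or np.any(L > K):
        raise ValueError(f"selected L must lie in [0, {K}]")
    # zero out scores beyond each voxel's selected L
    keep = np.arange(K)[None, :] < L[:, None]
    used = np.where(keep, scores, 0.0)
    vt = a0 * basis.v0 + used @ basis.vk
    irf = None
    if return_irf:
        irf = a0[:, None] * basis.mu_d[None, :] + used @ basis.phi_d
    return VTResult(vt=vt, a0=a0, scores=scores, n_components=L,
                    r2_path=r2_path, irf=irf)
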