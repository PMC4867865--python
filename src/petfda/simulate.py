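"""Synthetic data: 1D functional curves and 2D kinetic phantoms.

Two generators drive all testing and benchmarking without any measured
scans:

* :func:`simulate_1d_dataset` draws a sample of impulse-response
  functions ``M_i = mu_M + B_i1 psi_1 + B_i2 psi_2`` (a two-exponential
  mean plus L2-normalized sine/cosine perturbations of period 2000 s),
  convolves them with a known input function and adds iid Gaussian
  measurement noise at the observation times.

* :func:`simulate_phantom_scan` builds a 2D labelled phantom of nested
  elliptical regions, places a kinetic model in each region
  (two-compartment sums of decaying exponentials, or scaled gamma-mixture
  survival functions for non-compartmental shapes), jitters each voxel's
  volume of distribution by ~6.5% (the within-region variability seen in
  measured data), convolves with the input function, blurs each frame
  with a Gaussian point-spread function (FWHM 6 mm at 2 mm pixels),
  applies radioactive decay and adds Gaussian noise whose variance is
  proportional to the voxel's time-averaged signal (quasi-Poisson).

Since no measured arterial input function is distributed with the
package, a scaled-gamma bolus is the default input everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.stats import gamma as gamma_dist

from .datamodel import (DynamicScan, FrameSchedule, InputFunction, LAMBDA_C11,
                        X_SCALE)
from .deconv import (QuadratureGrid, build_convolution_operator,
                     forward_convolve, trapezoid_weights)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


# ---------------------------------------------------------------------------
# input function

def synthetic_input_function(shape: float = 3.0, scale: float = 30.0,
                             peak: float = 350.0, tau: float = 2000.0,
                             n_samples: int = 2001) -> InputFunction:
    """Scaled-gamma arterial bolus: I(t) ∝ t^(shape-1) e^(-t/scale).

    The curve is normalized so its maximum (at t = (shape-1)*scale) equals
    ``peak``; I(0) = 0 and I > 0 on (0, tau].  Defaults give a bolus
    peaking at 60 s with amplitude 350 activity units — a plausible
    arterial curve for a bolus tracer injection.
    """
    if shape <= 1 or scale <= 0 or peak <= 0 or tau <= 0:
        raise ValueError("require shape > 1 and scale, peak, tau > 0")
    t = np.linspace(0.0, tau, n_samples)
    mode = (shape - 1.0) * scale
    raw = np.where(t > 0, t ** (shape - 1.0) * np.exp(-t / scale), 0.0)
    peak_raw = mode ** (shape - 1.0) * np.exp(-(shape - 1.0))
    return InputFunction(t, peak * raw / peak_raw)


# ---------------------------------------------------------------------------
# 1D functional simulation

@dataclass
class Sim1DConfig:
    """Study conditions of the 1D curve simulation."""

    mean_amplitudes: tuple = (0.0049, 0.0018)
    mean_rates: tuple = (0.0005, 0.0112)
    period: float = 2000.0
    score_sds: tuple = (0.1, 0.05)
    noise_sd: float = 2.0
    n_curves: int = 200
    n_times: int = 200
    t_end: float = 2000.0
    seed: int = 0
    m_fine: int = 2000   # fine quadrature grid for the forward convolution

    def __post_init__(self):
        if any(s <= 0 for s in self.score_sds) or self.noise_sd <= 0:
            raise ValueError("standard deviations must be positive")
        if self.n_times < 2 or self.n_curves < 1:
            raise ValueError("need n_times >= 2 and n_curves >= 1")

    @property
    def times(self) -> np.ndarray:
        """n_times equally spaced observation times on (0, t_end]."""
        dt = self.t_end / self.n_times
        return np.linspace(dt, self.t_end, self.n_times)

    def mean_irf(self, t) -> np.ndarray:
        t = np.asarray(t, float)
        out = np.zeros_like(t)
        for a, b in zip(self.mean_amplitudes, self.mean_rates):
            out = out + a * np.exp(-b * t)
        return out

    def basis(self, t) -> np.ndarray:
        """L2-normalized (psi_1, psi_2) = c1 sin, c2 cos of the period."""
        t = np.asarray(t, float)
        c = np.sqrt(2.0 / self.period)  # closed form of the printed integrals
        return np.stack([c * np.sin(2 * np.pi * t / self.period),
                         c * np.cos(2 * np.pi * t / self.period)])


@dataclass
class Sim1DDataset:
    config: Sim1DConfig
    times: np.ndarray            # (p,)
    noisy: np.ndarray            # (n, p) observed Y
    clean: np.ndarray            # (n, p) noise-free convolved curves
    scores: np.ndarray           # (n, 2) planted B_ik
    grid: QuadratureGrid         # fine simulation grid

    def true_irf(self, t) -> np.ndarray:
        """Planted M_i evaluated on an arbitrary time grid, (n, len(t))."""
        base = self.config.mean_irf(t)
        psi = self.config.basis(t)
        return base[None, :] + self.scores @ psi


def simulate_1d_dataset(config: Sim1DConfig,
                        input_function: InputFunction | None = None
                        ) -> Sim1DDataset:
    """Generate the 1D sample; deterministic given ``config.seed``."""
    if input_function is None:
        input_function = synthetic_input_function(tau=config.t_end)
    if input_function.tau < config.t_end - 1e-9:
        raise ValueError("input function must cover [0, t_end]")
    rng = np.random.default_rng(config.seed)
    grid = QuadratureGrid.uniform(config.t_end, config.m_fine)
    op = build_convolution_operator(input_function, grid)
    s = grid.response_nodes
    B = np.column_stack([rng.normal(0.0, sd, config.n_curves)
                         for sd in config.score_sds])
    M = config.mean_irf(s)[None, :] + B @ config.basis(s)     # (n, m)
    C_grid = forward_convolve(M.T, op).T                       # (n, m)
    t = config.times
    nodes = np.concatenate([[0.0], grid.signal_nodes])
    clean = np.stack([np.interp(t, nodes, np.concatenate([[0.0], c]))
                      for c in C_grid])
    noisy = clean + rng.normal(0.0, config.noise_sd, clean.shape)
    return Sim1DDataset(config, t, noisy, clean, B, grid)


# ---------------------------------------------------------------------------
# closed forms and metrics

def closed_form_vt(alphas, betas, tau: float = np.inf) -> float:
    """V_T of a sum of decaying exponentials: sum_j (a_j/b_j)(1 - e^(-b_j tau))."""
    alphas = np.atleast_1d(np.asarray(alphas, float))
    betas = np.atleast_1d(np.asarray(betas, float))
    if alphas.shape != betas.shape:
        raise ValueError("alphas and betas must have equal length")
    if np.any(betas <= 0):
        raise ValueError("decay rates must be positive")
    if not (tau > 0):
        raise ValueError("tau must be positive (np.inf allowed)")
    frac = 1.0 if np.isinf(tau) else (1.0 - np.exp(-betas * tau))
    return float(np.sum(alphas / betas * frac))


def mise(estimates: np.ndarray, truths: np.ndarray, times: np.ndarray) -> float:
    """Mean (over curves) integrated squared error by trapezoid quadrature."""
    estimates = np.atleast_2d(np.asarray(estimates, float))
    truths = np.atleast_2d(np.asarray(truths, float))
    if estimates.shape != truths.shape:
        raise ValueError("shape mismatch between estimates and truths")
    w = trapezoid_weights(np.asarray(times, float))
    return float((((estimates - truths) ** 2) @ w).mean())


def vt_mse_by_region(vt_est: np.ndarray, vt_true: np.ndarray,
                     region_labels: np.ndarray) -> dict:
    """Per-region mean squared error of V_T estimates."""
    vt_est = np.asarray(vt_est, float)
    vt_true = np.asarray(vt_true, float)
    labels = np.asarray(region_labels)
    if not (vt_est.shape == vt_true.shape == labels.shape):
        raise ValueError("shape mismatch")
    return {int(r): float(np.mean((vt_est[labels == r] - vt_true[labels == r]) ** 2))
            for r in np.unique(labels) if r > 0}


def recovery_metrics(irf_est, irf_true, times, vt_est=None, vt_true=None,
                     region_labels=None) -> dict:
    """Bundle the two headline metrics: function MISE and regional V_T MSE."""
    out = {"mise": mise(irf_est, irf_true, times)}
    if vt_est is not None:
        out["vt_mse"] = vt_mse_by_region(vt_est, vt_true, region_labels)
    return out


# ---------------------------------------------------------------------------
# 2D phantom

def _lognormal_factors(rng, cv: float, n: int) -> np.ndarray:
    """Mean-1 multiplicative jitter with the requested coefficient of variation."""
    if cv <= 0:
        return np.ones(n)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), n)


@dataclass
class RegionSpec:
    """Kinetic model of one phantom region.

    ``kind='compartmental'``: IRF = sum_j alphas_j exp(-betas_j t); an
    empty alphas tuple means a signal-free region (V_T = 0).
    ``kind='survival'``: IRF is a rescaled survival function of a
    two-component gamma mixture evaluated in minutes (t/60), with the
    mixture parameters drawn per voxel from the given normal laws; each
    voxel is then rescaled so its finite-horizon integral hits the drawn
    V_T target around ``vt_mean``.
    """

    label: int
    size: int
    kind: str = "compartmental"
    alphas: tuple = ()
    betas: tuple = ()
    weights: tuple = ()
    gamma_shapes: tuple = ()
    gamma_shape_sds: tuple = ()
    gamma_scales: tuple = ()
    gamma_scale_sds: tuple = ()
    vt_mean: float | None = None
    vt_cv: float = 0.065

    def __post_init__(self):
        if self.kind not in ("compartmental", "survival"):
            raise ValueError("kind must be 'compartmental' or 'survival'")
        if self.kind == "compartmental":
            if len(self.alphas) != len(self.betas):
                raise ValueError("alphas and betas must pair up")
            if any(b <= 0 for b in self.betas):
                raise ValueError("rates must be positive")
        else:
            if abs(sum(self.weights) - 1.0) > 1e-9:
                raise ValueError("mixture weights must sum to 1")
            if self.vt_mean is None or self.vt_mean <= 0:
                raise ValueError("survival regions need a positive target V_T")


def table_compartmental_regions() -> list[RegionSpec]:
    """The five-region compartmental phantom (region sizes and rates as printed)."""
    return [
        RegionSpec(1, 9614, alphas=(), betas=()),
        RegionSpec(2, 5351, alphas=(0.0060,), betas=(0.0030,)),
        RegionSpec(3, 3701, alphas=(0.0040, 0.0023), betas=(0.0008, 0.0103)),
        RegionSpec(4, 414, alphas=(0.0068, 0.0009), betas=(0.0007, 0.0203)),
        RegionSpec(5, 5704, alphas=(0.0007,), betas=(0.0377,)),
    ]


def table_mixed_regions() -> list[RegionSpec]:
    """Same phantom with survival-function IRFs in regions 2 and 4."""
    regions = table_compartmental_regions()
    regions[1] = RegionSpec(
        2, 5351, kind="survival", weights=(0.7, 0.3),
        gamma_shapes=(1.5, 10.0), gamma_shape_sds=(0.05, 0.5),
        gamma_scales=(2.0, 1.5), gamma_scale_sds=(0.2, 0.1), vt_mean=1.97)
    regions[3] = RegionSpec(
        4, 414, kind="survival", weights=(0.8, 0.2),
        gamma_shapes=(2.0, 15.0), gamma_shape_sds=(0.15, 0.1),
        gamma_scales=(2.5, 2.0), gamma_scale_sds=(0.2, 0.15), vt_mean=8.54)
    return regions


def default_frame_schedule() -> FrameSchedule:
    """32 frames of increasing duration (87 min), PET-style rebinning."""
    durations = [15] * 4 + [30] * 4 + [60] * 4 + [120] * 4 + [180] * 4 + [300] * 12
    return FrameSchedule.from_durations(durations)


@dataclass
class PhantomConfig:
    """Geometry, kinetics, blur and noise model of the 2D phantom."""

    grid_shape: tuple = (160, 160)
    voxel_size_mm: float = 2.0
    regions: list = field(default_factory=table_compartmental_regions)
    psf_fwhm_mm: float = 6.0
    kappa: float | None = None    # noise variance per unit time-averaged signal
    target_snr: float = 5.0       # sets kappa at the median voxel when kappa is None
    lam: float = LAMBDA_C11
    schedule: FrameSchedule = field(default_factory=default_frame_schedule)
    seed: int = 0
    m_fine: int = 600             # fine quadrature grid for forward convolution

    def __post_init__(self):
        if self.psf_fwhm_mm < 0:
            raise ValueError("FWHM must be nonnegative")
        if self.kappa is not None and self.kappa < 0:
            raise ValueError("kappa must be nonnegative")
        if not self.regions:
            raise ValueError("need at least one region")


def build_phantom_labels(config: PhantomConfig) -> np.ndarray:
    """Nested elliptical regions with exact pixel counts.

    Pixels are sorted by elliptical radius from the grid centre; regions
    fill outward from the centre in order of increasing size, so the
    smallest region is innermost and the largest (typically the
    signal-free tissue) outermost.  Unassigned pixels get label 0
    (outside the phantom).
    """
    shape = tuple(config.grid_shape)
    total = int(np.prod(shape))
    sizes = [r.size for r in config.regions]
    if any(s < 0 for s in sizes) or sum(sizes) > total:
        raise ValueError(f"region sizes {sizes} exceed the {shape} grid")
    idx = np.indices(shape, dtype=float)
    centre = [(n - 1) / 2.0 for n in shape]
    semi = [max(n / 2.0, 1.0) for n in shape]
    r2 = sum(((idx[d] - centre[d]) / semi[d]) ** 2 for d in range(len(shape)))
    order = np.argsort(r2.ravel(), kind="stable")
    labels = np.zeros(total, dtype=int)
    start = 0
    for spec in sorted(config.regions, key=lambda s: s.size):
        labels[order[start:start + spec.size]] = spec.label
        start += spec.size
    return labels.reshape(shape)


def _survival_irf(t_seconds: np.ndarray, weights, shapes, scales) -> np.ndarray:
    """Unscaled survival shape S(t/60) of a gamma mixture (minutes)."""
    u = np.asarray(t_seconds, float) / 60.0
    cdf = np.zeros_like(u)
    for w, a, b in zip(weights, shapes, scales):
        cdf = cdf + w * gamma_dist.cdf(u, a=a, scale=b)
    return 1.0 - cdf


@dataclass
class PhantomTruth:
    """Ground truth accompanying a simulated phantom scan."""

    labels: np.ndarray           # (grid) region labels, 0 = outside
    vt: np.ndarray               # (grid) per-voxel true V_T (NaN outside)
    irf: np.ndarray              # (n_masked, m) true IRFs on the fine grid
    grid: QuadratureGrid
    kappa: float
    regions: list


def simulate_phantom_scan(config: PhantomConfig,
                          input_function: InputFunction | None = None
                          ) -> tuple[DynamicScan, PhantomTruth]:
    """Simulate a noisy dynamic phantom scan; deterministic given the seed.

    The drawn per-voxel V_T targets are finite-horizon integrals over
    [0, t_p] (the last frame mid-time), matching what the deconvolution
    pipeline can estimate without extrapolation.
    """
    sched = config.schedule
    t = sched.mid
    tau = float(t[-1])
    if input_function is None:
        input_function = synthetic_input_function(tau=tau)
    if input_function.tau < tau - 1e-9:
        raise ValueError("input function must cover the scan duration")
    rng = np.random.default_rng(config.seed)
    labels = build_phantom_labels(config)
    mask = labels > 0
    n_masked = int(mask.sum())
    flat_labels = labels[mask]

    grid = QuadratureGrid.uniform(tau, config.m_fine)
    s = grid.response_nodes
    w_resp = trapezoid_weights(s)
    M = np.zeros((n_masked, grid.m))
    vt_true = np.zeros(n_masked)
    for spec in config.regions:
        sel = flat_labels == spec.label
        n_r = int(sel.sum())
        if n_r == 0:
            continue
        if spec.kind == "compartmental":
            if not spec.alphas:
                continue  # signal-free region
            base = np.zeros(grid.m)
            for a, b in zip(spec.alphas, spec.betas):
                base += a * np.exp(-np.asarray(b) * s)
            vt_base = closed_form_vt(spec.alphas, spec.betas, tau)
            targets = vt_base * _lognormal_factors(rng, spec.vt_cv, n_r)
            M[sel] = (targets / vt_base)[:, None] * base[None, :]
            vt_true[sel] = targets
        else:
            targets = spec.vt_mean * _lognormal_factors(rng, spec.vt_cv, n_r)
            shapes = np.column_stack([
                rng.normal(m0, sd, n_r)
                for m0, sd in zip(spec.gamma_shapes, spec.gamma_shape_sds)])
            scales = np.column_stack([
                rng.normal(m0, sd, n_r)
                for m0, sd in zip(spec.gamma_scales, spec.gamma_scale_sds)])
            rows = np.flatnonzero(sel)
            for j, i in enumerate(rows):
                shape_j = np.clip(shapes[j], 1e-3, None)
                scale_j = np.clip(scales[j], 1e-3, None)
                S = _survival_irf(s, spec.weights, shape_j, scale_j)
                integral = float(w_resp @ S)
                M[i] = (targets[j] / integral) * S
            vt_true[sel] = targets

    op = build_convolution_operator(input_function, grid)
    C_grid = forward_convolve(M.T, op)          # (m, n_masked) at s_1..s_m
    nodes = np.concatenate([[0.0], grid.signal_nodes])
    Cf = np.zeros((n_masked, sched.p))
    vals = np.vstack([np.zeros(n_masked), C_grid])  # C(0) = 0
    for j, tj in enumerate(t):
        k = np.searchsorted(nodes, tj)
        k = min(max(k, 1), len(nodes) - 1)
        w1 = (tj - nodes[k - 1]) / (nodes[k] - nodes[k - 1])
        Cf[:, j] = (1 - w1) * vals[k - 1] + w1 * vals[k]

    frames = np.zeros(config.grid_shape + (sched.p,))
    frames[mask] = Cf
    if config.psf_fwhm_mm > 0:
        sigma_px = config.psf_fwhm_mm * FWHM_TO_SIGMA / config.voxel_size_mm
        for j in range(sched.p):
            frames[..., j] = gaussian_filter(frames[..., j], sigma_px)
    decayed = frames * np.exp(-config.lam * t)
    sbar = decayed.mean(axis=-1)
    kappa = config.kappa
    if kappa is None:
        med = float(np.median(sbar[mask]))
        kappa = med / config.target_snr ** 2 if med > 0 else 0.0
    sigma = np.sqrt(np.clip(kappa * sbar, 0.0, None))
    noisy = decayed + rng.normal(size=decayed.shape) * sigma[..., None]

    scan = DynamicScan(noisy, sched, lam=config.lam, mask=mask,
                       voxel_size=(config.voxel_size_mm,) * len(config.grid_shape),
                       scale=X_SCALE)
    vt_map = np.full(config.grid_shape, np.nan)
    vt_map[mask] = vt_true
    truth = PhantomTruth(labels=labels, vt=vt_map, irf=M, grid=grid,
                         kappa=float(kappa), regions=list(config.regions))
    return scan, truth
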