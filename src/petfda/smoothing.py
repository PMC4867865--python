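"""Spatiotemporal local-linear presmoothing with adaptive temporal bandwidth.

The measured voxel time courses are noisy; before any deconvolution the
latent decayed signal X_i(t) is reconstructed by a local-linear kernel
smoother over space and time jointly.  Two choices matter:

* **Sequential product-kernel passes.**  A product Epanechnikov kernel
  lets the joint (spatial dims + time) local-linear fit be computed as a
  sequence of one-dimensional local-linear passes, one per coordinate,
  which is what makes smoothing a whole dynamic volume affordable.  One
  spatial bandwidth h_z (mm) is shared by all spatial dimensions.

* **Locally adaptive temporal bandwidth.**  PET frames are short near
  injection (where the curve peaks sharply) and long late in the scan
  (where it is flat).  At each of n_b knot times the raw half-width is
  the smallest h such that [t-h, t+h] contains at least ``min_count``
  frame times; a degree-4 polynomial through the (knot, half-width)
  pairs gives a smooth bandwidth function h_T(t), later scaled by a
  cross-validated calibration coefficient beta.

Bandwidth calibration removes ``n_cv`` random voxels at a time, predicts
their measured values from the remaining voxels with the joint kernel
smoother, and averages the squared prediction error over ``n_replicates``
draws; h_z is selected first (beta fixed at 1), then beta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import DynamicScan, X_SCALE, apply_decay_transform

DEFAULT_NB = 13
DEFAULT_MIN_COUNT = 4
DEFAULT_N_CV = 1
DEFAULT_N_REPLICATES = 5000
PROFILE_FLOOR_FRACTION = 0.10   # clamp of the fitted profile, x median raw width


def epanechnikov(u: np.ndarray) -> np.ndarray:
    u = np.asarray(u, float)
    return np.where(np.abs(u) < 1.0, 0.75 * (1.0 - u * u), 0.0)


@dataclass
class BandwidthProfile:
    """Smooth temporal half-width function fitted through knot half-widths."""

    knots: np.ndarray
    raw_halfwidths: np.ndarray
    poly: np.polynomial.Polynomial
    beta: float = 1.0
    min_count: int = DEFAULT_MIN_COUNT
    floor: float = 0.0

    @property
    def n_b(self) -> int:
        return len(self.knots)

    def __call__(self, t, beta: float | None = None) -> np.ndarray:
        """Calibrated half-width beta * max(poly(t), floor); always > 0."""
        b = self.beta if beta is None else beta
        h = np.maximum(self.poly(np.asarray(t, float)), self.floor)
        return b * h


def build_bandwidth_profile(times, n_b: int = DEFAULT_NB,
                            min_count: int = DEFAULT_MIN_COUNT) -> BandwidthProfile:
    """Raw knot half-widths + degree-4 polynomial fit (see module docstring).

    The raw half-width at a knot is the distance to its ``min_count``-th
    nearest observation time (the knot itself included), which is the
    smallest h with at least ``min_count`` observations in [t-h, t+h];
    because min_count >= 2 this is automatically floored at the distance
    to the 2nd nearest observation, keeping the width positive at the
    left boundary.  The evaluated polynomial is clamped below at 10% of
    the median raw half-width.
    """
    t = np.asarray(times, float)
    p = len(t)
    if n_b > p:
        raise ValueError(f"n_b={n_b} exceeds the number of frames p={p}")
    if min_count < 2 or min_count > p:
        raise ValueError("min_count must be in [2, p]")
    if np.ptp(t) <= 0:
        raise ValueError("degenerate (all-equal) observation times")
    knot_idx = np.unique(np.round(np.linspace(0, p - 1, n_b)).astype(int))
    knots = t[knot_idx]
    raw = np.empty(len(knots))
    for i, tk in enumerate(knots):
        d = np.sort(np.abs(t - tk))
        raw[i] = d[min_count - 1]
    degree = min(4, len(knots) - 1)
    poly = np.polynomial.Polynomial.fit(knots, raw, degree).convert()
    floor = PROFILE_FLOOR_FRACTION * float(np.median(raw))
    return BandwidthProfile(knots, raw, poly, min_count=min_count, floor=floor)


@dataclass
class SmootherConfig:
    """All tunables of the presmoother; unset bandwidths mean 'calibrate'."""

    kernel: str = "epanechnikov"
    h_z: float | None = None
    beta: float = 1.0
    profile: BandwidthProfile | None = None
    n_b: int = DEFAULT_NB
    min_count: int = DEFAULT_MIN_COUNT
    h_z_candidates: tuple | None = None
    beta_candidates: tuple = (0.5, 0.75, 1.0, 1.5, 2.0)
    n_cv: int = DEFAULT_N_CV
    n_replicates: int = DEFAULT_N_REPLICATES
    seed: int = 0

    def __post_init__(self):
        if self.kernel != "epanechnikov":
            raise ValueError("only the Epanechnikov kernel is implemented")
        if self.h_z is not None and self.h_z <= 0:
            raise ValueError("h_z must be positive")
        if self.n_cv < 1 or self.n_replicates < 1:
            raise ValueError("n_cv and n_replicates must be >= 1")

    def resolve_profile(self, times) -> BandwidthProfile:
        if self.profile is None:
            p = len(np.asarray(times))
            self.profile = build_bandwidth_profile(
                times, min(self.n_b, p), min(self.min_count, p))
        return self.profile

    def default_hz_candidates(self, voxel_size) -> tuple:
        v = float(np.max(voxel_size))
        return tuple(f * v for f in (1.0, 1.5, 2.0, 3.0, 4.0))


class SingularLocalFit(RuntimeError):
    pass


def _local_linear_pass(values: np.ndarray, weights: np.ndarray, x: np.ndarray,
                       h: np.ndarray, axis: int, check: np.ndarray | None = None,
                       label: str = "") -> np.ndarray:
    """One 1D local-linear pass along ``axis`` with per-eval bandwidths.

    ``weights`` are per-sample base weights (the mask); evaluation happens
    at every sample position with bandwidth ``h[e]``.  Positions where the
    local design is singular yield NaN; if such a position is flagged in
    ``check`` a :class:`SingularLocalFit` is raised instead.
    """
    V = np.moveaxis(np.asarray(values, float), axis, -1)
    W = np.moveaxis(np.asarray(weights, float), axis, -1)
    n = V.shape[-1]
    x = np.asarray(x, float)
    h = np.broadcast_to(np.asarray(h, float), (n,))
    out = np.empty_like(V)
    for e in range(n):
        he = h[e]
        if he <= 0:
            raise ValueError("bandwidth must be positive")
        lo = int(np.searchsorted(x, x[e] - he, side="right"))
        hi = int(np.searchsorted(x, x[e] + he, side="left"))
        d = x[lo:hi] - x[e]
        k = epanechnikov(d / he) * W[..., lo:hi]
        s0 = k.sum(-1)
        s1 = (k * d).sum(-1)
        s2 = (k * d * d).sum(-1)
        t0 = (k * V[..., lo:hi]).sum(-1)
        t1 = (k * d * V[..., lo:hi]).sum(-1)
        den = s0 * s2 - s1 * s1
        scale = s0 * s2 + s1 * s1
        # a local-linear fit needs >= 2 support points; a lone point (or
        # collinear degeneracy) is a singular design
        bad = den <= 1e-12 * np.maximum(scale, 1e-300)
        with np.errstate(invalid="ignore", divide="ignore"):
            est = (s2 * t0 - s1 * t1) / den
        est = np.where(bad, np.nan, est)
        if check is not None:
            C = np.moveaxis(check, axis, -1)[..., e]
            if np.any(bad & C):
                where = np.argwhere(bad & C)[0]
                raise SingularLocalFit(
                    f"singular local-linear design in {label or 'pass'} at "
                    f"position index {e} (slice {tuple(where)}): bandwidth "
                    "too small for the data"
                )
        out[..., e] = est
    return np.moveaxis(out, -1, axis)


def smooth_scan(scan: DynamicScan, config: SmootherConfig
                ) -> tuple[DynamicScan, DynamicScan]:
    """Sequential local-linear smoothing; returns (X-hat, C-hat) scans.

    Spatial axes are smoothed first (bandwidth h_z, mm), then time with
    the calibrated adaptive bandwidth beta * h_T(t).  Out-of-mask voxels
    never contribute (weight zero) and are NaN in the output.
    """
    if scan.scale != X_SCALE:
        raise ValueError("smooth_scan expects the raw X-scale scan")
    if config.h_z is None:
        raise ValueError("h_z is unset; run calibrate_bandwidths first or set it")
    t = scan.frame_times
    profile = config.resolve_profile(t)
    V = scan.values.copy()
    W = scan.mask.astype(float)[..., None] * np.ones(scan.schedule.p)
    Cmask = np.broadcast_to(scan.mask[..., None], V.shape)
    for d in range(scan.ndim_spatial):
        xs = np.arange(scan.grid_shape[d], dtype=float) * scan.voxel_size[d]
        V = _local_linear_pass(V, W, xs, config.h_z, axis=d, check=Cmask,
                               label=f"spatial axis {d}")
        V = np.where(Cmask, V, 0.0)  # keep NaNs out of later passes
    ht = profile(t, beta=config.beta)
    V = _local_linear_pass(V, W, t, ht, axis=-1, check=Cmask, label="time")
    V = np.where(Cmask, V, np.nan)
    xhat = scan.with_values(V, scale=X_SCALE)
    chat = apply_decay_transform(xhat, "correct")
    return xhat, chat


def _predict_voxel(curve_grid: np.ndarray, mask: np.ndarray, coords: np.ndarray,
                   voxel_index: tuple, times: np.ndarray, h_z: float,
                   ht: np.ndarray, exclude: np.ndarray) -> np.ndarray:
    """Joint product-kernel local-linear prediction of one voxel's curve."""
    z0 = coords[voxel_index]
    usable = mask & ~exclude
    dz = coords[usable] - z0          # (n_nb, nd)
    kz = np.prod(epanechnikov(dz / h_z), axis=1)
    keep = kz > 0
    dz, kz = dz[keep], kz[keep]
    ycur = curve_grid[usable][keep]   # (n_nb, p)
    p = len(times)
    pred = np.empty(p)
    for j in range(p):
        dt = times - times[j]
        kt = epanechnikov(dt / ht[j])
        use = kt > 0
        w = (kz[:, None] * kt[None, use]).ravel()
        n_nb = len(dz)
        X = np.column_stack([
            np.ones(n_nb * use.sum()),
            np.repeat(dz, use.sum(), axis=0),
            np.tile(dt[use], n_nb),
        ])
        y = ycur[:, use].ravel()
        sw = np.sqrt(w)
        sol, res, rank, _ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        if rank < X.shape[1]:
            tot = w.sum()
            pred[j] = (w @ y) / tot if tot > 0 else np.nan
        else:
            pred[j] = sol[0]
    return pred


def calibrate_bandwidths(scan: DynamicScan, config: SmootherConfig
                         ) -> tuple[float, float]:
    """Leave-n_cv-voxels-out selection of (h_z, beta), sequentially.

    Deterministic given ``config.seed``: the held-out draws are made once
    and reused for every candidate.  Returns the selected pair and stores
    it on ``config``.
    """
    if scan.scale != X_SCALE:
        raise ValueError("calibration runs on the raw X-scale scan")
    if scan.n_voxels == 0:
        raise ValueError("all voxels are masked out")
    hz_cands = (config.default_hz_candidates(scan.voxel_size)
                if config.h_z_candidates is None else config.h_z_candidates)
    beta_cands = config.beta_candidates
    if not len(hz_cands) or not len(beta_cands):
        raise ValueError("candidate lists must be non-empty")
    t = scan.frame_times
    profile = config.resolve_profile(t)
    rng = np.random.default_rng(config.seed)
    vox = np.argwhere(scan.mask)
    draws = [vox[rng.choice(len(vox), size=min(config.n_cv, len(vox)),
                            replace=False)]
             for _ in range(config.n_replicates)]
    nd = scan.ndim_spatial
    coords = np.moveaxis(
        np.indices(scan.grid_shape, dtype=float), 0, -1
    ) * np.asarray(scan.voxel_size)

    def cv_error(h_z: float, beta: float) -> float:
        ht = profile(t, beta=beta)
        errs = []
        for held in draws:
            exclude = np.zeros(scan.grid_shape, bool)
            for v in held:
                exclude[tuple(v)] = True
            for v in held:
                pred = _predict_voxel(scan.values, scan.mask, coords, tuple(v),
                                      t, h_z, ht, exclude)
                obs = scan.values[tuple(v)]
                ok = np.isfinite(pred)
                if ok.any():
                    errs.append(np.mean((pred[ok] - obs[ok]) ** 2))
        if not errs:
            return np.inf
        return float(np.mean(errs))

    hz_scores = [cv_error(h, 1.0) for h in hz_cands]
    h_z = float(hz_cands[int(np.argmin(hz_scores))])
    beta_scores = [cv_error(h_z, b) for b in beta_cands]
    beta = float(beta_cands[int(np.argmin(beta_scores))])
    config.h_z = h_z
    config.beta = beta
    return h_z, beta


class AdaptiveKernelSmoother:
    """Estimator-style wrapper: fit builds/calibrates bandwidths, transform smooths.

    ``fit(scan)`` resolves the temporal bandwidth profile and, when ``h_z``
    was not given, calibrates (h_z, beta) by cross-validation.
    ``transform(scan)`` returns the smoothed X-scale scan.
    """

    def __init__(self, h_z: float | None = None, beta: float = 1.0,
                 n_b: int = DEFAULT_NB, min_count: int = DEFAULT_MIN_COUNT,
                 n_cv: int = DEFAULT_N_CV,
                 n_replicates: int = DEFAULT_N_REPLICATES, seed: int = 0,
                 h_z_candidates=None, beta_candidates=(0.5, 0.75, 1.0, 1.5, 2.0)):
        self.h_z = h_z
        self.beta = beta
        self.n_b = n_b
        self.min_count = min_count
        self.n_cv = n_cv
        self.n_replicates = n_replicates
        self.seed = seed
        self.h_z_candidates = h_z_candidates
        self.beta_candidates = beta_candidates

    def _config(self) -> SmootherConfig:
        return SmootherConfig(
            h_z=self.h_z, beta=self.beta, n_b=self.n_b,
            min_count=self.min_count, h_z_candidates=self.h_z_candidates,
            beta_candidates=tuple(self.beta_candidates), n_cv=self.n_cv,
            n_replicates=self.n_replicates, seed=self.seed)

    def fit(self, scan: DynamicScan, y=None):
        cfg = self._config()
        cfg.resolve_profile(scan.frame_times)
        if cfg.h_z is None:
            calibrate_bandwidths(scan, cfg)
        self.config_ = cfg
        self.h_z_ = cfg.h_z
        self.beta_ = cfg.beta
        self.profile_ = cfg.profile
        return self

    def transform(self, scan: DynamicScan) -> DynamicScan:
        xhat, _ = smooth_scan(scan, self.config_)
        return xhat

    def fit_transform(self, scan: DynamicScan, y=None) -> DynamicScan:
        return self.fit(scan).transform(scan)

    def get_params(self, deep=True):
        return {k: getattr(self, k) for k in (
            "h_z", "beta", "n_b", "min_count", "n_cv", "n_replicates",
            "seed", "h_z_candidates", "beta_candidates")}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self
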