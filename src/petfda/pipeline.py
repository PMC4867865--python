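"""End-to-end orchestration: smooth, decompose, deconvolve, map V_T.

The pipeline stages, in order:

1. spatiotemporal presmoothing of the decayed data (optional but
   recommended on noisy scans), then decay correction;
2. mean estimation from the *raw* data, multiplicative coefficients
   A_i0, residual covariance and eigensystem, per-voxel scores and an
   R^2-based per-voxel component count;
3. one deconvolution each for the mean and the K retained
   eigenfunctions against the arterial input function (1 + K triangular
   solves for the whole volume — never per voxel);
4. per-voxel impulse-response functions and V_T by linear combination.

:class:`FPCADeconvolver` exposes stages 2-4 as a scikit-learn style
estimator on a plain curve matrix; :func:`run_pipeline` wraps the full
image workflow including IO.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import DynamicScan, InputFunction, VolumeMap, X_SCALE
from .deconv import (DEFAULT_M, DeconvolvedBasis, QuadratureGrid, VTResult,
                     build_convolution_operator, deconvolve_basis,
                     estimate_irf_vt)
from .fpca import (DEFAULT_KMAX, DEFAULT_R2_THRESHOLD, MultiplicativeFPCA)
from .smoothing import SmootherConfig, calibrate_bandwidths, smooth_scan
from . import io as pio


class FPCADeconvolver:
    """FPCA-based deconvolution of a sample of measured curves.

    Parameters
    ----------
    input_function : InputFunction
        Known arterial input curve covering [0, tau].
    times : array-like (p,)
        Frame times of the curve values (s).
    lam : float, default 0
        Isotope decay constant (1/s); 0 for already-corrected data.
    m : int, default 250
        Size of the equispaced deconvolution grid on [0, tau], tau = t_p.
    kmax, r2_threshold, ridge
        FPCA truncation cap, component-selection threshold, optional
        ridge penalty of the deconvolution solve.

    ``fit(Y, C=...)`` takes raw measured curves Y (n, p) and optionally
    presmoothed decay-corrected curves C.  Fitted attributes: ``fpca_``
    (the :class:`MultiplicativeFPCA`), ``basis_`` (deconvolved mean and
    eigenfunctions with their integrals), ``result_`` (:class:`VTResult`)
    and ``vt_`` (per-curve volume of distribution).  ``predict(Y)``
    returns V_T for new curves under the fitted basis.
    """

    def __init__(self, input_function: InputFunction = None, times=None,
                 lam: float = 0.0, m: int = DEFAULT_M, kmax: int = DEFAULT_KMAX,
                 r2_threshold: float = DEFAULT_R2_THRESHOLD, ridge: float = 0.0,
                 return_irf: bool = False):
        self.input_function = input_function
        self.times = times
        self.lam = lam
        self.m = m
        self.kmax = kmax
        self.r2_threshold = r2_threshold
        self.ridge = ridge
        self.return_irf = return_irf

    def fit(self, Y, y=None, C=None):
        t = np.asarray(self.times, float)
        self.fpca_ = MultiplicativeFPCA(times=t, lam=self.lam, kmax=self.kmax,
                                        r2_threshold=self.r2_threshold)
        self.fpca_.fit(Y, C=C)
        tau = float(t[-1])
        self.grid_ = QuadratureGrid.uniform(tau, self.m)
        self.operator_ = build_convolution_operator(self.input_function, self.grid_)
        es = self.fpca_.eigensystem_
        self.basis_ = deconvolve_basis(self.fpca_.mean_.values,
                                       es.eigenfunctions, t, self.operator_,
                                       ridge=self.ridge)
        self.n_deconvolutions_ = 1 + es.n_components
        self.result_ = estimate_irf_vt(self.basis_, self.fpca_.a0_,
                                       self.fpca_.scores_,
                                       self.fpca_.n_components_,
                                       r2_path=self.fpca_.r2_path_,
                                       return_irf=self.return_irf)
        self.vt_ = self.result_.vt
        return self

    def predict(self, Y, C=None):
        scores = self.fpca_.transform(Y, C=C)
        Cc = self.fpca_._corrected(Y) if C is None else np.atleast_2d(np.asarray(C))
        from .fpca import estimate_a0
        a0 = estimate_a0(Cc, self.fpca_.mean_)
        L = np.full(len(scores), self.basis_.n_components)
        return estimate_irf_vt(self.basis_, a0, scores, L).vt

    def get_params(self, deep=True):
        return {k: getattr(self, k) for k in (
            "input_function", "times", "lam", "m", "kmax", "r2_threshold",
            "ridge", "return_irf")}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self


@dataclass
class PipelineConfig:
    """Everything :func:`run_pipeline` needs, path-based or in-memory."""

    scan: DynamicScan | None = None
    input_function: InputFunction | None = None
    scan_path: str | None = None
    frames_path: str | None = None
    aif_path: str | None = None
    mask_path: str | None = None
    out_dir: str | None = None
    lam: float = 0.0
    smoother: SmootherConfig = field(default_factory=SmootherConfig)
    skip_smoothing: bool = False
    kmax: int = DEFAULT_KMAX
    r2_threshold: float = DEFAULT_R2_THRESHOLD
    m: int = DEFAULT_M
    ridge: float = 0.0
    seed: int = 0
    save_irf: bool = False

    def __post_init__(self):
        if not (0 < self.r2_threshold < 1):
            raise ValueError("r2_threshold must lie in (0, 1)")
        if self.m < 10:
            raise ValueError("m must be >= 10")


@dataclass
class PipelineResult:
    """Output bundle of one pipeline run."""

    vt_map: VolumeMap
    a0_map: VolumeMap
    l_map: VolumeMap
    r2_map: VolumeMap
    result: VTResult
    basis: DeconvolvedBasis
    model: FPCADeconvolver
    smoothed: DynamicScan | None
    log: dict


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full workflow on a dynamic scan; optionally write outputs."""
    scan = config.scan
    if scan is None:
        scan = pio.read_dynamic_scan(config.scan_path, config.frames_path,
                                     config.lam, config.mask_path)
    aif = config.input_function
    if aif is None:
        aif = pio.read_input_function(config.aif_path)
    if scan.scale != X_SCALE:
        raise ValueError("pipeline expects the raw X-scale scan")
    t = scan.frame_times
    log = {"stages": [], "seed": config.seed, "n_voxels": scan.n_voxels,
           "p": scan.schedule.p, "m": config.m, "kmax": config.kmax,
           "r2_threshold": config.r2_threshold, "ridge": config.ridge}

    smoothed_x = None
    curves_c = None
    if not config.skip_smoothing:
        sm = config.smoother
        sm.seed = config.seed
        sm.resolve_profile(t)
        if sm.h_z is None:
            h_z, beta = calibrate_bandwidths(scan, sm)
            log["stages"].append("calibrate_bandwidths")
            log["cv"] = {"n_cv": sm.n_cv, "n_replicates": sm.n_replicates}
        log["h_z"] = sm.h_z
        log["beta"] = sm.beta
        smoothed_x, smoothed_c = smooth_scan(scan, sm)
        log["stages"].append("smooth_scan")
        curves_c = smoothed_c.curves
    else:
        log["stages"].append("smoothing skipped")

    # flat (zero-variance) voxels cannot enter the R^2 rule; they keep L=0
    Y = scan.curves
    flat = Y.var(axis=1) <= 0
    if flat.any():
        log["flat_voxels"] = int(flat.sum())

    model = FPCADeconvolver(input_function=aif, times=t, lam=scan.lam,
                            m=config.m, kmax=config.kmax,
                            r2_threshold=config.r2_threshold,
                            ridge=config.ridge, return_irf=config.save_irf)
    model.fit(Y, C=curves_c)
    log["stages"] += ["estimate_mean", "estimate_a0", "estimate_eigensystem",
                      "estimate_scores", "select_components",
                      "build_convolution_operator", "deconvolve_basis",
                      "estimate_irf_vt"]
    log["n_components_retained"] = int(model.fpca_.eigensystem_.n_components)
    log["n_deconvolutions"] = int(model.n_deconvolutions_)
    log["eigenvalues"] = [float(z) for z in model.fpca_.eigenvalues_]
    log["L_histogram"] = {int(k): int(v) for k, v in
                          zip(*np.unique(model.fpca_.n_components_,
                                         return_counts=True))}

    res = model.result_
    r2_final = res.r2_path[np.arange(len(res.vt)),
                           np.minimum(res.n_components,
                                      res.r2_path.shape[1] - 1)]
    vt_map = VolumeMap.from_scan(scan, res.vt, "V_T")
    a0_map = VolumeMap.from_scan(scan, res.a0, "A0")
    l_map = VolumeMap.from_scan(scan, res.n_components.astype(float), "L")
    r2_map = VolumeMap.from_scan(scan, r2_final, "R2")

    out = PipelineResult(vt_map, a0_map, l_map, r2_map, res, model.basis_,
                         model, smoothed_x, log)
    if config.out_dir is not None:
        _write_outputs(out, scan, model, Path(config.out_dir))
    return out


def _write_outputs(result: PipelineResult, scan: DynamicScan,
                   model: FPCADeconvolver, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for vmap, name in ((result.vt_map, "vt"), (result.a0_map, "a0"),
                       (result.l_map, "L"), (result.r2_map, "r2")):
        pio.write_volume_map(vmap, out_dir / f"{name}.nii.gz")
    es = model.fpca_.eigensystem_
    basis_df = pd.DataFrame({"time_s": model.fpca_.mean_.times,
                             "mean": model.fpca_.mean_.values})
    for k in range(es.n_components):
        basis_df[f"phi_{k + 1}"] = es.eigenfunctions[k]
    basis_df.to_csv(out_dir / "basis.tsv", sep="\t", index=False)
    dec_df = pd.DataFrame({"time_s": model.basis_.grid.response_nodes,
                           "mean_d": model.basis_.mu_d})
    for k in range(model.basis_.n_components):
        dec_df[f"phi_{k + 1}_d"] = model.basis_.phi_d[k]
    dec_df.to_csv(out_dir / "deconvolved_basis.tsv", sep="\t", index=False)
    spec_df = pd.DataFrame({"component": np.arange(1, es.n_components + 1),
                            "eigenvalue": es.eigenvalues,
                            "integral_vk": model.basis_.vk})
    spec_df.to_csv(out_dir / "eigenvalues.tsv", sep="\t", index=False)
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(result.log, fh, indent=2, default=str)
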