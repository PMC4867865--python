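"""Core data containers for dynamic PET quantification.

A dynamic PET acquisition is a 4D array of radioactivity concentrations:
three spatial dimensions (voxels) by a set of time frames of typically
increasing duration.  The scanner observes the *decayed* signal
``X_i(t) = C_i(t) exp(-lambda t)`` where ``C_i`` is the decay-corrected
tissue concentration and ``lambda`` is the isotope decay constant
(5.663e-4 1/s for carbon-11).  The containers below carry the frame
timing, the voxel geometry, the decay constant and a scale flag that
records whether values are on the decayed ("X") or decay-corrected
("C") scale, so that the decay transform can never be applied twice in
the same direction by accident.

Times are seconds everywhere; a frame is represented by its mid-time.
Activity units are opaque — only relative consistency between the scan
and the arterial input function matters for the deconvolution.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

# decay constant of 11C in 1/s
LAMBDA_C11 = 5.663e-4

X_SCALE = "X"  # decayed, as measured
C_SCALE = "C"  # decay-corrected


@dataclass(frozen=True)
class FrameSchedule:
    """Start/end times (s) of the time frames of a dynamic acquisition."""

    start: np.ndarray
    end: np.ndarray

    def __post_init__(self):
        start = np.asarray(self.start, dtype=float)
        end = np.asarray(self.end, dtype=float)
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "end", end)
        if start.ndim != 1 or start.shape != end.shape:
            raise ValueError("start and end must be 1D arrays of equal length")
        if len(start) < 2:
            raise ValueError("a frame schedule needs at least 2 frames")
        if np.any(start < 0) or np.any(end <= start):
            raise ValueError("frames must satisfy 0 <= start < end")
        if np.any(start[1:] < end[:-1] - 1e-9):
            raise ValueError("frames must not overlap")
        mid = 0.5 * (start + end)
        if np.any(np.diff(mid) <= 0):
            raise ValueError("frame mid-times must be strictly increasing")

    @property
    def mid(self) -> np.ndarray:
        """Representative (mid-frame) times t_j in seconds."""
        return 0.5 * (self.start + self.end)

    @property
    def p(self) -> int:
        return len(self.start)

    @property
    def duration(self) -> np.ndarray:
        return self.end - self.start

    @classmethod
    def from_durations(cls, durations, t0: float = 0.0) -> "FrameSchedule":
        d = np.asarray(durations, dtype=float)
        edges = t0 + np.concatenate([[0.0], np.cumsum(d)])
        return cls(edges[:-1], edges[1:])


@dataclass
class InputFunction:
    """Sampled arterial input curve I(t), linearly interpolated on [0, tau].

    The curve must start at t=0 (a (0, 0) sample is prepended when the
    table starts later) and be positive on (0, tau]; positivity is what
    makes the discretized convolution operator invertible.
    """

    times: np.ndarray
    values: np.ndarray
    _interp_guard: float = field(default=0.0, repr=False)

    NEG_TOL = 1e-10

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("times and values must be 1D arrays of equal length")
        if len(t) and t[0] > 0:
            t = np.concatenate([[0.0], t])
            v = np.concatenate([[0.0], v])
        if len(t) < 2:
            raise ValueError("input function needs at least 2 samples to interpolate")
        if np.any(np.diff(t) <= 0):
            raise ValueError("input-function times must be strictly increasing")
        if np.any(v < -self.NEG_TOL):
            raise ValueError("input-function values must be nonnegative")
        v = np.clip(v, 0.0, None)
        if np.any(v[1:] <= 0):
            raise ValueError("input function must be positive on (0, tau]")
        self.times = t
        self.values = v

    @property
    def tau(self) -> float:
        return float(self.times[-1])

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if np.any(t < -1e-9) or np.any(t > self.tau + 1e-9):
            raise ValueError(
                f"input function only defined on [0, {self.tau}]; "
                "extrapolation is not allowed"
            )
        return np.interp(t, self.times, self.values)


def _as_grid_shape(values: np.ndarray) -> tuple:
    return values.shape[:-1]


@dataclass
class DynamicScan:
    """Voxel-by-frame activity with geometry, timing and decay metadata.

    ``values`` has shape ``grid_shape + (p,)`` with 1-3 spatial dims.
    ``mask`` selects the voxels that take part in the analysis.
    ``scale`` is "X" (decayed, as measured) or "C" (decay-corrected).
    Voxel coordinates are in mm, derived from ``affine`` when present,
    otherwise from ``voxel_size`` and 0-based indices.
    """

    values: np.ndarray
    schedule: FrameSchedule
    lam: float = 0.0
    mask: np.ndarray | None = None
    voxel_size: tuple = (1.0,)
    affine: np.ndarray | None = None
    scale: str = X_SCALE

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim < 2 or self.values.ndim > 4:
            raise ValueError("values must be (spatial..., frames) with 1-3 spatial dims")
        if self.values.shape[-1] != self.schedule.p:
            raise ValueError(
                f"scan has {self.values.shape[-1]} frames but schedule has "
                f"{self.schedule.p}"
            )
        if self.lam < 0:
            raise ValueError("decay constant must be nonnegative")
        if self.scale not in (X_SCALE, C_SCALE):
            raise ValueError("scale must be 'X' or 'C'")
        if self.mask is None:
            self.mask = np.ones(self.grid_shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.grid_shape:
                raise ValueError("mask shape must match the spatial grid")
        vs = np.broadcast_to(np.asarray(self.voxel_size, float), (self.ndim_spatial,))
        self.voxel_size = tuple(float(x) for x in vs)
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("masked scan values must be finite")

    @property
    def grid_shape(self) -> tuple:
        return _as_grid_shape(self.values)

    @property
    def ndim_spatial(self) -> int:
        return self.values.ndim - 1

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def frame_times(self) -> np.ndarray:
        return self.schedule.mid

    @property
    def curves(self) -> np.ndarray:
        """Masked voxel curves, shape (n_voxels, p)."""
        return self.values[self.mask]

    @property
    def coords_mm(self) -> np.ndarray:
        """Spatial coordinates (mm) of the masked voxels, (n_voxels, ndim)."""
        idx = np.argwhere(self.mask).astype(float)
        if self.affine is not None:
            d = self.ndim_spatial
            hom = np.c_[idx, np.ones(len(idx))]
            A = np.r_[np.c_[self.affine[:d, :d], self.affine[:d, -1]],
                      [np.append(np.zeros(d), 1.0)]]
            return (hom @ A.T)[:, :d]
        return idx * np.asarray(self.voxel_size)

    def with_values(self, values: np.ndarray, scale: str | None = None) -> "DynamicScan":
        return dataclasses.replace(
            self, values=np.asarray(values, float),
            scale=self.scale if scale is None else scale,
        )

    def embed(self, curves: np.ndarray, fill=np.nan) -> np.ndarray:
        """Place per-masked-voxel curves/scalars back onto the spatial grid."""
        curves = np.asarray(curves)
        out_shape = self.grid_shape + curves.shape[1:]
        out = np.full(out_shape, fill, dtype=float)
        out[self.mask] = curves
        return out


def apply_decay_transform(scan: DynamicScan, direction: str) -> DynamicScan:
    """Move a scan between the decayed X-scale and decay-corrected C-scale.

    ``direction='correct'`` multiplies by exp(+lambda t) (X -> C) and
    ``direction='decay'`` by exp(-lambda t) (C -> X).  The two are exact
    mutual inverses; applying the same direction twice is an error.
    """
    if direction not in ("correct", "decay"):
        raise ValueError("direction must be 'correct' or 'decay'")
    want_scale = X_SCALE if direction == "correct" else C_SCALE
    if scan.scale != want_scale:
        raise ValueError(
            f"cannot apply '{direction}' to a scan already on the "
            f"{scan.scale}-scale"
        )
    sign = 1.0 if direction == "correct" else -1.0
    factor = np.exp(sign * scan.lam * scan.frame_times)
    new_scale = C_SCALE if direction == "correct" else X_SCALE
    return scan.with_values(scan.values * factor, scale=new_scale)


@dataclass
class VolumeMap:
    """A per-voxel scalar map (V_T, A0, L, R2, ...) with spatial metadata."""

    values: np.ndarray
    name: str
    mask: np.ndarray | None = None
    voxel_size: tuple = (1.0,)
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape must match map shape")

    @classmethod
    def from_scan(cls, scan: DynamicScan, per_voxel: np.ndarray, name: str,
                  fill=np.nan) -> "VolumeMap":
        return cls(scan.embed(per_voxel, fill=fill), name=name, mask=scan.mask,
                   voxel_size=scan.voxel_size, affine=scan.affine)
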