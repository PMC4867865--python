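"""Readers and writers: NIfTI volumes, frame tables, input-function tables.

Tabular sidecars are tab-separated text: the frame schedule has columns
``frame_start_s``/``frame_end_s`` and the input function has columns
``time_s``/``activity``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import nibabel as nib

from .datamodel import DynamicScan, FrameSchedule, InputFunction, VolumeMap

FRAME_COLUMNS = ("frame_start_s", "frame_end_s")
AIF_COLUMNS = ("time_s", "activity")


def read_frame_schedule(path) -> FrameSchedule:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in FRAME_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"frame table {path} lacks columns {missing}")
    return FrameSchedule(df[FRAME_COLUMNS[0]].to_numpy(),
                         df[FRAME_COLUMNS[1]].to_numpy())


def write_frame_schedule(schedule: FrameSchedule, path) -> None:
    pd.DataFrame({FRAME_COLUMNS[0]: schedule.start,
                  FRAME_COLUMNS[1]: schedule.end}).to_csv(path, sep="\t", index=False)


def read_input_function(path) -> InputFunction:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in AIF_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"input-function table {path} lacks columns {missing}")
    if len(df) < 2:
        raise ValueError("input-function table needs at least 2 rows")
    return InputFunction(df[AIF_COLUMNS[0]].to_numpy(), df[AIF_COLUMNS[1]].to_numpy())


def write_input_function(aif: InputFunction, path) -> None:
    pd.DataFrame({AIF_COLUMNS[0]: aif.times,
                  AIF_COLUMNS[1]: aif.values}).to_csv(path, sep="\t", index=False)


def read_dynamic_scan(volume_path, frames_path, lam: float,
                      mask_path=None) -> DynamicScan:
    """Load a 4D NIfTI + frame table (+ optional mask) as an X-scale scan."""
    img = nib.load(str(volume_path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D volume, got {data.ndim} dims")
    schedule = read_frame_schedule(frames_path)
    if schedule.p != data.shape[-1]:
        raise ValueError(
            f"frame table has {schedule.p} rows but volume has "
            f"{data.shape[-1]} frames"
        )
    mask = None
    if mask_path is not None:
        mimg = nib.load(str(mask_path))
        mask = np.asarray(mimg.get_fdata()) > 0.5
        if mask.shape != data.shape[:-1]:
            raise ValueError("mask shape does not match volume")
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return DynamicScan(data, schedule, lam=lam, mask=mask,
                       voxel_size=voxel_size, affine=np.asarray(img.affine))


def write_dynamic_scan(scan: DynamicScan, volume_path, frames_path=None) -> None:
    data = scan.values
    if data.ndim < 4:  # NIfTI wants 3 spatial dims
        data = data.reshape(data.shape[:-1] + (1,) * (4 - data.ndim) + data.shape[-1:])
    affine = scan.affine if scan.affine is not None else _affine_from_voxel_size(scan)
    nib.save(nib.Nifti1Image(np.asarray(data, np.float32), affine), str(volume_path))
    if frames_path is not None:
        write_frame_schedule(scan.schedule, frames_path)


def _affine_from_voxel_size(obj) -> np.ndarray:
    aff = np.eye(4)
    for d, vz in enumerate(obj.voxel_size[:3]):
        aff[d, d] = vz
    return aff


def write_volume_map(vmap: VolumeMap, path, fill=np.nan) -> None:
    """Write a scalar map as NIfTI; out-of-mask voxels get ``fill``."""
    values = np.where(vmap.mask, vmap.values, fill)
    if values.ndim > 3:
        raise ValueError("a volume map has at most 3 spatial dims")
    data = values.reshape(values.shape + (1,) * (3 - values.ndim))
    affine = vmap.affine if vmap.affine is not None else _affine_from_voxel_size(vmap)
    img = nib.Nifti1Image(np.asarray(data, np.float32), affine)
    img.header["descrip"] = vmap.name[:79].encode()
    nib.save(img, str(path))


def read_volume_map(path, name: str = "") -> VolumeMap:
    img = nib.load(str(path))
    values = np.squeeze(np.asarray(img.get_fdata(), dtype=float))
    return VolumeMap(values, name=name or str(img.header["descrip"].astype(str)),
                     voxel_size=tuple(float(z) for z in img.header.get_zooms()[:values.ndim]),
                     affine=np.asarray(img.affine))
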