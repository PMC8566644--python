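"""NIfTI / CSV round-trip helpers.

Studies are 4D NIfTI volumes (x, y, z, frame); masks are 3D uint8 NIfTI;
parametric images are 3D float NIfTI with the map kind recorded in the
header description and a JSON sidecar carrying provenance (kind, background
mean, schedule hash).  Labels travel as a two-column CSV.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .frames import FrameSchedule, default_frame_schedule
from .parametric import DynamicStudy, ParametricImage, VoxelMask

__all__ = [
    "schedule_hash",
    "read_study",
    "write_study",
    "read_mask",
    "write_mask",
    "read_parametric",
    "write_parametric",
    "read_labels",
    "write_labels",
]


def schedule_hash(schedule: FrameSchedule) -> str:
    payload = json.dumps(schedule.frames).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_study(study: DynamicStudy, path: str | Path) -> Path:
    path = Path(path)
    data = np.moveaxis(study.volume4d, 0, -1)  # (x, y, z, frame)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), _affine(study.voxel_spacing_mm))
    zooms = study.voxel_spacing_mm + (1.0,)
    img.header.set_zooms(zooms)
    nib.save(img, path)
    return path


def read_study(path: str | Path, schedule: FrameSchedule | None = None) -> DynamicStudy:
    schedule = schedule or default_frame_schedule()
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D volume, got shape {data.shape}")
    if data.shape[-1] != len(schedule):
        raise ValueError(
            f"{path}: volume has {data.shape[-1]} frames but the schedule has "
            f"{len(schedule)}"
        )
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return DynamicStudy(np.moveaxis(data, -1, 0), schedule, spacing)


def write_mask(mask: VoxelMask, spacing: tuple[float, float, float], path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(mask.grid.astype(np.uint8), _affine(spacing))
    img.header.set_zooms(spacing)
    nib.save(img, path)
    return path


def read_mask(path: str | Path, role: str = "tumour") -> VoxelMask:
    img = nib.load(str(path))
    return VoxelMask(np.asanyarray(img.dataobj) > 0, role=role)


def write_parametric(image: ParametricImage, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(image.grid, dtype=np.float32), _affine(image.voxel_spacing_mm))
    img.header.set_zooms(image.voxel_spacing_mm)
    img.header["descrip"] = image.kind.encode()
    nib.save(img, path)
    sidecar = {"kind": image.kind, **{k: v for k, v in image.meta.items()}}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_parametric(path: str | Path) -> ParametricImage:
    img = nib.load(str(path))
    sidecar_path = Path(str(path) + ".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    kind = meta.get("kind") or img.header["descrip"].tobytes().split(b"\x00")[0].decode()
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    grid = np.asanyarray(img.dataobj).astype(float)
    return ParametricImage(grid, kind, spacing, meta)


def write_labels(labels: pd.Series, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"patient_id": labels.index, "label": labels.to_numpy()}).to_csv(
        path, index=False
    )
    return path


def read_labels(path: str | Path) -> pd.Series:
    df = pd.read_csv(path)
    if not {"patient_id", "label"} <= set(df.columns):
        raise ValueError(f"{path}: labels CSV needs patient_id and label columns")
    return pd.Series(df["label"].to_numpy(dtype=int), index=df["patient_id"]).sort_index()
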