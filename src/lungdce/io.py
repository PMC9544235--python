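"""Shared containers and NIfTI / sidecar / table I/O.

Volumes are kept in ``(x, y, z[, volume])`` order with a RAS-oriented affine,
so the foot-head (inferior-superior) direction is always recoverable from the
affine's third world row. Files on disk are NIfTI-1; per-series metadata
(flip angles or time stamps) travels in a YAML sidecar.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .protocol import AcquisitionProtocol

log = logging.getLogger("lungdce")


class FormatError(ValueError):
    """Raised for unreadable or unsupported on-disk inputs."""


@dataclass
class VolumeSeries:
    """A 3D volume or 4D stack of volumes with spatial geometry.

    For VFA stacks ``flip_angles_deg`` holds one entry per volume (repeats at
    the same angle simply repeat the entry); for dynamic series ``times_sec``
    holds one acquisition time per volume.
    """

    data: np.ndarray
    affine: np.ndarray
    flip_angles_deg: np.ndarray | None = None
    times_sec: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim not in (3, 4):
            raise FormatError(f"expected 3D or 4D data, got {self.data.ndim}D")
        if self.affine.shape != (4, 4):
            raise FormatError("affine must be 4x4")
        if self.flip_angles_deg is not None:
            self.flip_angles_deg = np.asarray(self.flip_angles_deg, dtype=float)
        if self.times_sec is not None:
            self.times_sec = np.asarray(self.times_sec, dtype=float)

    @property
    def shape3(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return 1 if self.data.ndim == 3 else self.data.shape[3]

    @property
    def voxel_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))


def foot_head_axis(affine: np.ndarray) -> tuple[int, float]:
    """Identify the voxel axis most aligned with the world inferior-superior
    direction. Returns ``(axis, sign)`` where ``sign`` is +1 if increasing
    voxel index moves toward the head.
    """
    zrow = np.asarray(affine)[2, :3]
    if not np.any(np.abs(zrow) > 1e-9):
        raise ValueError("foot-head axis unidentifiable: affine has no "
                         "superior component on any voxel axis")
    axis = int(np.argmax(np.abs(zrow)))
    return axis, float(np.sign(zrow[axis]))


def world_z_coordinates(affine: np.ndarray, shape3: tuple[int, int, int]) -> np.ndarray:
    """Per-voxel world superior (foot-head) coordinate in mm, shape ``shape3``."""
    ii, jj, kk = np.meshgrid(
        np.arange(shape3[0]), np.arange(shape3[1]), np.arange(shape3[2]),
        indexing="ij",
    )
    a = np.asarray(affine)
    return (a[2, 0] * ii + a[2, 1] * jj + a[2, 2] * kk + a[2, 3]).astype(float)


# ---------------------------------------------------------------------------
# NIfTI round trip

def write_volume_series(path: str | Path, series: VolumeSeries,
                        sidecar: dict | None = None) -> None:
    """Write a series as NIfTI-1 plus an optional YAML sidecar next to it."""
    path = Path(path)
    img = nib.Nifti1Image(series.data, series.affine)
    nib.save(img, str(path))
    meta = dict(sidecar or {})
    if series.flip_angles_deg is not None:
        meta.setdefault("flip_angles_deg", [float(a) for a in series.flip_angles_deg])
    if series.times_sec is not None:
        meta.setdefault("times_sec", [float(t) for t in series.times_sec])
    if meta:
        sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=False))


def sidecar_path(path: str | Path) -> Path:
    path = Path(path)
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".yaml")
    return path.with_suffix(".yaml")


def read_volume_series(path: str | Path, sidecar: dict | str | Path | None = None,
                       require: tuple[str, ...] = ()) -> VolumeSeries:
    """Load a 3D/4D NIfTI volume, reoriented to canonical RAS.

    ``sidecar`` may be a dict, a YAML path, or None (in which case a YAML file
    next to the image is used when present). ``require`` lists sidecar fields
    that must be present; missing ones raise :class:`FormatError` by name.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad files
        raise FormatError(f"not a readable NIfTI file: {path}: {exc}") from exc
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if data.ndim not in (3, 4):
        raise FormatError(f"unsupported dimensionality {data.ndim}D in {path}; "
                          "expected 3D or 4D")

    if sidecar is None:
        sc = sidecar_path(path)
        meta = yaml.safe_load(sc.read_text()) if sc.exists() else {}
    elif isinstance(sidecar, (str, Path)):
        meta = yaml.safe_load(Path(sidecar).read_text())
    else:
        meta = dict(sidecar)
    meta = meta or {}

    missing = [f for f in require if f not in meta]
    if missing:
        raise FormatError(f"sidecar for {path} is missing required fields: "
                          + ", ".join(missing))

    return VolumeSeries(
        data=data,
        affine=img.affine,
        flip_angles_deg=np.asarray(meta["flip_angles_deg"], float)
        if "flip_angles_deg" in meta else None,
        times_sec=np.asarray(meta["times_sec"], float)
        if "times_sec" in meta else None,
    )


def write_map(path: str | Path, data: np.ndarray, affine: np.ndarray) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, np.float64), np.asarray(affine)),
             str(Path(path)))


def read_mask(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a binary mask (canonical orientation); returns (bool array, affine)."""
    series = read_volume_series(path)
    if series.data.ndim != 3:
        raise FormatError(f"mask must be 3D: {path}")
    return series.data > 0.5, series.affine


# ---------------------------------------------------------------------------
# Protocol / config / table serialization

def write_protocol(path: str | Path, protocol: AcquisitionProtocol,
                   extra: dict | None = None) -> None:
    d = {"protocol": protocol.to_dict()}
    if extra:
        d.update(extra)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def read_protocol(path: str | Path) -> tuple[AcquisitionProtocol, dict]:
    d = yaml.safe_load(Path(path).read_text())
    if not isinstance(d, dict) or "protocol" not in d:
        raise FormatError(f"{path} does not contain a 'protocol' section")
    proto = AcquisitionProtocol.from_dict(d["protocol"])
    extra = {k: v for k, v in d.items() if k != "protocol"}
    return proto, extra


def write_aif_csv(path: str | Path, times_sec: np.ndarray, cp_mM: np.ndarray) -> None:
    pd.DataFrame({"time_sec": times_sec, "cp_mM": cp_mM}).to_csv(path, index=False)


def read_aif_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return df["time_sec"].to_numpy(float), df["cp_mM"].to_numpy(float)
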