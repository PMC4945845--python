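"""Volume and mask I/O: NIfTI (read/write) and DICOM series (read-only).

Internal arrays are float HU in (slice, row, column) order; NIfTI files
store the same data transposed to the conventional (x, y, z) order with
spacing carried in the affine.  DICOM series are assembled slice by slice
with the rescale slope/intercept applied.
"""

from __future__ import annotations

import os
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom

from .core import CTVolume, RegionMask

__all__ = ["read_volume", "write_volume", "read_mask", "write_mask"]


def write_volume(volume: CTVolume, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI; values round-trip bit-exact (float64)."""
    affine = np.diag(list(volume.spacing[::-1]) + [1.0])
    affine[:3, 3] = volume.origin[::-1]
    img = nib.Nifti1Image(volume.values.T.astype(np.float64), affine)
    nib.save(img, str(path))


def _read_nifti(path: str) -> CTVolume:
    img = nib.load(path)
    data = np.asanyarray(img.dataobj).T.astype(np.float64)
    zooms = img.header.get_zooms()[:3]
    origin = img.affine[:3, 3]
    return CTVolume(values=data, spacing=tuple(zooms[::-1]),
                    origin=tuple(float(o) for o in origin[::-1]))


def _read_dicom_series(directory: Path) -> CTVolume:
    files = sorted(p for p in directory.iterdir() if p.is_file())
    slices = []
    for p in files:
        try:
            ds = pydicom.dcmread(str(p))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise ValueError(f"no DICOM images found in {directory}")
    for ds in slices:
        if not hasattr(ds, "RescaleSlope") or not hasattr(ds, "RescaleIntercept"):
            raise ValueError("DICOM slice missing RescaleSlope/RescaleIntercept")

    def zpos(ds):
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "InstanceNumber", 0))

    slices.sort(key=zpos)
    if len(slices) > 1:
        zs = np.array([zpos(s) for s in slices])
        gaps = np.diff(zs)
        if np.ptp(gaps) > 1e-3 * max(abs(gaps.mean()), 1e-9) + 1e-6:
            bad = np.nonzero(np.abs(gaps - gaps.mean()) > 1e-3)[0]
            raise ValueError(
                f"inconsistent slice spacing at slice indices {bad.tolist()}"
            )
        dz = float(abs(gaps.mean()))
    else:
        dz = float(getattr(slices[0], "SliceThickness", 1.0))
    ps = [float(v) for v in slices[0].PixelSpacing]
    data = np.stack([
        float(ds.RescaleSlope) * ds.pixel_array.astype(np.float64)
        + float(ds.RescaleIntercept)
        for ds in slices
    ])
    return CTVolume(values=data, spacing=(dz, ps[0], ps[1]),
                    origin=(zpos(slices[0]), 0.0, 0.0))


def read_volume(path: str | os.PathLike) -> CTVolume:
    """Read a CT volume from a NIfTI file or a DICOM series directory."""
    p = Path(path)
    if p.is_dir():
        return _read_dicom_series(p)
    if not p.exists():
        raise FileNotFoundError(str(p))
    return _read_nifti(str(p))


def write_mask(mask: RegionMask, path: str | os.PathLike,
               spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> None:
    affine = np.diag(list(spacing[::-1]) + [1.0])
    img = nib.Nifti1Image(mask.mask.T.astype(np.uint8), affine)
    img.header.set_intent("estimate", name=mask.label)
    nib.save(img, str(path))


def read_mask(path: str | os.PathLike, label: str = "other") -> RegionMask:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).T.astype(bool)
    return RegionMask(mask=data, label=label)
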