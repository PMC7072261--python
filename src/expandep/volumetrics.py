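"""Ablated-volume estimation from segmentation masks and diameter triples.

Two estimators are provided, matching how ablation zones are quantified
on post-treatment CT:

* ellipsoid estimator — the smallest ellipsoid whose axes are the three
  maximum orthogonal diameters of the ablated area:
  V = (4/3) pi a b c with a, b, c the semi-axes (cm);
* voxel-count estimator — the segmented pixel count times the voxel
  footprint: V_CT = n_pixel * PS_o * PS_v * SBS, where PS_o/PS_v are the
  in-plane pixel spacings and SBS the slice pitch (slice thickness plus
  any inter-slice gap).

Masks are binary 3D arrays in slice-major order (slice, row, column)
with spacing metadata; NIfTI and NRRD files are accepted, with an
optional JSON sidecar to carry a slice thickness distinct from the
pitch, which image headers cannot represent.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import nibabel as nib
import numpy as np
import SimpleITK as sitk

from .errors import DomainError, MaskIOError

__all__ = [
    "EllipsoidMeasure",
    "SegmentationVolume",
    "ellipsoid_volume",
    "voxel_volume",
    "diameters_from_mask",
    "load_mask",
    "save_mask",
]

CM3_PER_MM3 = 1e-3
CM_PER_MM = 0.1


@dataclass(frozen=True)
class EllipsoidMeasure:
    """Three orthogonal maximum diameters (cm): 2a, 2b, 2c."""

    diameter_a_cm: float
    diameter_b_cm: float
    diameter_c_cm: float

    def __post_init__(self) -> None:
        for d in (self.diameter_a_cm, self.diameter_b_cm, self.diameter_c_cm):
            if d <= 0:
                raise DomainError(f"diameters must be positive, got {d} cm")

    @property
    def diameters_cm(self) -> tuple[float, float, float]:
        return (self.diameter_a_cm, self.diameter_b_cm, self.diameter_c_cm)


@dataclass(frozen=True)
class SegmentationVolume:
    """Binary mask (slice, row, column) with CT spacing metadata in mm.

    ``ps_o_mm``/``ps_v_mm`` are the horizontal/vertical in-plane pixel
    spacings, ``st_mm`` the slice thickness, ``sbs_mm`` the space between
    slices (pitch).  A pitch below the thickness flags an overlapping
    acquisition but is accepted.
    """

    mask: np.ndarray
    ps_o_mm: float
    ps_v_mm: float
    st_mm: float
    sbs_mm: float

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask)
        if mask.ndim != 3:
            raise DomainError(f"mask must be 3D, got {mask.ndim} dims")
        object.__setattr__(self, "mask", mask.astype(bool))
        for attr in ("ps_o_mm", "ps_v_mm", "st_mm", "sbs_mm"):
            value = getattr(self, attr)
            if value is None or not value > 0:
                raise MaskIOError(f"missing or non-positive spacing metadata: {attr}")

    @property
    def n_pixel(self) -> int:
        return int(np.count_nonzero(self.mask))

    @property
    def overlapping_acquisition(self) -> bool:
        return self.sbs_mm < self.st_mm


def ellipsoid_volume(measure: EllipsoidMeasure) -> float:
    """(4/3) pi a b c in cm^3 from the three maximum diameters."""
    a, b, c = (d / 2.0 for d in measure.diameters_cm)
    return (4.0 / 3.0) * math.pi * a * b * c


def voxel_volume(volume: SegmentationVolume) -> float:
    """n_pixel * PS_o * PS_v * SBS, in cm^3.

    The slice pitch SBS already absorbs any inter-slice gap (ST plus
    (SBS - ST)); exactly linear in the pixel count.
    """
    return volume.n_pixel * volume.ps_o_mm * volume.ps_v_mm * volume.sbs_mm * CM3_PER_MM3


def diameters_from_mask(volume: SegmentationVolume) -> EllipsoidMeasure:
    """Maximum extents of the mask along the three grid axes, in cm.

    Extent convention: (max_index - min_index + 1) voxels per axis,
    voxel-inclusive, times that axis' spacing (SBS along slices).
    Returned in (column, row, slice) = (horizontal, vertical,
    through-slice) order.
    """
    mask = volume.mask
    if not mask.any():
        raise DomainError("cannot measure diameters of an empty mask")
    spacings = (volume.sbs_mm, volume.ps_v_mm, volume.ps_o_mm)  # per mask axis
    extents_mm = []
    for axis in range(3):
        profile = np.any(mask, axis=tuple(k for k in range(3) if k != axis))
        nz = np.flatnonzero(profile)
        extents_mm.append((nz[-1] - nz[0] + 1) * spacings[axis])
    slice_ext, row_ext, col_ext = extents_mm
    return EllipsoidMeasure(
        diameter_a_cm=col_ext * CM_PER_MM,
        diameter_b_cm=row_ext * CM_PER_MM,
        diameter_c_cm=slice_ext * CM_PER_MM,
    )


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii", ".nrrd"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def load_mask(
    path: Union[str, Path],
    st_mm: Optional[float] = None,
    sbs_mm: Optional[float] = None,
) -> SegmentationVolume:
    """Read a binary mask from NIfTI (.nii/.nii.gz) or NRRD.

    In-plane spacings and the slice pitch come from the header; the
    pitch doubles as the slice thickness unless overridden by the
    arguments or by a JSON sidecar with keys ``st_mm``/``sbs_mm``.
    """
    path = Path(path)
    if not path.exists():
        raise MaskIOError(f"mask file not found: {path}")
    try:
        if path.name.endswith((".nii", ".nii.gz")):
            img = nib.load(str(path))
            data = np.asanyarray(img.dataobj)  # (i, j, k) = (col, row, slice)
            zooms = img.header.get_zooms()[:3]
            mask = np.transpose(data, (2, 1, 0))
            ps_o, ps_v, pitch = float(zooms[0]), float(zooms[1]), float(zooms[2])
        elif path.name.endswith(".nrrd"):
            img = sitk.ReadImage(str(path))
            mask = sitk.GetArrayFromImage(img)  # already (slice, row, col)
            sp = img.GetSpacing()  # (x, y, z)
            ps_o, ps_v, pitch = float(sp[0]), float(sp[1]), float(sp[2])
        else:
            raise MaskIOError(f"unsupported mask format: {path}")
    except MaskIOError:
        raise
    except Exception as exc:  # file corrupt / not an image
        raise MaskIOError(f"could not read mask {path}: {exc}") from exc

    sidecar = _sidecar_path(path)
    if sidecar.exists() and (st_mm is None or sbs_mm is None):
        meta = json.loads(sidecar.read_text())
        st_mm = st_mm if st_mm is not None else meta.get("st_mm")
        sbs_mm = sbs_mm if sbs_mm is not None else meta.get("sbs_mm")
    return SegmentationVolume(
        mask=np.asarray(mask) > 0.5,
        ps_o_mm=ps_o,
        ps_v_mm=ps_v,
        st_mm=st_mm if st_mm is not None else pitch,
        sbs_mm=sbs_mm if sbs_mm is not None else pitch,
    )


def save_mask(volume: SegmentationVolume, path: Union[str, Path]) -> Path:
    """Write a mask to NIfTI or NRRD; spacing goes into the header and a
    JSON sidecar records ST/SBS when the thickness differs from the pitch."""
    path = Path(path)
    data = volume.mask.astype(np.uint8)
    try:
        if path.name.endswith((".nii", ".nii.gz")):
            affine = np.diag([volume.ps_o_mm, volume.ps_v_mm, volume.sbs_mm, 1.0])
            img = nib.Nifti1Image(np.transpose(data, (2, 1, 0)), affine)
            nib.save(img, str(path))
        elif path.name.endswith(".nrrd"):
            img = sitk.GetImageFromArray(data)
            img.SetSpacing((volume.ps_o_mm, volume.ps_v_mm, volume.sbs_mm))
            sitk.WriteImage(img, str(path), useCompression=False)
        else:
            raise MaskIOError(f"unsupported mask format: {path}")
    except MaskIOError:
        raise
    except Exception as exc:
        raise MaskIOError(f"could not write mask {path}: {exc}") from exc
    if volume.st_mm != volume.sbs_mm:
        _sidecar_path(path).write_text(
            json.dumps({"st_mm": volume.st_mm, "sbs_mm": volume.sbs_mm}, sort_keys=True)
        )
    return path
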