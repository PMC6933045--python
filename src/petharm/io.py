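"""Reading and writing images.

NIfTI-1 is the working format: voxel spacing comes from the header and
the unit tag travels in a small JSON sidecar next to the image
(``<name>.json`` with a ``unit`` key), since NIfTI has no standard slot
for activity-concentration units.

A minimal DICOM PET series reader is provided for convenience: it stacks
single-frame slices, applies RescaleSlope/RescaleIntercept to obtain
Bq/ml and converts to kBq/ml. Decay handling is limited to whatever
corrections the header values already carry.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .image import UNIT_KBQ_ML, VolumetricImage

__all__ = ["write_nifti", "read_nifti", "read_dicom_series"]


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_nifti(img: VolumetricImage, path) -> Path:
    """Write a VolumetricImage as NIfTI-1 plus a unit sidecar JSON.

    The array is stored in (x, y, z) order as NIfTI convention expects,
    with an affine carrying the spacing and origin.
    """
    path = Path(path)
    affine = np.diag([img.spacing[2], img.spacing[1], img.spacing[0], 1.0])
    affine[:3, 3] = [img.origin[2], img.origin[1], img.origin[0]]
    data = np.transpose(img.values, (2, 1, 0))
    nib.save(nib.Nifti1Image(data, affine), str(path))
    sidecar = _sidecar_path(path)
    sidecar.write_text(json.dumps({"unit": img.unit}, indent=2))
    return path


def read_nifti(path, unit: str | None = None) -> VolumetricImage:
    """Read a NIfTI image written by :func:`write_nifti` (or compatible).

    The unit is taken from the sidecar JSON when present; ``unit``
    overrides it. The affine must be axis-aligned.
    """
    path = Path(path)
    nii = nib.load(str(path))
    affine = nii.affine
    rot = affine[:3, :3]
    if not np.allclose(rot, np.diag(np.diag(rot))):
        raise ValueError("only axis-aligned NIfTI affines are supported")
    spacing_xyz = np.abs(np.diag(rot))
    if np.any(spacing_xyz <= 0):
        raise ValueError("NIfTI affine has nonpositive spacing")
    values = np.transpose(np.asarray(nii.dataobj, dtype=float), (2, 1, 0))
    origin_xyz = affine[:3, 3]
    if unit is None:
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            unit = json.loads(sidecar.read_text()).get("unit", UNIT_KBQ_ML)
        else:
            unit = UNIT_KBQ_ML
    return VolumetricImage(
        values=values,
        spacing=(spacing_xyz[2], spacing_xyz[1], spacing_xyz[0]),
        origin=(origin_xyz[2], origin_xyz[1], origin_xyz[0]),
        unit=unit,
    )


def read_dicom_series(directory) -> VolumetricImage:
    """Read a directory of single-frame PET DICOM slices into kBq/ml.

    Slices are ordered by ImagePositionPatient along the slice axis;
    pixel values are rescaled with RescaleSlope/RescaleIntercept
    (assumed Bq/ml for PET) and divided by 1000.
    """
    import pydicom

    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.suffix.lower() == ".dcm")
    if not files:
        raise ValueError(f"no .dcm files in {directory}")
    datasets = [pydicom.dcmread(str(p)) for p in files]
    datasets.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))

    first = datasets[0]
    px_spacing = [float(v) for v in first.PixelSpacing]  # (row, col) = (y, x)
    if len(datasets) > 1:
        dz = float(datasets[1].ImagePositionPatient[2]) - float(
            first.ImagePositionPatient[2]
        )
    else:
        dz = float(getattr(first, "SliceThickness", 1.0))
    slices = []
    for ds in datasets:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(ds.pixel_array.astype(float) * slope + intercept)
    values_bq = np.stack(slices, axis=0)  # (z, y, x)
    pos = first.ImagePositionPatient
    return VolumetricImage(
        values=values_bq / 1000.0,
        spacing=(abs(dz), px_spacing[0], px_spacing[1]),
        origin=(float(pos[2]), float(pos[1]), float(pos[0])),
        unit=UNIT_KBQ_ML,
    )
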