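"""Volume, mask and dose I/O (NIfTI / NRRD) with JSON provenance sidecars.

Arrays are stored on disk in the usual medical-imaging (x, y, z) layout and
transposed to the package's (z, y, x) convention on read.  Every writer can
attach a JSON sidecar recording the seed/config that produced the artifact,
so a run can be reproduced from its manifest alone.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import nibabel as nib

from .grid import DoseGrid, ImageVolume, StructureMask

__all__ = [
    "read_volume", "write_volume", "read_mask", "write_mask",
    "read_dose", "write_dose", "config_hash",
]

_NIFTI_EXT = (".nii", ".nii.gz")
_NRRD_EXT = (".nrrd",)


def config_hash(obj) -> str:
    """Stable short hash of any JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _is_nifti(path: Path) -> bool:
    return path.name.endswith(".nii.gz") or path.suffix == ".nii"


def _write_sidecar(path: Path, sidecar: dict | None) -> None:
    if sidecar is None:
        return
    meta = dict(sidecar)
    meta.setdefault("config_hash", config_hash(sidecar))
    with open(path.parent / (path.name + ".json"), "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=str)


def _write_array(data: np.ndarray, spacing, origin, path: Path) -> None:
    if _is_nifti(path):
        affine = np.eye(4)
        affine[0, 0], affine[1, 1], affine[2, 2] = spacing[2], spacing[1], spacing[0]
        affine[:3, 3] = (origin[2], origin[1], origin[0])
        img = nib.Nifti1Image(np.transpose(data, (2, 1, 0)), affine)
        nib.save(img, str(path))
    elif path.suffix in _NRRD_EXT:
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(data))
        img.SetSpacing(tuple(float(s) for s in spacing[::-1]))
        img.SetOrigin(tuple(float(o) for o in origin[::-1]))
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError(f"unsupported volume format: {path.name} "
                         f"(expected .nii, .nii.gz or .nrrd)")


def _read_array(path: Path):
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_nifti(path):
        try:
            img = nib.load(str(path))
            data = np.transpose(np.asanyarray(img.dataobj), (2, 1, 0))
        except Exception as exc:  # corrupt or truncated file
            raise ValueError(f"could not read {path} as NIfTI: {exc}") from exc
        zooms = img.header.get_zooms()[:3]
        spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
        t = img.affine[:3, 3]
        origin = (float(t[2]), float(t[1]), float(t[0]))
        return data, spacing, origin
    if path.suffix in _NRRD_EXT:
        import SimpleITK as sitk

        try:
            img = sitk.ReadImage(str(path))
        except Exception as exc:
            raise ValueError(f"could not read {path} as NRRD: {exc}") from exc
        data = sitk.GetArrayFromImage(img)
        spacing = tuple(float(s) for s in img.GetSpacing()[::-1])
        origin = tuple(float(o) for o in img.GetOrigin()[::-1])
        return data, spacing, origin
    raise ValueError(f"unsupported volume format: {path.name}")


def write_volume(vol: ImageVolume, path, sidecar: dict | None = None) -> None:
    path = Path(path)
    _write_array(np.asarray(vol.data, dtype=np.float64), vol.spacing, vol.origin, path)
    _write_sidecar(path, sidecar)


def read_volume(path) -> ImageVolume:
    data, spacing, origin = _read_array(Path(path))
    return ImageVolume(np.asarray(data, dtype=float), spacing, origin)


def write_mask(mask: StructureMask, path, sidecar: dict | None = None) -> None:
    path = Path(path)
    _write_array(mask.data.astype(np.uint8), mask.spacing, mask.origin, path)
    _write_sidecar(path, sidecar)


def read_mask(path, name: str | None = None) -> StructureMask:
    path = Path(path)
    data, spacing, origin = _read_array(path)
    if name is None:
        name = path.name.split(".")[0]
    return StructureMask(name, data > 0.5, spacing, origin)


def write_dose(dose: DoseGrid, path, sidecar: dict | None = None) -> None:
    path = Path(path)
    _write_array(np.asarray(dose.data, dtype=np.float64), dose.spacing, dose.origin, path)
    meta = dict(sidecar or {})
    meta.update(prescription_gy=dose.prescription_gy, fractions=dose.fractions)
    _write_sidecar(path, meta)


def read_dose(path, prescription_gy: float | None = None) -> DoseGrid:
    path = Path(path)
    data, spacing, origin = _read_array(path)
    if prescription_gy is None:
        sidecar = path.parent / (path.name + ".json")
        prescription_gy = 50.0
        if sidecar.exists():
            with open(sidecar) as fh:
                prescription_gy = float(json.load(fh).get("prescription_gy", 50.0))
    return DoseGrid(np.clip(data, 0.0, None), spacing, origin,
                    prescription_gy=prescription_gy)
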