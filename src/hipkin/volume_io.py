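"""Density volumes with landmarks: I/O, thresholding, and cropping.

A :class:`DensityVolume` is a CT-like scalar grid in *model coordinates*:
voxel (i, j, k) has its center at ``origin + (i, j, k) * spacing`` with
axes ordered (x, y, z) and zero-based indices.  Anatomical landmarks are
stored in the same model coordinates in a sidecar JSON next to the volume
file, so any volume format can carry them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk

from .errors import FormatError, ParameterError

_NIFTI_SUFFIXES = (".nii.gz", ".nii")
_META_SUFFIXES = (".mha", ".mhd")


@dataclass
class DensityVolume:
    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    landmarks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ParameterError("volume data must be 3D")
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if np.any(self.spacing <= 0):
            raise ParameterError("voxel spacing must be strictly positive")
        self.landmarks = {
            str(k): np.asarray(v, dtype=float) for k, v in self.landmarks.items()
        }

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def index_to_model(self, idx: np.ndarray) -> np.ndarray:
        """Model coordinates (mm) of voxel index triples (may be fractional)."""
        return self.origin + np.asarray(idx, dtype=float) * self.spacing

    def model_to_index(self, pts: np.ndarray) -> np.ndarray:
        return (np.asarray(pts, dtype=float) - self.origin) / self.spacing

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Model-coordinate box spanned by the interpolation support.

        Extends one voxel beyond the outer voxel centers: across that band
        trilinear interpolation against zero padding ramps down to zero.
        """
        lo = self.origin - self.spacing
        hi = self.origin + np.array(self.shape) * self.spacing
        return lo, hi


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suf in _NIFTI_SUFFIXES + _META_SUFFIXES:
        if name.endswith(suf):
            name = name[: -len(suf)]
            break
    return path.with_name(name + ".landmarks.json")


def write_volume(v: DensityVolume, path) -> None:
    """Write a volume as NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd)."""
    path = Path(path)
    name = path.name
    if name.endswith(_NIFTI_SUFFIXES):
        affine = np.diag([*v.spacing, 1.0])
        affine[:3, 3] = v.origin
        nib.save(nib.Nifti1Image(np.asarray(v.data), affine), str(path))
    elif name.endswith(_META_SUFFIXES):
        img = sitk.GetImageFromArray(np.ascontiguousarray(
            np.transpose(np.asarray(v.data), (2, 1, 0))))
        img.SetSpacing(tuple(float(s) for s in v.spacing))
        img.SetOrigin(tuple(float(o) for o in v.origin))
        sitk.WriteImage(img, str(path))
    else:
        raise FormatError(f"unsupported volume format: {path.name}")
    if v.landmarks:
        with open(_sidecar_path(path), "w") as fh:
            json.dump(
                {"landmarks": {k: list(map(float, p))
                               for k, p in v.landmarks.items()}},
                fh,
                indent=2,
            )


def read_volume(path) -> DensityVolume:
    """Read a NIfTI or MetaImage volume plus its landmark sidecar if present."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    name = path.name
    try:
        if name.endswith(_NIFTI_SUFFIXES):
            img = nib.load(str(path))
            affine = img.affine
            data = np.asarray(img.dataobj)
            spacing = np.linalg.norm(affine[:3, :3], axis=0)
            origin = affine[:3, 3]
        elif name.endswith(_META_SUFFIXES):
            img = sitk.ReadImage(str(path))
            data = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
            spacing = np.asarray(img.GetSpacing())
            origin = np.asarray(img.GetOrigin())
        else:
            raise FormatError(f"unsupported volume format: {path.name}")
    except FormatError:
        raise
    except Exception as exc:  # unreadable / corrupt file
        raise FormatError(f"could not read {path}: {exc}") from exc
    landmarks: dict[str, np.ndarray] = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        with open(sidecar) as fh:
            doc = json.load(fh)
        landmarks = {k: np.asarray(p, float)
                     for k, p in doc.get("landmarks", {}).items()}
    return DensityVolume(data=data, spacing=spacing, origin=origin,
                         landmarks=landmarks)


def threshold_bone(v: DensityVolume, level: float) -> DensityVolume:
    """Zero every voxel below ``level``; keep the rest and the landmarks."""
    data = np.where(v.data >= level, v.data, 0)
    return DensityVolume(data=data, spacing=v.spacing.copy(),
                         origin=v.origin.copy(),
                         landmarks={k: p.copy() for k, p in v.landmarks.items()})


def crop_to_mask(v: DensityVolume, margin: float = 0.0) -> DensityVolume:
    """Crop to the bounding box of nonzero voxels plus ``margin`` mm.

    The origin is shifted so retained voxels keep their model coordinates;
    landmark coordinates are therefore unchanged.
    """
    nz = np.nonzero(v.data)
    if nz[0].size == 0:
        raise ParameterError("cannot crop an all-zero volume")
    margin_vox = np.ceil(margin / v.spacing).astype(int)
    lo = np.maximum([int(a.min()) for a in nz] - margin_vox, 0)
    hi = np.minimum([int(a.max()) for a in nz] + margin_vox,
                    np.array(v.shape) - 1)
    sl = tuple(slice(a, b + 1) for a, b in zip(lo, hi))
    return DensityVolume(
        data=v.data[sl].copy(),
        spacing=v.spacing.copy(),
        origin=v.origin + lo * v.spacing,
        landmarks={k: p.copy() for k, p in v.landmarks.items()},
    )
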