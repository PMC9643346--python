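"""Labelled voxel volumes and their on-disk formats.

A :class:`LabelledVolume` is the pipeline's exchange container: an axis-aligned
3-D integer grid with isotropic spacing, a world origin, and a fixed label
scheme for temporal-bone anatomy.  Index convention: ``grid[i, j, k]`` is the
voxel whose *center* sits at ``origin + (i, j, k) * spacing`` (0-based, world
axes x/y/z).  Volumes round-trip through NRRD (via SimpleITK) and NIfTI-1
(via nibabel).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: Fixed label scheme shared by the generator and all measurement stages.
LABELS = {
    0: "background",
    1: "bone",           # otic-capsule bone, incl. the thin cover over the canal
    2: "perilymph",      # scala tympani fluid space deep to the round window
    3: "rc",             # Rosenthal's canal contents (spiral ganglion)
    4: "rw_membrane",    # round-window membrane
    5: "artery",         # vestibulocochlear artery
    6: "stapedius",      # stapedius muscle
    7: "modiolar_csf",   # central nerve-exit (CSF) space in the modiolus
}

LABEL_SCHEME_VERSION = "rcmorph-labels-1"


class VolumeError(ValueError):
    """Raised for malformed or inconsistent labelled volumes."""


@dataclass
class LabelledVolume:
    """Axis-aligned labelled voxel grid with isotropic spacing in mm."""

    grid: np.ndarray
    spacing: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.grid.ndim != 3:
            raise VolumeError(f"grid must be 3-D, got ndim={self.grid.ndim}")
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise VolumeError(f"grid must be integer-typed, got {self.grid.dtype}")
        if not (self.spacing > 0):
            raise VolumeError(f"spacing must be positive, got {self.spacing}")
        if self.origin.shape != (3,):
            raise VolumeError("origin must be a 3-vector")

    # -- coordinate transforms -------------------------------------------------
    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of voxel centers for (…, 3) index arrays."""
        return self.origin + np.asarray(idx, dtype=float) * self.spacing

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Nearest-voxel indices for (…, 3) world points (not bounds-checked)."""
        return np.rint((np.asarray(pts, dtype=float) - self.origin) / self.spacing).astype(int)

    def contains(self, pts: np.ndarray) -> np.ndarray:
        idx = self.world_to_index(pts)
        shape = np.asarray(self.grid.shape)
        return np.all((idx >= 0) & (idx < shape), axis=-1)

    def mask(self, label: int) -> np.ndarray:
        if label not in LABELS:
            raise VolumeError(f"label {label} not in scheme {sorted(LABELS)}")
        return self.grid == label

    def validate(self) -> None:
        """Check the label-scheme invariant; raise :class:`VolumeError` on failure."""
        bad = np.setdiff1d(np.unique(self.grid), np.array(sorted(LABELS)))
        if bad.size:
            raise VolumeError(f"grid contains labels outside the scheme: {bad.tolist()}")


# -- file IO -------------------------------------------------------------------

def write_volume(volume: LabelledVolume, path: str | Path) -> Path:
    """Write a labelled volume as ``.nrrd`` or ``.nii``/``.nii.gz`` by suffix."""
    path = Path(path)
    suffixes = "".join(path.suffixes)
    if path.suffix == ".nrrd":
        _write_sitk(volume, path)
    elif suffixes.endswith((".nii", ".nii.gz")):
        _write_nifti(volume, path)
    else:
        raise VolumeError(f"unsupported volume format: {path.name}")
    return path


def read_volume(path: str | Path) -> LabelledVolume:
    """Read a labelled volume written by :func:`write_volume`."""
    path = Path(path)
    if not path.exists():
        raise VolumeError(f"no such volume file: {path}")
    suffixes = "".join(path.suffixes)
    if path.suffix == ".nrrd":
        return _read_sitk(path)
    if suffixes.endswith((".nii", ".nii.gz")):
        return _read_nifti(path)
    raise VolumeError(f"unsupported volume format: {path.name}")


def _write_sitk(volume: LabelledVolume, path: Path) -> None:
    import SimpleITK as sitk

    # SimpleITK arrays are indexed (z, y, x)
    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.grid.T).astype(np.uint8))
    img.SetSpacing((volume.spacing,) * 3)
    img.SetOrigin(tuple(float(v) for v in volume.origin))
    sitk.WriteImage(img, str(path), useCompression=True)


def _read_sitk(path: Path) -> LabelledVolume:
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    spacing = img.GetSpacing()
    if not np.allclose(spacing, spacing[0], rtol=1e-6):
        raise VolumeError(f"anisotropic spacing {spacing} not supported")
    grid = sitk.GetArrayFromImage(img).T.astype(np.uint8)
    return LabelledVolume(grid=np.ascontiguousarray(grid), spacing=float(spacing[0]),
                          origin=np.array(img.GetOrigin(), dtype=float))


def _write_nifti(volume: LabelledVolume, path: Path) -> None:
    import nibabel as nib

    affine = np.diag([volume.spacing] * 3 + [1.0])
    affine[:3, 3] = volume.origin
    nib.save(nib.Nifti1Image(volume.grid.astype(np.uint8), affine), str(path))


def _read_nifti(path: Path) -> LabelledVolume:
    import nibabel as nib

    img = nib.load(str(path))
    affine = img.affine
    rot = affine[:3, :3]
    spacing = np.linalg.norm(rot, axis=0)
    if not np.allclose(spacing, spacing[0], rtol=1e-6):
        raise VolumeError(f"anisotropic spacing {spacing} not supported")
    if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-9):
        raise VolumeError("oblique NIfTI orientations are not supported for label maps")
    grid = np.asarray(img.dataobj).astype(np.uint8)
    return LabelledVolume(grid=grid, spacing=float(spacing[0]),
                          origin=np.array(affine[:3, 3], dtype=float))
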