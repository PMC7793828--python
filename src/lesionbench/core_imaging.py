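"""Volumetric image and mask containers plus NIfTI-1 I/O.

Every downstream stage (lesion characterization, transplantation,
segmentation) works on the two types defined here.  Conventions are fixed
once so that laterality decisions are testable:

* world frame is RAS+ in millimetres, with the mid-sagittal plane at
  world ``x = 0``;
* voxel indices are 0-based;
* images are strictly 3-D — 4-D or complex inputs are rejected, never
  squeezed;
* a mask is only ever used with an image on the *same* grid (shape equal,
  affines within 1e-4 per entry); grids are never silently resampled.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "ImageVolume",
    "BinaryMask",
    "GridMismatchError",
    "read_nifti",
    "read_mask",
    "write_nifti",
    "write_mask",
    "voxel_volume",
]

#: per-entry tolerance when comparing two affines for grid compatibility
AFFINE_ATOL = 1e-4


class GridMismatchError(ValueError):
    """Raised when an image and a mask do not share shape and affine."""


def _validate_grid(data: np.ndarray, affine: np.ndarray, what: str) -> None:
    if data.ndim != 3:
        raise ValueError(
            f"{what} must be 3-D; got {data.ndim} dimensions (shape {data.shape})"
        )
    if any(s < 1 for s in data.shape):
        raise ValueError(f"{what} has a degenerate axis: shape {data.shape}")
    if np.iscomplexobj(data):
        raise ValueError(f"{what} must be real-valued; got complex data")
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"{what} affine must be 4x4; got {affine.shape}")
    dims = np.linalg.norm(affine[:3, :3], axis=0)
    if np.any(dims <= 0):
        raise ValueError(f"{what} affine has a zero-length column: dims {dims}")


@dataclass
class ImageVolume:
    """A 3-D scalar intensity grid with a voxel-index -> world (RAS+, mm) affine."""

    data: np.ndarray
    affine: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        _validate_grid(self.data, self.affine, "ImageVolume")

    @property
    def voxel_dims(self) -> tuple[float, float, float]:
        """(dx, dy, dz) in mm — Euclidean norms of the affine's spatial columns."""
        d = np.linalg.norm(self.affine[:3, :3], axis=0)
        return (float(d[0]), float(d[1]), float(d[2]))

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


@dataclass
class BinaryMask:
    """A {0, 1} grid on the same convention as :class:`ImageVolume`."""

    data: np.ndarray
    affine: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        _validate_grid(arr, np.asarray(self.affine, dtype=float), "BinaryMask")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(
                f"BinaryMask values must be exactly 0 or 1; found {uniq[:10]}"
            )
        self.data = arr.astype(np.uint8)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.data))

    def bool(self) -> np.ndarray:
        return self.data.astype(bool)


def check_same_grid(a: ImageVolume | BinaryMask, b: ImageVolume | BinaryMask) -> None:
    """Assert two objects live on the same grid; raise GridMismatchError otherwise."""
    if a.data.shape != b.data.shape:
        raise GridMismatchError(
            f"grid shapes differ: {a.data.shape} vs {b.data.shape} "
            f"({a.id!r} vs {b.id!r})"
        )
    if not np.allclose(a.affine, b.affine, atol=AFFINE_ATOL, rtol=0):
        raise GridMismatchError(
            f"affines differ by more than {AFFINE_ATOL} ({a.id!r} vs {b.id!r})"
        )


def read_nifti(path: str | os.PathLike, id: str | None = None) -> ImageVolume:
    """Read a 3-D NIfTI-1 image (.nii or .nii.gz).

    The grid and affine are returned exactly as stored; the only intensity
    transformation applied is the format's own scl_slope/scl_inter scaling
    (handled by nibabel's ``get_fdata``).  4-D inputs are rejected.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = nib.load(path)
    if img.ndim != 3:
        raise ValueError(
            f"expected a 3-D image, got {img.ndim} dimensions "
            f"(shape {img.shape}) in {path}"
        )
    data = np.asarray(img.get_fdata(dtype=np.float64))
    return ImageVolume(data=data, affine=np.asarray(img.affine, dtype=float),
                       id=id if id is not None else os.path.basename(path))


def read_mask(path: str | os.PathLike, id: str | None = None) -> BinaryMask:
    """Read a NIfTI file as a binary mask; values must be exactly 0/1."""
    vol = read_nifti(path, id=id)
    return BinaryMask(data=vol.data, affine=vol.affine, id=vol.id)


def write_nifti(vol: ImageVolume | BinaryMask, path: str | os.PathLike) -> None:
    """Write to NIfTI-1.  Image data round-trips bit-exactly (float64 for
    images, uint8 for masks); the affine round-trips within 1e-6."""
    path = os.fspath(path)
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent):
        raise FileNotFoundError(f"parent directory does not exist: {parent}")
    if isinstance(vol, BinaryMask):
        data = vol.data.astype(np.uint8)
    else:
        data = np.asarray(vol.data, dtype=np.float64)
    img = nib.Nifti1Image(data, vol.affine)
    # pin qform/sform so the affine is stored losslessly and reproducibly
    img.set_qform(vol.affine, code=1)
    img.set_sform(vol.affine, code=1)
    try:
        nib.save(img, path)
    except PermissionError:
        raise
    except OSError as exc:  # unwritable target
        raise OSError(f"cannot write NIfTI to {path}: {exc}") from exc


write_mask = write_nifti


def voxel_volume(vol: ImageVolume | BinaryMask) -> float:
    """Volume of one voxel in mm³: |det| of the affine's 3x3 part.

    Equals dx·dy·dz for axis-aligned grids and is invariant under rotation.
    """
    return float(abs(np.linalg.det(np.asarray(vol.affine)[:3, :3])))
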