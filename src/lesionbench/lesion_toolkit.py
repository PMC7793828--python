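"""Lesion characterization: volume, laterality and intensity statistics.

T1-weighted MR intensities carry no absolute units, so intensity statistics
of a lesion are only comparable across subjects after mapping the image into
a *unit-invariant space*: demean and scale by the mean and sample SD of the
non-lesioned voxels of a reference set.  The reference set defaults to the
whole image; callers may pass a brain mask instead.  Sample SD (n-1
denominator) is used everywhere in this package.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core_imaging import BinaryMask, ImageVolume, check_same_grid, voxel_volume

__all__ = [
    "LesionCharacteristics",
    "lesion_volume",
    "unit_invariant_normalize",
    "lesion_intensity_stats",
    "determine_laterality",
    "characteristics_table",
]

#: default fraction of lesion voxels allowed in the minority hemisphere
#: before a lesion is called bilateral
BILATERAL_FRACTION = 0.02


@dataclass
class LesionCharacteristics:
    """Size, side and unit-invariant intensity statistics of one lesion."""

    lesion_id: str
    volume_native_mm3: float
    laterality: str  # 'lh' | 'rh' | 'bilateral'
    mean_intensity_ui: float
    sd_intensity_ui: float
    volume_transplanted_mm3: float | None = None
    reference: str = "whole-image"  # which reference set defined the ui space

    def with_transplanted(self, volume_mm3: float) -> "LesionCharacteristics":
        return replace(self, volume_transplanted_mm3=float(volume_mm3))


def lesion_volume(mask: BinaryMask) -> float:
    """Lesion volume in mm³: non-zero voxel count × voxel volume."""
    return mask.n_voxels * voxel_volume(mask)


def _reference_bool(vol: ImageVolume,
                    lesion_mask: BinaryMask | None,
                    reference_mask: BinaryMask | None) -> np.ndarray:
    if reference_mask is not None:
        check_same_grid(vol, reference_mask)
        ref = reference_mask.bool()
    else:
        ref = np.ones(vol.data.shape, dtype=bool)
    if lesion_mask is not None:
        check_same_grid(vol, lesion_mask)
        ref = ref & ~lesion_mask.bool()
    return ref


def reference_stats(vol: ImageVolume,
                    lesion_mask: BinaryMask | None = None,
                    reference_mask: BinaryMask | None = None) -> tuple[float, float]:
    """Mean and sample SD of reference-set intensities excluding lesion voxels."""
    ref = _reference_bool(vol, lesion_mask, reference_mask)
    vals = vol.data[ref]
    if vals.size == 0:
        raise ValueError("reference set is empty after excluding lesion voxels")
    if vals.size < 2:
        raise ValueError("reference set needs at least 2 voxels to define an SD")
    mu = float(vals.mean())
    sd = float(vals.std(ddof=1))
    if sd <= 0.0:
        raise ValueError("reference set has zero intensity variance; "
                         "unit-invariant space is undefined")
    return mu, sd


def unit_invariant_normalize(vol: ImageVolume,
                             lesion_mask: BinaryMask | None = None,
                             reference_mask: BinaryMask | None = None) -> ImageVolume:
    """Map the whole volume to unit-invariant space.

    Output = (input − μ)/σ where μ, σ are the mean and sample SD over the
    reference voxels that are *not* lesion voxels.  Those voxels have mean 0
    and SD 1 in the output.  Invariant to any positive affine transform of
    the raw intensities.
    """
    mu, sd = reference_stats(vol, lesion_mask, reference_mask)
    return ImageVolume(data=(vol.data - mu) / sd, affine=vol.affine.copy(),
                       id=f"{vol.id}|ui")


def lesion_intensity_stats(norm_vol: ImageVolume, mask: BinaryMask) -> tuple[float, float]:
    """Mean and sample SD of (already normalized) intensities over mask voxels.

    A single-voxel lesion has SD 0 by convention.
    """
    check_same_grid(norm_vol, mask)
    vals = norm_vol.data[mask.bool()]
    if vals.size == 0:
        raise ValueError("lesion mask is empty")
    mean = float(vals.mean())
    sd = 0.0 if vals.size == 1 else float(vals.std(ddof=1))
    return mean, sd


def world_x_coordinates(mask: BinaryMask) -> np.ndarray:
    """World x (mm, RAS+) of every non-zero voxel of the mask."""
    idx = np.argwhere(mask.data != 0)
    # world = affine @ [i j k 1]'
    return idx @ mask.affine[0, :3] + mask.affine[0, 3]


def determine_laterality(mask: BinaryMask,
                         bilateral_fraction: float = BILATERAL_FRACTION) -> str:
    """Classify a lesion as 'lh', 'rh' or 'bilateral' by world-x sign.

    Voxels with x < 0 are left, x > 0 right; voxels exactly on the midline
    are ignored.  If the minority hemisphere holds more than
    ``bilateral_fraction`` of the counted voxels the lesion is bilateral.
    """
    if mask.n_voxels == 0:
        raise ValueError("cannot determine laterality of an empty mask")
    x = world_x_coordinates(mask)
    n_left = int(np.count_nonzero(x < 0))
    n_right = int(np.count_nonzero(x > 0))
    total = n_left + n_right
    if total == 0:
        raise ValueError("all lesion voxels lie exactly on the midline")
    if min(n_left, n_right) / total > bilateral_fraction:
        return "bilateral"
    return "lh" if n_left >= n_right else "rh"


def characterize_lesion(vol: ImageVolume, mask: BinaryMask,
                        reference_mask: BinaryMask | None = None,
                        lesion_id: str | None = None,
                        bilateral_fraction: float = BILATERAL_FRACTION,
                        ) -> LesionCharacteristics:
    """Full characterization of one lesion on its native grid."""
    check_same_grid(vol, mask)
    norm = unit_invariant_normalize(vol, mask, reference_mask)
    mean_ui, sd_ui = lesion_intensity_stats(norm, mask)
    return LesionCharacteristics(
        lesion_id=lesion_id if lesion_id is not None else mask.id,
        volume_native_mm3=lesion_volume(mask),
        laterality=determine_laterality(mask, bilateral_fraction),
        mean_intensity_ui=mean_ui,
        sd_intensity_ui=sd_ui,
        reference="whole-image" if reference_mask is None else (reference_mask.id or "custom"),
    )


def characteristics_table(chars: list[LesionCharacteristics]):
    """Export characteristics as a DataFrame, one row per lesion."""
    import pandas as pd

    return pd.DataFrame(
        {
            "lesion_id": [c.lesion_id for c in chars],
            "volume_native_mm3": [c.volume_native_mm3 for c in chars],
            "volume_transplanted_mm3": [c.volume_transplanted_mm3 for c in chars],
            "laterality": [c.laterality for c in chars],
            "mean_intensity_ui": [c.mean_intensity_ui for c in chars],
            "sd_intensity_ui": [c.sd_intensity_ui for c in chars],
        }
    )
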