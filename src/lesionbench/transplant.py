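"""Lesion transplantation: build chimeric images and the crossed dataset.

A lesion is carried between subjects in unit-invariant intensity space.
Extraction z-scores the patient image against its non-lesion reference
voxels and keeps the z-values inside the mask; transplantation inverts the
map in the control's own intensity frame (``μ_c + σ_c·z``, with μ_c, σ_c
taken over the control's reference voxels outside the transplanted mask).
Everything outside the transplanted mask is the control image, bit-exactly —
the conservation property all downstream error attribution relies on: the
contralesional hemisphere of a chimeric image is anatomically identical to
its ground truth.

The spatial transform is pluggable: ``"identity"`` for matched grids, or a
4×4 world-to-world affine applied with trilinear interpolation followed by
0.5-threshold binarization of the mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .core_imaging import BinaryMask, ImageVolume, check_same_grid
from .lesion_toolkit import (
    LesionCharacteristics,
    characterize_lesion,
    determine_laterality,
    lesion_volume,
    reference_stats,
    unit_invariant_normalize,
)

__all__ = [
    "LesionPatch",
    "SimulatedCase",
    "BilateralLesionError",
    "extract_patch",
    "resample_mask",
    "transplant",
    "build_crossed_dataset",
]

MASK_THRESHOLD = 0.5


class BilateralLesionError(ValueError):
    """A lesion lands in both hemispheres on the control grid (rejected)."""


@dataclass
class LesionPatch:
    """A lesion ready for transplantation: z-valued intensities inside a mask."""

    source_id: str
    norm_intensities: np.ndarray  # 1-D, one value per non-zero mask voxel (C order)
    mask: BinaryMask
    characteristics: LesionCharacteristics

    def __post_init__(self) -> None:
        self.norm_intensities = np.asarray(self.norm_intensities, dtype=float).ravel()
        if self.norm_intensities.size != self.mask.n_voxels:
            raise ValueError(
                f"patch stores {self.norm_intensities.size} intensities for "
                f"{self.mask.n_voxels} mask voxels"
            )

    def z_field(self) -> np.ndarray:
        """Dense z-value grid: patch values inside the mask, 0 elsewhere."""
        z = np.zeros(self.mask.data.shape, dtype=float)
        z[self.mask.bool()] = self.norm_intensities
        return z


@dataclass
class SimulatedCase:
    """One chimeric image: (control × lesion) with its transformed mask."""

    case_id: str
    control_id: str
    lesion_id: str
    chimeric: ImageVolume
    transformed_mask: BinaryMask
    laterality: str  # 'lh' | 'rh' — bilateral transplants are rejected
    volume_transplanted_mm3: float


def extract_patch(patient: ImageVolume, mask: BinaryMask,
                  reference_mask: BinaryMask | None = None,
                  lesion_id: str | None = None) -> LesionPatch:
    """Characterize a lesion and lift it into unit-invariant space."""
    if mask.n_voxels == 0:
        raise ValueError("cannot extract a patch from an empty lesion mask")
    check_same_grid(patient, mask)
    lid = lesion_id if lesion_id is not None else (mask.id or patient.id)
    norm = unit_invariant_normalize(patient, mask, reference_mask)
    chars = characterize_lesion(patient, mask, reference_mask, lesion_id=lid)
    return LesionPatch(
        source_id=lid,
        norm_intensities=norm.data[mask.bool()],
        mask=mask,
        characteristics=chars,
    )


def _as_world_transform(transform) -> np.ndarray:
    if isinstance(transform, str):
        if transform != "identity":
            raise ValueError(f"unknown transform {transform!r}")
        return np.eye(4)
    T = np.asarray(transform, dtype=float)
    if T.shape != (4, 4):
        raise ValueError(f"transform must be a 4x4 matrix; got shape {T.shape}")
    if abs(np.linalg.det(T)) < 1e-12:
        raise ValueError("transform is singular")
    return T


def _is_identity_on_same_grid(transform, source, target) -> bool:
    if isinstance(transform, str) and transform == "identity":
        return (source.data.shape == target.data.shape
                and np.allclose(source.affine, target.affine, atol=1e-4, rtol=0))
    return False


def _resample_field(field: np.ndarray, source_affine: np.ndarray,
                    transform, target: ImageVolume) -> np.ndarray:
    """Trilinear resampling of a scalar field onto the target grid.

    ``transform`` maps source-world to target-world coordinates; the pull-back
    for a target voxel index j is  A_s^{-1} T^{-1} A_t j.
    """
    T = _as_world_transform(transform)
    M = np.linalg.inv(source_affine) @ np.linalg.inv(T) @ target.affine
    return ndimage.affine_transform(
        np.asarray(field, dtype=float), M[:3, :3], offset=M[:3, 3],
        output_shape=target.data.shape, order=1, mode="constant", cval=0.0,
    )


def resample_mask(mask: BinaryMask, transform, target: ImageVolume,
                  threshold: float = MASK_THRESHOLD) -> BinaryMask:
    """Carry a binary mask onto the target grid.

    The {0,1} field is trilinearly interpolated and binarized at
    ``threshold`` (strictly greater).  Integer-voxel translations preserve
    the voxel count exactly.  ``"identity"`` on a matching grid returns the
    input unchanged.  An empty result means the lesion fell outside the
    target field of view and is an error.
    """
    if _is_identity_on_same_grid(transform, mask, target):
        return BinaryMask(data=mask.data.copy(), affine=target.affine.copy(),
                          id=mask.id)
    field = _resample_field(mask.data, mask.affine, transform, target)
    out = (field > threshold).astype(np.uint8)
    if not out.any():
        raise ValueError(
            f"mask {mask.id!r} is empty after resampling onto {target.id!r}: "
            "the lesion fell outside the target field of view"
        )
    return BinaryMask(data=out, affine=target.affine.copy(), id=mask.id)


def transplant(patch: LesionPatch, control: ImageVolume,
               control_reference_mask: BinaryMask | None = None,
               transform="identity", case_id: str | None = None,
               bilateral_fraction: float = 0.02) -> SimulatedCase:
    """Insert a lesion patch into a control image, producing a chimeric case.

    Inside the transformed mask the chimeric intensity is μ_c + σ_c·z with z
    the resampled patch z-value; outside it the control image is copied
    bit-exactly.  Lesions that land bilaterally on the control grid are
    rejected.
    """
    cid = case_id if case_id is not None else f"{patch.source_id}_x_{control.id}"
    if patch.mask.n_voxels == 0:
        # degenerate but well-defined: nothing to transplant, the chimeric
        # image is the control itself (conservation holds trivially)
        empty = BinaryMask(data=np.zeros(control.data.shape, dtype=np.uint8),
                           affine=control.affine.copy(), id=patch.mask.id)
        return SimulatedCase(
            case_id=cid, control_id=control.id, lesion_id=patch.source_id,
            chimeric=ImageVolume(data=control.data.copy(),
                                 affine=control.affine.copy(), id=cid),
            transformed_mask=empty, laterality="none",
            volume_transplanted_mm3=0.0)
    same_grid = _is_identity_on_same_grid(transform, patch.mask, control)
    tmask = resample_mask(patch.mask, transform, control)
    laterality = determine_laterality(tmask, bilateral_fraction)
    if laterality == "bilateral":
        raise BilateralLesionError(
            f"lesion {patch.source_id!r} is bilateral on control "
            f"{control.id!r} and cannot enter the lesioned/contralesional design"
        )
    if same_grid:
        z_t = patch.z_field()
    else:
        z_t = _resample_field(patch.z_field(), patch.mask.affine, transform, control)

    mu_c, sd_c = reference_stats(control, tmask, control_reference_mask)
    chimeric_data = control.data.copy()
    inside = tmask.bool()
    chimeric_data[inside] = mu_c + sd_c * z_t[inside]

    chimeric = ImageVolume(data=chimeric_data, affine=control.affine.copy(), id=cid)
    return SimulatedCase(
        case_id=cid,
        control_id=control.id,
        lesion_id=patch.source_id,
        chimeric=chimeric,
        transformed_mask=tmask,
        laterality=laterality,
        volume_transplanted_mm3=lesion_volume(tmask),
    )


def build_crossed_dataset(patches: list[LesionPatch],
                          controls: list[ImageVolume],
                          transforms="identity",
                          seed: int = 0,
                          strict: bool = False,
                          control_reference_masks: dict | None = None,
                          ) -> tuple[list[SimulatedCase], pd.DataFrame]:
    """Apply every lesion to every control (fully crossed design).

    Ordering is deterministic: lesion-major, control-minor.  ``transforms``
    is either a single transform applied to every pair or a dict keyed by
    (lesion_id, control_id).  Individual transplant failures are recorded in
    the manifest's ``status`` column and skipped unless ``strict``.

    Returns (cases, manifest).  The manifest has one row per attempted pair.
    """
    lesion_ids = [p.source_id for p in patches]
    control_ids = [c.id for c in controls]
    if len(set(lesion_ids)) != len(lesion_ids):
        raise ValueError(f"duplicate lesion ids: {lesion_ids}")
    if len(set(control_ids)) != len(control_ids):
        raise ValueError(f"duplicate control ids: {control_ids}")

    cases: list[SimulatedCase] = []
    rows = []
    for patch in patches:
        for control in controls:
            if isinstance(transforms, dict):
                tr = transforms.get((patch.source_id, control.id), "identity")
            else:
                tr = transforms
            ref = None
            if control_reference_masks is not None:
                ref = control_reference_masks.get(control.id)
            case_id = f"{patch.source_id}_x_{control.id}"
            row = {
                "case_id": case_id,
                "lesion_id": patch.source_id,
                "control_id": control.id,
                "laterality": None,
                "volume_transplanted_mm3": np.nan,
                "status": "ok",
                "seed": int(seed),
            }
            try:
                case = transplant(patch, control, ref, tr, case_id=case_id)
            except (ValueError, BilateralLesionError) as exc:
                if strict:
                    raise
                row["status"] = f"error: {exc}"
            else:
                cases.append(case)
                row["laterality"] = case.laterality
                row["volume_transplanted_mm3"] = case.volume_transplanted_mm3
            rows.append(row)

    manifest = pd.DataFrame(
        rows, columns=["case_id", "lesion_id", "control_id", "laterality",
                       "volume_transplanted_mm3", "status", "seed"])
    return cases, manifest
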