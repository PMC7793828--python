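import numpy as np
import pytest

from lesionbench import (BinaryMask, ImageVolume, LesionPatch,
                         build_crossed_dataset, extract_patch, resample_mask,
                         transplant)
from lesionbench.transplant import BilateralLesionError

from conftest import make_mask, make_volume


def _patient_with_lesion():
    """Reference voxels {10,20,30} (mean 20, sample SD 10), lesion {40,50}."""
    vol = make_volume([10, 20, 30, 40, 50], id="patient")
    mask = make_mask([0, 0, 0, 1, 1], id="lesionA")
    return vol, mask


def test_extract_patch_z_values():
    vol, mask = _patient_with_lesion()
    patch = extract_patch(vol, mask, lesion_id="lesionA")
    assert patch.norm_intensities == pytest.approx([2.0, 3.0], abs=1e-12)
    assert patch.characteristics.volume_native_mm3 == pytest.approx(2.0)


def test_extract_patch_voxel_count_matches_mask(rng):
    data = rng.normal(80, 9, size=(6, 6, 6))
    maskdata = (rng.random((6, 6, 6)) < 0.2).astype(np.uint8)
    maskdata[0, 0, 0] = 1
    vol = ImageVolume(data=data, affine=np.eye(4), id="p")
    mask = BinaryMask(data=maskdata, affine=np.eye(4), id="m")
    patch = extract_patch(vol, mask)
    assert patch.norm_intensities.size == mask.n_voxels


def test_extract_patch_empty_mask_rejected():
    vol = make_volume([1, 2, 3])
    with pytest.raises(ValueError, match="empty"):
        extract_patch(vol, make_mask([0, 0, 0]))


# --- mask resampling --------------------------------------------------------

def test_resample_identity_same_grid_is_noop(rng):
    data = (rng.random((5, 5, 5)) < 0.3).astype(np.uint8)
    mask = BinaryMask(data=data, affine=np.eye(4))
    target = ImageVolume(data=np.zeros((5, 5, 5)), affine=np.eye(4))
    out = resample_mask(mask, "identity", target)
    assert np.array_equal(out.data, data)


def test_resample_integer_translation_preserves_volume():
    data = np.zeros((10, 10, 10), dtype=np.uint8)
    data[2:5, 3:6, 4:7] = 1  # 27-voxel cuboid
    mask = BinaryMask(data=data, affine=np.eye(4))
    target = ImageVolume(data=np.zeros((10, 10, 10)), affine=np.eye(4))
    T = np.eye(4)
    T[0, 3] = 2.0  # shift +2 mm along world x
    out = resample_mask(mask, T, target)
    assert out.n_voxels == 27
    assert np.array_equal(out.data[4:7, 3:6, 4:7], np.ones((3, 3, 3), np.uint8))


def test_resample_out_of_fov_is_error():
    data = np.zeros((6, 6, 6), dtype=np.uint8)
    data[2:4, 2:4, 2:4] = 1
    mask = BinaryMask(data=data, affine=np.eye(4))
    target = ImageVolume(data=np.zeros((6, 6, 6)), affine=np.eye(4))
    T = np.eye(4)
    T[0, 3] = 100.0
    with pytest.raises(ValueError, match="outside"):
        resample_mask(mask, T, target)


def test_singular_transform_rejected():
    mask = BinaryMask(data=np.ones((2, 2, 2), np.uint8), affine=np.eye(4))
    target = ImageVolume(data=np.zeros((2, 2, 2)), affine=np.eye(4))
    with pytest.raises(ValueError, match="singular"):
        resample_mask(mask, np.zeros((4, 4)), target)


# --- transplantation --------------------------------------------------------

def _left_affine(n):
    """First-axis world x runs from -(n-1)/2 ... +(n-1)/2? No: start negative."""
    A = np.eye(4)
    A[0, 3] = -float(n)  # all voxels at x < 0
    return A


def test_transplant_inverse_z_map():
    # control reference {100, 200, 300}: mean 200, sample SD 100
    A = _left_affine(5)
    control = make_volume([100, 200, 300, 0, 0], affine=A, id="ctrl")
    patient = make_volume([10, 20, 30, 40, 50], affine=A, id="pat")
    mask = make_mask([0, 0, 0, 1, 1], affine=A, id="les")
    patch = extract_patch(patient, mask)  # z = {2, 3}
    case = transplant(patch, control)
    assert case.chimeric.data[3:, 0, 0] == pytest.approx([400.0, 500.0])
    assert case.laterality == "lh"


def test_transplant_conservation_outside_mask(rng):
    shape = (8, 8, 8)
    A = np.eye(4)
    A[0, 3] = -8.0
    control = ImageVolume(data=rng.normal(100, 20, shape), affine=A, id="c")
    patient = ImageVolume(data=rng.normal(90, 25, shape), affine=A, id="p")
    maskdata = np.zeros(shape, np.uint8)
    maskdata[1:3, 2:5, 2:5] = 1
    mask = BinaryMask(data=maskdata, affine=A, id="m")
    case = transplant(extract_patch(patient, mask), control)
    outside = ~case.transformed_mask.bool()
    assert np.array_equal(case.chimeric.data[outside], control.data[outside])


def test_self_transplant_is_idempotent(rng):
    shape = (8, 8, 8)
    A = np.eye(4)
    A[0, 3] = -8.0
    control = ImageVolume(data=rng.normal(100, 20, shape), affine=A, id="c")
    maskdata = np.zeros(shape, np.uint8)
    maskdata[2:4, 1:4, 1:4] = 1
    mask = BinaryMask(data=maskdata, affine=A, id="m")
    patch = extract_patch(control, mask)
    case = transplant(patch, control)
    assert np.allclose(case.chimeric.data, control.data, atol=1e-6)


def test_empty_patch_transplant_conserves_control(rng):
    control = ImageVolume(data=rng.normal(0, 1, (4, 4, 4)), affine=np.eye(4),
                          id="c")
    patch = LesionPatch(
        source_id="empty", norm_intensities=np.zeros(0),
        mask=BinaryMask(data=np.zeros((4, 4, 4), np.uint8), affine=np.eye(4)),
        characteristics=None)
    case = transplant(patch, control)
    assert np.array_equal(case.chimeric.data, control.data)
    assert case.volume_transplanted_mm3 == 0.0


def test_bilateral_on_control_grid_rejected(rng):
    shape = (8, 4, 4)
    A = np.eye(4)
    A[0, 3] = -3.5  # world x spans -3.5 ... +3.5, midline between voxels 3|4
    control = ImageVolume(data=rng.normal(10, 3, shape), affine=A, id="c")
    patient = ImageVolume(data=rng.normal(10, 3, shape), affine=A, id="p")
    maskdata = np.zeros(shape, np.uint8)
    maskdata[2:6, 1:3, 1:3] = 1  # straddles the midline evenly
    mask = BinaryMask(data=maskdata, affine=A, id="m")
    with pytest.raises(BilateralLesionError):
        transplant(extract_patch(patient, mask), control)


# --- crossed dataset --------------------------------------------------------

def _cohort(rng, n_patients, n_controls):
    shape = (8, 6, 6)
    A = np.eye(4)
    A[0, 3] = -8.0
    patches = []
    for i in range(n_patients):
        vol = ImageVolume(data=rng.normal(100, 15, shape), affine=A, id=f"p{i}")
        maskdata = np.zeros(shape, np.uint8)
        maskdata[1 + i % 3, 2:4, 2:4] = 1
        patches.append(extract_patch(
            vol, BinaryMask(data=maskdata, affine=A, id=f"L{i}")))
    controls = [ImageVolume(data=rng.normal(100, 15, shape), affine=A,
                            id=f"C{j}") for j in range(n_controls)]
    return patches, controls


def test_crossed_dataset_cardinality(rng):
    patches, controls = _cohort(rng, 2, 3)
    cases, manifest = build_crossed_dataset(patches, controls)
    assert len(cases) == 6
    assert len(manifest) == 6
    assert (manifest.status == "ok").all()
    # lesion-major, control-minor deterministic ordering
    assert manifest.case_id.tolist()[:3] == ["L0_x_C0", "L0_x_C1", "L0_x_C2"]


def test_crossed_dataset_empty_patches(rng):
    _, controls = _cohort(rng, 1, 2)
    cases, manifest = build_crossed_dataset([], controls)
    assert cases == [] and len(manifest) == 0


def test_crossed_dataset_duplicate_ids_rejected(rng):
    patches, controls = _cohort(rng, 2, 2)
    patches[1] = LesionPatch(source_id=patches[0].source_id,
                             norm_intensities=patches[1].norm_intensities,
                             mask=patches[1].mask,
                             characteristics=patches[1].characteristics)
    with pytest.raises(ValueError, match="duplicate"):
        build_crossed_dataset(patches, controls)
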