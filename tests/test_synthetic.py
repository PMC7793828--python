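import numpy as np
import pytest

from lesionbench import (PhantomSpec, determine_laterality, extract_patch,
                         generate_phantom, generate_synthetic_lesion,
                         lesion_volume, mock_segment, simulate_lmm_dataset,
                         transplant, unit_invariant_normalize)
from lesionbench.lesion_toolkit import lesion_intensity_stats
from lesionbench.synthetic import SyntheticLesionSpec, control_cohort
from lesionbench.transplant import LesionPatch
from lesionbench.core_imaging import BinaryMask


SMALL = dict(grid_shape=(32, 32, 32), center_offset_mm=7.0,
             csf_semi_axes=(6.0, 12.0, 12.0), gm_semi_axes=(5.0, 10.0, 10.0),
             wm_semi_axes=(3.5, 7.0, 7.0))


def test_noise_free_phantom_has_four_intensities():
    ph = generate_phantom(class_noise_sd=(0, 0, 0), **SMALL)
    assert len(np.unique(ph.image.data)) == 4


def test_phantom_mirror_symmetric_ground_truth():
    ph = generate_phantom(**SMALL)
    gt = ph.ground_truth.pivot(index="tissue", columns="hemisphere",
                               values="volume_mm3")
    assert (gt.lh == gt.rh).all()


def test_phantom_deterministic():
    a = generate_phantom(seed=12, **SMALL)
    b = generate_phantom(seed=12, **SMALL)
    assert np.array_equal(a.image.data, b.image.data)
    c = generate_phantom(seed=13, **SMALL)
    assert not np.array_equal(a.image.data, c.image.data)


def test_phantom_ground_truth_equals_label_counts():
    ph = generate_phantom(**SMALL)
    x = np.arange(32) - 15.5  # world x along the first axis
    for hemi, sel in (("lh", x < 0), ("rh", x > 0)):
        for tissue, code in (("csf", 1), ("cortex", 2), ("cwm", 3)):
            n = int(((ph.labels == code) & sel[:, None, None]).sum())
            assert ph.ground_truth_volume(hemi, tissue) == float(n)


def test_phantom_geometry_validation():
    with pytest.raises(ValueError, match="nested"):
        generate_phantom(grid_shape=(32, 32, 32), center_offset_mm=7.0,
                         csf_semi_axes=(4.0, 8.0, 8.0),
                         gm_semi_axes=(5.0, 10.0, 10.0),
                         wm_semi_axes=(3.0, 6.0, 6.0))
    with pytest.raises(ValueError, match="fit"):
        generate_phantom(grid_shape=(16, 16, 16), center_offset_mm=7.0,
                         csf_semi_axes=(6.0, 12.0, 12.0),
                         gm_semi_axes=(5.0, 10.0, 10.0),
                         wm_semi_axes=(3.0, 6.0, 6.0))


# --- synthetic lesions -------------------------------------------------------

def test_lesion_exact_voxel_count_on_anisotropic_grid():
    """25 mm³ at 0.25 mm³/voxel -> exactly 100 voxels."""
    ph = generate_phantom(grid_shape=(32, 64, 64), voxel_dims=(1.0, 0.5, 0.5),
                          center_offset_mm=7.0,
                          csf_semi_axes=(6.0, 12.0, 12.0),
                          gm_semi_axes=(5.0, 10.0, 10.0),
                          wm_semi_axes=(3.5, 7.0, 7.0))
    spec = SyntheticLesionSpec(target_volume_mm3=25.00, hemisphere="lh", seed=1)
    mask, _ = generate_synthetic_lesion(ph, spec)
    assert mask.n_voxels == 100
    assert lesion_volume(mask) == pytest.approx(25.00)


def test_lesion_volume_error_at_most_one_voxel():
    ph = generate_phantom(**SMALL)
    spec = SyntheticLesionSpec(target_volume_mm3=70.4, hemisphere="rh", seed=2)
    mask, _ = generate_synthetic_lesion(ph, spec)
    assert abs(lesion_volume(mask) - 70.4) <= 1.0  # one 1-mm³ voxel


def test_lesion_zero_sd_gives_constant_intensity():
    ph = generate_phantom(**SMALL)
    spec = SyntheticLesionSpec(target_volume_mm3=50, hemisphere="lh",
                               mean_intensity_ui=-1.0, sd_intensity_ui=0.0,
                               seed=3)
    mask, patient = generate_synthetic_lesion(ph, spec)
    vals = patient.data[mask.bool()]
    assert np.allclose(vals, vals[0])


def test_lesion_realized_ui_stats_match_spec():
    ph = generate_phantom(**SMALL)
    spec = SyntheticLesionSpec(target_volume_mm3=200, hemisphere="rh",
                               mean_intensity_ui=-1.8, sd_intensity_ui=0.4,
                               seed=4)
    mask, patient = generate_synthetic_lesion(ph, spec)
    norm = unit_invariant_normalize(patient, mask)
    mean_ui, sd_ui = lesion_intensity_stats(norm, mask)
    assert mean_ui == pytest.approx(-1.8, abs=0.05)
    assert sd_ui == pytest.approx(0.4, abs=0.05)


def test_lesion_laterality_matches_spec_hemisphere():
    ph = generate_phantom(**SMALL)
    for hemi in ("lh", "rh"):
        spec = SyntheticLesionSpec(target_volume_mm3=120, hemisphere=hemi,
                                   seed=5)
        mask, _ = generate_synthetic_lesion(ph, spec)
        assert determine_laterality(mask) == hemi


def test_multifocal_lesion_total_count():
    ph = generate_phantom(**SMALL)
    spec = SyntheticLesionSpec(target_volume_mm3=90, hemisphere="lh",
                               shape="multifocal-blobs", n_foci=3, seed=6)
    mask, _ = generate_synthetic_lesion(ph, spec)
    assert mask.n_voxels == 90


def test_infeasible_lesion_volume_rejected():
    ph = generate_phantom(**SMALL)
    spec = SyntheticLesionSpec(target_volume_mm3=1e9, hemisphere="lh", seed=7)
    with pytest.raises(ValueError, match="tissue"):
        generate_synthetic_lesion(ph, spec)


def test_control_cohort_varies_ground_truth():
    cohort = control_cohort(3, seed=11, base_spec=PhantomSpec(**SMALL))
    vols = [ph.ground_truth_volume("lh", "cortex") for ph in cohort]
    assert len(set(vols)) > 1
    assert [ph.id for ph in cohort] == ["control01", "control02", "control03"]


def test_end_to_end_null_pvd_is_zero():
    """Empty lesion -> chimeric == control -> identical volumes, both modes."""
    ph = generate_phantom(**SMALL)
    empty = LesionPatch(
        source_id="none", norm_intensities=np.zeros(0),
        mask=BinaryMask(data=np.zeros(ph.image.shape, np.uint8),
                        affine=ph.image.affine), characteristics=None)
    case = transplant(empty, ph.image)
    for mode in ("local", "global-normalized"):
        sim = mock_segment(case.chimeric, ph, mode=mode)
        gt = mock_segment(ph.image, ph, mode=mode)
        for hemi in ("lh", "rh"):
            for measure in ("cortex", "cwm"):
                assert sim.volume(hemi, measure) == gt.volume(hemi, measure)


# --- generative statistical datasets ----------------------------------------

def test_simulated_dataset_deterministic():
    a = simulate_lmm_dataset("b", n_lesions=4, n_controls=3, seed=9)
    b = simulate_lmm_dataset("b", n_lesions=4, n_controls=3, seed=9)
    assert a.equals(b)


def test_zero_variance_zero_effect_outcome_constant():
    df = simulate_lmm_dataset(
        "b", {"intercept": 2.0, "hemisphere": 0.0, "sd_pair": 0.0,
              "sd_lesion": 0.0, "sd_control": 0.0, "sd_resid": 0.0},
        n_lesions=3, n_controls=3, seed=10)
    assert np.allclose(df.pvd, 2.0)


def test_lesion_variance_component_increases_dispersion():
    """Dispersion of lesion-level means grows with the lesion variance."""
    def lesion_mean_var(sd_lesion, seed):
        df = simulate_lmm_dataset("b", {"sd_lesion": sd_lesion},
                                  n_lesions=10, n_controls=6, seed=seed)
        return df.groupby("lesion_id").pvd.mean().var(ddof=1)

    lo = np.mean([lesion_mean_var(0.0, s) for s in range(30)])
    hi = np.mean([lesion_mean_var(1.0, s) for s in range(30)])
    assert hi > lo


def test_invalid_variance_rejected():
    with pytest.raises(ValueError, match="sd_resid"):
        simulate_lmm_dataset("b", {"sd_resid": -1.0}, seed=0)


def test_design_too_small_rejected():
    with pytest.raises(ValueError, match="2"):
        simulate_lmm_dataset("a", n_lesions=1, n_controls=5, seed=0)
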