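"""Build a brain phantom with known tissue volumes and grow a synthetic lesion.

The phantom is two mirrored sets of nested ellipsoids (CSF shell, GM shell,
WM core) on a 64³ 1-mm grid, so every hemispheric tissue volume is known
exactly from the construction labels.  The lesion has a controlled volume
and controlled intensity statistics in unit-invariant space (z-scores of the
non-lesion image intensities).
"""

from lesionbench import (determine_laterality, generate_phantom,
                         generate_synthetic_lesion, lesion_volume,
                         unit_invariant_normalize)
from lesionbench.lesion_toolkit import lesion_intensity_stats
from lesionbench.synthetic import SyntheticLesionSpec

phantom = generate_phantom(seed=1)
print("ground-truth volumes (mm³):")
print(phantom.ground_truth.to_string(index=False))

spec = SyntheticLesionSpec(target_volume_mm3=1030.0, hemisphere="lh",
                           mean_intensity_ui=-1.5, sd_intensity_ui=0.5, seed=2)
mask, patient = generate_synthetic_lesion(phantom, spec)

norm = unit_invariant_normalize(patient, mask)
mean_ui, sd_ui = lesion_intensity_stats(norm, mask)
print(f"\nlesion volume: {lesion_volume(mask):.2f} mm³ "
      f"(target {spec.target_volume_mm3})")
print(f"laterality: {determine_laterality(mask)} (requested {spec.hemisphere})")
print(f"unit-invariant intensity: mean {mean_ui:.3f} (target "
      f"{spec.mean_intensity_ui}), SD {sd_ui:.3f} (target {spec.sd_intensity_ui})")
print("\nA hypointense (negative-mean) lesion like this mimics the dark "
      "appearance of TBI lesions on T1-weighted MRI.")
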