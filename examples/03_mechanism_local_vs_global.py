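"""Show how image-global intensity normalization transmits lesion-induced
error to the hemisphere that was never touched.

A large, strongly hypointense lesion is transplanted into the left
hemisphere of a noise-free phantom.  The mock segmenter's 'local' mode
classifies each voxel independently, so the right (contralesional)
hemisphere measures exactly its ground truth.  The 'global-normalized' mode
first rescales the image to reference brain-intensity statistics — the
lesion shifts those statistics, the rescaling moves every voxel's effective
class boundary, and volume error appears contralesionally.
"""

from lesionbench import (compute_pvd, extract_patch, generate_phantom,
                         generate_synthetic_lesion, mock_segment, transplant)
from lesionbench.synthetic import SyntheticLesionSpec

ctrl = generate_phantom(class_noise_sd=(0, 0, 0), seed=5, id="ctrl")
donor = generate_phantom(class_noise_sd=(0, 0, 0), seed=5, id="donor")
spec = SyntheticLesionSpec(target_volume_mm3=8000.0, hemisphere="lh",
                           mean_intensity_ui=-2.0, sd_intensity_ui=0.5, seed=3)
mask, patient = generate_synthetic_lesion(donor, spec)
case = transplant(extract_patch(patient, mask, lesion_id="L1"), ctrl.image)

print("contralesional (right-hemisphere) PVD vs. ground truth:")
for mode in ("local", "global-normalized"):
    sim = mock_segment(case.chimeric, ctrl, mode=mode)
    gt = mock_segment(ctrl.image, ctrl, mode=mode)
    for measure in ("cortex", "cwm"):
        pvd = compute_pvd(sim.volume("rh", measure), gt.volume("rh", measure))
        print(f"  {mode:>18s}  {measure:>6s}: {pvd:8.3f} %")
print("\nLocal classification cannot act at a distance (PVD exactly 0); "
      "global normalization makes the untouched hemisphere's measured "
      "cortex volume depend on the lesion.")
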