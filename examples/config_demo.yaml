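# Desk-scale demo: 3 synthetic lesions x 2 control phantoms.
# Run with:  lesionbench run --config examples/config_demo.yaml
# (hypothesis (c) needs more lesions than covariates, so the demo fits a, b)
output_dir: scratch/demo_run
seed: 7
n_lesions: 3
n_controls: 2
phantom:
  grid_shape: [32, 32, 32]
  center_offset_mm: 7.0
  csf_semi_axes: [6.0, 12.0, 12.0]
  gm_semi_axes: [5.0, 10.0, 10.0]
  wm_semi_axes: [3.5, 7.0, 7.0]
lesion_volumes_mm3: [40.0, 120.0, 300.0]
lesion_lateralities: [lh, rh, lh]
segmenter_mode: global-normalized
hypotheses: [a, b]
write_images: true
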