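# lesionbench

Simulated focal brain lesions for benchmarking lesion-induced error in
automated brain-volume measurement.

## The problem

Morphometry pipelines are validated on healthy brains, yet they are applied
to injured ones. A focal lesion (for example pediatric traumatic brain
injury visible on T1-weighted MRI) can bias volume estimates in two ways:
focally, where the lesion sits, and globally, through image-wide processing
steps such as intensity normalization. The global component is the
dangerous one — it contaminates measurements of tissue the lesion never
touched — and it cannot be detected on patient data alone, because no
lesion-free version of a patient's brain exists.

`lesionbench` implements the chimeric-image design that makes the error
measurable. A lesion is *transplanted* from a patient (or synthetic donor)
into a lesion-free control image; the control itself is the ground truth.
In a fully crossed design every lesion meets every control (16 lesions ×
11 controls = 176 cases by default). Hemispheric cortex and cerebral
white-matter volumes are measured on both members of each pair, recoded to
**lesioned** / **contralesional** hemisphere, and compared. Because every
voxel outside the transplanted lesion is bit-identical to the control, any
contralesional measurement difference is algorithm-induced error, full stop.

The error is quantified by the percent volume difference

    PVD = 100 · |V_sim − V_gt| / (½ (V_sim + V_gt))

and analysed with linear mixed-effects models with **crossed random
effects** (lesion used × control used, plus the pair), fitted by profiled
REML/ML with likelihood-ratio tests for the random structure and
normal-approximation Wald tests (p = 2·Φ(−|t|)) for fixed effects:

* (a) volume ~ case (simulated vs. ground truth), random slope of case
  within pair + crossed lesion/control intercepts;
* (b) PVD ~ hemisphere role, crossed random intercepts;
* (c) PVD ~ z-scored lesion volume / mean intensity / intensity SD, random
  control intercept, per hemisphere.

Everything runs on synthetic, programmatically generated data: ellipsoid
brain phantoms with known tissue volumes, lesions with controlled volume and
unit-invariant intensity statistics, and a mock segmenter whose two modes
(`local` vs `global-normalized`) isolate exactly the mechanism by which
image-global intensity normalization transmits focal error to the untouched
hemisphere. See `docs/methods.md` for the model details and design choices.

## Worked example

`examples/03_mechanism_local_vs_global.py` transplants a large hypointense
lesion (8,000 mm³, unit-invariant mean −2) into the left hemisphere of a
noise-free phantom and measures the *right* (contralesional) hemisphere:

```
contralesional (right-hemisphere) PVD vs. ground truth:
               local  cortex:    0.000 %
               local     cwm:    0.000 %
   global-normalized  cortex:   64.184 %
   global-normalized     cwm:    0.000 %
```

With purely local voxel classification the untouched hemisphere measures
exactly its ground truth (PVD = 0). When the segmenter first rescales the
image to global brain-intensity statistics — which the lesion has shifted —
the contralesional cortex volume changes although not one of its voxels was
modified. That is the global-error mechanism in miniature (the magnitude is
exaggerated by the mock segmenter's hard thresholds; see
`docs/methods.md`).

The other examples build phantoms and lesions (`01`), verify bit-exact
conservation outside the transplant (`02`), and run the full 176-case
crossed study with all three model families (`04`).

A full study replica is one command:

```bash
lesionbench run --config config.yaml          # or: python -m lesionbench.cli
```

with a YAML config selecting design size, phantom geometry, segmenter mode,
hypotheses, and seeds; each stage (`simulate`, `characterize`, `segment`,
`tabulate`, `fit`) is also independently invokable and resumable. Outputs
are CSV tables, optional NIfTI images, and a JSON run record whose hash is
reproducible given the config and seed.

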