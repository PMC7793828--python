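"""Run the full crossed study on synthetic data and fit the hypothesis models.

Every lesion is applied to every control (16 × 11 = 176 chimeric cases),
each case and its ground-truth control are segmented, volumes are recoded to
lesioned/contralesional, and three mixed-model families ask: (a) does the
lesion change measured volume, (b) is the error magnitude (PVD) different
between hemispheres, (c) which lesion characteristics predict the error.
Runs in well under a minute on one CPU; writes CSVs and a JSON run record.
"""

import tempfile

import pandas as pd

from lesionbench import RunConfig, run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    cfg = RunConfig(output_dir=tmp, seed=1, n_lesions=16, n_controls=11,
                    segmenter_mode="global-normalized")
    record = run_pipeline(cfg)

    print(f"simulated cases: {record['stages']['simulate']['n_cases']}")
    print(f"long-table rows: {record['stages']['tabulate']['n_long_rows']}")

    print("\nPVD descriptives (20% trimmed mean, %):")
    summary = pd.DataFrame(record["stages"]["tabulate"]["pvd_summary"])
    print(summary[["hemi_role", "measure", "trimmed_mean_pct", "median_pct",
                   "max_pct"]].to_string(index=False))

    print("\nhypothesis-(b) hemisphere effect on cortex PVD:")
    models = pd.DataFrame(record["stages"]["fit"]["models"])
    row = models[(models.hypothesis == "b") & (models.subset == "cortex")
                 & (models.term == "hemi_role[lesioned]")].iloc[0]
    print(f"  B = {row.B:.3f}, SE = {row.SE:.3f}, t = {row.t:.2f}, "
          f"p = {row.p:.3g}")
    side = "lesioned" if row.B > 0 else "contralesional"
    print(f"\nB is the lesioned-minus-contralesional difference in mean PVD, "
          f"so here the {side} hemisphere carries the larger estimated error "
          "on these synthetic data (the mock segmenter's threshold "
          "classification makes PVD heavy-tailed: a few large contralesional "
          "errors coexist with a zero trimmed mean). The LRT table in the "
          "run record tests whether the crossed random effects (pair, "
          "lesion, control) were warranted.")
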