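"""Hemisphere recoding, percent volume difference, and descriptive summaries.

Each lesion × control pair contributes one repeated-measures "datapoint" of
eight rows: {simulated, ground_truth} × {lesioned, contralesional} ×
{cortex, cwm}.  Volumes are recoded from lh/rh to lesioned/contralesional
using the lesion's laterality, and the matched ground-truth case is recoded
with the same mapping, so any simulated-vs-truth difference in the
contralesional hemisphere is measurement error by construction.

PVD (percent volume difference) between a simulated and a ground-truth
volume is

    PVD = 100 · |V_sim − V_gt| / (½ (V_sim + V_gt))

— unsigned, symmetric, scale-invariant, in [0, 200].
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .segmentation import SegmentationResult

__all__ = [
    "recode_hemispheres",
    "compute_pvd",
    "build_long_table",
    "pvd_table",
    "trimmed_mean",
    "pvd_summary",
]

MEASURES = ("cortex", "cwm")
GROUND_TRUTH_LESION_CODE = "0"  # lesion id assigned to ground-truth rows


def recode_hemispheres(result: SegmentationResult, laterality: str
                       ) -> tuple[dict, dict]:
    """Map lh/rh volumes to (lesioned, contralesional) dicts keyed by measure."""
    if laterality not in ("lh", "rh"):
        raise ValueError(
            f"laterality must be unilateral ('lh'/'rh'); got {laterality!r}")
    les, contra = (("lh", "rh") if laterality == "lh" else ("rh", "lh"))
    lesioned = {m: result.volume(les, m) for m in MEASURES}
    contralesional = {m: result.volume(contra, m) for m in MEASURES}
    return lesioned, contralesional


def compute_pvd(v_sim: float, v_gt: float) -> float:
    """Percent volume difference between a simulated and ground-truth volume."""
    if v_sim < 0 or v_gt < 0:
        raise ValueError(f"volumes must be >= 0; got ({v_sim}, {v_gt})")
    denom = 0.5 * (v_sim + v_gt)
    if denom == 0:
        raise ValueError("PVD undefined: both volumes are zero")
    return 100.0 * abs(v_sim - v_gt) / denom


def build_long_table(sim_results: dict[str, SegmentationResult],
                     gt_results: dict[str, SegmentationResult],
                     manifest: pd.DataFrame) -> pd.DataFrame:
    """Assemble the long-format measurement table: 8 rows per pair.

    ``sim_results`` is keyed by case_id, ``gt_results`` by control_id.
    Ground-truth rows carry lesion_id "0".  Manifest rows whose status is not
    'ok' are skipped; a missing segmentation for an 'ok' pair is an error
    naming the pair.
    """
    rows = []
    for rec in manifest.itertuples(index=False):
        if getattr(rec, "status", "ok") != "ok":
            continue
        pair_id = rec.case_id
        if pair_id not in sim_results:
            raise KeyError(f"no simulated segmentation for pair {pair_id!r}")
        if rec.control_id not in gt_results:
            raise KeyError(
                f"no ground-truth segmentation for pair {pair_id!r} "
                f"(control {rec.control_id!r})")
        for case, result, lesion_id in (
                ("simulated", sim_results[pair_id], rec.lesion_id),
                ("ground_truth", gt_results[rec.control_id],
                 GROUND_TRUTH_LESION_CODE)):
            lesioned, contralesional = recode_hemispheres(result, rec.laterality)
            for hemi_role, vols in (("lesioned", lesioned),
                                    ("contralesional", contralesional)):
                for measure in MEASURES:
                    rows.append({
                        "pair_id": pair_id,
                        "case": case,
                        "hemi_role": hemi_role,
                        "measure": measure,
                        "volume_mm3": vols[measure],
                        "lesion_id": str(lesion_id),
                        "control_id": str(rec.control_id),
                    })
    return pd.DataFrame(
        rows, columns=["pair_id", "case", "hemi_role", "measure",
                       "volume_mm3", "lesion_id", "control_id"])


def pvd_table(long_table: pd.DataFrame) -> pd.DataFrame:
    """One PVD row per (pair × hemi_role × measure).

    The unsigned PVD follows the formula; a signed simulated-minus-truth
    difference (mm³) is kept as a diagnostic column since the direction of
    error is interpretable even though PVD itself is a magnitude.
    """
    wide = long_table.pivot_table(
        index=["pair_id", "hemi_role", "measure", "control_id"],
        columns="case", values="volume_mm3", aggfunc="first").reset_index()
    if "simulated" not in wide or "ground_truth" not in wide:
        raise ValueError("long table must contain both case levels")
    lesion_ids = (long_table[long_table.case == "simulated"]
                  [["pair_id", "lesion_id"]].drop_duplicates()
                  .set_index("pair_id").lesion_id)
    wide["lesion_id"] = wide.pair_id.map(lesion_ids)
    wide["pvd"] = [compute_pvd(s, g)
                   for s, g in zip(wide.simulated, wide.ground_truth)]
    wide["signed_diff_mm3"] = wide.simulated - wide.ground_truth
    return wide[["pair_id", "lesion_id", "control_id", "hemi_role",
                 "measure", "pvd", "signed_diff_mm3"]].copy()


def trimmed_mean(values, trim: float = 0.2) -> float:
    """Mean after discarding floor(trim·n) values from each tail."""
    vals = np.sort(np.asarray(values, dtype=float).ravel())
    if vals.size == 0:
        raise ValueError("trimmed_mean of an empty sequence")
    if not 0.0 <= trim < 0.5:
        raise ValueError(f"trim must be in [0, 0.5); got {trim}")
    k = math.floor(trim * vals.size)
    core = vals[k:vals.size - k]
    return float(core.mean())


def pvd_summary(pvds: pd.DataFrame, trim: float = 0.2,
                threshold_pct: float = 1.0) -> pd.DataFrame:
    """Descriptives per (hemi_role × measure): trimmed mean, median, max,
    and the count of cases with PVD above ``threshold_pct``."""
    if len(pvds) == 0:
        raise ValueError("empty PVD table")
    rows = []
    for (hemi_role, measure), grp in pvds.groupby(["hemi_role", "measure"],
                                                  sort=True):
        v = grp.pvd.to_numpy()
        rows.append({
            "hemi_role": hemi_role,
            "measure": measure,
            "trimmed_mean_pct": trimmed_mean(v, trim),
            "median_pct": float(np.median(v)),
            "max_pct": float(v.max()),
            f"n_gt_{threshold_pct:g}pct": int(np.count_nonzero(v > threshold_pct)),
            "n": int(v.size),
        })
    return pd.DataFrame(rows)
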