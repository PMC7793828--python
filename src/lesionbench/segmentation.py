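"""Hemispheric cortex / cerebral-white-matter volumes from a T1w-like volume.

Two routes produce a :class:`SegmentationResult`:

* an adapter that shells out to an external surface segmenter and parses its
  plain-text summary-stats file (never required by the test suite), and
* a built-in mock segmenter operating on phantoms, with two modes that
  bracket the mechanism under study:

  - ``local``: each voxel is classified to the nearest tissue class mean
    via fixed thresholds midway between class means.  Purely local — a
    lesion cannot change measurements in the other hemisphere.
  - ``global-normalized``: the image is first rescaled so its brain-voxel
    mean and SD match the reference phantom's, then the same thresholds are
    applied.  A lesion shifts the global intensity statistics and thereby
    moves every voxel's effective class boundary — image-wide intensity
    normalization is exactly how a focal lesion can transmit error to the
    anatomically untouched contralesional hemisphere.

In both modes brain membership (brain vs. background) is decided once, from
the raw intensities, so total brain volume is mode-invariant by construction
(the analogue of skull-stripping preceding intensity normalization).
"""

from __future__ import annotations

import os
import shlex
import subprocess
from dataclasses import dataclass

import numpy as np

from .core_imaging import ImageVolume, voxel_volume
from .synthetic import Phantom

__all__ = [
    "SegmentationResult",
    "parse_stats_file",
    "write_stats_file",
    "mock_segment",
    "run_external_segmenter",
    "SegmenterError",
]

STATS_KEYS = {
    "lhCortexVol": "lh_cortex_mm3",
    "rhCortexVol": "rh_cortex_mm3",
    "lhCerebralWhiteMatterVol": "lh_cwm_mm3",
    "rhCerebralWhiteMatterVol": "rh_cwm_mm3",
}


class SegmenterError(RuntimeError):
    """External segmenter invocation failed."""


@dataclass
class SegmentationResult:
    """Hemispheric cortex and cerebral white matter volumes (mm³)."""

    subject_id: str
    lh_cortex_mm3: float
    rh_cortex_mm3: float
    lh_cwm_mm3: float
    rh_cwm_mm3: float
    segmenter: str = "mock"
    mode: str = "local"  # 'local' | 'global-normalized' | 'external'
    # CSF is reported by the mock segmenter only (external stats files carry
    # the four primary measures); together the three classes partition the
    # brain mask, whose total volume is mode-invariant
    lh_csf_mm3: float = 0.0
    rh_csf_mm3: float = 0.0

    def __post_init__(self) -> None:
        for name in ("lh_cortex_mm3", "rh_cortex_mm3", "lh_cwm_mm3",
                     "rh_cwm_mm3", "lh_csf_mm3", "rh_csf_mm3"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def volume(self, hemisphere: str, measure: str) -> float:
        """hemisphere in {'lh','rh'}, measure in {'cortex','cwm'}."""
        return float(getattr(self, f"{hemisphere}_{measure}_mm3"))


def parse_stats_file(path: str | os.PathLike,
                     subject_id: str | None = None) -> SegmentationResult:
    """Parse the summary-stats dialect:

        # Measure <name>, <key>, <description>, <value>, mm^3

    Extra measures are ignored; any of the four required keys missing is an
    error naming that key.
    """
    path = os.fspath(path)
    found: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line.startswith("# Measure"):
                continue
            body = line[len("# Measure"):].strip()
            parts = [p.strip() for p in body.split(",")]
            if len(parts) < 4:
                continue
            key = parts[1]
            if key in STATS_KEYS:
                try:
                    found[STATS_KEYS[key]] = float(parts[3])
                except ValueError as exc:
                    raise ValueError(
                        f"malformed value for measure {key!r} in {path}: "
                        f"{parts[3]!r}") from exc
    missing = [k for k, v in STATS_KEYS.items() if v not in found]
    if missing:
        raise KeyError(f"stats file {path} is missing measure(s): {missing}")
    sid = subject_id if subject_id is not None else os.path.splitext(
        os.path.basename(path))[0]
    return SegmentationResult(subject_id=sid, segmenter="external",
                              mode="external", **found)


def write_stats_file(result: SegmentationResult, path: str | os.PathLike) -> None:
    """Write a result back out in the summary-stats dialect (fixture helper)."""
    inverse = {v: k for k, v in STATS_KEYS.items()}
    with open(path, "w") as fh:
        fh.write(f"# subject {result.subject_id}\n")
        for field_name, key in inverse.items():
            label = key.replace("Vol", "")
            fh.write(f"# Measure {label}, {key}, {label} volume, "
                     f"{getattr(result, field_name):.6f}, mm^3\n")


def _class_thresholds(phantom: Phantom) -> tuple[float, float, float]:
    csf, gm, wm = phantom.spec.class_mean_intensities
    if not (0.0 < csf < gm < wm):
        raise ValueError(f"degenerate class means: {phantom.spec.class_mean_intensities}")
    return (0.0 + csf) / 2.0, (csf + gm) / 2.0, (gm + wm) / 2.0


def mock_segment(vol: ImageVolume, phantom: Phantom,
                 mode: str = "local") -> SegmentationResult:
    """Threshold-based tissue segmentation with known class means.

    ``phantom`` supplies the reference class mean intensities, the reference
    brain mask used by the global normalization, and the reference brain
    mean/SD.  Volumes are class voxel counts × voxel volume, split by the
    world-x sign of each voxel (the x = 0 plane belongs to neither
    hemisphere).
    """
    if mode not in ("local", "global-normalized"):
        raise ValueError(f"unknown mock segmenter mode {mode!r}")
    t_bg, t_csf_gm, t_gm_wm = _class_thresholds(phantom)

    img = np.asarray(vol.data, dtype=float)
    brain = img > t_bg  # fixed in both modes: raw-intensity skull-strip
    if not brain.any():
        raise ValueError(f"no brain voxels found in {vol.id!r}")

    if mode == "global-normalized":
        stats_mask = phantom.brain_mask()
        vals = img[stats_mask]
        m, s = float(vals.mean()), float(vals.std(ddof=1))
        if s <= 0:
            raise ValueError("degenerate brain-intensity distribution")
        img = (img - m) / s * phantom.brain_sd + phantom.brain_mean

    # world x per voxel (axis-aligned or not)
    idx = np.indices(vol.data.shape).reshape(3, -1)
    x_world = (vol.affine[0, :3] @ idx + vol.affine[0, 3]).reshape(vol.data.shape)

    vv = voxel_volume(vol)
    out = {}
    for hemi, hsel in (("lh", x_world < 0), ("rh", x_world > 0)):
        sel = brain & hsel
        v = img[sel]
        out[f"{hemi}_csf_mm3"] = float(np.count_nonzero(v <= t_csf_gm)) * vv
        out[f"{hemi}_cortex_mm3"] = float(
            np.count_nonzero((v > t_csf_gm) & (v <= t_gm_wm))) * vv
        out[f"{hemi}_cwm_mm3"] = float(np.count_nonzero(v > t_gm_wm)) * vv
    return SegmentationResult(subject_id=vol.id, segmenter="mock", mode=mode, **out)


def run_external_segmenter(case_dir: str | os.PathLike, command_template: str,
                           subject_id: str, t1_path: str | os.PathLike,
                           timeout: float = 3600.0,
                           stats_filename: str | None = None,
                           ) -> SegmentationResult:
    """Invoke an external segmenter and parse its stats file.

    ``command_template`` may use the placeholders {subject_id}, {t1_path}
    and {out_dir}.  The stats file is expected at
    ``<case_dir>/<subject_id>.stats`` unless ``stats_filename`` is given.
    """
    case_dir = os.fspath(case_dir)
    cmd = command_template.format(subject_id=subject_id,
                                  t1_path=os.fspath(t1_path), out_dir=case_dir)
    proc = subprocess.run(shlex.split(cmd), capture_output=True, text=True,
                          timeout=timeout)
    if proc.returncode != 0:
        raise SegmenterError(
            f"segmenter command failed with exit status {proc.returncode}: "
            f"{cmd!r}\nstderr: {proc.stderr[-500:]}")
    stats_path = os.path.join(case_dir,
                              stats_filename or f"{subject_id}.stats")
    if not os.path.exists(stats_path):
        raise SegmenterError(
            f"segmenter exited 0 but produced no stats file at {stats_path}")
    return parse_stats_file(stats_path, subject_id=subject_id)
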