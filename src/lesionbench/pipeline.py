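"""Full study replica from one YAML configuration.

Stages, in order: simulate (build the crossed lesion × control dataset of
chimeric phantoms), characterize (lesion covariates), segment (mock
segmenter on every simulated and ground-truth case), tabulate (long table,
PVD table, descriptives), fit (the three hypothesis families).  Each stage
writes CSV outputs under the configured output directory, and the run ends
with a machine-readable JSON run record whose content (and hash) is
deterministic given the config and seed.

Re-running against an existing output directory loads the stored stage
outputs instead of recomputing, unless ``force`` is set.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core_imaging import write_nifti
from .error_metrics import build_long_table, pvd_summary, pvd_table
from .lesion_toolkit import lesion_intensity_stats, unit_invariant_normalize
from .mixed_models import hypothesis_a, hypothesis_b, hypothesis_c
from .segmentation import mock_segment, SegmentationResult
from .synthetic import (PhantomSpec, control_cohort, lesion_cohort)
from .transplant import build_crossed_dataset, extract_patch

__all__ = ["RunConfig", "ConfigError", "validate_config", "load_config",
           "run_pipeline"]

log = logging.getLogger("lesionbench")

STAGES = ("simulate", "characterize", "segment", "tabulate", "fit")


class ConfigError(ValueError):
    """Invalid run configuration; ``errors`` lists every problem found."""

    def __init__(self, errors: list[str]):
        super().__init__("invalid config:\n  - " + "\n  - ".join(errors))
        self.errors = errors


@dataclass
class RunConfig:
    output_dir: str = "lesionbench_out"
    seed: int = 0
    n_lesions: int = 16
    n_controls: int = 11
    phantom: dict = field(default_factory=dict)  # PhantomSpec overrides
    lesion_volumes_mm3: list | None = None
    lesion_lateralities: list | None = None
    segmenter_mode: str = "global-normalized"  # 'local' | 'global-normalized'
    hypotheses: list = field(default_factory=lambda: ["a", "b", "c"])
    trim: float = 0.2
    bilateral_fraction: float = 0.02
    transform: str = "identity"
    strict: bool = False
    write_images: bool = False


_KNOWN_KEYS = set(RunConfig.__dataclass_fields__)


def _validate_dict(raw: dict) -> tuple[RunConfig | None, list[str]]:
    errors: list[str] = []
    if not isinstance(raw, dict):
        return None, ["config root must be a mapping"]
    unknown = sorted(set(raw) - _KNOWN_KEYS)
    for key in unknown:
        errors.append(f"unknown config key: {key!r}")
    cfg = RunConfig(**{k: v for k, v in raw.items() if k in _KNOWN_KEYS})
    if not isinstance(cfg.seed, int):
        errors.append(f"seed must be an integer, got {cfg.seed!r}")
    if not (isinstance(cfg.n_lesions, int) and cfg.n_lesions >= 0):
        errors.append(f"n_lesions must be a non-negative integer, got {cfg.n_lesions!r}")
    if not (isinstance(cfg.n_controls, int) and cfg.n_controls >= 1):
        errors.append(f"n_controls must be a positive integer, got {cfg.n_controls!r}")
    if cfg.segmenter_mode not in ("local", "global-normalized"):
        errors.append(f"segmenter_mode must be 'local' or 'global-normalized', "
                      f"got {cfg.segmenter_mode!r}")
    if not (0 <= cfg.trim < 0.5):
        errors.append(f"trim must be in [0, 0.5), got {cfg.trim!r}")
    if not (0 <= cfg.bilateral_fraction < 0.5):
        errors.append(f"bilateral_fraction must be in [0, 0.5), got "
                      f"{cfg.bilateral_fraction!r}")
    if cfg.transform != "identity":
        errors.append(f"transform must be 'identity' in config files, got "
                      f"{cfg.transform!r} (pass matrices via the API)")
    bad_h = [h for h in cfg.hypotheses if h not in ("a", "b", "c")]
    if bad_h:
        errors.append(f"unknown hypotheses: {bad_h}")
    if cfg.phantom:
        unknown_ph = sorted(set(cfg.phantom) - set(PhantomSpec.__dataclass_fields__))
        if unknown_ph:
            errors.append(f"unknown phantom keys: {unknown_ph}")
    if cfg.lesion_volumes_mm3 is not None:
        if cfg.lesion_lateralities is not None and \
                len(cfg.lesion_lateralities) != len(cfg.lesion_volumes_mm3):
            errors.append("lesion_lateralities and lesion_volumes_mm3 differ in length")
        if any(v <= 0 for v in cfg.lesion_volumes_mm3):
            errors.append("lesion_volumes_mm3 must all be positive")
    return (None, errors) if errors else (cfg, [])


def validate_config(path: str | os.PathLike) -> RunConfig:
    """Load and validate a YAML config; all problems are reported at once."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise ConfigError([f"config file does not exist: {path}"])
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg, errors = _validate_dict(raw)
    if errors:
        raise ConfigError(errors)
    return cfg


load_config = validate_config


def _phantom_spec(cfg: RunConfig) -> PhantomSpec:
    overrides = dict(cfg.phantom)
    for key in ("grid_shape", "voxel_dims", "class_mean_intensities",
                "class_noise_sd", "csf_semi_axes", "gm_semi_axes",
                "wm_semi_axes"):
        if key in overrides:
            overrides[key] = tuple(overrides[key])
    return PhantomSpec(**overrides)


def _seg_to_row(r: SegmentationResult) -> dict:
    return {"subject_id": r.subject_id, "lh_cortex_mm3": r.lh_cortex_mm3,
            "rh_cortex_mm3": r.rh_cortex_mm3, "lh_cwm_mm3": r.lh_cwm_mm3,
            "rh_cwm_mm3": r.rh_cwm_mm3, "segmenter": r.segmenter,
            "mode": r.mode}


def _row_to_seg(row) -> SegmentationResult:
    return SegmentationResult(
        subject_id=row.subject_id, lh_cortex_mm3=row.lh_cortex_mm3,
        rh_cortex_mm3=row.rh_cortex_mm3, lh_cwm_mm3=row.lh_cwm_mm3,
        rh_cwm_mm3=row.rh_cwm_mm3, segmenter=row.segmenter, mode=row.mode)


def _fit_to_rows(name: str, subset: str, hres) -> tuple[list[dict], dict]:
    coef_rows = []
    for c in hres.fit.coefficients.values():
        coef_rows.append({
            "hypothesis": name, "subset": subset, "term": c.term,
            "B": c.B, "SE": c.SE, "t": c.t, "p": c.p,
            "estimation": hres.fit.estimation,
            "converged": hres.fit.converged,
            "correlation_dropped": hres.fit.correlation_dropped,
        })
    lrt_row = {
        "hypothesis": name, "subset": subset,
        "chi_square": hres.lrt.chi_square, "df": hres.lrt.df, "p": hres.lrt.p,
        "ll_full_ml": hres.ml_fit.log_likelihood,
        "ll_reduced_ml": hres.null_fit.log_likelihood,
    }
    return coef_rows, lrt_row


def run_pipeline(config: RunConfig, force: bool = False,
                 stop_after: str = "fit") -> dict:
    """Execute the pipeline and return the run record (also written to disk).

    ``stop_after`` names the last stage to run ('simulate', 'characterize',
    'segment', 'tabulate' or 'fit').
    """
    if stop_after not in STAGES:
        raise ValueError(f"stop_after must be one of {STAGES}, got {stop_after!r}")
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    paths = {name: os.path.join(out, f"{name}.csv") for name in
             ("manifest", "characteristics", "segmentations", "long_table",
              "pvd_table", "pvd_summary", "models", "lrt")}
    record: dict = {"config": asdict(config), "version": __version__,
                    "stages": {}, "warnings": []}
    stage_limit = STAGES.index(stop_after)

    core = ["manifest", "characteristics", "segmentations", "long_table",
            "pvd_table"][: {0: 1, 1: 2, 2: 3, 3: 5, 4: 5}[stage_limit]]
    resume = (not force) and all(os.path.exists(paths[p]) for p in core)

    if resume:
        log.info("existing outputs found in %s; loading (use force to recompute)", out)
        manifest = pd.read_csv(paths["manifest"], float_precision="round_trip")
        chars = (pd.read_csv(paths["characteristics"],
                             float_precision="round_trip")
                 if stage_limit >= 1 else None)
        if stage_limit >= 2:
            seg_df = pd.read_csv(paths["segmentations"],
                                 float_precision="round_trip")
        if stage_limit >= 3:
            long_table = pd.read_csv(paths["long_table"],
                                     dtype={"lesion_id": str, "control_id": str},
                                     float_precision="round_trip")
            pvds = pd.read_csv(paths["pvd_table"],
                               dtype={"lesion_id": str, "control_id": str},
                               float_precision="round_trip")
    else:
        # --- simulate -----------------------------------------------------
        log.info("stage simulate: %d lesions x %d controls",
                 config.n_lesions, config.n_controls)
        base_spec = _phantom_spec(config)
        rng = np.random.default_rng(config.seed)
        controls = control_cohort(config.n_controls,
                                  seed=int(rng.integers(2 ** 31 - 1)),
                                  base_spec=base_spec)
        cohort = lesion_cohort(config.n_lesions,
                               seed=int(rng.integers(2 ** 31 - 1)),
                               base_spec=base_spec,
                               volumes_mm3=config.lesion_volumes_mm3,
                               lateralities=config.lesion_lateralities)
        patches = [extract_patch(patient, mask, lesion_id=spec.lesion_id)
                   for mask, patient, spec in cohort]
        control_imgs = [ph.image for ph in controls]
        cases, manifest = build_crossed_dataset(
            patches, control_imgs, transforms=config.transform,
            seed=config.seed, strict=config.strict)
        manifest.to_csv(paths["manifest"], index=False)
        n_failed = int((manifest.status != "ok").sum())
        if n_failed:
            record["warnings"].append(f"{n_failed} transplants failed; see manifest")
        if config.write_images:
            img_dir = os.path.join(out, "cases")
            os.makedirs(img_dir, exist_ok=True)
            for case in cases:
                write_nifti(case.chimeric,
                            os.path.join(img_dir, f"{case.case_id}_t1.nii.gz"))
                write_nifti(case.transformed_mask,
                            os.path.join(img_dir, f"{case.case_id}_mask.nii.gz"))

        # --- characterize ---------------------------------------------------
        if stage_limit >= 1:
            log.info("stage characterize: %d cases", len(cases))
            by_lesion: dict[str, list] = {}
            for case in cases:
                norm = unit_invariant_normalize(case.chimeric,
                                                case.transformed_mask)
                m_ui, s_ui = lesion_intensity_stats(norm, case.transformed_mask)
                by_lesion.setdefault(case.lesion_id, []).append(
                    (case.volume_transplanted_mm3, m_ui, s_ui))
            char_rows = []
            for patch in patches:
                vals = np.array(by_lesion.get(patch.source_id, [])).reshape(-1, 3)
                c = patch.characteristics
                char_rows.append({
                    "lesion_id": c.lesion_id,
                    "volume_native_mm3": c.volume_native_mm3,
                    "volume_transplanted_mm3": (float(vals[:, 0].mean())
                                                if len(vals) else np.nan),
                    "laterality": c.laterality,
                    # chimeric-image ui stats, averaged over controls
                    "mean_intensity_ui": (float(vals[:, 1].mean())
                                          if len(vals) else c.mean_intensity_ui),
                    "sd_intensity_ui": (float(vals[:, 2].mean())
                                        if len(vals) else c.sd_intensity_ui),
                    "mean_intensity_ui_native": c.mean_intensity_ui,
                    "sd_intensity_ui_native": c.sd_intensity_ui,
                })
            chars = pd.DataFrame(char_rows)
            chars.to_csv(paths["characteristics"], index=False)

        # --- segment ----------------------------------------------------------
        if stage_limit >= 2:
            log.info("stage segment: mode=%s", config.segmenter_mode)
            phantom_by_id = {ph.id: ph for ph in controls}
            seg_rows = []
            for ph in controls:
                seg_rows.append(_seg_to_row(mock_segment(
                    ph.image, ph, mode=config.segmenter_mode)))
            for case in cases:
                ph = phantom_by_id[case.control_id]
                seg_rows.append(_seg_to_row(mock_segment(
                    case.chimeric, ph, mode=config.segmenter_mode)))
            seg_df = pd.DataFrame(seg_rows)
            seg_df.to_csv(paths["segmentations"], index=False)

        # --- tabulate ---------------------------------------------------------
        if stage_limit >= 3:
            log.info("stage tabulate")
            results = {row.subject_id: _row_to_seg(row)
                       for row in seg_df.itertuples(index=False)}
            control_ids = [ph.id for ph in controls]
            gt_results = {cid: results[cid] for cid in control_ids}
            sim_results = {k: v for k, v in results.items()
                           if k not in gt_results}
            long_table = build_long_table(sim_results, gt_results, manifest)
            long_table.to_csv(paths["long_table"], index=False)
            pvds = pvd_table(long_table)
            pvds.to_csv(paths["pvd_table"], index=False)

    record["stages"]["simulate"] = {
        "n_cases": int((manifest.status == "ok").sum()),
        "n_attempted": int(len(manifest)),
    }
    if stage_limit >= 1:
        record["stages"]["characterize"] = {"n_lesions": int(len(chars))}
    if stage_limit >= 2:
        record["stages"]["segment"] = {"n_segmentations": int(len(seg_df)),
                                       "mode": config.segmenter_mode}
    if stage_limit >= 3:
        summary = pvd_summary(pvds, trim=config.trim)
        summary.to_csv(paths["pvd_summary"], index=False)
        record["stages"]["tabulate"] = {
            "n_long_rows": int(len(long_table)),
            "n_pvd_rows": int(len(pvds)),
            "pvd_summary": summary.to_dict(orient="records"),
        }

    # --- fit -----------------------------------------------------------------
    if stage_limit >= 4:
        log.info("stage fit: hypotheses %s", config.hypotheses)
        chars_idx = chars if chars is not None else None
        coef_rows, lrt_rows = [], []
        for measure in ("cortex", "cwm"):
            if "a" in config.hypotheses:
                for subset in (None, "lesioned", "contralesional"):
                    hres = hypothesis_a(long_table, measure, subset)
                    label = f"{measure}:{subset or 'both'}"
                    cr, lr = _fit_to_rows("a", label, hres)
                    coef_rows += cr
                    lrt_rows.append(lr)
            if "b" in config.hypotheses:
                hres = hypothesis_b(pvds, measure)
                cr, lr = _fit_to_rows("b", f"{measure}", hres)
                coef_rows += cr
                lrt_rows.append(lr)
            if "c" in config.hypotheses:
                for hemi in ("lesioned", "contralesional"):
                    hres = hypothesis_c(pvds, chars_idx, measure, hemi)
                    cr, lr = _fit_to_rows("c", f"{measure}:{hemi}", hres)
                    coef_rows += cr
                    lrt_rows.append(lr)
        models = pd.DataFrame(coef_rows)
        lrts = pd.DataFrame(lrt_rows)
        models.to_csv(paths["models"], index=False)
        lrts.to_csv(paths["lrt"], index=False)
        record["stages"]["fit"] = {
            "models": models.to_dict(orient="records"),
            "lrt": lrts.to_dict(orient="records"),
        }

    # hash the scientific content only: where the outputs live must not
    # change what they are
    hashed = {k: v for k, v in record.items() if k != "config"}
    hashed["config"] = {k: v for k, v in record["config"].items()
                        if k != "output_dir"}
    payload = json.dumps(hashed, sort_keys=True, default=float)
    record["record_hash"] = hashlib.sha256(payload.encode()).hexdigest()
    with open(os.path.join(out, "run_record.json"), "w") as fh:
        json.dump(record, fh, sort_keys=True, indent=2, default=float)
    return record
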