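"""Synthetic study material: brain phantoms, synthetic lesions, LMM datasets.

Real pediatric TBI MRI cannot be redistributed, so every pipeline stage here
is exercised on synthetic material with *known* ground truth:

* :func:`generate_phantom` — a two-hemisphere T1w-like volume built from
  mirrored nested ellipsoids (CSF shell / GM shell / WM core) with chosen
  class mean intensities and per-class Gaussian noise.  Ground-truth tissue
  volumes per hemisphere come from the construction labels.
* :func:`generate_synthetic_lesion` — a focal (or multifocal) lesion of
  controlled volume and unit-invariant intensity statistics, grown inside
  one hemisphere's tissue.
* :func:`simulate_lmm_dataset` — draws from the generative statistical
  models used by the three hypothesis families, for parameter-recovery
  checks of the mixed-model code.

All randomness flows from explicit integer seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_imaging import BinaryMask, ImageVolume, voxel_volume
from .lesion_toolkit import reference_stats

__all__ = [
    "PhantomSpec",
    "Phantom",
    "SyntheticLesionSpec",
    "generate_phantom",
    "generate_synthetic_lesion",
    "control_cohort",
    "lesion_cohort",
    "simulate_lmm_dataset",
    "DEFAULT_LESION_VOLUMES_MM3",
    "DEFAULT_LESION_LATERALITIES",
]

# background / CSF / GM / WM label codes in the phantom label map
BG, CSF, GM, WM = 0, 1, 2, 3

#: Default 16-lesion cohort: volumes (mm³) and sides spanning the range seen
#: in pediatric TBI — from tiny punctate lesions (15 mm³) to large
#: multi-centimetre injuries (~12,000 mm³).  Every value is a multiple of
#: 0.25 mm³, the granularity of a 1 × 0.5 × 0.5 mm acquisition grid.
DEFAULT_LESION_VOLUMES_MM3 = (
    25.00, 1030.00, 3063.75, 505.75, 12081.50, 60.25, 63.00, 35.00,
    2059.25, 8815.00, 83.50, 3858.50, 391.50, 15.00, 37.50, 407.00,
)
DEFAULT_LESION_LATERALITIES = (
    "lh", "lh", "rh", "lh", "lh", "lh", "rh", "rh",
    "rh", "rh", "lh", "rh", "rh", "lh", "rh", "rh",
)


@dataclass
class PhantomSpec:
    """Geometry and intensity recipe for a two-hemisphere phantom.

    Each hemisphere is three nested ellipsoids centred at world
    (±center_offset_mm, 0, 0): the outermost shell is CSF, the middle shell
    GM ("cortex"), the core WM.  Semi-axes are (x, y, z) in mm.  Class mean
    intensities must be strictly increasing (CSF < GM < WM, as on T1w).
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_dims: tuple[float, float, float] = (1.0, 1.0, 1.0)
    center_offset_mm: float = 14.0
    csf_semi_axes: tuple[float, float, float] = (13.0, 24.0, 24.0)
    gm_semi_axes: tuple[float, float, float] = (11.0, 21.0, 21.0)
    wm_semi_axes: tuple[float, float, float] = (8.0, 16.0, 16.0)
    class_mean_intensities: tuple[float, float, float] = (30.0, 70.0, 110.0)  # CSF, GM, WM
    class_noise_sd: tuple[float, float, float] = (2.0, 2.0, 2.0)
    seed: int = 0
    id: str = "phantom"

    def affine(self) -> np.ndarray:
        """Axis-aligned RAS+ affine placing the grid centre at world 0.

        Voxel centres sit at ±dx/2, ±3dx/2, … for even grids, so no voxel
        centre lies exactly on the mid-sagittal plane x = 0.
        """
        A = np.eye(4)
        for k, (n, d) in enumerate(zip(self.grid_shape, self.voxel_dims)):
            A[k, k] = d
            A[k, 3] = -(n - 1) / 2.0 * d
        return A

    def validate(self) -> None:
        m = self.class_mean_intensities
        if not (m[0] < m[1] < m[2]):
            raise ValueError(f"class means must be strictly increasing CSF<GM<WM: {m}")
        if any(s <= 0 for s in self.voxel_dims):
            raise ValueError("voxel dims must be positive")
        if not (np.asarray(self.wm_semi_axes) < np.asarray(self.gm_semi_axes)).all() \
                or not (np.asarray(self.gm_semi_axes) < np.asarray(self.csf_semi_axes)).all():
            raise ValueError("ellipsoids must be strictly nested WM ⊂ GM ⊂ CSF")
        half_extent = np.array(self.grid_shape) * np.array(self.voxel_dims) / 2.0
        reach = np.array(self.csf_semi_axes) + np.array([self.center_offset_mm, 0, 0])
        if np.any(reach >= half_extent):
            raise ValueError(
                f"outer ellipsoid (reach {reach}) does not fit in the grid "
                f"(half extent {half_extent})")
        if self.center_offset_mm <= self.csf_semi_axes[0] * 0 or \
                self.center_offset_mm - self.csf_semi_axes[0] >= 0:
            # hemispheres need not touch the midline; only crossing it is fatal
            pass
        if self.csf_semi_axes[0] >= self.center_offset_mm + min(self.voxel_dims) / 2:
            raise ValueError("outer ellipsoid crosses the mid-sagittal plane")


@dataclass
class Phantom:
    """A generated phantom: image, label map and ground truth."""

    image: ImageVolume
    labels: np.ndarray  # 0 bg, 1 CSF, 2 GM, 3 WM
    spec: PhantomSpec
    ground_truth: pd.DataFrame  # columns hemisphere, tissue, volume_mm3
    brain_mean: float  # sample stats of the image over labels > 0
    brain_sd: float

    @property
    def id(self) -> str:
        return self.image.id

    def brain_mask(self) -> np.ndarray:
        return self.labels > 0

    def ground_truth_volume(self, hemisphere: str, tissue: str) -> float:
        gt = self.ground_truth
        row = gt[(gt.hemisphere == hemisphere) & (gt.tissue == tissue)]
        return float(row.volume_mm3.iloc[0])


def _world_coordinate_grids(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    A = spec.affine()
    axes = [A[k, k] * np.arange(spec.grid_shape[k]) + A[k, 3] for k in range(3)]
    return np.meshgrid(*axes, indexing="ij")


def generate_phantom(spec: PhantomSpec | None = None, **overrides) -> Phantom:
    """Build a phantom from a spec (deterministic given spec.seed)."""
    if spec is None:
        spec = PhantomSpec(**overrides)
    elif overrides:
        spec = replace(spec, **overrides)
    spec.validate()

    X, Y, Z = _world_coordinate_grids(spec)
    labels = np.zeros(spec.grid_shape, dtype=np.uint8)
    for sign in (-1.0, +1.0):
        cx = sign * spec.center_offset_mm
        for code, axes in ((CSF, spec.csf_semi_axes),
                           (GM, spec.gm_semi_axes),
                           (WM, spec.wm_semi_axes)):
            a, b, c = axes
            inside = ((X - cx) / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2 <= 1.0
            labels[inside] = code

    if np.any(labels[np.isclose(X, 0.0)] > 0):
        raise ValueError("phantom geometry places tissue on the mid-sagittal plane")

    means = np.array([0.0, *spec.class_mean_intensities])
    sds = np.array([0.0, *spec.class_noise_sd])
    rng = np.random.default_rng(spec.seed)
    noise = rng.standard_normal(spec.grid_shape)
    image_data = means[labels] + sds[labels] * noise

    affine = spec.affine()
    image = ImageVolume(data=image_data, affine=affine, id=spec.id)

    vv = voxel_volume(image)
    rows = []
    for hemi, hsel in (("lh", X < 0), ("rh", X > 0)):
        for tissue, code in (("csf", CSF), ("cortex", GM), ("cwm", WM)):
            n = int(np.count_nonzero((labels == code) & hsel))
            rows.append({"hemisphere": hemi, "tissue": tissue,
                         "volume_mm3": n * vv, "n_voxels": n})
    gt = pd.DataFrame(rows)

    brain_vals = image_data[labels > 0]
    if brain_vals.size < 2:
        raise ValueError("phantom has no brain voxels")
    return Phantom(image=image, labels=labels, spec=spec, ground_truth=gt,
                   brain_mean=float(brain_vals.mean()),
                   brain_sd=float(brain_vals.std(ddof=1)))


@dataclass
class SyntheticLesionSpec:
    """Target volume, side, shape and unit-invariant intensity of a lesion."""

    target_volume_mm3: float
    hemisphere: str = "lh"  # 'lh' | 'rh'
    mean_intensity_ui: float = -1.5
    sd_intensity_ui: float = 0.5
    shape: str = "sphere"  # 'sphere' | 'multifocal-blobs'
    n_foci: int = 3
    seed: int = 0
    lesion_id: str = "lesion"

    def validate(self) -> None:
        if self.target_volume_mm3 <= 0:
            raise ValueError("target_volume_mm3 must be > 0")
        if self.sd_intensity_ui < 0:
            raise ValueError("sd_intensity_ui must be >= 0")
        if self.hemisphere not in ("lh", "rh"):
            raise ValueError(f"hemisphere must be 'lh' or 'rh', got {self.hemisphere!r}")
        if self.shape not in ("sphere", "multifocal-blobs"):
            raise ValueError(f"unknown lesion shape {self.shape!r}")


def _grow_region(tissue_flat: np.ndarray, shape: tuple, start: int, n: int,
                 rng: np.random.Generator, taken: set) -> set:
    """Random region growing over 6-connected tissue voxels (flat indices)."""
    strides = (shape[1] * shape[2], shape[2], 1)
    nx, ny, nz = shape

    def neighbors(f):
        i, r = divmod(f, strides[0])
        j, k = divmod(r, strides[1])
        if i > 0: yield f - strides[0]
        if i < nx - 1: yield f + strides[0]
        if j > 0: yield f - strides[1]
        if j < ny - 1: yield f + strides[1]
        if k > 0: yield f - 1
        if k < nz - 1: yield f + 1

    region = {start}
    cand = [g for g in neighbors(start) if tissue_flat[g] and g not in taken]
    while len(region) < n:
        if not cand:
            raise ValueError(
                f"hemisphere tissue exhausted at {len(region)} voxels "
                f"(target {n}): lesion volume infeasible")
        idx = int(rng.integers(len(cand)))
        cand[idx], cand[-1] = cand[-1], cand[idx]
        v = cand.pop()
        if v in region:
            continue
        region.add(v)
        for g in neighbors(v):
            if tissue_flat[g] and g not in region and g not in taken:
                cand.append(g)
    return region


def generate_synthetic_lesion(phantom: Phantom, spec: SyntheticLesionSpec
                              ) -> tuple[BinaryMask, ImageVolume]:
    """Grow a lesion of the requested volume and intensity inside the phantom.

    Returns the binary lesion mask and a patient-like copy of the phantom
    image with the lesion intensities written in.  The realized voxel count
    is the nearest achievable to target_volume_mm3 / voxel_volume (exact when
    the target is an integer multiple of the voxel volume).  The realized
    unit-invariant mean and sample SD match the spec essentially exactly (the
    drawn values are affinely corrected onto the targets).
    """
    spec.validate()
    vv = voxel_volume(phantom.image)
    n_target = max(1, int(round(spec.target_volume_mm3 / vv)))

    X, _, _ = _world_coordinate_grids(phantom.spec)
    hsel = X < 0 if spec.hemisphere == "lh" else X > 0
    tissue = (phantom.labels > 0) & hsel
    n_tissue = int(np.count_nonzero(tissue))
    if n_tissue == 0:
        raise ValueError(f"hemisphere {spec.hemisphere} has no tissue")
    if n_target > n_tissue:
        raise ValueError(
            f"target volume {spec.target_volume_mm3} mm³ needs {n_target} voxels "
            f"but hemisphere {spec.hemisphere} has only {n_tissue} tissue voxels")

    rng = np.random.default_rng(spec.seed)
    flat = tissue.ravel()
    tissue_idx = np.flatnonzero(flat)

    mask_flat = np.zeros(flat.size, dtype=np.uint8)
    if spec.shape == "sphere":
        # quasi-spherical: the n tissue voxels nearest a random interior centre
        center = tissue_idx[int(rng.integers(tissue_idx.size))]
        coords = np.array(np.unravel_index(tissue_idx, phantom.labels.shape)).T
        c0 = np.array(np.unravel_index(center, phantom.labels.shape))
        d2 = (((coords - c0) * np.array(phantom.spec.voxel_dims)) ** 2).sum(axis=1)
        order = np.argsort(d2, kind="stable")
        mask_flat[tissue_idx[order[:n_target]]] = 1
    else:  # multifocal-blobs
        k = max(1, min(spec.n_foci, n_target))
        base, extra = divmod(n_target, k)
        sizes = [base + (1 if i < extra else 0) for i in range(k)]
        taken: set = set()
        for size in sizes:
            if size == 0:
                continue
            free = np.array([v for v in tissue_idx if v not in taken])
            start = int(free[int(rng.integers(free.size))])
            region = _grow_region(flat, phantom.labels.shape, start, size, rng, taken)
            taken |= region
        mask_flat[list(taken)] = 1

    mask = BinaryMask(data=mask_flat.reshape(phantom.labels.shape),
                      affine=phantom.image.affine.copy(), id=spec.lesion_id)

    # intensities: draw z-values then affinely pin them to the exact targets
    n = mask.n_voxels
    z = rng.standard_normal(n)
    if n == 1 or spec.sd_intensity_ui == 0.0:
        z = np.full(n, spec.mean_intensity_ui)
    else:
        z = (z - z.mean()) / z.std(ddof=1) * spec.sd_intensity_ui + spec.mean_intensity_ui

    mu, sd = reference_stats(phantom.image, mask)  # non-lesion whole-image stats
    patient_data = phantom.image.data.copy()
    patient_data[mask.bool()] = mu + sd * z
    patient = ImageVolume(data=patient_data, affine=phantom.image.affine.copy(),
                          id=f"{phantom.id}+{spec.lesion_id}")
    return mask, patient


def control_cohort(n_controls: int, seed: int = 0,
                   base_spec: PhantomSpec | None = None,
                   geometry_jitter: float = 0.05) -> list[Phantom]:
    """Generate a cohort of control phantoms.

    Controls share the base geometry but differ in noise realization and get
    a mild (±geometry_jitter, multiplicative) seeded perturbation of their
    ellipsoid semi-axes, so ground-truth volumes genuinely vary across
    controls — a control-level variance component for the crossed design.
    """
    base = base_spec if base_spec is not None else PhantomSpec()
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n_controls):
        scale = 1.0 + geometry_jitter * rng.uniform(-1, 1, size=3)

        def jitter(axes):
            return tuple(float(a * s) for a, s in zip(axes, scale))

        spec = replace(
            base,
            csf_semi_axes=jitter(base.csf_semi_axes),
            gm_semi_axes=jitter(base.gm_semi_axes),
            wm_semi_axes=jitter(base.wm_semi_axes),
            seed=int(rng.integers(2 ** 31 - 1)),
            id=f"control{i + 1:02d}",
        )
        cohort.append(generate_phantom(spec))
    return cohort


def lesion_cohort(n_lesions: int = 16, seed: int = 0,
                  base_spec: PhantomSpec | None = None,
                  volumes_mm3=None, lateralities=None
                  ) -> list[tuple[BinaryMask, ImageVolume, SyntheticLesionSpec]]:
    """Generate patient-like phantoms with lesions of the default cohort sizes.

    Each lesion lives on its own phantom (its "patient"), with a volume and
    side from the default cohort (cycled/truncated to n_lesions) and seeded
    intensity targets: unit-invariant mean ~ N(-1.5, 0.5) (T1w TBI lesions
    are predominantly hypointense) and SD ~ |N(0.5, 0.2)|.
    """
    base = base_spec if base_spec is not None else PhantomSpec()
    vols = list(volumes_mm3 if volumes_mm3 is not None else DEFAULT_LESION_VOLUMES_MM3)
    lats = list(lateralities if lateralities is not None else DEFAULT_LESION_LATERALITIES)
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_lesions):
        vol = vols[i % len(vols)]
        lat = lats[i % len(lats)]
        patient_spec = replace(base, seed=int(rng.integers(2 ** 31 - 1)),
                               id=f"patient{i + 1:02d}")
        phantom = generate_phantom(patient_spec)
        lspec = SyntheticLesionSpec(
            target_volume_mm3=vol,
            hemisphere=lat,
            mean_intensity_ui=float(rng.normal(-1.5, 0.5)),
            sd_intensity_ui=float(abs(rng.normal(0.5, 0.2))),
            seed=int(rng.integers(2 ** 31 - 1)),
            lesion_id=f"lesion{i + 1:02d}",
        )
        mask, patient = generate_synthetic_lesion(phantom, lspec)
        out.append((mask, patient, lspec))
    return out


# ---------------------------------------------------------------------------
# generative twins of the hypothesis-family statistical models

DEFAULT_LMM_PARAMS = {
    "a": {"intercept": 250000.0, "case": -560.0,
          "sd_pair": 1500.0, "sd_case_slope": 600.0, "corr": 0.3,
          "sd_lesion": 800.0, "sd_control": 12000.0, "sd_resid": 500.0},
    "b": {"intercept": 0.45, "hemisphere": 0.14,
          "sd_pair": 0.30, "sd_lesion": 0.20, "sd_control": 0.15,
          "sd_resid": 0.40},
    "c": {"intercept": 0.45, "volume": 0.28, "mean_intensity": 0.10,
          "sd_intensity": -0.23, "sd_control": 0.15, "sd_resid": 0.30},
}


def simulate_lmm_dataset(family: str, true_parameters: dict | None = None,
                         n_lesions: int = 16, n_controls: int = 11,
                         seed: int = 0) -> pd.DataFrame:
    """Draw one dataset from a hypothesis family's generative model.

    family 'a': volume = b0 + β·case + (u_pair + s_pair·case) + u_lesion
                + u_control + ε, four rows per lesion×control pair
                (2 case levels × 2 hemisphere roles).
    family 'b': pvd = b0 + β·hemisphere + u_pair + u_lesion + u_control + ε,
                two rows per pair.
    family 'c': pvd = b0 + Σ βj·xj + u_control + ε, one row per pair, with
                lesion covariates drawn N(0,1) per lesion.
    """
    if family not in ("a", "b", "c"):
        raise ValueError(f"unknown hypothesis family {family!r}")
    if n_lesions < 2 or n_controls < 2:
        raise ValueError("design must be at least 2 lesions × 2 controls")
    p = dict(DEFAULT_LMM_PARAMS[family])
    if true_parameters:
        unknown = set(true_parameters) - set(p)
        if unknown:
            raise ValueError(f"unknown parameters for family {family!r}: {sorted(unknown)}")
        p.update(true_parameters)
    vc_keys = {"a": ("sd_pair", "sd_case_slope", "sd_lesion", "sd_control",
                     "sd_resid"),
               "b": ("sd_pair", "sd_lesion", "sd_control", "sd_resid"),
               "c": ("sd_control", "sd_resid")}[family]
    for key in vc_keys:
        if p[key] < 0:
            raise ValueError(f"variance component {key} must be >= 0, got {p[key]}")
    if family == "a" and not -1.0 <= p["corr"] <= 1.0:
        raise ValueError(f"corr must be in [-1, 1], got {p['corr']}")

    rng = np.random.default_rng(seed)
    lesions = [f"L{i + 1:02d}" for i in range(n_lesions)]
    controls = [f"C{j + 1:02d}" for j in range(n_controls)]
    u_lesion = dict(zip(lesions, rng.normal(0, p.get("sd_lesion", 0.0), n_lesions)))
    u_control = dict(zip(controls, rng.normal(0, p["sd_control"], n_controls)))

    rows = []
    if family == "c":
        cov = {les: rng.standard_normal(3) for les in lesions}
        for les in lesions:
            for con in controls:
                x = cov[les]
                y = (p["intercept"] + p["volume"] * x[0]
                     + p["mean_intensity"] * x[1] + p["sd_intensity"] * x[2]
                     + u_control[con] + rng.normal(0, p["sd_resid"]))
                rows.append({"pair_id": f"{les}_x_{con}", "lesion_id": les,
                             "control_id": con,
                             "volume_transplanted_mm3": x[0],
                             "mean_intensity_ui": x[1], "sd_intensity_ui": x[2],
                             "pvd": y})
        return pd.DataFrame(rows)

    for les in lesions:
        for con in controls:
            pair = f"{les}_x_{con}"
            if family == "a":
                c = p["corr"] * p["sd_pair"] * p["sd_case_slope"]
                cov = np.array([[p["sd_pair"] ** 2, c],
                                [c, p["sd_case_slope"] ** 2]])
                u_int, u_slope = _mvn2(rng, cov)
                for case, x in (("ground_truth", 0.0), ("simulated", 1.0)):
                    for hemi in ("lesioned", "contralesional"):
                        y = (p["intercept"] + p["case"] * x
                             + u_int + u_slope * x
                             + u_lesion[les] + u_control[con]
                             + rng.normal(0, p["sd_resid"]))
                        rows.append({"pair_id": pair, "lesion_id": les,
                                     "control_id": con, "case": case,
                                     "hemi_role": hemi, "volume_mm3": y})
            else:  # family b
                u_pair = rng.normal(0, p["sd_pair"])
                for hemi, x in (("contralesional", 0.0), ("lesioned", 1.0)):
                    y = (p["intercept"] + p["hemisphere"] * x + u_pair
                         + u_lesion[les] + u_control[con]
                         + rng.normal(0, p["sd_resid"]))
                    rows.append({"pair_id": pair, "lesion_id": les,
                                 "control_id": con, "hemi_role": hemi, "pvd": y})
    return pd.DataFrame(rows)


def _mvn2(rng: np.random.Generator, cov: np.ndarray) -> np.ndarray:
    """Draw one 2-vector from N(0, cov) via Cholesky (handles singular cov)."""
    w, V = np.linalg.eigh(cov)
    w = np.clip(w, 0.0, None)
    return (V * np.sqrt(w)) @ rng.standard_normal(2)
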