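"""Synthetic cohort and volume generator with known ground truth.

Emulates preprocessed, spatially normalized and smoothed VBM-style tissue
volume maps: a smooth baseline field, regionally varying age decline, a sex
offset, spatially correlated (Gaussian-smoothed) noise, idiosyncratic focal
lesions in patients with low between-patient overlap, and one small shared
effect region. Everything is deterministic under the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from normdev.io import VolumeStack, write_cohort, write_map, write_volumes_4d


class ConfigurationError(ValueError):
    pass


def fwhm_to_sigma(fwhm: float) -> float:
    """FWHM -> standard deviation of a Gaussian: sigma = FWHM / (2 sqrt(2 ln 2))."""
    return float(fwhm) / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def smooth_field(field: np.ndarray, fwhm_mm: float, voxel_size_mm: float) -> np.ndarray:
    """Separable discrete Gaussian smoothing, reflect boundary handling."""
    if fwhm_mm <= 0:
        return np.asarray(field, dtype=float)
    sigma_vox = fwhm_to_sigma(fwhm_mm) / float(voxel_size_mm)
    return ndimage.gaussian_filter(np.asarray(field, dtype=float), sigma_vox, mode="reflect")


def smoothing_variance_factor(fwhm_mm: float, voxel_size_mm: float, ndim: int = 3) -> float:
    """Factor by which smoothing shrinks the variance of white noise.

    For a separable filter the factor is ``(sum_i w_i^2)^ndim`` where ``w``
    are the discrete 1D kernel weights (evaluated away from boundaries).
    """
    if fwhm_mm <= 0:
        return 1.0
    sigma_vox = fwhm_to_sigma(fwhm_mm) / float(voxel_size_mm)
    # recover scipy's truncated kernel from its impulse response
    half = int(4.0 * sigma_vox + 0.5)
    impulse = np.zeros(2 * (2 * half + 1) + 1)
    impulse[len(impulse) // 2] = 1.0
    weights = ndimage.gaussian_filter1d(impulse, sigma_vox, mode="constant")
    return float(np.sum(weights**2) ** ndim)


def default_mask(grid_shape: Sequence[int], margin: float = 2.0) -> np.ndarray:
    """Ellipsoidal analysis mask inscribed in the grid with a border margin."""
    shape = tuple(int(s) for s in grid_shape)
    center = (np.asarray(shape) - 1) / 2.0
    semi = np.maximum((np.asarray(shape) - 1) / 2.0 - margin, 1.0)
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    return r2 <= 1.0


def octant_labels(grid_shape: Sequence[int]) -> np.ndarray:
    """Coarse 2x2x2 partition of the grid into region labels 0..7."""
    nx, ny, nz = (int(s) for s in grid_shape)
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    return (
        (ii >= nx // 2).astype(int) * 4
        + (jj >= ny // 2).astype(int) * 2
        + (kk >= nz // 2).astype(int)
    )


def sphere_offsets(radius: int) -> np.ndarray:
    """Integer offsets of voxels within Euclidean distance ``radius`` of 0."""
    r = int(radius)
    rng = np.arange(-r, r + 1)
    ii, jj, kk = np.meshgrid(rng, rng, rng, indexing="ij")
    inside = ii**2 + jj**2 + kk**2 <= r**2
    return np.stack([ii[inside], jj[inside], kk[inside]], axis=1)


# Steeper decline in the "frontal-like" anterior octants (labels 0-3), milder
# elsewhere; units are volume units per year.
DEFAULT_AGE_SLOPES: Mapping[int, float] = {
    0: -0.060, 1: -0.055, 2: -0.050, 3: -0.045,
    4: -0.025, 5: -0.020, 6: -0.015, 7: -0.010,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of the synthetic cohort; seed determines all output."""

    n_controls: int = 100
    n_patients: int = 100
    grid_shape: tuple[int, int, int] = (20, 20, 20)
    # 4 mm voxels keep the 8 mm smoothing kernel below one voxel sd, so the
    # 20^3 desk-scale grid retains enough independent spatial patches for
    # group inference (heavier correlation leaves too few noise dof and lets
    # chance global shifts masquerade as group effects)
    voxel_size: float = 4.0
    smoothing_fwhm: float = 8.0
    regional_age_slopes: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_AGE_SLOPES)
    )
    sex_offset: float = 1.5
    noise_sd: float = 2.0
    n_idiosyncratic_lesions: int = 3
    # radius 0 implants single-voxel lesions; keep the total lesion volume far
    # below the mask volume or idiosyncratic deviations start to overlap by
    # construction (300 radius-1 lesions already cover ~1/6 of a 20^3 mask)
    lesion_radius: int = 0
    lesion_effect: float = -4.0  # multiples of noise_sd, signed
    # optional age dependence of the per-patient lesion count: the count is
    # scaled by (1 + gradient * standardized age), clipped at zero
    lesion_age_gradient: float = 0.0
    shared_roi: tuple[tuple[int, int, int], ...] | None = None
    shared_roi_radius: int = 3
    shared_effect: float = -1.0  # multiples of noise_sd, signed
    mask_margin: float = 2.0
    age_min: float = 18.0
    age_max: float = 65.0
    # truncated-Poisson symptom score means (0-9 scale)
    patient_symptom_mean: float = 7.0
    control_symptom_mean: float = 1.0
    patient_medication_rate: float = 0.7
    patient_comorbidity_mean: float = 0.8
    baseline_level: float = 60.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_controls < 0 or self.n_patients < 0:
            raise ConfigurationError("group sizes must be nonnegative")
        if self.n_controls + self.n_patients < 1:
            raise ConfigurationError("cohort must contain at least one subject")
        if any(s <= 0 for s in self.grid_shape) or len(self.grid_shape) != 3:
            raise ConfigurationError("grid_shape must be three positive integers")
        if self.voxel_size <= 0:
            raise ConfigurationError("voxel_size must be positive")
        if not np.isfinite(self.lesion_effect) or not np.isfinite(self.shared_effect):
            raise ConfigurationError("effects must be finite")
        if self.lesion_radius < 0 or 2 * self.lesion_radius + 1 > min(self.grid_shape):
            raise ConfigurationError("lesion radius exceeds grid")
        if self.age_min >= self.age_max:
            raise ConfigurationError("age_min must be below age_max")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")

    def mask(self) -> np.ndarray:
        return default_mask(self.grid_shape, self.mask_margin)

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size
        return aff

    def shared_roi_mask(self) -> np.ndarray:
        """Boolean map of the shared-effect region (must lie inside the mask)."""
        mask = self.mask()
        roi = np.zeros(self.grid_shape, dtype=bool)
        if self.shared_roi is not None:
            for ijk in self.shared_roi:
                roi[tuple(int(v) for v in ijk)] = True
        else:
            center = tuple(int(s) // 2 + int(s) // 8 for s in self.grid_shape)
            for off in sphere_offsets(self.shared_roi_radius):
                idx = tuple(int(c + o) for c, o in zip(center, off))
                if all(0 <= v < s for v, s in zip(idx, self.grid_shape)):
                    roi[idx] = True
            roi &= mask
        if not (roi <= mask).all():
            raise ConfigurationError("shared_roi must be a subset of the analysis mask")
        return roi


@dataclass
class GroundTruth:
    """Implanted-effect bookkeeping for recovery tests.

    ``deviation_masks[i]`` marks every voxel of patient ``i`` carrying an
    implanted effect (idiosyncratic lesions plus the shared region);
    ``lesion_masks`` holds the idiosyncratic part only.
    """

    patient_ids: list[str]
    deviation_masks: np.ndarray  # (n_patients, nx, ny, nz) bool
    lesion_masks: np.ndarray  # (n_patients, nx, ny, nz) bool
    shared_roi_mask: np.ndarray  # (nx, ny, nz) bool
    effect_signs: list[list[str]]  # per patient, per lesion: "positive"/"negative"
    slope_field: np.ndarray  # per-voxel true age slope
    sex_offset: float

    def to_manifest(self) -> dict:
        return {
            "patient_ids": self.patient_ids,
            "effect_signs": self.effect_signs,
            "sex_offset": self.sex_offset,
            "n_shared_roi_voxels": int(self.shared_roi_mask.sum()),
        }


def _truncated_poisson(rng: np.random.Generator, mean: float, size: int, high: int = 9) -> np.ndarray:
    return np.clip(rng.poisson(mean, size=size), 0, high)


def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Generate demographics: matched age/sex structure, elevated patient scores."""
    config.validate()
    rng = np.random.default_rng([int(config.seed), 11])
    rows = []
    for group, n in (("control", config.n_controls), ("patient", config.n_patients)):
        if n == 0:
            continue
        ages = rng.uniform(config.age_min, config.age_max, size=n)
        sexes = rng.choice(["female", "male"], size=n)
        mean = config.control_symptom_mean if group == "control" else config.patient_symptom_mean
        hyper = _truncated_poisson(rng, mean, n)
        inatt = _truncated_poisson(rng, mean, n)
        if group == "patient":
            medication = np.where(
                rng.random(n) < config.patient_medication_rate, "yes", "no"
            )
            comorbidity = rng.poisson(config.patient_comorbidity_mean, size=n)
        else:
            medication = np.full(n, "no")
            comorbidity = np.zeros(n, dtype=int)
        prefix = "con" if group == "control" else "pat"
        for i in range(n):
            rows.append(
                {
                    "subject_id": f"{prefix}-{i + 1:04d}",
                    "age": float(ages[i]),
                    "sex": str(sexes[i]),
                    "diagnosis": group,
                    "hyperactivity": int(hyper[i]),
                    "inattention": int(inatt[i]),
                    "medication": str(medication[i]),
                    "comorbidity": int(comorbidity[i]),
                }
            )
    return pd.DataFrame(rows)


def _baseline_field(config: SimulationConfig) -> np.ndarray:
    """Smooth low-order polynomial baseline over normalized voxel coordinates."""
    nx, ny, nz = config.grid_shape
    x = np.linspace(-1, 1, nx)[:, None, None]
    y = np.linspace(-1, 1, ny)[None, :, None]
    z = np.linspace(-1, 1, nz)[None, None, :]
    return config.baseline_level * (1.0 - 0.15 * x**2 - 0.10 * y**2 - 0.12 * z**2 + 0.05 * x * y)


def slope_field(config: SimulationConfig) -> np.ndarray:
    labels = octant_labels(config.grid_shape)
    out = np.zeros(config.grid_shape, dtype=float)
    for label, slope in config.regional_age_slopes.items():
        out[labels == int(label)] = float(slope)
    return out


def generate_volumes(
    cohort: pd.DataFrame, config: SimulationConfig
) -> tuple[VolumeStack, GroundTruth]:
    """Generate per-subject volumes plus ground truth of implanted effects.

    Each volume is baseline + age*slope_field + sex_offset*(sex==male) +
    smoothed noise (normalized so the marginal per-voxel sd equals
    ``noise_sd``). Patients additionally receive ``n_idiosyncratic_lesions``
    spherical effects at independent uniform in-mask locations and the shared
    region effect.
    """
    config.validate()
    if len(cohort) == 0:
        raise ConfigurationError("cohort is empty")
    rng = np.random.default_rng([int(config.seed), 23])
    mask = config.mask()
    slopes = slope_field(config)
    baseline = _baseline_field(config)
    shared_roi = config.shared_roi_mask()
    norm = np.sqrt(smoothing_variance_factor(config.smoothing_fwhm, config.voxel_size))

    # lesion centers restricted so the whole sphere stays inside the mask
    offsets = sphere_offsets(config.lesion_radius)
    struct = np.zeros((2 * config.lesion_radius + 1,) * 3, dtype=bool)
    struct[tuple((offsets + config.lesion_radius).T)] = True
    eroded = ndimage.binary_erosion(mask, structure=struct, border_value=0)
    valid_centers = np.argwhere(eroded)
    any_patients = bool((cohort["diagnosis"] == "patient").any())
    if any_patients and config.n_idiosyncratic_lesions > 0 and len(valid_centers) == 0:
        raise ConfigurationError("lesion radius leaves no valid in-mask placement")

    patients = cohort.loc[cohort["diagnosis"] == "patient", "subject_id"].tolist()
    n_pat = len(patients)
    lesion_masks = np.zeros((n_pat, *config.grid_shape), dtype=bool)
    effect_signs: list[list[str]] = [[] for _ in range(n_pat)]

    data = np.empty((len(cohort), *config.grid_shape), dtype=float)
    pat_pos = 0
    for row_i, row in enumerate(cohort.itertuples(index=False)):
        noise = rng.standard_normal(config.grid_shape)
        noise = smooth_field(noise, config.smoothing_fwhm, config.voxel_size) / norm
        vol = (
            baseline
            + row.age * slopes
            + (config.sex_offset if row.sex == "male" else 0.0)
            + config.noise_sd * noise
        )
        if row.diagnosis == "patient":
            n_lesions = config.n_idiosyncratic_lesions
            if config.lesion_age_gradient != 0.0:
                age_mid = 0.5 * (config.age_min + config.age_max)
                age_half = 0.5 * (config.age_max - config.age_min)
                age_std = (row.age - age_mid) / age_half
                n_lesions = max(
                    0,
                    int(round(n_lesions * (1.0 + config.lesion_age_gradient * age_std))),
                )
            for _ in range(n_lesions):
                center = valid_centers[rng.integers(len(valid_centers))]
                idx = tuple((center + offsets).T)
                vol[idx] += config.lesion_effect * config.noise_sd
                lesion_masks[pat_pos][idx] = True
                effect_signs[pat_pos].append(
                    "positive" if config.lesion_effect > 0 else "negative"
                )
            vol[shared_roi] += config.shared_effect * config.noise_sd
            pat_pos += 1
        data[row_i] = vol

    deviation_masks = lesion_masks.copy()
    if config.shared_effect != 0.0 and n_pat:
        deviation_masks |= shared_roi[None, :, :, :]
    truth = GroundTruth(
        patient_ids=patients,
        deviation_masks=deviation_masks,
        lesion_masks=lesion_masks,
        shared_roi_mask=shared_roi,
        effect_signs=effect_signs,
        slope_field=slopes,
        sex_offset=config.sex_offset,
    )
    stack = VolumeStack(data, cohort["subject_id"].tolist(), mask, config.affine())
    return stack, truth


def simulate_dataset(config: SimulationConfig) -> tuple[pd.DataFrame, VolumeStack, GroundTruth]:
    cohort = generate_cohort(config)
    stack, truth = generate_volumes(cohort, config)
    return cohort, stack, truth


def write_simulation(
    out_dir: str | Path,
    cohort: pd.DataFrame,
    stack: VolumeStack,
    truth: GroundTruth,
) -> dict[str, str]:
    """Write covariates CSV, 4D volumes, mask and ground truth to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "covariates": write_cohort(cohort, out / "covariates.csv"),
        "volumes": write_volumes_4d(stack, out / "volumes_4d.nii"),
        "mask": write_map(stack.mask, stack.affine, out / "mask.nii"),
        "shared_roi": write_map(
            truth.shared_roi_mask, stack.affine, out / "truth_shared_roi.nii"
        ),
    }
    for i, pid in enumerate(truth.patient_ids):
        paths[f"truth_{pid}"] = write_map(
            truth.deviation_masks[i], stack.affine, out / f"truth_{pid}.nii"
        )
    manifest = truth.to_manifest()
    # record paths relative to the output directory so reruns are byte-identical
    manifest["files"] = {k: str(p.relative_to(out)) for k, p in paths.items()}
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return {k: str(p) for k, p in paths.items()}
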