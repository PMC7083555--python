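"""End-to-end pipeline: simulate -> fit/crossval -> score -> deviations ->
overlap -> group inference -> score tests, with a checksummed run manifest.

Every stochastic stage takes an explicit seed from the config, so re-running
with the same config reproduces byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import normdev
from normdev import io as ndio
from normdev.deviations import extreme_masks, extreme_scores, overlap_map
from normdev.inference import (
    TfceParams,
    association_tests,
    group_contrast_map,
    group_mean_map,
    holm_correct,
    score_group_test,
)
from normdev.normative import (
    DeviationStack,
    ReferenceModel,
    _FittedSet,
    crossval_reference,
    fit_reference,
    score_targets,
)
from normdev.simulate import SimulationConfig, simulate_dataset, write_simulation

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration for a full run; round-trips losslessly through YAML."""

    # input paths (ignored when simulate=True)
    volumes: str | None = None
    covariates: str | None = None
    mask: str | None = None
    simulate: bool = True
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides
    # model options
    kfold: int = 10
    separate_sexes: bool = False
    hyper_voxels: int | None = None  # fast path: share hyperparameters, off by default
    scale_mode: str = "global"  # voxel normalization in the fast path
    n_restarts: int = 3
    # thresholds
    z_threshold: float = 2.6
    fdr_q: float = 0.05
    overlap_cut: float = 0.02
    # inference options
    n_perm: int = 500
    tfce_h: float = 2.0
    tfce_e: float = 0.5
    tfce_dh: float | None = None
    tfce_connectivity: int = 26
    contrast_fdr_q: float = 0.05
    score_test_n_perm: int = 0
    association_family_size: int = 8
    # one seed per stochastic stage
    seed_simulate: int = 0
    seed_folds: int = 1
    seed_fit: int = 2
    seed_perm: int = 3
    seed_scoretests: int = 4

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(**{**self.simulation, "seed": self.seed_simulate})

    def tfce_params(self) -> TfceParams:
        return TfceParams(
            H=self.tfce_h, E=self.tfce_e, dh=self.tfce_dh, connectivity=self.tfce_connectivity
        )

    def validate_paths(self) -> None:
        if self.simulate:
            return
        for name in ("volumes", "covariates", "mask"):
            value = getattr(self, name)
            if value is None or not Path(value).exists():
                raise FileNotFoundError(f"config path {name!r} missing or not found: {value}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def save_reference(model: ReferenceModel, cohort: pd.DataFrame, model_dir: str | Path) -> Path:
    """Persist a fitted reference: JSON hyperparameter records + array store."""
    model_dir = Path(model_dir)
    model_dir.mkdir(parents=True, exist_ok=True)
    arrays: dict[str, np.ndarray] = {"mask": model.mask, "affine": model.affine}
    meta: dict = {"separate_sexes": model.separate_sexes, "sets": {}}
    voxel_indices = np.argwhere(model.mask)
    for key, fs in model.sets.items():
        prefix = f"{key}__"
        arrays[prefix + "x_mean"] = fs.x_mean
        arrays[prefix + "x_scale"] = fs.x_scale
        arrays[prefix + "Xs_train"] = fs.Xs_train
        arrays[prefix + "y_mean"] = fs.y_mean
        arrays[prefix + "y_scale"] = fs.y_scale
        if fs.shared:
            arrays[prefix + "log_params"] = fs.log_params
            arrays[prefix + "L"] = fs.L
            arrays[prefix + "alpha"] = fs.alpha
            arrays[prefix + "mean_var"] = np.array(fs.mean_var)
            meta["sets"][key] = {
                "shared": True,
                "hyperparameters": {"shared": list(map(float, np.exp(fs.log_params)))},
            }
        else:
            per_voxel = np.array([m.log_params for m in fs.models])
            arrays[prefix + "log_params"] = per_voxel
            arrays[prefix + "y_train"] = np.column_stack(
                [m.y_train if m.y_train is not None else np.zeros(len(fs.Xs_train)) for m in fs.models]
            )
            arrays[prefix + "degenerate"] = np.array([m.degenerate for m in fs.models])
            meta["sets"][key] = {
                "shared": False,
                "hyperparameters": {
                    ",".join(map(str, voxel_indices[j])): list(map(float, np.exp(per_voxel[j])))
                    for j in range(per_voxel.shape[0])
                },
            }
    np.savez(model_dir / "reference_arrays.npz", **arrays)
    with open(model_dir / "model.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    cohort.to_csv(model_dir / "training_cohort.csv", index=False)
    return model_dir


def load_reference(model_dir: str | Path) -> ReferenceModel:
    model_dir = Path(model_dir)
    with open(model_dir / "model.json") as fh:
        meta = json.load(fh)
    npz = np.load(model_dir / "reference_arrays.npz")
    sets: dict[str, _FittedSet] = {}
    for key, info in meta["sets"].items():
        prefix = f"{key}__"
        if info["shared"]:
            sets[key] = _FittedSet(
                shared=True,
                log_params=npz[prefix + "log_params"],
                x_mean=npz[prefix + "x_mean"],
                x_scale=npz[prefix + "x_scale"],
                Xs_train=npz[prefix + "Xs_train"],
                y_mean=npz[prefix + "y_mean"],
                y_scale=npz[prefix + "y_scale"],
                L=npz[prefix + "L"],
                alpha=npz[prefix + "alpha"],
                models=None,
                mean_var=float(npz[prefix + "mean_var"]),
            )
        else:
            from normdev.gp import VoxelNormativeModel, _factor
            from scipy import linalg

            Xs = npz[prefix + "Xs_train"]
            y_train = npz[prefix + "y_train"]
            log_params = npz[prefix + "log_params"]
            degenerate = npz[prefix + "degenerate"]
            y_mean = npz[prefix + "y_mean"]
            y_scale = npz[prefix + "y_scale"]
            models = []
            for j in range(log_params.shape[0]):
                if degenerate[j]:
                    models.append(
                        VoxelNormativeModel(
                            log_params=log_params[j],
                            x_mean=npz[prefix + "x_mean"],
                            x_scale=npz[prefix + "x_scale"],
                            y_mean=float(y_mean[j]),
                            y_scale=1.0,
                            X_train=Xs,
                            alpha=None,
                            L=None,
                            y_train=None,
                            log_marginal_likelihood=float("nan"),
                            degenerate=True,
                        )
                    )
                    continue
                L, _ = _factor(log_params[j], Xs)
                alpha = linalg.cho_solve((L, True), y_train[:, j])
                models.append(
                    VoxelNormativeModel(
                        log_params=log_params[j],
                        x_mean=npz[prefix + "x_mean"],
                        x_scale=npz[prefix + "x_scale"],
                        y_mean=float(y_mean[j]),
                        y_scale=float(y_scale[j]),
                        X_train=Xs,
                        alpha=alpha,
                        L=L,
                        y_train=y_train[:, j],
                        log_marginal_likelihood=float("nan"),
                        degenerate=False,
                    )
                )
            sets[key] = _FittedSet(
                shared=False,
                log_params=np.empty(4),
                x_mean=npz[prefix + "x_mean"],
                x_scale=npz[prefix + "x_scale"],
                Xs_train=Xs,
                y_mean=y_mean,
                y_scale=y_scale,
                L=None,
                alpha=None,
                models=models,
            )
    return ReferenceModel(sets, npz["mask"].astype(bool), npz["affine"], meta["separate_sexes"])


def write_deviation_stack(stack: DeviationStack, path: str | Path) -> Path:
    """Write a deviation stack as a 4D NIfTI (subject axis last)."""
    vols = np.stack([stack.z_volume(i) for i in range(stack.n_subjects)], axis=-1)
    if stack.n_subjects == 0:
        vols = np.zeros((*stack.mask.shape, 0))
    return ndio.write_map(vols, stack.affine, path)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute the full pipeline into ``out_dir`` and write a manifest.

    Any stage failure halts with a stage-tagged error; partial outputs are
    retained alongside a FAILED marker naming the stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "validate"
    try:
        config.validate_paths()
        config.to_yaml(out / "config.yaml")

        stage = "simulate"
        if config.simulate:
            cohort, volumes, truth = simulate_dataset(config.simulation_config())
            write_simulation(out / "data", cohort, volumes, truth)
        else:
            cohort = ndio.read_cohort(config.covariates)
            volumes = ndio.read_volumes(
                config.volumes, cohort["subject_id"].tolist(), config.mask
            )

        stage = "fit"
        z_controls = crossval_reference(
            volumes,
            cohort,
            k=config.kfold,
            seed=config.seed_folds,
            hyper_voxels=config.hyper_voxels,
            n_restarts=config.n_restarts,
            separate_sexes=config.separate_sexes,
            scale_mode=config.scale_mode,
        )
        reference = fit_reference(
            volumes,
            cohort,
            hyper_voxels=config.hyper_voxels,
            n_restarts=config.n_restarts,
            seed=config.seed_fit,
            separate_sexes=config.separate_sexes,
            scale_mode=config.scale_mode,
        )
        save_reference(reference, cohort, out / "model")

        stage = "score"
        z_patients = score_targets(volumes, cohort, reference)
        write_deviation_stack(z_controls, out / "z_controls_4d.nii")
        if z_patients.n_subjects:
            write_deviation_stack(z_patients, out / "z_patients_4d.nii")

        stage = "deviations"
        stacks = {"control": z_controls, "patient": z_patients}
        score_tables = []
        for group, stack in stacks.items():
            if stack.n_subjects == 0:
                continue
            table = extreme_scores(stack, "fixed-threshold", threshold=config.z_threshold)
            table.insert(1, "diagnosis", group)
            score_tables.append(table)
        scores = pd.concat(score_tables, ignore_index=True)
        scores.to_csv(out / "extreme_scores.csv", index=False)

        stage = "overlap"
        for group, stack in stacks.items():
            if stack.n_subjects == 0:
                continue
            masks = extreme_masks(stack, "fixed-threshold", threshold=config.z_threshold)
            for direction in ("positive", "negative"):
                om = overlap_map(masks, direction, group=group)
                ndio.write_map(om.proportion, stack.affine, out / f"overlap_{group}_{direction}.nii")
                ndio.write_map(
                    om.exceedance(config.overlap_cut),
                    stack.affine,
                    out / f"overlap_{group}_{direction}_gt{config.overlap_cut:g}.nii",
                )

        stage = "inference"
        inference_meta = {"n_perm": config.n_perm, "seed": config.seed_perm}
        for group, stack in stacks.items():
            if stack.n_subjects < 2:
                continue
            gm = group_mean_map(stack, n_perm=config.n_perm, seed=config.seed_perm)
            ndio.write_map(gm.z_equivalent, stack.affine, out / f"mean_{group}_zmap.nii")
            ndio.write_map(
                gm.significant_mask, stack.affine, out / f"mean_{group}_z{config.z_threshold:g}.nii"
            )
        contrast = None
        if z_patients.n_subjects >= 2:
            contrast = group_contrast_map(
                z_controls,
                z_patients,
                tfce=config.tfce_params(),
                q=config.contrast_fdr_q,
                n_perm=config.n_perm,
                seed=config.seed_perm,
            )
            ndio.write_map(contrast.stat, volumes.affine, out / "contrast_stat.nii")
            ndio.write_map(contrast.z_equivalent, volumes.affine, out / "contrast_zmap.nii")
            ndio.write_map(contrast.p_corrected, volumes.affine, out / "contrast_p_fdr.nii")
            ndio.write_map(contrast.significant_mask, volumes.affine, out / "contrast_sig.nii")
            inference_meta["tfce"] = dataclasses.asdict(config.tfce_params())

        stage = "scoretests"
        results: dict = {"seeds": dataclasses.asdict(config), "inference": inference_meta}
        if z_patients.n_subjects >= 2:
            tests = {}
            for measure in ("pct_negative", "pct_positive"):
                res = score_group_test(
                    scores,
                    cohort,
                    measure=measure,
                    n_perm=config.score_test_n_perm,
                    seed=config.seed_scoretests,
                )
                tests[measure] = dataclasses.asdict(res)
            corrected = holm_correct([tests[m]["p"] for m in tests])
            for (measure, _), p_corr in zip(tests.items(), corrected):
                tests[measure]["p_corrected"] = float(p_corr)
            results["score_tests"] = tests
            assoc = association_tests(
                scores,
                cohort,
                measure="pct_negative",
                family_size=config.association_family_size,
            )
            results["associations"] = assoc.to_dict(orient="records")
        with open(out / "results.json", "w") as fh:
            json.dump(results, fh, indent=2, sort_keys=True, default=_json_default)

        stage = "manifest"
        files = sorted(p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json")
        manifest = {
            "normdev_version": normdev.__version__,
            "config": dataclasses.asdict(config),
            "seeds": {
                k: getattr(config, k)
                for k in dataclasses.asdict(config)
                if k.startswith("seed_")
            },
            "files": {str(p.relative_to(out)): _sha256(p) for p in files},
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except Exception as exc:  # noqa: BLE001 - tag the failing stage
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise StageError(stage, exc) from exc
    return out
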