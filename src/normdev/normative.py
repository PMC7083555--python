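"""Normative reference fitting and deviation Z-maps.

Builds per-voxel GP normative models of volume on age and sex over the
control group, scores controls under k-fold cross-validation and patients
out-of-sample, and collects the results as a ``DeviationStack``.

Two fitting routes are provided: per-voxel hyperparameter optimization
(exact, slow) and a fast path that jointly optimizes one shared
hyperparameter set on a voxel subsample (one Cholesky per fold, vectorized
solves across voxels). The fast path is off by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from normdev.gp import (
    VoxelNormativeModel,
    fit_voxel_gp,
    kernel_diag,
    kernel_matrix,
    predict_voxel,
    standardize_covariates,
    zscore,
    JITTER_REL,
)
from normdev.io import VolumeStack

logger = logging.getLogger(__name__)

PROVENANCE_CONTROL = "cross-validated-control"
PROVENANCE_PATIENT = "out-of-sample-patient"


def design_matrix(cohort: pd.DataFrame) -> np.ndarray:
    """Covariate rows: age in years (column 0) and sex coded female=0/male=1."""
    if cohort[["age", "sex"]].isna().any().any():
        raise ValueError("missing covariates in design matrix")
    age = cohort["age"].to_numpy(dtype=float)
    sex = (cohort["sex"].to_numpy() == "male").astype(float)
    return np.column_stack([age, sex])


@dataclass
class DeviationStack:
    """Per-subject, per-voxel deviation Z-scores over the in-mask voxels."""

    z: np.ndarray  # (n_subjects, n_mask_voxels)
    subjects: list[str]
    mask: np.ndarray  # (nx, ny, nz) bool
    affine: np.ndarray
    provenance: list[str]

    def __post_init__(self) -> None:
        self.z = np.atleast_2d(np.asarray(self.z, dtype=float))
        if self.z.shape[0] != len(self.subjects):
            raise ValueError("z rows do not match subject list")
        if self.z.size and self.z.shape[1] != int(self.mask.sum()):
            raise ValueError("z columns do not match in-mask voxel count")
        if self.z.size and not np.all(np.isfinite(self.z)):
            raise ValueError("non-finite Z inside mask")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def z_volume(self, i: int, fill: float = 0.0) -> np.ndarray:
        vol = np.full(self.mask.shape, fill, dtype=float)
        vol[self.mask] = self.z[i]
        return vol

    @staticmethod
    def concatenate(stacks: list["DeviationStack"]) -> "DeviationStack":
        ref = stacks[0]
        return DeviationStack(
            np.vstack([s.z for s in stacks]),
            sum((s.subjects for s in stacks), []),
            ref.mask,
            ref.affine,
            sum((s.provenance for s in stacks), []),
        )

    def reorder(self, subject_ids: list[str]) -> "DeviationStack":
        index = {s: i for i, s in enumerate(self.subjects)}
        rows = [index[s] for s in subject_ids]
        return DeviationStack(
            self.z[rows],
            list(subject_ids),
            self.mask,
            self.affine,
            [self.provenance[r] for r in rows],
        )


@dataclass
class _FittedSet:
    """Normative models for all in-mask voxels fit on one training sample."""

    shared: bool
    log_params: np.ndarray  # (4,) if shared else unused
    x_mean: np.ndarray
    x_scale: np.ndarray
    Xs_train: np.ndarray
    y_mean: np.ndarray  # (V,)
    y_scale: np.ndarray  # (V,)
    L: np.ndarray | None
    alpha: np.ndarray | None  # (n_train, V) for the shared path
    models: list[VoxelNormativeModel] | None  # per-voxel path
    mean_var: float = 0.0  # variance of the subtracted training mean (shared path)

    def predict(self, X_raw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Predictive mean and variance, shape (n_test, V), original units."""
        X_raw = np.atleast_2d(np.asarray(X_raw, dtype=float))
        if self.shared:
            Xs = (X_raw - self.x_mean) / self.x_scale
            Ks = kernel_matrix(self.log_params, Xs, self.Xs_train)
            mean_s = Ks @ self.alpha
            v = linalg.solve_triangular(self.L, Ks.T, lower=True)
            latent = np.maximum(
                kernel_diag(self.log_params, Xs) - np.einsum("ij,ij->j", v, v), 0.0
            )
            var_s = latent + float(np.exp(self.log_params[3])) + self.mean_var
            mean = self.y_mean[None, :] + self.y_scale[None, :] * mean_s
            var = (self.y_scale[None, :] ** 2) * var_s[:, None]
            return mean, np.broadcast_to(var, mean.shape).copy()
        means = np.empty((len(X_raw), len(self.models)))
        vars_ = np.empty_like(means)
        for j, model in enumerate(self.models):
            means[:, j], vars_[:, j] = predict_voxel(model, X_raw)
        return means, vars_


def _shared_cholesky(log_params: np.ndarray, Xs: np.ndarray) -> np.ndarray:
    K = kernel_matrix(log_params, Xs, include_noise=True)
    K[np.diag_indices_from(K)] += JITTER_REL * np.trace(K) / len(K)
    return linalg.cholesky(K, lower=True)


def _pooled_log_params(
    Xs: np.ndarray, Ys: np.ndarray, n_restarts: int, seed: int
) -> np.ndarray:
    """Joint MLE of shared hyperparameters: maximize the summed per-voxel
    log marginal likelihood (one Cholesky per objective evaluation)."""
    from scipy import optimize

    from normdev.gp import LOG_BOUND, _default_starts

    n, V = Ys.shape

    def neg(log_params: np.ndarray) -> float:
        K = kernel_matrix(log_params, Xs, include_noise=True)
        K[np.diag_indices_from(K)] += JITTER_REL * np.trace(K) / n
        try:
            L = linalg.cholesky(K, lower=True)
        except linalg.LinAlgError:
            return 1e12
        a = linalg.cho_solve((L, True), Ys)
        return float(
            0.5 * np.einsum("ij,ij->", Ys, a) / V
            + np.sum(np.log(np.diag(L)))
            + 0.5 * n * np.log(2.0 * np.pi)
        )

    rng = np.random.default_rng(seed)
    best, best_fun = None, np.inf
    for start in _default_starts(rng, n_restarts):
        res = optimize.minimize(neg, start, method="L-BFGS-B", bounds=[LOG_BOUND] * 4)
        if np.isfinite(res.fun) and res.fun < best_fun:
            best, best_fun = res.x, float(res.fun)
    if best is None:
        raise RuntimeError("shared hyperparameter optimization failed")
    return np.asarray(best, dtype=float)


def _fit_set(
    X_raw: np.ndarray,
    Y: np.ndarray,
    *,
    hyper_voxels: int | None,
    n_restarts: int,
    seed: int,
    scale_mode: str = "global",
) -> _FittedSet:
    """Fit normative models for all voxel columns of ``Y`` on one sample.

    ``hyper_voxels=None`` optimizes hyperparameters independently per voxel.
    Otherwise hyperparameters are shared: fit jointly on a random subsample
    of ``hyper_voxels`` voxels and reused everywhere. In the shared path,
    voxels are centered by their training mean; ``scale_mode`` picks the
    variance normalization — "global" (one scale for all voxels; correct when
    voxel variances are comparable, and free of per-voxel scale-estimation
    noise) or "voxel" (per-voxel training sd with a reciprocal-unbiasedness
    correction; robust to heteroscedastic voxels, slightly heavier Z tails).
    """
    X_raw = np.atleast_2d(np.asarray(X_raw, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n, V = Y.shape
    if hyper_voxels is None:
        models = [
            fit_voxel_gp(X_raw, Y[:, j], n_restarts=n_restarts, seed=seed + j)
            for j in range(V)
        ]
        return _FittedSet(
            shared=False,
            log_params=np.empty(4),
            x_mean=models[0].x_mean,
            x_scale=models[0].x_scale,
            Xs_train=models[0].X_train,
            y_mean=np.array([m.y_mean for m in models]),
            y_scale=np.array([m.y_scale for m in models]),
            L=None,
            alpha=None,
            models=models,
        )

    if scale_mode not in ("global", "voxel"):
        raise ValueError("scale_mode must be 'global' or 'voxel'")
    if n < 4:
        raise ValueError("shared-hyperparameter path needs at least 4 training subjects")
    y_mean = Y.mean(axis=0)
    y_sd = Y.std(axis=0, ddof=1)
    usable = np.flatnonzero(y_sd > 1e-12 * np.maximum(1.0, np.abs(y_mean)))
    if usable.size == 0:
        raise ValueError("all voxels degenerate; cannot fit shared hyperparameters")
    if scale_mode == "voxel":
        # sqrt((n-1)/(n-3)) makes E[true_var / scale^2] = 1 (reciprocal bias)
        scale = y_sd * np.sqrt((n - 1) / (n - 3))
        y_scale = np.where(scale > 0, scale, 1.0)
    else:
        y_scale = np.full(V, float(y_sd[usable].mean()))
    Ys = (Y - y_mean[None, :]) / y_scale[None, :]

    rng = np.random.default_rng(seed)
    sample = rng.choice(usable, size=min(int(hyper_voxels), usable.size), replace=False)
    Xs, x_mean, x_scale = standardize_covariates(X_raw)
    log_params = _pooled_log_params(Xs, Ys[:, sample], n_restarts, seed)

    L = _shared_cholesky(log_params, Xs)
    alpha = linalg.cho_solve((L, True), Ys)
    # hyperparameters are estimated on the centered/scaled data themselves, so
    # no extra correction for the subtracted training mean is applied
    mean_var = 0.0
    return _FittedSet(
        shared=True,
        log_params=log_params,
        x_mean=x_mean,
        x_scale=x_scale,
        Xs_train=Xs,
        y_mean=y_mean,
        y_scale=y_scale,
        L=L,
        alpha=alpha,
        models=None,
        mean_var=mean_var,
    )


@dataclass
class ReferenceModel:
    """Normative model trained on all controls, optionally one fit per sex."""

    sets: dict[str, _FittedSet]  # key "all" or sex label
    mask: np.ndarray
    affine: np.ndarray
    separate_sexes: bool

    def score(self, volumes: VolumeStack, cohort: pd.DataFrame, provenance: str) -> DeviationStack:
        """Z-score every subject in ``cohort`` against the reference."""
        cohort = cohort.reset_index(drop=True)
        if len(cohort) == 0:
            return DeviationStack(
                np.empty((0, int(self.mask.sum()))), [], self.mask, self.affine, []
            )
        stack = volumes.subset(cohort["subject_id"].tolist())
        Y = stack.masked()
        z = np.empty_like(Y)
        if self.separate_sexes:
            for sex, fitted in self.sets.items():
                rows = np.flatnonzero(cohort["sex"].to_numpy() == sex)
                if rows.size == 0:
                    continue
                X = design_matrix(cohort.iloc[rows])
                mean, var = fitted.predict(X)
                z[rows] = zscore(Y[rows], mean, var)
        else:
            X = design_matrix(cohort)
            mean, var = self.sets["all"].predict(X)
            z = zscore(Y, mean, var)
        return DeviationStack(
            z,
            cohort["subject_id"].tolist(),
            self.mask,
            self.affine,
            [provenance] * len(cohort),
        )


def _controls(cohort: pd.DataFrame) -> pd.DataFrame:
    return cohort[cohort["diagnosis"] == "control"].reset_index(drop=True)


def fit_reference(
    volumes: VolumeStack,
    cohort: pd.DataFrame,
    *,
    hyper_voxels: int | None = None,
    n_restarts: int = 3,
    seed: int = 0,
    separate_sexes: bool = False,
    scale_mode: str = "global",
) -> ReferenceModel:
    """Fit the normative reference on all controls."""
    controls = _controls(cohort)
    if len(controls) < 2:
        raise ValueError("need at least two controls to fit a reference")
    stack = volumes.subset(controls["subject_id"].tolist())
    Y = stack.masked()
    sets: dict[str, _FittedSet] = {}
    if separate_sexes:
        for sex in ("female", "male"):
            rows = np.flatnonzero(controls["sex"].to_numpy() == sex)
            if rows.size < 2:
                raise ValueError(f"too few {sex} controls for separate-sex fitting")
            X = design_matrix(controls.iloc[rows])
            sets[sex] = _fit_set(
                X,
                Y[rows],
                hyper_voxels=hyper_voxels,
                n_restarts=n_restarts,
                seed=seed,
                scale_mode=scale_mode,
            )
    else:
        sets["all"] = _fit_set(
            design_matrix(controls),
            Y,
            hyper_voxels=hyper_voxels,
            n_restarts=n_restarts,
            seed=seed,
            scale_mode=scale_mode,
        )
    return ReferenceModel(sets, volumes.mask, volumes.affine, separate_sexes)


def assign_folds(cohort: pd.DataFrame, k: int, seed: int) -> np.ndarray:
    """Deterministic fold labels in 0..k-1, stratified by sex."""
    n = len(cohort)
    if k > n:
        raise ValueError(f"k={k} exceeds the number of subjects ({n})")
    if k < 2:
        raise ValueError("k must be at least 2")
    rng = np.random.default_rng([int(seed), 7])
    folds = np.empty(n, dtype=int)
    offset = 0
    for sex in sorted(cohort["sex"].unique()):
        rows = np.flatnonzero(cohort["sex"].to_numpy() == sex)
        perm = rng.permutation(rows.size)
        folds[rows[perm]] = (offset + np.arange(rows.size)) % k
        offset += rows.size
    return folds


def crossval_reference(
    volumes: VolumeStack,
    cohort: pd.DataFrame,
    k: int = 10,
    seed: int = 0,
    *,
    hyper_voxels: int | None = None,
    n_restarts: int = 3,
    separate_sexes: bool = False,
    scale_mode: str = "global",
) -> DeviationStack:
    """k-fold cross-validated deviation Z for every control.

    Each control is scored against a model fit without it; fold assignment is
    a seeded, sex-stratified shuffle, so results are deterministic under the
    seed and every control is scored exactly once.
    """
    controls = _controls(cohort)
    if len(controls) == 0:
        raise ValueError("no controls in cohort")
    stack = volumes.subset(controls["subject_id"].tolist())
    Y = stack.masked()
    folds = assign_folds(controls, k, seed)
    z = np.empty_like(Y)
    for f in range(k):
        test = np.flatnonzero(folds == f)
        train = np.flatnonzero(folds != f)
        if test.size == 0:
            continue
        if separate_sexes:
            for sex in ("female", "male"):
                tr = train[controls["sex"].to_numpy()[train] == sex]
                te = test[controls["sex"].to_numpy()[test] == sex]
                if te.size == 0:
                    continue
                if tr.size < 2:
                    raise ValueError(f"fold {f}: too few {sex} training controls")
                fitted = _fit_set(
                    design_matrix(controls.iloc[tr]),
                    Y[tr],
                    hyper_voxels=hyper_voxels,
                    n_restarts=n_restarts,
                    seed=seed + f,
                    scale_mode=scale_mode,
                )
                mean, var = fitted.predict(design_matrix(controls.iloc[te]))
                z[te] = zscore(Y[te], mean, var)
        else:
            fitted = _fit_set(
                design_matrix(controls.iloc[train]),
                Y[train],
                hyper_voxels=hyper_voxels,
                n_restarts=n_restarts,
                seed=seed + f,
                scale_mode=scale_mode,
            )
            mean, var = fitted.predict(design_matrix(controls.iloc[test]))
            z[test] = zscore(Y[test], mean, var)
    return DeviationStack(
        z,
        controls["subject_id"].tolist(),
        volumes.mask,
        volumes.affine,
        [PROVENANCE_CONTROL] * len(controls),
    )


def score_targets(
    volumes: VolumeStack,
    cohort: pd.DataFrame,
    reference: ReferenceModel | None = None,
    **fit_kwargs,
) -> DeviationStack:
    """Out-of-sample deviation Z for every patient against the control model.

    Patients with missing covariates are excluded (logged), matching the
    train-on-all-controls / apply-to-patients protocol.
    """
    patients = cohort[cohort["diagnosis"] == "patient"].reset_index(drop=True)
    complete = ~patients[["age", "sex"]].isna().any(axis=1)
    if (~complete).any():
        excluded = patients.loc[~complete, "subject_id"].tolist()
        logger.warning("excluding patients with missing covariates: %s", excluded)
        patients = patients[complete].reset_index(drop=True)
    if reference is None:
        reference = fit_reference(volumes, cohort, **fit_kwargs)
    return reference.score(volumes, patients, PROVENANCE_PATIENT)
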