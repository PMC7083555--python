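"""Exact Gaussian-process regression for one voxel.

Kernel: squared-exponential on standardized age + linear term on the full
covariate row (with bias) + white noise. Hyperparameters are optimized by
multi-restart L-BFGS on log-parameters against the exact log marginal
likelihood. A jitter of 1e-8 * trace(K)/n is added to the kernel diagonal
before factorization (oracle comparisons must include it).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import linalg, optimize

logger = logging.getLogger(__name__)

LOG_BOUND = (np.log(1e-6), np.log(1e6))
JITTER_REL = 1e-8
DEGENERATE_VAR_FLOOR = 1e-12

# hyperparameter vector layout: log of
PARAM_NAMES = ("signal_variance", "length_scale", "linear_variance", "noise_variance")


class DegenerateVoxelError(ValueError):
    pass


def kernel_matrix(
    log_params: np.ndarray,
    X1: np.ndarray,
    X2: np.ndarray | None = None,
    include_noise: bool = False,
) -> np.ndarray:
    """Evaluate k(X1, X2) for the SE(age) + linear(+bias) kernel.

    Column 0 of X is the (standardized) age; the linear term acts on all
    columns plus an implicit bias.
    """
    sf2, ell, sl2, sn2 = np.exp(np.asarray(log_params, dtype=float))
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2v = X1 if X2 is None else np.atleast_2d(np.asarray(X2, dtype=float))
    d = X1[:, :1] - X2v[:, :1].T
    K = sf2 * np.exp(-0.5 * (d / ell) ** 2) + sl2 * (X1 @ X2v.T + 1.0)
    if include_noise:
        if X2 is not None:
            raise ValueError("noise applies only to the symmetric train kernel")
        K = K + sn2 * np.eye(len(X1))
    return K


def kernel_diag(log_params: np.ndarray, X: np.ndarray) -> np.ndarray:
    sf2, _, sl2, _ = np.exp(np.asarray(log_params, dtype=float))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return sf2 + sl2 * (np.einsum("ij,ij->i", X, X) + 1.0)


def _factor(log_params: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float]:
    K = kernel_matrix(log_params, X, include_noise=True)
    jitter = JITTER_REL * np.trace(K) / len(K)
    K[np.diag_indices_from(K)] += jitter
    return linalg.cholesky(K, lower=True), jitter


def log_marginal_likelihood(
    log_params: np.ndarray, X: np.ndarray, y: np.ndarray
) -> float:
    """Exact GP log marginal likelihood (includes the diagonal jitter)."""
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    L, _ = _factor(log_params, X)
    alpha = linalg.cho_solve((L, True), y)
    return float(
        -0.5 * y @ alpha - np.sum(np.log(np.diag(L))) - 0.5 * n * np.log(2.0 * np.pi)
    )


@dataclass
class VoxelNormativeModel:
    """Fitted per-voxel GP: hyperparameters plus training summaries."""

    log_params: np.ndarray
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    y_scale: float
    X_train: np.ndarray  # standardized covariates
    alpha: np.ndarray | None
    L: np.ndarray | None
    y_train: np.ndarray | None  # standardized targets
    log_marginal_likelihood: float
    degenerate: bool = False
    voxel_index: tuple[int, int, int] | None = None

    @property
    def hyperparameters(self) -> dict[str, float]:
        return dict(zip(PARAM_NAMES, np.exp(self.log_params)))

    @property
    def noise_variance(self) -> float:
        return float(np.exp(self.log_params[3]))


def standardize_covariates(
    X: np.ndarray, x_mean: np.ndarray | None = None, x_scale: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Z-score continuous covariate columns using (training) statistics.

    Binary 0/1 columns are centered but not rescaled so their linear-kernel
    weight stays interpretable; scale 1 is used wherever the sd vanishes.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if x_mean is None:
        x_mean = X.mean(axis=0)
        x_scale = X.std(axis=0)
        is_binary = np.array([set(np.unique(col)) <= {0.0, 1.0} for col in X.T])
        x_scale = np.where(is_binary | (x_scale < 1e-12), 1.0, x_scale)
    return (X - x_mean) / x_scale, np.asarray(x_mean), np.asarray(x_scale)


def _default_starts(rng: np.random.Generator, n_restarts: int) -> list[np.ndarray]:
    base = np.log(np.array([0.5, 1.0, 0.5, 0.5]))
    starts = [base]
    for _ in range(max(0, n_restarts - 1)):
        starts.append(base + rng.uniform(-2.0, 2.0, size=4))
    return starts


def fit_voxel_gp(
    X: np.ndarray,
    y: np.ndarray,
    *,
    n_restarts: int = 3,
    seed: int = 0,
    fixed_log_params: Sequence[float] | None = None,
    voxel_index: tuple[int, int, int] | None = None,
) -> VoxelNormativeModel:
    """Fit the per-voxel GP by maximizing the exact log marginal likelihood.

    ``X`` holds raw covariate rows (age first); targets and covariates are
    standardized internally using the training sample. Zero-variance targets
    yield a flagged degenerate constant-mean model rather than an error.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if len(y) != len(X):
        raise ValueError("X and y disagree in length")
    if not np.all(np.isfinite(y)) or not np.all(np.isfinite(X)):
        raise ValueError("non-finite training values")

    y_mean = float(y.mean())
    y_sd = float(y.std())
    Xs, x_mean, x_scale = standardize_covariates(X)
    if y_sd < 1e-12 * max(1.0, abs(y_mean)):
        logger.warning("degenerate voxel %s: zero-variance target", voxel_index)
        return VoxelNormativeModel(
            log_params=np.log(np.full(4, 1e-6)),
            x_mean=x_mean,
            x_scale=x_scale,
            y_mean=y_mean,
            y_scale=1.0,
            X_train=Xs,
            alpha=None,
            L=None,
            y_train=None,
            log_marginal_likelihood=float("nan"),
            degenerate=True,
            voxel_index=voxel_index,
        )
    ys = (y - y_mean) / y_sd

    if fixed_log_params is not None:
        best = np.asarray(fixed_log_params, dtype=float)
        best_lml = log_marginal_likelihood(best, Xs, ys)
    else:
        rng = np.random.default_rng(seed)
        best, best_lml = None, -np.inf
        for start in _default_starts(rng, n_restarts):
            res = optimize.minimize(
                lambda p: -log_marginal_likelihood(p, Xs, ys),
                start,
                method="L-BFGS-B",
                bounds=[LOG_BOUND] * 4,
            )
            if np.isfinite(res.fun) and -res.fun > best_lml:
                best, best_lml = res.x, -float(res.fun)
        if best is None:
            logger.warning("optimizer failed at voxel %s; using start values", voxel_index)
            best = _default_starts(np.random.default_rng(seed), 1)[0]
            best_lml = log_marginal_likelihood(best, Xs, ys)

    L, _ = _factor(best, Xs)
    alpha = linalg.cho_solve((L, True), ys)
    return VoxelNormativeModel(
        log_params=np.asarray(best, dtype=float),
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        y_scale=y_sd,
        X_train=Xs,
        alpha=alpha,
        L=L,
        y_train=ys,
        log_marginal_likelihood=best_lml,
        degenerate=False,
        voxel_index=voxel_index,
    )


def predict_voxel(
    model: VoxelNormativeModel, X_test: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Predictive mean and variance (latent + noise) in original volume units."""
    X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
    Xs = (X_test - model.x_mean) / model.x_scale
    if model.degenerate:
        mean = np.full(len(Xs), model.y_mean)
        var = np.full(len(Xs), DEGENERATE_VAR_FLOOR * max(1.0, model.y_mean**2))
        return mean, var
    outside = np.abs(Xs[:, 0]) > 3.0
    if outside.any():
        logger.info(
            "extrapolating %d test points beyond the training age support", int(outside.sum())
        )
    Ks = kernel_matrix(model.log_params, Xs, model.X_train)
    mean_s = Ks @ model.alpha
    v = linalg.solve_triangular(model.L, Ks.T, lower=True)
    latent = np.maximum(kernel_diag(model.log_params, Xs) - np.einsum("ij,ij->j", v, v), 0.0)
    var_s = latent + model.noise_variance
    return model.y_mean + model.y_scale * mean_s, (model.y_scale**2) * var_s


def zscore(
    y_observed: np.ndarray, mean: np.ndarray, variance: np.ndarray
) -> np.ndarray:
    """Deviation Z = (observed - predicted) / sqrt(predictive variance).

    Negative Z means less volume than predicted by the normative model.
    """
    variance = np.asarray(variance, dtype=float)
    if np.any(variance <= 0):
        raise ValueError("predictive variance must be strictly positive")
    return (np.asarray(y_observed, dtype=float) - np.asarray(mean, dtype=float)) / np.sqrt(
        variance
    )
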