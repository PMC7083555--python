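"""Permutation-based group inference on deviation maps and extreme scores.

Group mean maps use a sign-flipping null; group contrasts permute diagnosis
labels, optionally enhancing every permutation's statistic map with
threshold-free cluster enhancement (TFCE) before voxelwise permutation
p-values and BH-FDR. Extreme-deviation percentage scores are compared between
groups with an overdispersed-binomial Wald test (optionally cross-checked by
label permutation), and associations with covariates use standardized
regressions under Bonferroni-Holm correction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import ndimage, special, stats

from normdev.normative import DeviationStack

logger = logging.getLogger(__name__)

_LARGE_STAT = 1e30
DEFAULT_ASSOCIATION_COVARIATES = (
    "age",
    "hyperactivity",
    "inattention",
    "medication",
    "comorbidity",
)


@dataclass(frozen=True)
class TfceParams:
    """TFCE settings: TFCE(v) = sum_h e(h, v)^E * h^H * dh."""

    H: float = 2.0
    E: float = 0.5
    dh: float | None = None  # None -> max(|stat|) / 100
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.H <= 0 or self.E <= 0 or (self.dh is not None and self.dh <= 0):
            raise ValueError("H, E and dh must be positive")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")

    def structure(self) -> np.ndarray:
        rank = {6: 1, 18: 2, 26: 3}[self.connectivity]
        return ndimage.generate_binary_structure(3, rank)


@dataclass
class GroupStatMap:
    """Per-voxel permutation statistics; p = 1 and stat = 0 outside the mask."""

    stat: np.ndarray
    z_equivalent: np.ndarray
    p_uncorrected: np.ndarray
    p_corrected: np.ndarray | None
    significant_mask: np.ndarray
    n_permutations: int
    enhancement: str  # "none" | "tfce"
    mask: np.ndarray
    enhanced: np.ndarray | None = None


@dataclass
class ScoreTestResult:
    """Wald chi-square test of a diagnosis effect on extreme-deviation scores."""

    measure: str
    statistic: float
    df: int
    p: float
    p_corrected: float | None
    effect_direction: int
    group_estimates: dict[str, dict[str, float]]
    n_subjects: dict[str, int]
    permutation_p: float | None = None
    n_permutations: int = 0


def holm_correct(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """Step-down Holm-adjusted p-values with monotonicity enforcement.

    ``m`` may exceed ``len(p_values)`` when the declared family is larger
    than the number of tests actually run.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m_eff = p.size if m is None else int(m)
    if m_eff < p.size:
        raise ValueError("family size m cannot be below the number of tests")
    order = np.argsort(p, kind="stable")
    adjusted = np.empty_like(p)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m_eff - rank) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (reject iff adjusted <= q)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if m == 0:
        return p
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty_like(p)
    adjusted[order] = np.minimum(ranked, 1.0)
    return adjusted


def tfce_transform(
    stat_map: np.ndarray, params: TfceParams = TfceParams(), mask: np.ndarray | None = None
) -> np.ndarray:
    """TFCE of the positive part of ``stat_map`` (negate and re-apply for the
    negative tail)."""
    s = np.asarray(stat_map, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("stat map must be finite")
    if mask is not None:
        s = np.where(mask, s, 0.0)
    out = np.zeros_like(s)
    smax = float(s.max(initial=0.0))
    if smax <= 0:
        return out
    dh = params.dh if params.dh is not None else smax / 100.0
    if smax / dh > 1e5:
        raise ValueError(f"dh={dh} is too fine for a map with maximum {smax}")
    structure = params.structure()
    # midpoint quadrature: second-order accurate in dh across peak heights
    n_steps = int(np.ceil(smax / dh))
    for step in range(n_steps):
        h = (step + 0.5) * dh
        sup = s >= h
        labels, n_lab = ndimage.label(sup, structure=structure)
        if n_lab == 0:
            break
        sizes = np.bincount(labels.ravel())
        out[sup] += (sizes[labels[sup]] ** params.E) * (h**params.H) * dh
    return out


def signed_tfce(
    stat_map: np.ndarray, params: TfceParams, mask: np.ndarray | None = None
) -> np.ndarray:
    return tfce_transform(stat_map, params, mask) - tfce_transform(
        -np.asarray(stat_map, dtype=float), params, mask
    )


def _perm_p_to_z(p_two_sided: np.ndarray, sign: np.ndarray) -> np.ndarray:
    z = stats.norm.isf(np.clip(p_two_sided, 1e-300, 1.0) / 2.0)
    return np.where(sign < 0, -z, z)


def _embed(flat: np.ndarray, mask: np.ndarray, fill: float = 0.0) -> np.ndarray:
    out = np.full(mask.shape, fill, dtype=float)
    out[mask] = flat
    return out


def _one_sample_t(z: np.ndarray) -> np.ndarray:
    n = z.shape[0]
    m = z.mean(axis=0)
    sd = z.std(axis=0, ddof=1) if n > 1 else np.zeros(z.shape[1])
    se = sd / np.sqrt(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / se
    return np.where(se > 0, t, np.where(m == 0, 0.0, np.sign(m) * _LARGE_STAT))


def _sign_flip_matrix(n: int, n_perm: int, seed: int) -> tuple[np.ndarray, bool]:
    """Random sign flips, or exhaustive enumeration when 2^n <= n_perm."""
    if n <= 30 and 2**n <= n_perm:
        signs = np.array(list(product((1.0, -1.0), repeat=n)))
        return signs, True
    rng = np.random.default_rng([int(seed), 101])
    return rng.choice([1.0, -1.0], size=(n_perm, n)), False


def group_mean_map(
    deviations: DeviationStack,
    n_perm: int = 500,
    seed: int = 0,
    display_threshold: float = 2.6,
) -> GroupStatMap:
    """One-sample group mean map with a sign-flipping permutation null.

    Under H0 the deviation scores are symmetric about zero, so flipping each
    subject's sign is exchangeable. The significant mask is the +-2.6
    display threshold on the permutation z-equivalent map.
    """
    if deviations.n_subjects < 2:
        raise ValueError("need at least two subjects")
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations gives coarse p-values")
    z = deviations.z
    n, V = z.shape
    t_obs = _one_sample_t(z)

    signs, exhaustive = _sign_flip_matrix(n, n_perm, seed)
    m2 = np.sum(z**2, axis=0) / n  # invariant under sign flips
    means = signs @ z / n
    with np.errstate(divide="ignore", invalid="ignore"):
        var = np.maximum(m2[None, :] - means**2, 0.0) * n / (n - 1)
        t_perm = means / np.sqrt(var / n)
    t_perm = np.where(
        var > 0, t_perm, np.where(means == 0, 0.0, np.sign(means) * _LARGE_STAT)
    )

    abs_obs = np.abs(t_obs)[None, :]
    exceed = (np.abs(t_perm) >= abs_obs - 1e-12).sum(axis=0)
    if exhaustive:
        p = exceed / signs.shape[0]  # identity permutation is included
        n_reported = signs.shape[0] - 1
    else:
        p = (1.0 + exceed) / (signs.shape[0] + 1.0)
        n_reported = signs.shape[0]

    z_eq = _perm_p_to_z(p, np.sign(t_obs))
    mask = deviations.mask
    z_map = _embed(z_eq, mask)
    return GroupStatMap(
        stat=_embed(t_obs, mask),
        z_equivalent=z_map,
        p_uncorrected=_embed(p, mask, fill=1.0),
        p_corrected=None,
        significant_mask=(np.abs(z_map) > display_threshold) & mask,
        n_permutations=n_reported,
        enhancement="none",
        mask=mask,
    )


def _two_sample_t(
    sum1: np.ndarray, ss1: np.ndarray, n1: int, sum2: np.ndarray, ss2: np.ndarray, n2: int
) -> np.ndarray:
    """Difference of means (group2 - group1) studentized by pooled variance."""
    m1, m2 = sum1 / n1, sum2 / n2
    v1 = (ss1 - n1 * m1**2) / max(n1 - 1, 1)
    v2 = (ss2 - n2 * m2**2) / max(n2 - 1, 1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    se = np.sqrt(np.maximum(sp2, 0.0) * (1.0 / n1 + 1.0 / n2))
    diff = m2 - m1
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    return np.where(se > 0, t, np.where(diff == 0, 0.0, np.sign(diff) * _LARGE_STAT))


def group_contrast_map(
    dev_controls: DeviationStack,
    dev_patients: DeviationStack,
    tfce: TfceParams | None = None,
    q: float = 0.05,
    n_perm: int = 500,
    seed: int = 0,
) -> GroupStatMap:
    """Two-sample (patients minus controls) permutation contrast map.

    Group labels are permuted; when ``tfce`` is given, every permutation's
    statistic map is TFCE-enhanced (both tails) with a step size fixed from
    the observed map, voxelwise permutation p-values are computed on the
    enhanced values and BH-FDR is applied across in-mask voxels at ``q``.
    """
    if dev_controls.n_subjects == 0 or dev_patients.n_subjects == 0:
        raise ValueError("both groups must be nonempty")
    if min(dev_controls.n_subjects, dev_patients.n_subjects) == 1:
        warnings.warn("a group of size 1 gives a degenerate permutation space")
    if not np.array_equal(dev_controls.mask, dev_patients.mask):
        raise ValueError("groups use different analysis masks")
    mask = dev_controls.mask
    z = np.vstack([dev_controls.z, dev_patients.z])
    n1, n2 = dev_controls.n_subjects, dev_patients.n_subjects
    n = n1 + n2
    z2 = z**2
    tot_sum = z.sum(axis=0)
    tot_ss = z2.sum(axis=0)

    def stat_for(patient_rows: np.ndarray) -> np.ndarray:
        s2 = z[patient_rows].sum(axis=0)
        q2 = z2[patient_rows].sum(axis=0)
        return _two_sample_t(tot_sum - s2, tot_ss - q2, n1, s2, q2, n2)

    obs_rows = np.arange(n1, n)
    t_obs = stat_for(obs_rows)
    obs_scale = float(np.max(np.abs(t_obs)))
    if obs_scale < 1e-8:
        # numerically zero contrast (e.g. duplicated groups): nothing can be
        # significant, and a data-derived dh would be degenerate
        t_obs = np.zeros_like(t_obs)

    params = tfce
    if params is not None and params.dh is None:
        # step size fixed from the observed map so the same transform is
        # applied to every permutation
        dh = obs_scale / 100.0
        if dh > 0:
            params = TfceParams(
                H=params.H, E=params.E, dh=dh, connectivity=params.connectivity
            )

    if params is not None:
        obs_val = signed_tfce(_embed(t_obs, mask), params, mask)[mask]
    else:
        obs_val = t_obs

    rng = np.random.default_rng([int(seed), 211])
    exceed = np.zeros(obs_val.shape, dtype=np.int64)
    abs_obs = np.abs(obs_val)
    if not abs_obs.any():
        # degenerate all-zero observed map: every permutation ties or exceeds
        exceed[:] = n_perm
    else:
        for _ in range(n_perm):
            rows = rng.permutation(n)[:n2]
            t_b = stat_for(rows)
            if params is not None:
                val_b = signed_tfce(_embed(t_b, mask), params, mask)[mask]
            else:
                val_b = t_b
            exceed += np.abs(val_b) >= abs_obs - 1e-12

    p = (1.0 + exceed) / (n_perm + 1.0)
    p_adj = bh_adjust(p)
    sig = np.zeros(mask.shape, dtype=bool)
    sig[mask] = p_adj <= q
    z_map = _embed(_perm_p_to_z(p, np.sign(obs_val)), mask)
    return GroupStatMap(
        stat=_embed(t_obs, mask),
        z_equivalent=z_map,
        p_uncorrected=_embed(p, mask, fill=1.0),
        p_corrected=_embed(p_adj, mask, fill=1.0),
        significant_mask=sig,
        n_permutations=n_perm,
        enhancement="none" if params is None else "tfce",
        mask=mask,
        enhanced=_embed(obs_val, mask) if params is not None else None,
    )


def quasibinomial_wald(
    events: np.ndarray, trials: np.ndarray, group: np.ndarray
) -> tuple[float, float]:
    """Closed-form Wald statistic and coefficient for a binary-predictor
    overdispersed-binomial GLM (events/trials ~ group), Pearson-X2 scale.

    Matches ``statsmodels`` GLM(Binomial).fit(scale='X2') on the same data.
    """
    events = np.asarray(events, dtype=float)
    trials = np.asarray(trials, dtype=float)
    group = np.asarray(group, dtype=int)
    if np.any(trials <= 0):
        raise ValueError("zero trials")
    out = []
    for g in (0, 1):
        rows = group == g
        e, t = events[rows].sum(), trials[rows].sum()
        out.append((e / t, t))
    (p0, t0), (p1, t1) = out
    if p0 in (0.0, 1.0) or p1 in (0.0, 1.0):
        # complete separation: identical rates give no evidence, else infinite
        return (0.0 if p0 == p1 else np.inf), 0.0
    coef = float(special.logit(p1) - special.logit(p0))
    # Pearson dispersion across subjects at the fitted group rates
    fitted = np.where(group == 1, p1, p0)
    pearson = np.sum((events - trials * fitted) ** 2 / (trials * fitted * (1 - fitted)))
    scale = pearson / max(len(events) - 2, 1)
    var = scale * (1.0 / (t0 * p0 * (1 - p0)) + 1.0 / (t1 * p1 * (1 - p1)))
    return float(coef**2 / var), coef


def score_group_test(
    scores: pd.DataFrame,
    cohort: pd.DataFrame,
    measure: str = "pct_negative",
    n_perm: int = 0,
    seed: int = 0,
) -> ScoreTestResult:
    """Diagnosis effect on an extreme-deviation percentage score.

    The per-subject extreme voxel count (events out of in-mask trials) is
    modeled as an overdispersed binomial GLM with diagnosis as predictor; the
    Wald chi-square (1 df) on the diagnosis coefficient is reported, with
    per-group percentage estimates and 95% CIs, optionally validated against
    a label-permutation reference.
    """
    merged = scores.drop(columns="diagnosis", errors="ignore").merge(
        cohort[["subject_id", "diagnosis"]], on="subject_id"
    )
    if set(merged["diagnosis"].unique()) != {"control", "patient"}:
        raise ValueError("both diagnosis groups must be represented")
    trials = merged["n_mask_voxels"].to_numpy(dtype=float)
    if np.any(trials <= 0):
        raise ValueError("zero trials (empty analysis mask)")
    events = np.round(merged[measure].to_numpy(dtype=float) / 100.0 * trials)
    group = (merged["diagnosis"] == "patient").to_numpy(dtype=int)

    exog = sm.add_constant(group.astype(float))
    model = sm.GLM(
        events / trials, exog, family=sm.families.Binomial(), var_weights=trials
    )
    fit = model.fit(scale="X2")
    coef = float(fit.params[1])
    if fit.scale < 1e-12:
        # zero dispersion (all responses identical): no evidence either way
        wald = 0.0 if abs(coef) < 1e-8 else float("inf")
    else:
        wald = float((fit.params[1] / fit.bse[1]) ** 2)
    p = float(stats.chi2.sf(wald, df=1))

    estimates: dict[str, dict[str, float]] = {}
    cov = fit.cov_params()
    for label, g in (("control", 0.0), ("patient", 1.0)):
        x = np.array([1.0, g])
        eta = float(x @ fit.params)
        se = float(np.sqrt(x @ cov @ x))
        estimates[label] = {
            "pct": 100.0 * float(special.expit(eta)),
            "ci_low": 100.0 * float(special.expit(eta - 1.96 * se)),
            "ci_high": 100.0 * float(special.expit(eta + 1.96 * se)),
        }

    perm_p = None
    if n_perm > 0:
        rng = np.random.default_rng([int(seed), 307])
        obs, _ = quasibinomial_wald(events, trials, group)
        count = 0
        for _ in range(n_perm):
            stat_b, _ = quasibinomial_wald(events, trials, rng.permutation(group))
            count += stat_b >= obs - 1e-12
        perm_p = (1.0 + count) / (n_perm + 1.0)

    return ScoreTestResult(
        measure=measure,
        statistic=wald,
        df=1,
        p=max(p, np.nextafter(0, 1)),
        p_corrected=None,
        effect_direction=int(np.sign(coef)),
        group_estimates=estimates,
        n_subjects={"control": int((group == 0).sum()), "patient": int((group == 1).sum())},
        permutation_p=perm_p,
        n_permutations=n_perm,
    )


def association_tests(
    scores: pd.DataFrame,
    cohort: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_ASSOCIATION_COVARIATES,
    measure: str = "pct_negative",
    group: str = "patient",
    family_size: int = 8,
) -> pd.DataFrame:
    """Standardized regression of a deviation score on each covariate.

    Run within ``group`` (patients by default); Holm correction over the
    declared family (``family_size`` may exceed the number of tests run,
    mirroring a pre-registered family of correlations).
    """
    overlap_cols = (set(scores.columns) & set(cohort.columns)) - {"subject_id"}
    merged = scores.drop(columns=list(overlap_cols)).merge(cohort, on="subject_id")
    merged = merged[merged["diagnosis"] == group]
    if len(merged) < 3:
        raise ValueError("too few subjects for association tests")
    y = merged[measure].to_numpy(dtype=float)
    if y.std() == 0:
        raise ValueError(f"constant response {measure}")
    zy = (y - y.mean()) / y.std()

    rows = []
    for cov_name in covariates:
        if cov_name not in merged.columns:
            raise KeyError(f"covariate {cov_name!r} missing from cohort")
        col = merged[cov_name]
        x = (
            (col == "yes").to_numpy(dtype=float)
            if col.dtype == object
            else col.to_numpy(dtype=float)
        )
        if x.std() == 0:
            logger.warning("skipping constant covariate %r", cov_name)
            continue
        zx = (x - x.mean()) / x.std()
        fit = sm.OLS(zy, sm.add_constant(zx)).fit()
        rows.append(
            {
                "covariate": cov_name,
                "beta": float(fit.params[1]),
                "p": float(max(fit.pvalues[1], np.nextafter(0, 1))),
                "n": int(len(merged)),
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        m = max(int(family_size), len(table))
        table["p_corrected"] = holm_correct(table["p"].to_numpy(), m=m)
        table["family_size"] = m
    logger.info("association family size: %d", family_size)
    return table
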