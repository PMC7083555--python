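"""Extreme-deviation thresholding, per-subject percentage scores, overlap maps."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from normdev.normative import DeviationStack

DEFAULT_THRESHOLD = 2.6
DEFAULT_OVERLAP_CUT = 0.02


@dataclass
class ExtremeMaskPair:
    """Binary maps of extreme positive (Z > thr) and negative (Z < -thr) voxels.

    Voxels with |Z| exactly at the threshold are excluded (strict
    inequalities on both sides). Masks are disjoint and confined to the
    analysis mask by construction.
    """

    positive_mask: np.ndarray
    negative_mask: np.ndarray
    threshold: float
    method: str  # "fixed-threshold" or "per-subject-FDR"

    def __post_init__(self) -> None:
        if (self.positive_mask & self.negative_mask).any():
            raise ValueError("positive and negative masks overlap")


@dataclass
class OverlapMap:
    """Per-voxel fraction of a group's subjects with an extreme voxel there."""

    proportion: np.ndarray  # float in [0, 1], zero outside the analysis mask
    group: str
    direction: str  # "positive" | "negative"
    n_subjects: int

    def exceedance(self, cut: float = DEFAULT_OVERLAP_CUT) -> np.ndarray:
        """Binary map of voxels where overlap strictly exceeds ``cut``."""
        return self.proportion > cut


def _check_z(z_map: np.ndarray, mask: np.ndarray) -> np.ndarray:
    z_map = np.asarray(z_map, dtype=float)
    if z_map.shape != mask.shape:
        raise ValueError("z map and mask shapes differ")
    if not np.all(np.isfinite(z_map[mask])):
        raise ValueError("non-finite Z inside the analysis mask")
    return z_map


def threshold_map(
    z_map: np.ndarray, mask: np.ndarray, threshold: float = DEFAULT_THRESHOLD
) -> ExtremeMaskPair:
    """Fixed-threshold extreme masks: strictly Z > threshold / Z < -threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    z_map = _check_z(z_map, mask)
    return ExtremeMaskPair(
        positive_mask=(z_map > threshold) & mask,
        negative_mask=(z_map < -threshold) & mask,
        threshold=float(threshold),
        method="fixed-threshold",
    )


def bh_reject(p_values: np.ndarray, q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection set at FDR level ``q``."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if m == 0:
        return np.zeros(0, dtype=bool)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    below = ranked <= q * (np.arange(1, m + 1) / m)
    reject = np.zeros(m, dtype=bool)
    if below.any():
        k = int(np.max(np.flatnonzero(below)))
        reject[order[: k + 1]] = True
    return reject


def threshold_map_fdr(
    z_map: np.ndarray, mask: np.ndarray, q: float = 0.05
) -> ExtremeMaskPair:
    """Per-subject BH-FDR extreme masks from two-sided normal p = 2*Phi(-|Z|)."""
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    z_map = _check_z(z_map, mask)
    z_in = z_map[mask]
    p = 2.0 * stats.norm.sf(np.abs(z_in))
    rejected = bh_reject(p, q)
    pos = np.zeros(mask.shape, dtype=bool)
    neg = np.zeros(mask.shape, dtype=bool)
    pos[mask] = rejected & (z_in > 0)
    neg[mask] = rejected & (z_in < 0)
    return ExtremeMaskPair(pos, neg, threshold=float(q), method="per-subject-FDR")


def extreme_masks(
    deviations: DeviationStack,
    method: str = "fixed-threshold",
    threshold: float = DEFAULT_THRESHOLD,
    q: float = 0.05,
) -> list[ExtremeMaskPair]:
    if method == "fixed-threshold":
        return [
            threshold_map(deviations.z_volume(i), deviations.mask, threshold)
            for i in range(deviations.n_subjects)
        ]
    if method == "per-subject-FDR":
        return [
            threshold_map_fdr(deviations.z_volume(i), deviations.mask, q)
            for i in range(deviations.n_subjects)
        ]
    raise ValueError(f"unknown method: {method}")


def extreme_scores(
    deviations: DeviationStack,
    method: str = "fixed-threshold",
    threshold: float = DEFAULT_THRESHOLD,
    q: float = 0.05,
) -> pd.DataFrame:
    """Percentage of in-mask voxels with extreme positive/negative deviation.

    One row per subject, order preserved; denominator is the in-mask voxel
    count, recorded in ``n_mask_voxels``.
    """
    if deviations.n_subjects == 0:
        raise ValueError("empty deviation stack")
    n_mask = int(deviations.mask.sum())
    if n_mask == 0:
        raise ValueError("empty analysis mask")
    rows = []
    for i, pair in enumerate(extreme_masks(deviations, method, threshold, q)):
        rows.append(
            {
                "subject_id": deviations.subjects[i],
                "pct_positive": 100.0 * pair.positive_mask.sum() / n_mask,
                "pct_negative": 100.0 * pair.negative_mask.sum() / n_mask,
                "n_mask_voxels": n_mask,
                "method": pair.method,
                "threshold": pair.threshold,
            }
        )
    return pd.DataFrame(rows)


def overlap_map(
    masks: Sequence[ExtremeMaskPair] | Sequence[np.ndarray],
    direction: str = "negative",
    group: str = "",
) -> OverlapMap:
    """Voxel-wise fraction of the group's subjects whose extreme mask hits a voxel.

    The denominator is the number of subjects in the group, including those
    with empty masks.
    """
    if len(masks) == 0:
        raise ValueError("need at least one subject")
    if direction not in ("positive", "negative"):
        raise ValueError("direction must be 'positive' or 'negative'")
    arrays = []
    for m in masks:
        if isinstance(m, ExtremeMaskPair):
            arrays.append(m.negative_mask if direction == "negative" else m.positive_mask)
        else:
            arrays.append(np.asarray(m, dtype=bool))
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("subject masks disagree in grid shape")
    counts = np.zeros(shape, dtype=float)
    for a in arrays:
        counts += a
    return OverlapMap(counts / len(arrays), group=group, direction=direction, n_subjects=len(arrays))
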