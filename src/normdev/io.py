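"""NIfTI / CSV input-output and the in-memory volume container.

All voxel indices are 0-based; world coordinates come exclusively from the
NIfTI affine, which is preserved exactly on write.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

COHORT_COLUMNS = [
    "subject_id",
    "age",
    "sex",
    "diagnosis",
    "hyperactivity",
    "inattention",
    "medication",
    "comorbidity",
]


class GridMismatchError(ValueError):
    """Raised when subject volumes disagree in shape or affine."""


@dataclass
class VolumeStack:
    """Subjects x (x, y, z) volumetric values with mask and geometry.

    ``data`` has shape ``(n_subjects, nx, ny, nz)``; ``mask`` is a boolean
    array of shape ``(nx, ny, nz)``; ``subjects`` is the ordered id list
    matching axis 0 of ``data``.
    """

    data: np.ndarray
    subjects: list[str]
    mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 4:
            raise ValueError("data must be (n_subjects, nx, ny, nz)")
        if self.data.shape[0] != len(self.subjects):
            raise ValueError("subject list does not match data axis 0")
        if self.data.shape[1:] != self.mask.shape:
            raise GridMismatchError(
                f"mask shape {self.mask.shape} != grid {self.data.shape[1:]}"
            )

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def masked(self) -> np.ndarray:
        """Return an ``(n_subjects, n_mask_voxels)`` view of in-mask values."""
        return self.data[:, self.mask]

    def subset(self, subject_ids: Sequence[str]) -> "VolumeStack":
        index = {s: i for i, s in enumerate(self.subjects)}
        missing = [s for s in subject_ids if s not in index]
        if missing:
            raise KeyError(f"subjects without a volume: {missing}")
        rows = [index[s] for s in subject_ids]
        return VolumeStack(
            self.data[rows], list(subject_ids), self.mask, self.affine
        )


def write_map(array: np.ndarray, affine: np.ndarray, path: str | Path) -> Path:
    """Write a 3D (or 4D) array as NIfTI-1, preserving the affine exactly."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(array)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    img = nib.Nifti1Image(arr, np.asarray(affine, dtype=float))
    nib.save(img, str(path))
    return path


def read_map(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def read_mask(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    data, affine = read_map(path)
    return data > 0, affine


def _check_geometry(
    shape: tuple, affine: np.ndarray, ref_shape: tuple, ref_affine: np.ndarray, name: str
) -> None:
    if shape != ref_shape or not np.allclose(affine, ref_affine, atol=1e-6):
        raise GridMismatchError(
            f"{name}: shape {shape} / affine differ from reference {ref_shape}"
        )


def read_volumes(
    volume_paths: Sequence[str | Path] | str | Path,
    subjects: Sequence[str],
    mask_path: str | Path,
) -> VolumeStack:
    """Load subject volumes (one 4D file or per-subject 3D files) plus mask.

    Subject order is taken from ``subjects`` (normally the covariate table);
    for per-subject files the i-th path belongs to the i-th subject.
    """
    mask, mask_affine = read_mask(mask_path)
    if isinstance(volume_paths, (str, Path)):
        img = nib.load(str(volume_paths))
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim == 3:
            data = data[..., None]
        if data.ndim != 4:
            raise ValueError("expected a 4D NIfTI volume stack")
        if data.shape[3] != len(subjects):
            raise ValueError(
                f"4D file has {data.shape[3]} volumes but {len(subjects)} subjects"
            )
        _check_geometry(data.shape[:3], img.affine, mask.shape, mask_affine, str(volume_paths))
        stack = np.moveaxis(data, -1, 0)
        return VolumeStack(stack, list(subjects), mask, img.affine)

    paths = list(volume_paths)
    if len(paths) != len(subjects):
        raise ValueError("number of volume files does not match subject count")
    arrays = []
    offenders = []
    for sid, p in zip(subjects, paths):
        arr, affine = read_map(p)
        if arr.shape != mask.shape or not np.allclose(affine, mask_affine, atol=1e-6):
            offenders.append(sid)
            continue
        arrays.append(np.asarray(arr, dtype=float))
    if offenders:
        raise GridMismatchError(f"grid/affine mismatch for subjects: {offenders}")
    return VolumeStack(np.stack(arrays), list(subjects), mask, mask_affine)


def write_volumes_4d(stack: VolumeStack, path: str | Path) -> Path:
    """Write the full stack as one 4D NIfTI (subject axis last)."""
    return write_map(np.moveaxis(stack.data, 0, -1), stack.affine, path)


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"covariate table missing columns: {missing}")
    if df["subject_id"].duplicated().any():
        raise ValueError("duplicate subject_id in covariate table")
    return df


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(path, index=False, columns=COHORT_COLUMNS)
    return path
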