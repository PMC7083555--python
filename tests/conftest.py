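import numpy as np
import pandas as pd
import pytest

from normdev.gp import kernel_matrix, standardize_covariates
from normdev.io import VolumeStack
from normdev.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def tiny_config() -> SimulationConfig:
    return SimulationConfig(
        n_controls=24,
        n_patients=12,
        grid_shape=(12, 12, 12),
        lesion_radius=1,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return simulate_dataset(tiny_config)


def make_control_cohort(n: int, seed: int) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "subject_id": [f"s{i:03d}" for i in range(n)],
            "age": rng.uniform(18, 65, n),
            "sex": rng.choice(["female", "male"], n),
            "diagnosis": "control",
            "hyperactivity": 0,
            "inattention": 0,
            "medication": "no",
            "comorbidity": 0,
        }
    )


def gp_class_stack(
    n: int,
    n_voxels: int,
    seed: int,
    log_params=np.log([0.3, 1.0, 0.2, 1.0]),
) -> tuple[pd.DataFrame, VolumeStack]:
    """Control volumes drawn exactly from the GP model class.

    Each voxel is an independent draw of a latent function from the
    SE+linear kernel on (standardized age, sex) plus unit-variance noise, so
    held-out deviation Z-scores have a known standard-normal reference.
    """
    cohort = make_control_cohort(n, seed)
    rng = np.random.default_rng(seed + 1)
    X = np.column_stack(
        [cohort["age"].to_numpy(), (cohort["sex"] == "male").to_numpy(float)]
    )
    Xs, _, _ = standardize_covariates(X)
    K = kernel_matrix(np.asarray(log_params), Xs)
    L = np.linalg.cholesky(K + 1e-10 * np.eye(n))
    noise_sd = float(np.exp(0.5 * np.asarray(log_params)[3]))
    Y = L @ rng.standard_normal((n, n_voxels)) + noise_sd * rng.standard_normal(
        (n, n_voxels)
    )
    side = int(np.ceil(n_voxels ** (1 / 3)))
    grid = (side, side, side)
    mask = np.zeros(grid, dtype=bool)
    mask.ravel()[:n_voxels] = True
    data = np.zeros((n, *grid))
    data[:, mask] = Y
    return cohort, VolumeStack(data, cohort["subject_id"].tolist(), mask)
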