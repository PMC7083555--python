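# normdev

Voxelwise normative modeling of volumetric brain images. `normdev` fits a
per-voxel Gaussian-process regression of tissue volume on age and sex over a
reference (control) population, scores every individual as a deviation
Z-map — cross-validated for controls, out-of-sample for patients — and then
quantifies and compares those deviations:

- **Extreme-deviation maps and scores**: per-subject thresholding at
  |Z| > 2.6 (or per-subject Benjamini–Hochberg FDR), with percentage scores
  of extreme positive/negative voxels.
- **Overlap maps**: the per-voxel fraction of a group whose extreme mask
  includes that voxel, plus the binary >2% reading-level map.
- **Group inference**: sign-flipping permutation mean maps, label-permutation
  group contrasts with threshold-free cluster enhancement (TFCE) and
  voxelwise FDR, an overdispersed-binomial Wald test of the diagnosis effect
  on extreme-deviation scores (with an optional permutation reference), and
  Holm-corrected covariate associations.
- **Synthetic cohort generator**: seeded VBM-style volumes with a smooth
  baseline, regionally varying age decline, a sex offset, Gaussian-smoothed
  noise, idiosyncratic per-patient lesions, and one shared effect region —
  with full ground truth, so the entire pipeline is testable offline.

## Command line

All verbs are deterministic under their `--seed`.

```sh
# generate a synthetic cohort (covariates CSV, 4D NIfTI, mask, ground truth)
normdev simulate --config sim.yaml --out data/ --seed 1

# fit the control normative model; writes cross-validated control Z maps
# and a reusable model store. --hyper-voxels N enables the fast path
# (shared hyperparameters fit jointly on N sampled voxels).
normdev fit --volumes data/volumes_4d.nii --covariates data/covariates.csv \
    --mask data/mask.nii --kfold 10 --seed 2 --hyper-voxels 50 --out fit/

# score patients out-of-sample against the stored model
normdev score --model fit/model --volumes data/volumes_4d.nii \
    --covariates data/covariates.csv --mask data/mask.nii --out score/

# extreme-deviation masks, percentage scores, overlap maps
normdev deviations --z fit/z_controls_4d.nii --covariates data/covariates.csv \
    --subjects fit/z_controls_subjects.csv --mask data/mask.nii \
    --threshold 2.6 --out dev/

# permutation group maps and the TFCE+FDR contrast
normdev infer --z-controls fit/z_controls_4d.nii --z-patients score/z_patients_4d.nii \
    --controls-csv dev/controls.csv --patients-csv dev/patients.csv \
    --mask data/mask.nii --n-perm 500 --tfce H=2,E=0.5 --fdr 0.05 --seed 3 --out inf/

# diagnosis test and covariate associations on the scores table
normdev scoretests --scores dev/extreme_scores.csv \
    --covariates data/covariates.csv --out results.json

# or the whole pipeline in one go (simulates by default)
normdev run --config pipeline.yaml --out run/ --seed 9
```

`normdev run` writes a manifest (`manifest.json`) listing every output file
with its SHA-256 checksum and every stage seed; re-running with the same
config and seed reproduces byte-identical numeric outputs.

## Python API

```python
from normdev import (
    SimulationConfig, simulate_dataset,
    crossval_reference, fit_reference, score_targets,
    extreme_scores, overlap_map, threshold_map,
    group_contrast_map, score_group_test, TfceParams,
)

cohort, volumes, truth = simulate_dataset(SimulationConfig(seed=1))
z_controls = crossval_reference(volumes, cohort, k=10, seed=2, hyper_voxels=50)
z_patients = score_targets(volumes, cohort, hyper_voxels=50, seed=3)
scores = extreme_scores(z_patients, threshold=2.6)
contrast = group_contrast_map(z_controls, z_patients, tfce=TfceParams(), q=0.05,
                              n_perm=500, seed=4)
```

Two fitting routes are available: exact per-voxel hyperparameter
optimization (`hyper_voxels=None`, the default) and a fast path
(`hyper_voxels=N`) that jointly optimizes one shared hyperparameter set on a
random voxel subsample and reuses it everywhere, reducing each fold to one
Cholesky factorization plus vectorized solves. The fast path assumes voxel
variances are comparable after global scaling (`scale_mode="global"`); use
`scale_mode="voxel"` for strongly heteroscedastic data.

## Tests and the acceptance report

```sh
python -m pytest -q                     # full suite, incl. tests/test_acceptance.py
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` holds the property-based acceptance battery: GP
oracle equivalence against a dense brute-force implementation, held-out Z
calibration, exact agreement of the BH/Holm procedures with definitional
oracles, TFCE against a fine-step threshold-sum oracle, permutation p-value
uniformity under the null, recovery of the implanted group and individual
effects on the default demo simulation, and CLI determinism.

`scripts/acceptance.py` runs the full pipeline on the default synthetic
cohort under the given seed, prints the demo summary, and writes the
(empty) acceptance-target report to `--out`.
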