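# pannen

Multiphase CT quantification and 3D first-order texture analysis for tumor
grade-group comparison, exercised end to end on a synthetic phantom cohort.

The package implements:

* **`pannen.imaging_io`** — NIfTI volume/mask I/O in Hounsfield Units
  (optional DICOM-series ingestion when `pydicom` is installed), slice-thickness
  standardization by linear z-interpolation (default 5 mm), and a lossless
  per-patient cohort CSV.
* **`pannen.roi_quant`** — circular-ROI mean HU measurement, ROI propagation
  across contrast phases (no registration), and the seven
  enhancement/permeability ratios. The identity
  `permeability_1 − permeability_2 = 2 · arterial_ratio` holds by construction.
* **`pannen.texture3d`** — first-order features of the masked 3D tumor on the
  pancreatic phase: mean, variance, skewness, **excess** kurtosis, and Shannon
  entropy (bits) over a configurable histogram (default 128 bins, mask min–max).
* **`pannen.phantom`** — synthetic three-phase cohort generator. Lesions are
  boundary-perturbed ellipsoids whose voxels follow a viable + clustered
  necrosis Gaussian mixture with grade-calibrated parameters, so every lesion
  carries exact analytic moment ground truth (`mixture_moments`,
  delta-method `moment_standard_errors`). Default grade counts are 31/52/17.
* **`pannen.stats_grade`** — Student's t for sizes, Pearson χ² for qualitative
  flags, pairwise two-sided Mann-Whitney U for quantitative features, and
  empirical ROC (positive class G3) with cutoff sensitivity/specificity.
* **`pannen.pipeline_cli`** — `simulate → extract → analyze → report`
  orchestration with per-patient failure isolation and deterministic reruns.

## CLI

```bash
pannen simulate --n 31,52,17 --seed 7 --cohort-dir cohort
pannen extract  --cohort-dir cohort --out out
pannen analyze  --cohort-dir cohort --out out
pannen report   --cohort-dir cohort --out out
```

Each command also accepts `--config config.yaml` with keys
`cohort_dir, out_dir, thickness_mm, n_bins, range_mode, alpha, seed,
n_per_grade, directions, cutoffs`. Exit codes: 0 success, 1 user error,
2 internal error.

Cohort layout on disk:
`cohort/<id>/{precontrast,pancreatic,portal}.nii.gz`, `mask.nii.gz`,
`rois.json` (circular-ROI sidecar: structure/phase/slice/center/radius_mm),
plus a `manifest.json` holding profiles, per-patient seeds, analytic mixture
moments, true ROI measurements and qualitative ground-truth flags.

The features CSV written by `extract` has one row per patient:
`patient_id, grade, size_mm`, 10 qualitative columns, the 6 HU measurements,
7 ratios, 5 texture features (+`n_voxels`, `n_bins`, `degenerate_flag`), and
an extraction status flag.

## Notes

* Intensities are HU everywhere; `BinningConfig.offset` exposes a constant
  additive offset for gray-level texture dialects.
* Kurtosis is excess kurtosis (Gaussian = 0) with population (1/N) moments.
* Masks are never resampled implicitly; use `imaging_io.resample_mask`
  alongside `resample_slices`.
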