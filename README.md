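# ivimkit

Quantitative analysis of multi-b-value diffusion-weighted MRI (DWI) of the
knee with an intravoxel-incoherent-motion (IVIM) signal model, plus the
reader-agreement statistics used to validate DWI against contrast-enhanced
imaging for synovitis.

The package provides:

- **`ivimkit.core`** — the bi-exponential IVIM signal model
  `S(b) = S0*((1-f)*exp(-b*D) + f*exp(-b*Dp))`, the two-point mono-exponential
  ADC, and the segmented two-step fit (log-linear stage over b ≥ 200 s/mm²
  for `D` and `f`, then a bounded one-parameter fit for `Dp`).
- **`ivimkit.maps`** — voxelwise fitting of whole volumes with the 30 %-of-max
  b=0 intensity mask; undefined voxels carry NaN.
- **`ivimkit.phantom`** — a synthetic knee-like phantom (effusion disc,
  synovial ring, muscle, background) simulated on the 10-point b-value scheme
  (0–1000 s/mm², 1/1/1/1/1/1/2/2/3/3 averages) with Rician noise scaled by
  1/√NEX, plus cohort generation with per-subject parameter jitter.
- **`ivimkit.roi`** — ROI statistics (mean/SD/min/max of D and f, b=1000
  signal as the mean of two seeded ROI drawings), the repeat-measurement
  coefficient of variation, and the two-sided Mann-Whitney U test (exact by
  enumeration for small samples).
- **`ivimkit.agreement`** — Likert rating records, dichotomization
  (categories 1–2 → 0, 3–4 → 1), unweighted Cohen's kappa with Landis–Koch
  labels, level-of-confidence summaries, and a built-in 10-knee two-reader
  rating fixture.
- **`ivimkit.pipeline` / `ivimkit.cli`** — end-to-end orchestration with a
  seed + config-hash manifest.

Internal units are mm²/s and fractions; exported maps and CSVs use
10⁻³ mm²/s and percent.

## CLI

```sh
# simulate a cohort of synthetic subjects
ivimkit phantom --group patients --n 3 --seed 1 --out out/phantom

# fit parameter maps from a 4D NIfTI + FSL-style bval sidecar
ivimkit fit --dwi out/phantom/patient_00_dwi.nii.gz \
            --bval out/phantom/patient_00_dwi.bval --out out/maps

# ROI statistics per tissue label
ivimkit quantify --maps-dir out/maps --labels out/phantom/patient_00_labels.nii.gz \
                 --out out/roi.csv

# reader-agreement report (built-in fixture or your own ratings CSV)
ivimkit agreement --fixture --out out/agreement.json

# full demo run: two 10-subject cohorts -> maps -> ROI stats -> group tests
ivimkit demo --out out/demo --seed 1
```

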