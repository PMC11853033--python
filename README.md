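# lumipath

Surface-luminance image analysis for tissue screening, with a full
diagnostic-accuracy evaluation stage.

The package turns calibrated luminance maps (cd/m²) of tissue samples into
per-sample reports — luminance-band (pseudo-color) segmentation, connected
lesion-focus detection, min/mean/max summaries — and evaluates the maximum
field luminance (Lmax) as a binary classifier against a histopathology
reference: threshold sweeps with 2×2 contingency tables, sensitivity /
specificity / PPV / NPV / likelihood ratios / overall accuracy, ROC with
trapezoidal AUC and Youden-J threshold selection, Pearson χ² with Cramér's V,
a rank-sum group comparison, and AUC-based minimum-sample-size calculation.

Because no measurement-bench data are distributable, a synthetic module
generates luminance phantoms (even background, tissue ellipse, lesion-focus
variants, noise, specular artifacts) with exact ground truth, plus a fixed
48-sample reference cohort whose threshold-assignment counts reproduce the
published contingency tables.

## Layout

| Module | Contents |
|---|---|
| `lumipath.image` | `LuminanceMap`, `MeasurementField`, `LuminanceBand`, segmentation, focus detection, summaries, evenness, pseudo-color rendering, TIFF/CSV I/O |
| `lumipath.phantom` | `PhantomSpec` / `generate_phantom`, `generate_cohort`, the packaged reference cohort `fixture_lmax_table2`, cohort CSV I/O |
| `lumipath.diagnostics` | contingency tables, diagnostic metrics, threshold sweep, ROC/AUC, threshold selection, χ²/Cramér's V, rank comparison, sample size |
| `lumipath.cli` | `lumipath simulate / analyze / evaluate` |

## CLI

```bash
# 1. render phantoms (or write the packaged reference cohort CSV)
lumipath simulate --out-dir scratch/sim --seed 1 --variant multifocal_diffuse --n 3
lumipath simulate --out-dir scratch/sim --seed 1 --fixture-table2
lumipath simulate --out-dir scratch/sim --seed 1 --fixture-phantoms   # 48 images

# 2. image stage: JSON report + pseudo-color PNG per image, cohort CSV of Lmax
lumipath analyze scratch/sim/*.tif --out-dir scratch/analyzed --calibration-factor 1.0

# 3. diagnostic stage: threshold counts/metrics CSVs, JSON summary, ROC plot
lumipath evaluate scratch/analyzed/cohort.csv --report-dir scratch/report \
    --thresholds 1070,1080,1090,1100,1110,1120,1130 --direction le
```

Every parameter can also come from a YAML config (`--config`); precedence is
CLI flag > config file > defaults. Reports embed a config hash.

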