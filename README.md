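# mrinorm

Intensity standardization and cohort-level consistency analysis for
conventional weighted MRI, with a focus on head-and-neck T2-weighted images.

## The problem

Voxel intensities of conventional T1-/T2-weighted MRI are in arbitrary,
scanner- and protocol-dependent units: the same tissue can map to very
different numbers across patients, or even across visits on one scanner.
Any cohort-level quantitative analysis (radiomics, deep learning, response
modelling) therefore needs an intensity standardization step — and a way to
check whether it worked. `mrinorm` provides both for imaging scientists and
radiotherapy researchers:

* five standardization transforms f(x) applied per image:
  * **MinMax** — f(x) = (x − min x) / (max x − min x)
  * **Z-All** — f(x) = (x − μ_x) / σ_x over all voxels
  * **Z-External** — the same, with μ_x, σ_x taken over a body ("external")
    mask of the head-and-neck region
  * **Fat** — f(x) = x / μ_fat · 350, with μ_fat the pooled mean intensity
    of the left + right cheek-fat ROIs
  * **Nyul** — landmark-percentile histogram standardization: learn a
    standard histogram template from a cohort (landmarks at the
    1, 10, 20, …, 90, 99th percentiles) and map each image onto it
    piecewise-linearly between its own landmarks;
* a consistency statistic over healthy-tissue ROIs. For patient *i* and
  ROI *r*,

  NMI_c(i, r) = μ_{i,r} / (max_r − min_r),

  where μ_{i,r} is the patient's mean ROI intensity and (min_r, max_r) is
  the range of the pooled voxel intensities of that ROI across the cohort.
  The **SD NMI_c** of ROI *r* is the sample standard deviation of
  NMI_c(·, r) across patients: 0 for a perfectly consistent cohort, larger
  when the tissue's intensity drifts between patients. The statistic is
  invariant to any single global affine rescaling of the cohort, so methods
  living on different output scales are directly comparable;
* nonparametric method comparison: Shapiro–Wilk normality gate, Friedman
  omnibus test over methods with ROIs as blocks, and a Bonferroni-corrected
  two-sided Wilcoxon signed-rank matrix over all method pairs;
* I/O for DICOM image series, DICOM-RT Structure Sets (polygon contour
  rasterization with an exact voxel-center rule) and NIfTI volumes with
  integer label maps;
* a synthetic phantom-cohort generator with `het_like` (wide per-patient
  gain/offset/bias/noise heterogeneity, emulating a multi-scanner cohort)
  and `hom_like` (single-protocol) presets, so the complete workflow runs
  with no patient data.

The standardizers are scikit-learn-style transformers (`fit`/`transform`,
`get_params`, cloneable), so they compose with sklearn pipelines; thin
functions (`standardize_minmax`, `nyul_learn`, …) wrap them for one-shot
use.

## Worked example

```python
from mrinorm import preset, generate_cohort, evaluate_cohort, pairwise_wilcoxon

cohort = generate_cohort(preset("het_like", seed=1), label="HET-like")
table = evaluate_cohort(cohort)          # 6 methods x 12 evaluated ROIs
print(table.method_summary.round(4))

matrix = pairwise_wilcoxon(table, alpha=0.05)
print(f"Friedman Q = {matrix.friedman_statistic:.2f}, p = {matrix.friedman_p:.2e}")
print(matrix.corrected_p.loc["Original"].round(4))
```

prints

```
              mean      sd
Original    0.2124  0.0082
MinMax      0.0722  0.0218
Z-All       0.0456  0.0159
Z-External  0.0457  0.0159
Fat         0.1090  0.0510
Nyul        0.0473  0.0133
Friedman Q = 45.14, p = 1.36e-08
Original         NaN
MinMax        0.0073
Z-All         0.0073
Z-External    0.0073
Fat           0.0073
Nyul          0.0073
```

Read: on a 15-patient cohort with heterogeneous simulated acquisitions, the
unstandardized images have a mean SD NMI_c of 0.21 across the 12 evaluated
ROIs; every standardization method improves consistency (Z-scoring over the
body mask and Nyul histogram matching the most, down to ≈ 0.05). The
Friedman test finds the methods significantly different, and each method's
Bonferroni-corrected signed-rank p-value against `Original` is 0.0073.

The same analysis is available from the shell:

```bash
mrinorm simulate --preset het_like --seed 1 --out cohort/
mrinorm evaluate --preset het_like --seed 1 --out results/ --heatmap
mrinorm compare  --table results/sd_nmi_c.csv --out results/
```

`evaluate` writes the SD NMI_c table (`sd_nmi_c.csv`: one row per method,
one column per evaluated ROI plus a `Mean` column), an optional heatmap PNG
and the Friedman-gated comparison matrix (`comparison.csv` / `.json`).

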