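# boldvar

Spatiotemporal variance analysis of intrinsic (resting) BOLD MRI for the
placenta and fetal brain, with a synthetic-data module so the whole pipeline
is testable without any clinical data.

The pipeline computes two dimensionless statistics per subject and tissue
volume of interest (VOI):

- **Temporal variance (TV)** — sample SD over time of the VOI-mean signal
  after unity-mean normalisation (proxy for cyclical maternal-inflow
  fluctuation).
- **Spatial variance (SV)** — sample SD across VOI voxels of each voxel's
  percent amplitude fluctuation (PAF) after dividing by the across-voxel mean
  PAF (proxy for perfusion heterogeneity across cotyledon-like regions).

and then runs a heteroskedasticity-robust statistical battery against
maternal risk factors (MRF: obesity, hypertension, diabetes) and CHD status:
null-restricted wild-bootstrap regression with gestational-age adjustment and
CHD interactions, one-sided p-values, Benjamini–Hochberg FDR within predictor
families, GA-adjusted two-sample Kolmogorov–Smirnov comparisons,
histogram-moment tests and Welch t-tests.

## Modules

| Module | Purpose |
| --- | --- |
| `boldvar.synthdata` | 4D BOLD phantoms (cyclical inflow signal, cotyledon patches via Voronoi cells, fluid compartment, rigid slice motion, noise) with analytic ground truth; covariate cohorts with known effect sizes |
| `boldvar.preprocess` | VOI propagation / slice restriction, per-slice 2D rigid motion correction with an NCC cost (grid + phase correlation + bounded refinement), Gaussian temporal filtering and amniotic-fluid nuisance regression |
| `boldvar.metrics` | TV, per-voxel PAF (mean-absolute-deviation convention; SD convention available), SV |
| `boldvar.stats` | design construction, OLS, wild bootstrap, BH-FDR, GA adjustment, K-S, moment tests, Welch t |
| `boldvar.pipeline` | one-config orchestration: simulate → preprocess → metrics → stats, QC report, deterministic seeding |

## CLI

```bash
# write one phantom + masks + ground-truth sidecar
boldvar simulate --out phantom/ --grid 16,16,5,50 --patches 6 --noise-sd 1 --seed 1

# motion-correct and denoise a series
boldvar preprocess --bold phantom/bold.nii --fluid-mask phantom/mask_fluid.nii \
    --out corrected.nii --transforms-out transforms.csv

# TV/SV of one VOI
boldvar metrics --bold corrected.nii --mask phantom/mask_placenta.nii \
    --tissue placenta --out metrics.csv

# regression battery from a metrics table joined to covariates
boldvar stats --metrics-csv metrics.csv --covariates-csv covariates.csv \
    --out results.csv --n-boot 5000 --seed 1

# full synthetic pipeline from one YAML config
boldvar run-all --config config.yaml
```

A minimal `config.yaml`:

```yaml
seed: 1
output_dir: out
synthetic:
  cohort: {n_subjects: 60, beta0: 5.0, beta_mrf: -0.5, noise_sd: 0.1}
  phantom: {grid_shape: [16, 16, 5, 50], n_patches: 16, noise_sd: 1.0,
            motion_max_voxels: 0.25, fluid_fraction: 0.15}
stats: {n_boot: 2000}
```

Cohort metric columns are on a percent scale (`tv_placenta: 5.0` means a 5%
fluctuation); the pipeline maps each subject's target onto the phantom's
inflow amplitude and reports measured metrics on the same scale.

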