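# mtpfluor

2D-fluorescence monitoring of microtiter-plate (MTP) batch cultures as a
reusable, tested analysis pipeline:

* **synthetic data** — Monod batch-growth kinetics (glycerol, CDW, pH, a
  GFP-like signal proxy, OTR from the oxygen mass balance) and a forward
  spectral model rendering excitation × emission matrices with Gaussian
  fluorophore bands, a saturating scattered-light ridge on the Em = Ex
  bisecting line, an early-cultivation optical artifact and configurable
  noise (`mtpfluor.synth`);
* **data model & I/O** — `Spectrum2D`/`SpectraDataset` containers with long-CSV
  (plus JSON sidecar) and HDF5 round-trip, single-wavelength signal
  extraction and replicate statistics (`mtpfluor.data`);
* **preprocessing** — emission-window masking (−10 / +270 nm relative to the
  excitation), 25-point moving-average smoothing, unfolding with 5-point
  downsampling, and I−I₀ referencing to each well's first cycle
  (`mtpfluor.preprocess`);
* **PCA** — SVD-based scores/loadings/explained-variance with deterministic
  sign convention, score-over-time and score-plot views (`mtpfluor.pca`);
* **PLS** — single-response SIMPLS regression, NIPALS-equivalent for
  univariate responses, RMSE / relative RMSE / R² metrics (`mtpfluor.pls`);
* **alignment & validation** — linear interpolation of destructive offline
  samples to spectral timestamps, 25-h horizon truncation, the
  consumed-glycerol transform, calibration/prediction splitting, the
  RMSE_cal,6-h / RMSE_cal,1.5-h / RMSE_pred,1.5-h triplet, latent-variable
  sweep with overfitting flags, and replicate-averaging comparison
  (`mtpfluor.align`, `mtpfluor.validate`);
* **layouts** — the original five-plate campaign (8 conditions, 120 samples)
  and the revised single-plate layout (14 conditions, 48 samples) with
  sampling/throughput metrics (`mtpfluor.layout`).

## CLI

All commands accept `--config <yaml/json>`, `--seed`, `--out`; every run
writes `runconfig.json` with the fully resolved settings and a content
hash.

```sh
mtpfluor simulate   --seed 42 --out out/        # spectra.h5, offline.csv, otr.csv
mtpfluor preprocess --out out/                  # features.csv
mtpfluor pca        --out out/ --n-pc 2         # scores/loadings/explained CSVs
mtpfluor fit        --out out/ --n-lv 2         # pls_<param>.json models
mtpfluor validate   --out out/ --n-lv 2         # validation_report.json + parity CSVs
mtpfluor lvsweep    --out out/ --max-lv 6       # lv_sweep.csv + selected counts
mtpfluor layout     --which revised --out out/  # plate map + metrics
```

`mtpfluor validate --full-auto` runs the whole default experiment
(8 conditions in duplicate, 0.5-h spectral cycle, coarse 2-nm emission
grid, 25-h horizon, 2 latent variables) in-process. `--n-lv auto` selects
the latent-variable count by the 1.5-h-interval validation minimum.

The default emission grid for pipeline runs is coarsened to a 2 nm step to
keep runtimes at desk scale; set `em_step: 0.45` in the config (or
`--canonical-grid` for `simulate`) to restore the canonical grid.

## Library use

```python
from mtpfluor.validate import run_default_pipeline

report = run_default_pipeline(seed=42, n_lv=2)
print(report.table())
```
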