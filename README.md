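# canopyreg

Estimation of wheat biophysical variables (dry matter, LAI, nitrogen
concentration, nitrogen uptake, and their partitioning between stem,
inferior leaves, flag leaf and ear) from proximal RGB/multispectral canopy
imagery.  The package implements:

- **core_data** — domain types (trait vectors with organ partitioning,
  acquisitions, reference samples), CSV/TIFF I/O, exact-key joining of
  sparse reference labels to dense image acquisitions, and
  treatment-held-out train/validation splitting.
- **synthetic_trial** — a synthetic trial generator (logistic dry-matter,
  unimodal LAI, N-dilution %N, organ appearance schedules, procedural
  canopy scenes and an engineered-feature response) so the whole stack is
  testable without field data.
- **canopy_features** — Otsu segmentation, plant cover ratio from the
  800 nm band, 95th-percentile canopy height, 12 six-band vegetation
  indices (user-overridable registry), and the scan-based LAI calibration
  regression: the 20-feature input of the PLSr baseline.
- **plsr_baseline** — PLS regression with sequential backward feature
  selection under fixed, optionally microplot-grouped 5-fold CV.
- **deep_regression** — a numpy CNN stack (im2col convolutions, manual
  backprop, Adam) with single-output and multi-output heads (linear or
  softmax proportions), a trainable 1×1 channel adapter for 6-band input,
  masked and flag-leaf-weighted MSE losses, flip augmentation, and phase
  training with scope freezing.  The `tiny_test_cnn` backbone (~100k
  parameters) runs every experiment on one CPU; large named backbones are
  declared but require pretrained weights that are not bundled.
- **pseudo_label** — the two-stage pseudo-labeling pipeline: Model 1 is
  trained on the sparse labels, predicts every acquisition, per-microplot
  growth curves (cubic B-spline for LAI, cubic polynomial otherwise)
  smooth the predictions against thermal time, corrections are applied
  (non-negativity, organ-absence zeros, proportion renormalization), and
  Model 2 retrains from scratch on the corrected pseudo-labels.  The
  pipeline is model-agnostic (CNN, PLSr or oracle trainers).
- **evaluation** — R²/RMSE, the nitrogen nutrition index against a
  configurable critical dilution curve, organ reconstruction
  (total × proportions), and report/stackplot assembly.

## CLI

```bash
canopyreg simulate --treatments 5 --replicates 3 --acq-dates 15 \
    --ref-dates 6 --mode image --out trial/        # synthetic trial
canopyreg features --metadata trial/metadata.csv \
    --references trial/references.csv --out features.csv
canopyreg plsr --features trial/features.csv \
    --references trial/references.csv --trait lai --out plsr_run/
canopyreg pseudolabel --metadata trial/metadata.csv \
    --references trial/references.csv --trait dm_total \
    --val-treatments T2 --out pl_run/
```

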