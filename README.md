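# stratiforest

Pixel-based forest stratification and inventory estimation for carbon-offset
projects. From gridded remote-sensing layers (canopy height model, DEM,
optical bands) and variable-radius prism plots, the toolkit:

1. **summarizes** rasters and watershed-segmented crown polygons to a 20 m
   (0.04 ha) analysis grid (topographic, crown and image features, NDVI);
2. **reduces** each image feature set to leading principal components;
3. **screens** predictors with a cross-validated Lasso and fits log-linear
   basal-area / stem-density models and a logistic conifer-share model
   (post-selection least-squares refit, optional back-transform bias
   correction);
4. **stratifies** the landscape by exact dynamic-programming binning of the
   basal-area × canopy-height volume proxy, dissolving strata under a minimum
   area (default 4.05 ha) into proxy-rank neighbors by attribute nearness;
5. **allocates** a second-phase sample across strata (Neyman or cost-aware
   optimal allocation, exact integerization) and places plots randomly, one
   per cell;
6. **estimates** post-stratified means, totals and 90% accuracy half-widths,
   strata tree lists, and sample-efficiency diagnostics 2(1−√R²);
7. **selects** an optimal grid-cell size by circular extraction around plots
   and an exhaustive lowest-BIC subset search per candidate area.

A fully synthetic landscape generator (spatially correlated basal-area /
stem-density / conifer fields, stem maps, crown-stamped CHM, noisy optical
bands, prism-cruise simulation with GPS error) makes every stage testable
offline with known ground truth.

## CLI

```bash
# full two-phase workflow on a synthetic landscape
stratiforest run --config cfg.yaml --out artifacts/

# individual stages against the same artifact directory
stratiforest simulate  --config cfg.yaml
stratiforest summarize --config cfg.yaml
stratiforest reduce    --config cfg.yaml
stratiforest fit       --config cfg.yaml
stratiforest stratify  --config cfg.yaml
stratiforest allocate  --config cfg.yaml --total-n 611 --seed 42
stratiforest estimate  --config cfg.yaml

# grid-cell-size scan (circular extraction + exhaustive BIC search)
stratiforest gridsize --out artifacts/ --plots plots.csv --response ba
```

Example `cfg.yaml`:

```yaml
out_dir: artifacts
landscape:
  extent_m: [1000, 1000]
  cell_size_m: 20
  spatial_corr_range_m: 150
  ba_mean: 40
  ba_sd: 20
  seed: 1
phase1_n: 100      # training plots
total_n: 200       # second-phase plots
strata_k: 8
min_area_ha: 4.05
baf: 4.6
seed: 1
```

Artifacts written per run: rasters (`*.asc`), `crowns.geojson`, `stems.csv`,
`cells.csv` (feature table + PCA scores + predictions + stratum labels),
`models.json`, `strata.csv`, `allocation.csv`, `phase2_plots.csv`,
`estimates.csv`, and `manifest.json` with content hashes for reproducibility.

## Package layout

| module | role |
|---|---|
| `stratiforest.raster` | grid spec, raster layers, ASCII-grid I/O |
| `stratiforest.synthetic` | landscape generator, prism-cruise simulator |
| `stratiforest.features` | crown segmentation, per-cell summaries |
| `stratiforest.reduction` | PCA reduction, cross-set correlation |
| `stratiforest.models` | Lasso screen, model fits, predictions |
| `stratiforest.stratify` | volume proxy, optimal binning, min-area merge |
| `stratiforest.design` | Neyman allocation, plot placement |
| `stratiforest.estimate` | plot expansion, post-stratified estimators |
| `stratiforest.gridsize` | circular extraction, BIC subset search |
| `stratiforest.pipeline` / `cli` | staged workflow and CLI |
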