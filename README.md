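# soundlur

City-scale sound-environment modelling as a reusable pipeline:

1. **synthetic_city** — generates a synthetic study area (covariate rasters,
   road/POI/water vector layers), a stratified monitoring campaign with core
   oversampling, per-clip top-3 sound-class detections on a 10-minute
   schedule driven by a logistic ground-truth process, and day/night sound
   level surfaces (dBA). Everything downstream is testable without external
   data; any real dataset matching the same schemas can be substituted.
2. **prevalence** — maps fine class labels to sound categories
   (road-transport, animal/insect, music, speech, geophysical nature,
   aircraft, other), splits clips into day (06:00–21:59) and night
   (22:00–05:59) windows, computes per-site-date-period prevalence (%),
   rebalances year-long fixed sites by subsampling 30 random days, and
   provides classifier-validation arithmetic (accuracy/PPV/NPV).
3. **features** — buffer-based spatial predictors at sites and grid cells:
   road length per class, POI counts, NDVI/population means, land-cover
   shares, building counts, waterway length, elevation, and distance to the
   nearest major road, at radii 50/100/200/500 m. Closed-disk convention,
   cell-center rule for raster statistics.
4. **lur** — one 500-tree Random Forest per category × period with
   permutation-importance buffer selection (one radius per variable,
   ties to the smaller radius), a-priori day/night predictor exclusion,
   site-grouped 10-fold cross-validation (MdAE/MAE/ME/Pearson r),
   Moran's I residual diagnostics, and a combined standardized-residual
   score across models.
5. **predict** — masked 50 m prediction surfaces (cells without roads,
   fully water, or fully natural are excluded) plus zonal summaries
   (median/IQR/min/max by whole area, core, road proximity).
6. **index** — the composite SoundType Index: equal-weight geometric
   aggregation of min-max-normalized sound levels with prevalence
   proportions, per category and period, values in [0, 1].
7. **pipeline** — YAML-configured orchestration with derived stage seeds
   and a deterministic SHA-256 run manifest.

All geometry is planar (meters). Rasters are plain-text ESRI ASCII grids,
vectors are GeoJSON, tables are CSV — the whole artifact chain is text.

## CLI

```bash
# everything at once
soundlur run-all --config examples/demo.yaml --seed 7

# or stage by stage on serialized artifacts
soundlur simulate --config examples/demo.yaml --out-dir runs/sim
soundlur prevalence --clips runs/sim/clips.csv --sites runs/sim/sites.csv \
    --subsample-fixed 30 --seed 7 --out runs/prevalence.csv
soundlur features --sites runs/sim/sites.csv --layers-dir runs/sim \
    --out runs/site_features.csv
soundlur fit --table runs/model_table.csv --features runs/site_features.csv \
    --category road_transport --period day --trees 500 --folds 10 --seed 7 \
    --out runs/road_day.joblib
soundlur predict --model runs/road_day.joblib --layers-dir runs/sim \
    --out runs/road_day.asc
soundlur index --levels runs/sim/l_day.asc --prevalence-surface runs/road_day.asc \
    --category road_transport --period day --weights 0.5 0.5 \
    --out runs/road_day_index.asc
```

## Layout

```
src/soundlur/
  synthetic_city.py  prevalence.py  features.py  lur.py
  predict.py         index.py       pipeline.py  cli.py
  io.py  _grid.py    data/default_specs.yaml
tests/               # unit + property + acceptance suites
scripts/acceptance.py
examples/demo.yaml
```
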