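# eslines

Ecosystem-service constraint-line analysis as a tested, reusable pipeline:

1. **synthgen** — synthetic inputs with known structure: land-use mosaics
   with tunable composition and clumping, spatially autocorrelated
   climate/NDVI surfaces with imposed interannual trends, a central-ridge
   DEM, soil texture fields, and ES-pair scatter clouds whose upper
   boundary is a known analytic hump or exponential curve.
2. **esmodels** — four ecosystem services per year: light-use-efficiency
   NPP, NDVI-proportional food-production allocation (zone totals
   conserved exactly), RUSLE soil conservation (monthly erosivity, EPIC
   erodibility, slope-length LS, cover and practice factors), and
   Budyko-curve annual water yield.
3. **landmetrics** — landscape composition shares plus five
   configuration metrics (PAFRAC, LSI, CONTAG, SHDI, PD) from their
   standard landscape-level raster definitions.
4. **constraint** — constraint-line extraction by quantile segmentation:
   bin the x-axis, take a high per-bin quantile of y, fit a quadratic
   hump (vertex = threshold) or exponential decay `y = b * k**x`.
5. **dynamics** — characteristic values tracked over years: OLS-on-year
   trend tests with the two-star convention, type-7 box statistics with
   1.5*IQR fences, series extrema, per-service annual summaries. A
   transcribed 21-year reference table ships as a packaged CSV fixture.
6. **drivers** — attribution of characteristic-value change to climate,
   vegetation, landscape composition/configuration and socioeconomic
   drivers: standardized forward-stepwise OLS (AICc entry, VIF guard),
   Shapley-decomposed relative importance summing to 1, and an
   interaction model adding socioeconomic x configuration products.

## CLI

```bash
eslines run-all --outdir runs/demo --seed 1            # default demo config
eslines run-all --config my.yaml --seed 7 --outdir out # custom config
eslines metrics --outdir out                           # run through one stage
eslines fixtures table4 --outdir fixtures              # packaged fixtures
```

The default configuration (150x150 grid, 21 years) runs end to end in a
few seconds and writes per-stage CSVs (`es_means.csv`,
`landscape_metrics.csv`, `constraint_curves.csv`, `feature_trends.csv`,
`feature_boxstats.csv`, `attribution.csv`), per-year rasters as
single-band TIFF, and a `manifest.yaml` with the config hash and output
checksums. Re-running with the same seed reproduces every CSV
byte-for-byte. See `eslines.config.default_config()` for all knobs; user
YAML is validated against the schema and unknown keys are rejected.

## Layout

```
src/eslines/        grids, synthgen, esmodels, landmetrics, constraint,
                    dynamics, drivers, config, pipeline, cli
src/eslines/data/   packaged reference table (table4_features.csv)
tests/              unit + property tests and test_acceptance.py
scripts/            acceptance.py
```
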