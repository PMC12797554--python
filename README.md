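# chmbiomass

Scale-aware estimation of forest aboveground biomass density (AGBD, Mg ha⁻¹)
from canopy height model (CHM) rasters and inventory plots.

The package implements and compares three inference engines over arbitrary
reporting scopes (forest strata, administrative domains, and their
crossings):

* **DB** — design-based estimation: the plot sample mean with the
  simple-random-sampling variance and Student-t intervals.
* **MB** — model-based estimation: per-stratum power-law calibrations
  (`AGBD = a·h₁ᵇ·h₂ᶜ`) applied to every grid cell, with a delta-method
  standard error driven by the fitted parameter covariance.
* **SAE** — two-phase small-area estimation with an exhaustive first phase:
  a global OLS working model on canopy metrics (h99, h_mean, cover), applied
  to the exhaustive auxiliary mean of the small area plus a local
  mean-residual correction.

Its central experiment is **scale transfer**: models calibrated at the
plot-native 44-m support are applied unchanged to canopy-metric grids
computed at 10, 25, 44 and 100 m, quantifying the aggregation bias of
nonlinear prediction relative to the 44-m baseline (finer grids overpredict,
coarser grids underpredict).

Because the original survey data is not deposited, the package ships a
first-class synthetic landscape generator (`chmbiomass.landscape`):
autocorrelated lognormal height fields with canopy gaps, Voronoi stratum
patches, rectangular domains, a known power-law height→biomass truth, and
systematic circular-plot sampling with a canopy-cover inclusion filter.
Every downstream stage is testable against exact known truths.

## CLI

```bash
chmbiomass simulate   --config examples/config.yaml --out runs/sim
chmbiomass metrics    --config examples/config.yaml --in runs/sim --out runs/metrics
chmbiomass calibrate  --plots runs/metrics/plots_metrics.csv --out runs/models.json
chmbiomass experiment --config examples/config.yaml --out runs/exp --seed 7
chmbiomass coverage   --config examples/config.yaml --out runs/cov --replicates 200
chmbiomass report     --in runs/exp
```

`experiment` runs the whole pipeline (simulate → metrics → calibrate →
estimate → compare) and writes `comparison.csv` with one row per
(method, scope, scale): mean, SE, CI half-width ε, relative SE (%), totals
(mean × area for DB/SAE; per-pixel biomass weight summation for MB) and the
relative change of each MB estimate against the 44-m baseline.  Every output
directory gets a `manifest.json` (seed, config hash, versions) sufficient to
reproduce the run bit-identically.

## Package layout

| module | contents |
|---|---|
| `chmbiomass.raster` | planar `RasterGrid`, TIFF round trip |
| `chmbiomass.landscape` | synthetic landscape generator, plot sampling, exact truth |
| `chmbiomass.metrics` | plot-footprint and square-window canopy metrics, label stamping |
| `chmbiomass.calibration` | nonlinear power-model fits, VIF screen, predictor selection, fit statistics |
| `chmbiomass.estimators` | DB / MB / SAE estimators, working model, coverage counting |
| `chmbiomass.experiment` | scale-transfer experiment, totals upscaling, coverage driver |
| `chmbiomass.reference` | bundled reference stratum table and published calibrations |
| `chmbiomass.acceptance` | the acceptance-report computations |
| `chmbiomass.config`, `chmbiomass.cli` | YAML run configuration and the `chmbiomass` CLI |
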