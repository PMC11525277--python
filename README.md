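# regcdi

Regional combined agricultural drought monitoring from gridded land-surface
time series.

Agricultural drought is the joint outcome of low soil moisture, heat stress
and crop water stress, and no single remote-sensing indicator captures all
three.  This package builds a **regional combined drought index (RegCDI)**:
a per-pixel, entropy-weighted convex combination of normalized drought
indicators, with low values meaning severe drought.  It is aimed at
researchers and analysts who have co-registered monthly raster stacks of
land surface temperature, surface soil moisture, surface reflectance and
precipitation (for example from land data assimilation systems and optical
sensors) plus district crop-yield tables, and who want a single monitorable
index with drought classification, hotspot mapping, yield validation and
short-lead early warning.

## The method

1. **Candidate indicators** are computed from the raw stacks: reflectance
   ratios NDWI = (NIR−SWIR)/(NIR+SWIR), NDVI, and SIWSI = (ρ_swir−ρ_nir)/(ρ_swir+ρ_nir);
   climatology-scaled condition indices VCI, TCI and SMCI
   (e.g. SMCI = (SSM−SSM_min)/(SSM_max−SSM_min)); the recursive soil
   moisture deficit index SMDI_i = 0.5·SMDI_{i−1} + SD_i/50; the soil water
   deficit index SWDI = (θ−θ_FC)/θ_AWC; and SPI-3/SPI-6 from gamma-fitted
   precipitation accumulations.
2. **Indicator selection** screens candidates by the Pearson correlation of
   growing-season drought severity with district yield and standardized
   yield, keeping the best of each type; the shipped default triple is
   {SMCI, TCI, SIWSI-1}.
3. **Entropy weighting**, per pixel: each normalized indicator series
   r ∈ [0,1] gives frequencies f_j = r_j / Σ_j r_j, Shannon entropy
   H = −(1/ln n) Σ f ln f, and weight W_i = (1−H_i)/(m−ΣH_i); the index is
   RegCDI_j = Σ_i W_i r_{i,j} ∈ [0,1].
4. **Classification** follows the USDM categories D0–D4, either by fixed
   index ranges (D4 ≤ 0.02 < D3 ≤ 0.05 < D2 ≤ 0.10 < D1 ≤ 0.20 < D0 ≤ 0.30
   < wet) or by each pixel's own 2/5/10/20/30 percentiles.
5. **Run theory** extracts drought events (maximal runs below a threshold,
   default 0.12 at 0.25° and 0.17 at 1°) with duration and severity, and
   assembles hotspot layers (mean annual severity/duration, drought-month
   and severe-month counts, seasonal propensity).
6. **Validation and early warning** use confusion matrices between binary
   drought states — accuracy 100·(TP+TN)/total and the Matthews correlation
   coefficient — against standardized yield and between the index and its
   constituent indicators lagged by 1–3 months.

## Worked example

The package ships a synthetic-scene generator that emulates a 19-year
monsoon-climate record (seasonal cycles, AR(1) anomalies, two localized
multi-month drought episodes, yield coupled to Kharif-season drought
stress), so the whole pipeline runs without any external data:

```python
import numpy as np
import regcdi
from regcdi.pipeline import default_index
from regcdi.runstats import RunConfig, hotspot_stack
from regcdi.core import classify

scene = regcdi.generate_scene(regcdi.SceneConfig(seed=1))
result = default_index(scene.ssm, scene.lst, scene.swir1, scene.nir)

w = result.weights
print("indicator weights (grid mean):")
for name, wi in zip(w.names, w.weights):
    print(f"  {name:8s} {np.nanmean(wi):.3f}")

classes = classify(result.index, "percentile")
months = regcdi.drought_months(classes, "all")
print(f"drought months per pixel (D1-D4): mean {months.mean():.1f} "
      f"of {result.index.series.n_time}")

hs = hotspot_stack(result.index, classify(result.index, "fixed"),
                   RunConfig(0.12))
print(f"mean annual drought duration: {np.nanmean(hs.mean_annual_duration):.2f} months/yr")

table = regcdi.standardize_yield(scene.yields)
sev = regcdi.seasonal_severity(result.index, regcdi.KHARIF)
pcc = regcdi.correlation_map(sev, table, scene.zones, target="z")
print(f"mean PCC, Kharif severity vs standardized yield: {np.nanmean(pcc):.2f}")

for lag in (1, 3):
    ew = regcdi.early_warning(result.index, scene.ssm, lag, threshold=0.12)
    print(f"early warning, SSM lag {lag}: accuracy {ew['accuracy']:.1f}%  "
          f"MCC {ew['mcc']:.2f}")
```

prints

```
indicator weights (grid mean):
  SMCI     0.414
  TCI      0.438
  SIWSI-1  0.148
drought months per pixel (D1-D4): mean 46.0 of 228
mean annual drought duration: 0.47 months/yr
mean PCC, Kharif severity vs standardized yield: 0.10
early warning, SSM lag 1: accuracy 80.0%  MCC 0.15
early warning, SSM lag 3: accuracy 78.4%  MCC 0.05
```

Reading the numbers: the entropy method spreads weight over the three
constituents according to the information content of each pixel's series;
the percentile scheme flags close to its nominal 20 % of months (46 of 228)
as drought; the seasonal-minimum index correlates positively with
standardized yield (drought years → low index and low yield); and the
soil-moisture predictor loses skill as the lead time grows from one to
three months, because the generator propagates soil-moisture deficit into
the vegetation response with a one-month lead.

The same pipeline is available from the shell:

```
regcdi --seed 7 synth --out-dir data/
regcdi combine --in-dir data/ --out regcdi.nc
regcdi classify --in regcdi.nc --scheme percentile --out classes.nc
regcdi stats --regcdi regcdi.nc --threshold 0.12 --out hotspots.json
regcdi earlywarn --regcdi regcdi.nc --predictors preds/ --lags 1,2,3 --out ew.csv
```

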