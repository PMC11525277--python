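# Methods

## The combined index

The package's core is a per-pixel convex combination of m normalized,
drought-oriented indicator series.  For each indicator i at a pixel, the
monthly series is min–max rescaled to r_ij ∈ [0, 1] over the full study
period (the same window over which the weights are computed), oriented so
that *low* values mean drought.  The Shannon-entropy weighting then treats
each series as a discrete distribution over its n months:

    f_ij = r_ij / Σ_j r_ij
    H_i  = −(1/ln n) Σ_j f_ij ln f_ij        (0·ln 0 := 0, so H ∈ [0, 1])
    W_i  = (1 − H_i) / (m − Σ_i H_i)

A series whose mass is spread uniformly over time (H → 1) carries no
discriminating information and gets weight → 0; a series concentrated in a
few months earns more weight.  The combined index is
RegCDI_j = Σ_i W_i r_ij ∈ [0, 1].  Weights are per pixel and per
indicator, computed once over the whole monthly record (not per season),
so spatial variation in indicator informativeness is preserved.

Assumptions worth stating plainly:

* The entropy functional is applied to the normalized values themselves,
  not to a histogram of them — months are the categories.  This is the
  convention of entropy-weighted composite indices in the drought
  literature, and it means the weights react to the *temporal shape* of
  each indicator, not to its marginal distribution.
* If every indicator at a pixel is maximally uninformative (Σ H = m) the
  weight formula is 0/0; the implementation falls back to equal weights
  with a logged warning rather than failing the whole grid.
* Indicators that increase with stress (SIWSI) are flipped (1 − r) during
  normalization so the combination is orientation-consistent; a flag
  disables this for users who want the raw orientation.

## Indicators

All eight candidate indicators are implemented: NDWI, VCI, TCI (vegetation
condition), SMCI, SMDI, SWDI (soil moisture), SIWSI-1/2 (crop water
stress), plus NDVI and SPI-3/6 for comparison.  Climatologies (per-pixel
min/mean/max) are computed **per calendar month across years** by default —
"maximum NDVI" is the multi-year maximum for that month — which is the
standard VCI/TCI convention; a whole-series mode exists for short records.
Out-of-envelope condition-index values are clipped to the nominal range by
default (maskable via `clip=False`).  Division-by-zero cells (flat
climatology, zero reflectance sums) are masked, never silently zeroed.

SMDI uses the two-branch monthly departure SD ∈ [−1, 1] and the recursion
SMDI_i = 0.5·SMDI_{i−1} + SD_i/50 from a neutral start (SMDI₀ = 0; the 0.5
memory makes the initialization decay within about six months).  The
printed constants force |SMDI| ≤ (1/50)/(1−0.5) = 0.04 in the limit, which
the tests check as a geometric-series identity.  Values exactly at the
climatological mean are assigned SD = 0 with a relative tolerance, because
an exactly-repeating cycle can otherwise produce ±1 from a ratio of two
round-off residuals.

SPI follows the McKee construction: k-month trailing accumulations, a
zero-inflated gamma fit per pixel and calendar month
(H(x) = q + (1−q)·G(x), maximum likelihood with the location fixed at
zero), then the inverse standard normal.  A minimum of 15 years is
required; degenerate fits (constant or near-constant accumulations) are
masked with a logged count.  Zero-accumulation months map through q/2
(the midpoint of the zero mass).  SWDI soil parameters (θ_FC, θ_AWC) are
user-supplied; a fallback estimates them from the 95th/5th percentiles of
the soil-moisture record itself and is clearly flagged as an
approximation, not a pedotransfer function.

## Classification, runs and hotspots

Classification offers two schemes.  The fixed-range scheme maps the index
through the published category bounds with lower-exclusive /
upper-inclusive intervals — D4 = [0, 0.02], D3 = (0.02, 0.05], D2 =
(0.05, 0.10], D1 = (0.10, 0.20], D0 = (0.20, 0.30], wet above — chosen so
every boundary value lands in exactly one class.  The percentile scheme
applies the USDM cuts (2/5/10/20/30) to each pixel's own empirical index
distribution, making severity site-specific.  Note a structural
consequence: under the percentile scheme every pixel has, by construction,
the same expected count of drought months, so hotspot *count* maps should
use the fixed scheme (the percentile scheme is for categorizing conditions
at a site, not for contrasting sites).

Run theory defines an event as a maximal run of months with index strictly
below a threshold (defaults 0.12 at 0.25° and 0.17 at 1° — the published
region-mean severe-drought boundaries at those resolutions; `--threshold
auto` selects by the stack's resolution tag).  Duration is the run length;
severity is the sum of index values in the run, so a lower sum per month
is a worse event.  Masked months terminate runs — data gaps are never
bridged.  Drought-month counts include D1–D4; D0 ("abnormally dry") is
never counted as drought.

A second structural consequence of per-pixel normalization: a pixel that
experienced a deep episode has its whole series stretched by that episode,
which *lifts* its ordinary months relative to pixels without one.  Mild
drought counts (D1) are therefore weak hotspot discriminators; the
severe-to-exceptional count and the mean annual severity carry the
hotspot signal, and the test suite asserts recovery on those layers.

## Validation and early warning

Yield is standardized per district, z = (x − μ)/σ with the *sample*
standard deviation (ddof = 1; configurable), requiring at least three
usable years and positive spread.  Seasonal drought severity is the
minimum index over a season's months per year ("season-min") or the value
at a configured critical growth-stage month (default August, the middle of
the Kharif season).  Indicator screening correlates severity with yield
and standardized yield per pixel against the pixel's district, and picks
the best indicator per type by the mean of the two region-mean
correlations (ties: standardized-yield correlation, then name).

Binary agreement uses the confusion matrix with accuracy in percent and
the Matthews correlation coefficient; MCC equals the Pearson correlation
of the two 0/1 vectors, which the tests assert to 1e−12, and a zero
denominator factor is reported as 0 with a warning.  Yield years are
binarized by z < 0; index months by value < threshold (strict, so a value
at the threshold is not drought).  For early warning, a predictor
indicator at month t − lag is compared with the index drought state at
month t, pooled over all pixels and months into one matrix per lag.
Predictors are binarized by the percentile classification of their own
normalized series (D1–D4 = drought) by default, which puts indicators
with different native scales on a common footing.

## The synthetic generator

`generate_scene` produces the study conditions the tests run under: a
10×10 grid, 19 years (2001–2019) of monthly data, six rectangular
districts, deterministic seasonal cycles (LST sinusoid peaking
pre-monsoon; a Gaussian Jun–Sep monsoon pulse driving soil-moisture
recharge, rainfall and vegetation green-up), and AR(1) anomalies
(ρ = 0.6) split into a region-wide component and pixel noise so districts
have coherent interannual variability.  Drought stress combines imposed
episodes (two by default: a 6-month Kharif-season episode at intensity
0.8 and a 5-month Rabi/summer episode at 0.75, each in a 3×3 region) with
background dry anomalies.  Stress depresses soil moisture and rainfall
and elevates temperature immediately; the vegetation/reflectance response
(NIR down, red and SWIR up) lags by one month (`veg_lag`).  District
yield is base 2000 kg/ha minus 600 kg/ha per unit mean Kharif stress plus
N(0, 60²) noise.  Reflectance bands are clipped to [0, 1] after
perturbation.

What the generator does *not* emulate: radiative-transfer realism, cloud
or sensor artifacts, spatially structured soil properties, irrigation,
and any particular region's climatology.  Passing recovery tests
therefore demonstrate that the pipeline's statistics behave as designed
under the assumed structure (seasonality + autocorrelated anomalies +
localized episodes + lagged propagation), not that the index is validated
against real satellite archives — that requires the user's own data.

## Numerical choices and problem sizes

* Combined-index values are clamped to [0, 1] after combination (the
  convex sum can exceed 1 by ~1e−16 in floats); classification rejects
  genuine out-of-range input.
* Constant pixels cannot be min–max normalized and are masked, with a
  logged count; all-zero normalized series have undefined entropy
  frequencies and are likewise masked.
* NetCDF I/O uses the NetCDF3 64-bit format via xarray's scipy backend
  (CF-style time/lat/lon); the alternative raster dialect is a directory
  of single-band monthly TIFFs with timestamps in file names.  An
  unordered time axis is sorted ascending with a logged notice.  Missing
  cells are stored as NaN and recovered into the mask on read.
* Tests and the acceptance script run the full pipeline on 10×10 × 228
  month scenes (and ten replicate seeds for the recovery properties),
  which keeps a complete run in the low seconds while leaving every
  statistic well away from small-sample degeneracy; SPI checks use 30
  years of synthetic gamma rainfall on a 2×2 grid.

## Known limitations

* Inputs must be pre-co-registered; no reprojection or resampling is
  performed (resolution is a metadata tag used only for threshold
  defaults).
* The entropy weights are stationary over the analysis window; regime
  changes within the record will be averaged over.
* The percentile classification needs a long record to make its tail cuts
  (2 %, 5 %) meaningful; on short records the fixed scheme is preferable.
* District–pixel pairing is by the user-supplied zone raster; pixels
  spanning several districts must be assigned by majority area upstream.
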