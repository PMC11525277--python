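"""Candidate agricultural drought indicators.

Implements the standard remote-sensing indicator suite used for combined
drought indexing: reflectance ratios (NDWI, NDVI, SIWSI), condition
indices scaled against a per-pixel climatology (VCI, TCI, SMCI), soil
water deficit indices (SMDI, SWDI) and the standardized precipitation
index (SPI).

Conventions
-----------
* Climatologies (min/max/mean) are computed per pixel and per calendar
  month across all study years — "maximum NDVI" means the multi-year
  maximum for that calendar month, the usual VCI/TCI convention.  A
  whole-series mode is available via ``monthly=False``.
* Division by zero (flat climatology, zero reflectance sums) masks the
  cell; it is never silently zero.
* Condition indices are clipped to their nominal range for values outside
  the climatology envelope (``clip=True`` default); ``clip=False`` masks
  them instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from regcdi.grid import GriddedSeries, GridError, assert_aligned

logger = logging.getLogger(__name__)

__all__ = [
    "ClimatologyGrid", "SoilParameterGrid", "SpiParameters",
    "compute_ndwi", "compute_ndvi", "compute_vci", "compute_tci",
    "compute_smci", "compute_smdi", "compute_swdi", "compute_siwsi",
    "fit_spi", "compute_spi", "estimate_soil_parameters",
]


# ---------------------------------------------------------------------------
# Climatology
# ---------------------------------------------------------------------------

@dataclass
class ClimatologyGrid:
    """Per-pixel min/mean/max of a series over a reference period.

    In monthly mode the arrays have shape (12, row, col), one slice per
    calendar month; in whole-series mode they are (1, row, col) and apply
    to every month.  Only unmasked months contribute.
    """

    vmin: np.ndarray
    vmean: np.ndarray
    vmax: np.ndarray
    monthly: bool
    reference: tuple[int, int]  # (first year, last year)

    @classmethod
    def from_series(cls, series: GriddedSeries, monthly: bool = True) -> "ClimatologyGrid":
        vals = series.masked()
        years = series.years
        if monthly:
            months = series.months
            shape = (12,) + series.grid_shape
            vmin = np.full(shape, np.nan)
            vmax = np.full(shape, np.nan)
            vmean = np.full(shape, np.nan)
            for m in range(1, 13):
                sel = vals[months == m]
                if sel.size == 0:
                    continue
                with np.errstate(all="ignore"):
                    vmin[m - 1] = np.nanmin(sel, axis=0)
                    vmax[m - 1] = np.nanmax(sel, axis=0)
                    vmean[m - 1] = np.nanmean(sel, axis=0)
        else:
            with np.errstate(all="ignore"):
                vmin = np.nanmin(vals, axis=0)[None]
                vmax = np.nanmax(vals, axis=0)[None]
                vmean = np.nanmean(vals, axis=0)[None]
        return cls(vmin=vmin, vmean=vmean, vmax=vmax, monthly=monthly,
                   reference=(int(years.min()), int(years.max())))

    def at_months(self, months: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(min, mean, max) broadcast to a (time, row, col) stack."""
        if self.monthly:
            idx = np.asarray(months) - 1
        else:
            idx = np.zeros(len(months), dtype=int)
        return self.vmin[idx], self.vmean[idx], self.vmax[idx]


@dataclass
class SoilParameterGrid:
    """Per-pixel field capacity and available water capacity (m3/m3)."""

    theta_fc: np.ndarray
    theta_awc: np.ndarray

    def __post_init__(self) -> None:
        self.theta_fc = np.asarray(self.theta_fc, dtype=float)
        self.theta_awc = np.asarray(self.theta_awc, dtype=float)
        ok = np.isfinite(self.theta_fc) & np.isfinite(self.theta_awc)
        if np.any((self.theta_awc[ok] <= 0)):
            raise GridError("theta_AWC must be positive")
        if np.any((self.theta_fc[ok] <= 0) | (self.theta_fc[ok] >= 1)):
            raise GridError("theta_FC must lie in (0, 1)")


def estimate_soil_parameters(theta: GriddedSeries) -> SoilParameterGrid:
    """Approximate soil parameters from the soil-moisture record itself.

    Field capacity is taken as the per-pixel 95th percentile of volumetric
    water content and the available water capacity as the 95th-5th
    percentile spread.  This is a pragmatic approximation for when mapped
    soil properties are unavailable, not a pedotransfer estimate.
    """
    vals = theta.masked()
    with np.errstate(all="ignore"):
        p95 = np.nanpercentile(vals, 95, axis=0)
        p05 = np.nanpercentile(vals, 5, axis=0)
    awc = p95 - p05
    awc[awc <= 0] = np.nan
    logger.warning("soil parameters estimated from the soil moisture record "
                   "(95th/5th percentiles); supply mapped values if available")
    return SoilParameterGrid(theta_fc=np.clip(p95, 1e-6, 1 - 1e-6), theta_awc=awc)


# ---------------------------------------------------------------------------
# Reflectance ratios
# ---------------------------------------------------------------------------

def _normalized_difference(a: GriddedSeries, b: GriddedSeries,
                           variable: str) -> GriddedSeries:
    assert_aligned(a, b)
    num = a.values - b.values
    den = a.values + b.values
    mask = a.mask | b.mask | (den == 0)
    out = np.zeros_like(num)
    np.divide(num, den, out=out, where=~mask)
    out[mask] = np.nan
    return a.replace(out, variable=variable, units="", mask=mask)


def compute_ndwi(nir: GriddedSeries, swir: GriddedSeries) -> GriddedSeries:
    """Normalized difference water index (NIR-SWIR)/(NIR+SWIR), in [-1, 1].

    Decreases with canopy water loss; zero-sum denominators are masked.
    """
    return _normalized_difference(nir, swir, "NDWI")


def compute_ndvi(nir: GriddedSeries, red: GriddedSeries) -> GriddedSeries:
    """Normalized difference vegetation index (NIR-red)/(NIR+red)."""
    return _normalized_difference(nir, red, "NDVI")


def compute_siwsi(swir_band: GriddedSeries, nir_band: GriddedSeries,
                  variant: int = 1) -> GriddedSeries:
    """Shortwave-infrared water stress index (rho_swir-rho_nir)/(rho_swir+rho_nir).

    Variant 1 uses the 1628-1652 nm SWIR channel (MODIS band 5), variant 2
    the 1230-1250 nm channel (band 6 numbering of the source product);
    either way the caller supplies the SWIR stack.  Higher values indicate
    greater leaf-water stress — note the opposite orientation to NDWI.
    """
    return _normalized_difference(swir_band, nir_band, f"SIWSI-{variant}")


# ---------------------------------------------------------------------------
# Condition indices against the climatology
# ---------------------------------------------------------------------------

def _condition_index(series: GriddedSeries, clim: ClimatologyGrid,
                     invert: bool, scale: float, variable: str,
                     clip: bool = True) -> GriddedSeries:
    vmin, _, vmax = clim.at_months(series.months)
    span = vmax - vmin
    flat = ~(span > 0)  # includes NaN climatology
    if invert:
        num = vmax - series.values
    else:
        num = series.values - vmin
    mask = series.mask | flat
    frac = np.zeros_like(series.values)
    np.divide(num, span, out=frac, where=~mask)
    if clip:
        frac = np.clip(frac, 0.0, 1.0)
    else:
        mask = mask | (frac < 0) | (frac > 1)
    out = frac * scale
    out[mask] = np.nan
    return series.replace(out, variable=variable, units="", mask=mask)


def compute_vci(ndvi: GriddedSeries, clim: ClimatologyGrid,
                clip: bool = True) -> GriddedSeries:
    """Vegetation condition index 100*(NDVI-NDVImin)/(NDVImax-NDVImin) in [0, 100]."""
    return _condition_index(ndvi, clim, invert=False, scale=100.0,
                            variable="VCI", clip=clip)


def compute_tci(lst: GriddedSeries, clim: ClimatologyGrid,
                clip: bool = True) -> GriddedSeries:
    """Temperature condition index (LSTmax-LST)/(LSTmax-LSTmin).

    1 at the cool extreme, 0 at the hot extreme (hot = stressed).
    """
    return _condition_index(lst, clim, invert=True, scale=1.0,
                            variable="TCI", clip=clip)


def compute_smci(ssm: GriddedSeries, clim: ClimatologyGrid,
                 clip: bool = True) -> GriddedSeries:
    """Soil moisture condition index (SSM-SSMmin)/(SSMmax-SSMmin) in [0, 1]."""
    return _condition_index(ssm, clim, invert=False, scale=1.0,
                            variable="SMCI", clip=clip)


# ---------------------------------------------------------------------------
# Soil water deficit indices
# ---------------------------------------------------------------------------

def compute_smdi(ssm: GriddedSeries, clim: ClimatologyGrid) -> GriddedSeries:
    """Soil moisture deficit index, the first-order recursive deficit index.

    The monthly soil-water departure is scaled to [-1, 1] against the
    climatological mean and the dry/wet extreme of the active branch::

        SD_i = (SW_i - MSW_i) / (MSW_i - MinSW_i)   if SW_i <= MSW_i
        SD_i = (SW_i - MSW_i) / (MaxSW_i - MSW_i)   if SW_i >  MSW_i
        SMDI_i = 0.5 * SMDI_{i-1} + SD_i / 50

    starting from SMDI = 0 before the first month (the 0.5 memory makes
    the initial condition decay within ~6 months).  With SD bounded in
    [-1, 1] the recursion is bounded by |SMDI| <= (1/50)/(1-0.5) = 0.04.
    A flat climatology in the active branch masks the cell, which also
    resets the recursion there.
    """
    vmin, vmean, vmax = clim.at_months(ssm.months)
    sw = ssm.values
    below = sw <= vmean
    dry_span = vmean - vmin
    wet_span = vmax - vmean
    num = sw - vmean
    # at the climatological mean both branches give 0; zero the departure
    # there so float round-off in the mean cannot masquerade as +-1
    with np.errstate(invalid="ignore"):
        at_mean = np.isclose(sw, vmean, rtol=1e-9, atol=1e-12)
    num = np.where(at_mean, 0.0, num)
    sd = np.zeros_like(sw)
    flat = np.where(below, ~(dry_span > 0), ~(wet_span > 0))
    # SW exactly at the mean: both branches give 0, so a flat span is harmless
    flat &= num != 0
    span = np.where(below, dry_span, wet_span)
    with np.errstate(all="ignore"):
        np.divide(num, span, out=sd, where=~flat & (span != 0))
    mask = ssm.mask | flat
    sd[mask] = np.nan

    out = np.full_like(sw, np.nan)
    prev = np.zeros(ssm.grid_shape)
    for i in range(ssm.n_time):
        cur = 0.5 * prev + sd[i] / 50.0
        out[i] = cur
        # masked month: value undefined, recursion restarts from neutral
        prev = np.where(mask[i], 0.0, cur)
    return ssm.replace(out, variable="SMDI", units="", mask=mask)


def compute_swdi(theta: GriddedSeries, soil: SoilParameterGrid) -> GriddedSeries:
    """Soil water deficit index (theta - theta_FC) / theta_AWC.

    0 at field capacity, negative in deficit, ~1 when the profile holds a
    full available-water capacity above field capacity.
    """
    if soil.theta_fc.shape != theta.grid_shape:
        raise GridError("soil parameter grid does not match the stack grid")
    bad = ~np.isfinite(soil.theta_fc) | ~np.isfinite(soil.theta_awc)
    vals = (theta.values - soil.theta_fc) / np.where(bad, np.nan, soil.theta_awc)
    mask = theta.mask | bad[None]
    vals[mask] = np.nan
    return theta.replace(vals, variable="SWDI", units="", mask=mask)


# ---------------------------------------------------------------------------
# Standardized precipitation index
# ---------------------------------------------------------------------------

@dataclass
class SpiParameters:
    """Zero-inflated gamma fit of k-month precipitation sums.

    Arrays are (12, row, col): a gamma shape/scale pair and a
    zero-accumulation probability per pixel and calendar month (the month
    indexing the *end* of the accumulation window).
    """

    shape: np.ndarray
    scale: np.ndarray
    zero_prob: np.ndarray
    scale_months: int

    def valid(self) -> np.ndarray:
        return (np.isfinite(self.shape) & np.isfinite(self.scale)
                & (self.shape > 0) & (self.scale > 0))


def _rolling_sum(values: np.ndarray, mask: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """k-month trailing sums; a window touching a masked month is masked."""
    t = values.shape[0]
    out = np.full_like(values, np.nan)
    out_mask = np.ones_like(mask)
    filled = np.where(mask, 0.0, values)
    csum = np.cumsum(filled, axis=0)
    cbad = np.cumsum(mask.astype(int), axis=0)
    for i in range(k - 1, t):
        total = csum[i] - (csum[i - k] if i >= k else 0.0)
        nbad = cbad[i] - (cbad[i - k] if i >= k else 0)
        ok = nbad == 0
        out[i] = np.where(ok, total, np.nan)
        out_mask[i] = ~ok
    return out, out_mask


def fit_spi(precip: GriddedSeries, scale_months: int = 3,
            min_years: int = 15) -> SpiParameters:
    """Fit the SPI distribution to monthly precipitation.

    Accumulations over ``scale_months`` trailing months are fitted per
    pixel and calendar month with a mixed distribution
    ``H(x) = q + (1 - q) * Gamma(shape, scale)`` where q is the fraction
    of zero accumulations — the McKee convention.  Pixels/months whose
    nonzero accumulations are too few or degenerate (e.g. constant) are
    left unfitted and later masked with a logged warning.
    """
    if precip.n_years < min_years:
        raise GridError(f"SPI fit needs >= {min_years} years of data, "
                        f"got {precip.n_years}")
    acc, acc_mask = _rolling_sum(precip.values, precip.mask, scale_months)
    months = precip.months
    nr, nc = precip.grid_shape
    shp = np.full((12, nr, nc), np.nan)
    scl = np.full((12, nr, nc), np.nan)
    q = np.full((12, nr, nc), np.nan)
    n_degenerate = 0
    for m in range(1, 13):
        sel = months == m
        if not sel.any():
            continue
        block = acc[sel]          # (years, nr, nc)
        bmask = acc_mask[sel]
        for r in range(nr):
            for c in range(nc):
                x = block[:, r, c][~bmask[:, r, c]]
                if x.size < min_years - 1:  # tolerate one window lost to edges
                    continue
                nz = x[x > 0]
                q_m = 1.0 - nz.size / x.size
                if nz.size < 4 or np.ptp(nz) == 0:
                    n_degenerate += 1
                    continue
                try:
                    a, _, s = stats.gamma.fit(nz, floc=0)
                except Exception:
                    n_degenerate += 1
                    continue
                if not (np.isfinite(a) and np.isfinite(s) and a > 0 and s > 0):
                    n_degenerate += 1
                    continue
                shp[m - 1, r, c] = a
                scl[m - 1, r, c] = s
                q[m - 1, r, c] = q_m
    if n_degenerate:
        logger.warning("SPI-%d fit degenerate at %d pixel-months; masked",
                       scale_months, n_degenerate)
    return SpiParameters(shape=shp, scale=scl, zero_prob=q,
                         scale_months=scale_months)


def compute_spi(precip: GriddedSeries, params: SpiParameters) -> GriddedSeries:
    """Standardized precipitation index from a fitted :class:`SpiParameters`.

    Accumulations are mapped through the mixed CDF and the inverse
    standard normal; the first ``scale_months - 1`` months and unfitted
    cells are masked.
    """
    k = params.scale_months
    acc, acc_mask = _rolling_sum(precip.values, precip.mask, k)
    idx = precip.months - 1
    a = params.shape[idx]
    s = params.scale[idx]
    q = params.zero_prob[idx]
    ok = (np.isfinite(a) & (a > 0) & np.isfinite(s) & (s > 0) & ~acc_mask
          & np.isfinite(acc))
    with np.errstate(all="ignore"):
        g = stats.gamma.cdf(acc, a, scale=s)
        h = np.where(acc > 0, q + (1 - q) * g, q / 2.0)  # zero months at mid-mass
        h = np.clip(h, 1e-8, 1 - 1e-8)
        z = stats.norm.ppf(h)
    z[~ok] = np.nan
    return precip.replace(z, variable=f"SPI-{k}", units="", mask=~ok)
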