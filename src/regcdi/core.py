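"""Entropy-weighted combination of drought indicators and classification.

The combined index is a per-pixel convex combination of [0, 1]-normalized,
drought-oriented indicators.  Each indicator's weight at a pixel derives
from the Shannon entropy of its normalized monthly series: the frequency
series ``f_ij = r_ij / sum_j r_ij`` gives an entropy
``H_i = -K * sum_j f_ij ln f_ij`` with ``K = 1/ln n`` (n months), and the
weight is ``W_i = (1 - H_i) / (m - sum H_i)`` over the m indicators — a
less uniform series carries more information and earns more weight.  The
combined index is ``sum_i W_i r_ij``, low values meaning severe drought.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from regcdi.grid import GriddedSeries, GridError, assert_aligned

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizedIndicator", "EntropyWeights", "CombinedIndexSeries",
    "DroughtClassGrid", "CLASS_LABELS", "CLASS_BOUNDS", "PERCENTILE_CUTS",
    "normalize_indicator", "entropy_frequencies", "shannon_entropy",
    "entropy_weights", "weights_from_stack", "combine_regcdi", "classify",
]


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

@dataclass
class NormalizedIndicator:
    """A [0, 1] min-max-rescaled indicator, oriented so low = drought."""

    series: GriddedSeries
    source: str

    @property
    def values(self) -> np.ndarray:
        return self.series.values

    @property
    def mask(self) -> np.ndarray:
        return self.series.mask


def normalize_indicator(series: GriddedSeries,
                        drought_is_high: bool = False) -> NormalizedIndicator:
    """Min-max rescale a series to [0, 1] per pixel over the study period.

    ``drought_is_high=True`` flips the result (1 - r) for indicators that
    increase with stress (SIWSI), so that after preparation low values
    uniformly mean drought.  Pixels with a constant series are masked:
    min-max scaling is undefined there.
    """
    vals = series.masked()
    with np.errstate(all="ignore"):
        lo = np.nanmin(vals, axis=0)
        hi = np.nanmax(vals, axis=0)
    span = hi - lo
    constant = ~(span > 0)
    if constant.any():
        logger.warning("normalize_indicator(%s): %d constant pixels masked",
                       series.variable, int(constant.sum()))
    mask = series.mask | constant[None]
    r = np.zeros_like(series.values)
    np.divide(series.values - lo, span, out=r, where=~mask)
    if drought_is_high:
        r = 1.0 - r
    r[mask] = np.nan
    out = series.replace(r, mask=mask, units="")
    return NormalizedIndicator(series=out, source=series.variable)


# ---------------------------------------------------------------------------
# Entropy weighting
# ---------------------------------------------------------------------------

def entropy_frequencies(r: NormalizedIndicator) -> np.ndarray:
    """Frequency series f_ij = r_ij / sum_j r_ij per pixel.

    Returns a (time, row, col) array summing to 1 over time at every
    valid pixel; pixels whose series sums to zero (or has any missing
    month) come back as NaN with a logged warning.
    """
    vals = np.where(r.mask, np.nan, r.values)
    total = np.nansum(vals, axis=0)
    any_missing = r.mask.any(axis=0)
    bad = ~(total > 0) | any_missing
    if (~(total > 0) & ~any_missing).any():
        logger.warning("entropy_frequencies(%s): all-zero series at %d pixels",
                       r.source, int((~(total > 0) & ~any_missing).sum()))
    f = np.full_like(vals, np.nan)
    np.divide(vals, total[None], out=f, where=~bad[None])
    return f


def shannon_entropy(f: np.ndarray) -> np.ndarray:
    """Normalized Shannon entropy H = -K sum f ln f, K = 1/ln n, 0 ln 0 := 0.

    ``f`` is a frequency series along axis 0 (values in [0, 1] summing to
    1); the result lies in [0, 1] with 1 for the uniform distribution and
    0 for a one-hot series.
    """
    f = np.asarray(f, dtype=float)
    n = f.shape[0]
    if n < 2:
        raise GridError("entropy needs at least two time steps")
    with np.errstate(all="ignore"):
        terms = np.where(f > 0, f * np.log(f), 0.0)
        h = -np.nansum(terms, axis=0) / np.log(n)
    h = np.where(np.isnan(f).any(axis=0), np.nan, h)
    return h


def entropy_weights(h: np.ndarray) -> np.ndarray:
    """Entropy weights W_i = (1 - H_i) / (m - sum_i H_i) along axis 0.

    ``h`` has shape (m, ...) with m >= 2 indicators.  Where every
    indicator is maximally uninformative (sum H = m, a 0/0 form) the
    weights fall back to equal with a logged warning.
    """
    h = np.asarray(h, dtype=float)
    m = h.shape[0]
    if m < 2:
        raise GridError("entropy weighting needs at least two indicators")
    total = h.sum(axis=0)
    degenerate = np.isclose(total, m)
    if np.any(degenerate & np.isfinite(total)):
        logger.warning("entropy_weights: all-uniform indicators at %d pixels; "
                       "equal weights used", int(np.sum(degenerate & np.isfinite(total))))
    denom = np.where(degenerate, np.nan, m - total)
    w = (1.0 - h) / denom
    w = np.where(np.broadcast_to(degenerate, w.shape), 1.0 / m, w)
    return w


@dataclass
class EntropyWeights:
    """Per-pixel entropy weights for a named set of indicators.

    ``weights`` and ``entropy`` have shape (m, row, col); weights are
    nonnegative and sum to 1 across indicators at every valid pixel.
    """

    names: list[str]
    weights: np.ndarray
    entropy: np.ndarray
    n_months: int

    @property
    def m(self) -> int:
        return len(self.names)


def weights_from_stack(indicators: list[NormalizedIndicator]) -> EntropyWeights:
    """Compute per-pixel entropy weights for a set of normalized indicators."""
    if len(indicators) < 2:
        raise GridError("need at least two indicators to weight")
    assert_aligned(*[ind.series for ind in indicators])
    hs = []
    for ind in indicators:
        f = entropy_frequencies(ind)
        hs.append(shannon_entropy(f))
    h = np.stack(hs)
    w = entropy_weights(h)
    return EntropyWeights(names=[ind.source for ind in indicators],
                          weights=w, entropy=h,
                          n_months=indicators[0].series.n_time)


# ---------------------------------------------------------------------------
# Combination
# ---------------------------------------------------------------------------

@dataclass
class CombinedIndexSeries:
    """The combined drought index per pixel-month, in [0, 1], low = severe."""

    series: GriddedSeries
    indicator_names: list[str] = field(default_factory=list)

    @property
    def values(self) -> np.ndarray:
        return self.series.values

    @property
    def mask(self) -> np.ndarray:
        return self.series.mask


def combine_regcdi(indicators: list[NormalizedIndicator],
                   weights: EntropyWeights) -> CombinedIndexSeries:
    """Combine normalized indicators with per-pixel weights.

    ``index_j = sum_i W_i * r_ij`` — a convex combination, so the result
    stays in [0, 1] and is invariant to indicator order.  Any masked
    constituent masks the output cell.
    """
    names = [ind.source for ind in indicators]
    if sorted(names) != sorted(weights.names):
        raise GridError(f"indicator names {names} do not match weight names "
                        f"{weights.names}")
    assert_aligned(*[ind.series for ind in indicators])
    order = [names.index(n) for n in weights.names]
    ref = indicators[0].series
    out = np.zeros(ref.shape)
    mask = np.zeros(ref.shape, dtype=bool)
    for w_idx, ind_idx in enumerate(order):
        ind = indicators[ind_idx]
        w = weights.weights[w_idx]
        out += np.where(ind.mask, 0.0, ind.values) * np.where(np.isfinite(w), w, 0.0)
        mask |= ind.mask | ~np.isfinite(w)[None]
    # convex combination of [0, 1] values; clamp float round-off at the ends
    out = np.clip(out, 0.0, 1.0)
    out[mask] = np.nan
    series = ref.replace(out, variable="RegCDI", units="", mask=mask)
    return CombinedIndexSeries(series=series, indicator_names=list(weights.names))


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

# Severity categories, USDM style.  Code 0 = wet, 1..5 = D0..D4; -1 = masked.
CLASS_LABELS = ["wet", "D0", "D1", "D2", "D3", "D4"]
# Upper bounds of D4..D0 on the index scale; intervals are (a, b] with
# D4 = [0, 0.02].  Values above the last bound are wet.
CLASS_BOUNDS = (0.02, 0.05, 0.10, 0.20, 0.30)
PERCENTILE_CUTS = (2.0, 5.0, 10.0, 20.0, 30.0)


@dataclass
class DroughtClassGrid:
    """Per pixel-month drought class codes (see :data:`CLASS_LABELS`)."""

    codes: np.ndarray  # int, -1 masked, 0 wet, 1..5 = D0..D4
    timestamps: list[tuple[int, int]]
    scheme: str

    @property
    def months(self) -> np.ndarray:
        return np.array([m for _, m in self.timestamps])

    @property
    def years(self) -> np.ndarray:
        return np.array([y for y, _ in self.timestamps])

    def is_class(self, labels: list[str]) -> np.ndarray:
        wanted = [CLASS_LABELS.index(lab) for lab in labels]
        return np.isin(self.codes, wanted)


def _classify_values(values: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    """Map index values to class codes given (a, b]-style upper bounds.

    ``bounds`` broadcasts against ``values`` with a trailing axis of 5
    thresholds (D4..D0 upper bounds).
    """
    v = values[..., None]
    # number of bounds strictly below the value = steps up from D4
    above = np.sum(v > bounds, axis=-1)
    # above=0 -> D4 (code 5) ... above=5 -> wet (code 0)
    return 5 - above


def classify(index: CombinedIndexSeries, scheme: str = "fixed") -> DroughtClassGrid:
    """Classify the combined index into wet + five drought categories.

    ``fixed`` applies the published index ranges (D4 <= 0.02 < D3 <= 0.05
    < D2 <= 0.10 < D1 <= 0.20 < D0 <= 0.30 < wet) with intervals read as
    lower-exclusive, upper-inclusive.  ``percentile`` applies the USDM
    percentile cuts (2/5/10/20/30) to each pixel's own empirical index
    distribution, making the severity ranges site-specific.
    """
    vals = index.values
    valid = ~index.mask
    if np.any((vals[valid] < 0) | (vals[valid] > 1)):
        raise GridError("combined index values outside [0, 1]; "
                        "upstream normalization contract breached")
    if scheme == "fixed":
        bounds = np.asarray(CLASS_BOUNDS, dtype=float)
        codes = _classify_values(vals, bounds)
    elif scheme == "percentile":
        masked = index.series.masked()
        with np.errstate(all="ignore"):
            pixel_bounds = np.nanpercentile(masked, PERCENTILE_CUTS, axis=0)
        # (5, row, col) -> (row, col, 5) for broadcasting against (t, r, c)
        bounds = np.moveaxis(pixel_bounds, 0, -1)
        codes = _classify_values(vals, bounds[None, ...])
    else:
        raise GridError(f"unknown classification scheme {scheme!r}")
    codes = codes.astype(int)
    codes[index.mask] = -1
    return DroughtClassGrid(codes=codes, timestamps=list(index.series.timestamps),
                            scheme=scheme)
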