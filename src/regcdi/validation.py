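"""Validation of the combined drought index against crop yield.

Covers yield standardization, correlation-based indicator selection,
confusion-matrix agreement metrics (accuracy, Matthews correlation
coefficient) between drought/non-drought classifications, and lagged
early-warning evaluation at 1-3 month lead times.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from regcdi.core import (CLASS_LABELS, CombinedIndexSeries, DroughtClassGrid,
                         classify, normalize_indicator)
from regcdi.grid import (GriddedSeries, GridError, SeasonDefinition,
                         YieldTable, ZoneMap)

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionMatrix", "SeasonalSeverity",
    "standardize_yield", "seasonal_severity", "pearson_correlation",
    "correlation_map", "select_indicators",
    "binarize_threshold", "binarize_classes", "binarize_z",
    "confusion", "confusion_multiclass", "accuracy", "mcc", "early_warning",
]


# ---------------------------------------------------------------------------
# Yield standardization (z-scores per district)
# ---------------------------------------------------------------------------

def standardize_yield(table: YieldTable, ddof: int = 1,
                      min_years: int = 3) -> YieldTable:
    """Add standardized yield z = (x - mu) / sigma per district.

    ``mu`` and ``sigma`` are the district's own yield mean and standard
    deviation (sample sigma with ``ddof=1`` by default; set ``ddof=0``
    for the population convention).  Districts with fewer than
    ``min_years`` usable years or zero spread are flagged: their z is
    left missing and they are excluded from downstream correlation.
    """
    df = table.data.copy()
    df["z"] = np.nan
    for district, sub in df.groupby("district"):
        x = sub["yield"].dropna()
        if len(x) < min_years:
            logger.warning("district %s: only %d yield years; z not computed",
                           district, len(x))
            continue
        mu = x.mean()
        sigma = x.std(ddof=ddof)
        if not sigma > 0:
            logger.warning("district %s: zero yield variance; excluded", district)
            continue
        df.loc[x.index, "z"] = (x - mu) / sigma
    return YieldTable(df)


# ---------------------------------------------------------------------------
# Seasonal drought severity
# ---------------------------------------------------------------------------

@dataclass
class SeasonalSeverity:
    """Per pixel-year drought severity drawn from a monthly index.

    ``values`` has shape (n_years, row, col).  In ``season-min`` mode the
    value is the minimum index over the season's months of that year —
    i.e. the *maximum* drought severity of the season.  In
    ``critical-month`` mode it is the index at one configured month of
    the crop's critical growth stage.
    """

    values: np.ndarray
    years: np.ndarray
    season: str
    mode: str


def seasonal_severity(series: GriddedSeries | CombinedIndexSeries,
                      season: SeasonDefinition, mode: str = "season-min",
                      critical_month: int = 8) -> SeasonalSeverity:
    """Reduce a monthly stack to one severity value per pixel and year."""
    if isinstance(series, CombinedIndexSeries):
        series = series.series
    if mode not in ("season-min", "critical-month"):
        raise GridError(f"unknown severity mode {mode!r}")
    vals = series.masked()
    years = series.years
    months = series.months
    uyears = np.unique(years)
    out = np.full((len(uyears),) + series.grid_shape, np.nan)
    for i, y in enumerate(uyears):
        if mode == "season-min":
            sel = (years == y) & np.isin(months, list(season.months))
        else:
            if critical_month not in season.months:
                raise GridError(f"critical month {critical_month} not in "
                                f"season {season.name!r}")
            sel = (years == y) & (months == critical_month)
        if not sel.any():
            continue
        with np.errstate(all="ignore"):
            out[i] = np.nanmin(vals[sel], axis=0)
    return SeasonalSeverity(values=out, years=uyears, season=season.name, mode=mode)


# ---------------------------------------------------------------------------
# Correlation with yield
# ---------------------------------------------------------------------------

def pearson_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Product-moment correlation of two yearly series.

    Requires >= 3 paired finite years and nonconstant inputs; anything
    else is undefined and raises.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 3:
        raise GridError("Pearson correlation needs >= 3 paired years")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise GridError("Pearson correlation undefined for constant input")
    return float(np.corrcoef(a, b)[0, 1])


def correlation_map(severity: SeasonalSeverity, yields: YieldTable,
                    zones: ZoneMap, target: str = "yield") -> np.ndarray:
    """Per-pixel correlation of seasonal severity with its district's yield.

    ``target`` selects the raw ``yield`` column or the standardized ``z``.
    Pixels outside any zone, or whose district has fewer than 3 usable
    years overlapping the severity record, come back NaN.
    """
    if target not in ("yield", "z"):
        raise GridError(f"correlation target must be 'yield' or 'z', got {target!r}")
    if target == "z" and "z" not in yields.data.columns:
        raise GridError("yield table has no z column; run standardize_yield first")
    nr, nc = zones.labels.shape
    if severity.values.shape[1:] != (nr, nc):
        raise GridError("zone map grid does not match severity grid")
    out = np.full((nr, nc), np.nan)
    for zone in zones.zone_ids:
        dist = yields.district_series(int(zone), target)
        common = np.intersect1d(severity.years, dist.index.values)
        if len(common) < 3:
            continue
        y = dist.loc[common].values
        if np.ptp(y) == 0:
            continue
        yr_idx = np.searchsorted(severity.years, common)
        pix = zones.pixels(int(zone))
        sev = severity.values[yr_idx][:, pix]  # (years, n_pixels)
        finite = np.isfinite(sev).all(axis=0)
        nonconst = np.ptp(sev, axis=0) > 0
        usable = finite & nonconst
        if not usable.any():
            continue
        s = sev[:, usable]
        sc = s - s.mean(axis=0)
        yc = y - y.mean()
        denom = np.sqrt((sc ** 2).sum(axis=0) * (yc ** 2).sum())
        r = (sc * yc[:, None]).sum(axis=0) / denom
        tmp = np.full(pix.sum(), np.nan)
        tmp[usable] = r
        out[pix] = tmp
    return out


def select_indicators(summaries: dict[str, tuple[float, float]],
                      types: dict[str, str]) -> dict[str, str]:
    """Pick the best indicator per type from mean yield correlations.

    ``summaries`` maps indicator name to its (yield PCC, standardized-yield
    PCC) region means; ``types`` maps indicator name to its category
    (vegetation condition, soil moisture, crop stress).  Within each type
    the indicator with the highest mean of the two summary correlations
    wins; ties break on the standardized-yield PCC, then lexicographically
    (logged).
    """
    groups: dict[str, list[str]] = {}
    for name in summaries:
        if name not in types:
            raise GridError(f"indicator {name!r} has no declared type")
        groups.setdefault(types[name], []).append(name)
    chosen: dict[str, str] = {}
    for typ, names in groups.items():
        def key(n: str):
            py, pz = summaries[n]
            return (-(py + pz) / 2.0, -pz, n)
        ranked = sorted(names, key=key)
        if len(ranked) > 1 and key(ranked[0])[:2] == key(ranked[1])[:2]:
            logger.warning("indicator selection tie in type %r resolved "
                           "lexicographically: %s", typ, ranked[:2])
        chosen[typ] = ranked[0]
    return chosen


# ---------------------------------------------------------------------------
# Binarization
# ---------------------------------------------------------------------------

def binarize_threshold(values: np.ndarray, threshold: float) -> np.ndarray:
    """Drought where value < threshold (strictly); NaN stays NaN-masked out."""
    return np.asarray(values) < threshold


def binarize_classes(classes: DroughtClassGrid) -> np.ndarray:
    """Drought where the class is D1-D4; D0 and wet are non-drought."""
    return classes.is_class(["D1", "D2", "D3", "D4"])


def binarize_z(z: np.ndarray) -> np.ndarray:
    """Drought year where standardized yield is negative (below average)."""
    return np.asarray(z) < 0


# ---------------------------------------------------------------------------
# Confusion-matrix metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """A k x k class-count table; binary uses labels (non-drought, drought).

    ``table[i, j]`` counts observations with actual class i and predicted
    class j.  For the binary case TP counts joint drought, TN joint
    non-drought.
    """

    table: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=np.int64)
        k = len(self.labels)
        if self.table.shape != (k, k):
            raise GridError("confusion table must be k x k with k labels")
        if (self.table < 0).any():
            raise GridError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.table.sum())

    # binary accessors (labels ordered [negative, positive])
    @property
    def tn(self) -> int:
        return int(self.table[0, 0])

    @property
    def fp(self) -> int:
        return int(self.table[0, 1])

    @property
    def fn(self) -> int:
        return int(self.table[1, 0])

    @property
    def tp(self) -> int:
        return int(self.table[1, 1])

    @classmethod
    def from_counts(cls, tp: int, tn: int, fp: int, fn: int) -> "ConfusionMatrix":
        return cls(table=np.array([[tn, fp], [fn, tp]]),
                   labels=["non-drought", "drought"])


def confusion(actual: np.ndarray, predicted: np.ndarray) -> ConfusionMatrix:
    """Binary confusion matrix from two boolean series (True = drought)."""
    a = np.asarray(actual, dtype=bool).ravel()
    p = np.asarray(predicted, dtype=bool).ravel()
    if a.shape != p.shape:
        raise GridError("actual and predicted series differ in length")
    tp = int(np.sum(a & p))
    tn = int(np.sum(~a & ~p))
    fp = int(np.sum(~a & p))
    fn = int(np.sum(a & ~p))
    return ConfusionMatrix.from_counts(tp=tp, tn=tn, fp=fp, fn=fn)


def confusion_multiclass(actual: np.ndarray, predicted: np.ndarray,
                         labels: list[str] | None = None) -> ConfusionMatrix:
    """k x k confusion matrix from two integer-coded class series."""
    a = np.asarray(actual).ravel()
    p = np.asarray(predicted).ravel()
    if a.shape != p.shape:
        raise GridError("actual and predicted series differ in length")
    codes = np.union1d(np.unique(a), np.unique(p))
    if labels is None:
        labels = [str(c) for c in codes]
    k = len(codes)
    idx = {c: i for i, c in enumerate(codes)}
    table = np.zeros((k, k), dtype=np.int64)
    for ai, pi in zip(a, p):
        table[idx[ai], idx[pi]] += 1
    return ConfusionMatrix(table=table, labels=labels)


def accuracy(cm: ConfusionMatrix) -> float:
    """Accuracy in percent: 100 * correctly classified / total.

    For the binary matrix this is 100 * (TP + TN) / (TP + TN + FP + FN);
    for a k-class matrix, 100 * trace / total.
    """
    if cm.total == 0:
        raise GridError("empty confusion matrix")
    return 100.0 * float(np.trace(cm.table)) / cm.total


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient of a binary confusion matrix.

    (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)), equal to the
    Pearson correlation of the two 0/1 label vectors.  If any denominator
    factor is zero the value is reported as 0 with a logged flag (one
    class absent on one side makes the correlation undefined).
    """
    if len(cm.labels) != 2:
        raise GridError("MCC is defined for binary classification only")
    tp, tn, fp, fn = cm.tp, cm.tn, cm.fp, cm.fn
    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom2 == 0:
        logger.warning("MCC denominator zero (a class is absent); reporting 0")
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom2))


# ---------------------------------------------------------------------------
# Early warning at 1-3 month lead times
# ---------------------------------------------------------------------------

def early_warning(index: CombinedIndexSeries, predictor: GriddedSeries,
                  lag: int, threshold: float = 0.12,
                  predictor_rule: str = "percentile") -> dict:
    """Lagged drought-prediction skill of an indicator against the index.

    The predictor at month t - ``lag`` is compared with the index drought
    state at month t, pooled over all pixels and months into one binary
    confusion matrix.  The index is binarized by ``value < threshold``;
    the predictor either by the percentile classification of its own
    normalized series (``percentile``, D1-D4 = drought — puts indicators
    on a common footing) or by the same fixed threshold (``threshold``).

    Returns a dict with ``accuracy`` (%), ``mcc``, ``lag`` and the pooled
    ``confusion`` matrix.
    """
    nt = index.series.n_time
    if not 1 <= lag < nt:
        raise GridError(f"lag {lag} outside the series length {nt}")
    if predictor.shape != index.series.shape:
        raise GridError("predictor and index stacks are not co-registered")
    actual = binarize_threshold(index.values, threshold)
    actual_ok = ~index.mask
    if predictor_rule == "percentile":
        norm = normalize_indicator(predictor)
        pred_classes = classify(
            CombinedIndexSeries(series=norm.series), scheme="percentile")
        predicted = binarize_classes(pred_classes)
        pred_ok = pred_classes.codes >= 0
    elif predictor_rule == "threshold":
        predicted = binarize_threshold(predictor.values, threshold)
        pred_ok = ~predictor.mask
    else:
        raise GridError(f"unknown predictor rule {predictor_rule!r}")
    a = actual[lag:]
    p = predicted[:-lag]
    ok = actual_ok[lag:] & pred_ok[:-lag]
    cm = confusion(a[ok], p[ok])
    return {"lag": lag, "accuracy": accuracy(cm), "mcc": mcc(cm),
            "confusion": cm}
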