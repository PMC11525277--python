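"""Run-theory drought events and hotspot summaries.

A drought event at a pixel is a maximal run of consecutive months with
the combined index strictly below a threshold (run theory).  Duration is
the run length in months; severity is the sum of index values within the
run — because low index = severe drought, a *lower* severity sum per
month means a worse event.  Masked months terminate runs (data gaps are
never bridged).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from regcdi.core import CombinedIndexSeries, DroughtClassGrid
from regcdi.grid import GriddedSeries, GridError, SeasonDefinition

__all__ = [
    "RunConfig", "DroughtEvent", "HotspotStack",
    "extract_runs", "drought_months", "propensity", "seasonal_filter",
    "hotspot_stack", "DEFAULT_THRESHOLDS",
]

# Published index thresholds for drought onset in run/confusion analyses,
# by grid resolution tag (the region-wide mean of the severe-drought
# boundary at each resolution).
DEFAULT_THRESHOLDS = {"0.25deg": 0.12, "1deg": 0.17}


@dataclass(frozen=True)
class RunConfig:
    """Run-theory configuration: drought when index < threshold (strict)."""

    threshold: float = 0.12

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise GridError("run threshold must lie in (0, 1)")

    @classmethod
    def for_resolution(cls, resolution: str) -> "RunConfig":
        try:
            return cls(threshold=DEFAULT_THRESHOLDS[resolution])
        except KeyError:
            raise GridError(f"no default threshold for resolution "
                            f"{resolution!r}; pass one explicitly") from None


@dataclass
class DroughtEvent:
    """One below-threshold run at one pixel."""

    pixel: tuple[int, int]
    start: tuple[int, int]  # (year, month)
    end: tuple[int, int]    # (year, month), inclusive
    duration: int           # months
    severity: float         # sum of index values within the run


def extract_runs(index: CombinedIndexSeries, cfg: RunConfig) -> list[DroughtEvent]:
    """Extract all drought events (maximal runs with value < threshold).

    Events are returned ordered by pixel (row-major) then start time;
    a value exactly at the threshold is *not* drought.  Masked months
    break runs.
    """
    vals = index.values
    below = (vals < cfg.threshold) & ~index.mask
    ts = index.series.timestamps
    events: list[DroughtEvent] = []
    nt, nr, nc = vals.shape
    for r in range(nr):
        for c in range(nc):
            col = below[:, r, c]
            if not col.any():
                continue
            # run boundaries from the 0/1 transition pattern
            padded = np.concatenate([[False], col, [False]])
            d = np.diff(padded.astype(int))
            starts = np.flatnonzero(d == 1)
            ends = np.flatnonzero(d == -1)  # exclusive
            for s, e in zip(starts, ends):
                events.append(DroughtEvent(
                    pixel=(r, c),
                    start=ts[s],
                    end=ts[e - 1],
                    duration=int(e - s),
                    severity=float(vals[s:e, r, c].sum()),
                ))
    return events


def drought_months(classes: DroughtClassGrid, subset: str = "all") -> np.ndarray:
    """Per-pixel count of drought-class months.

    ``all`` counts D1-D4 (moderate to exceptional); ``severe`` counts
    D2-D4.  D0 ("dry condition" / abnormally dry) is never counted as
    drought.
    """
    if subset == "all":
        labels = ["D1", "D2", "D3", "D4"]
    elif subset == "severe":
        labels = ["D2", "D3", "D4"]
    else:
        raise GridError(f"unknown drought-month subset {subset!r}")
    return classes.is_class(labels).sum(axis=0).astype(int)


def propensity(classes: DroughtClassGrid) -> np.ndarray:
    """Drought propensity: months per pixel in classes D1-D4."""
    return drought_months(classes, "all")


def seasonal_filter(obj, season: SeasonDefinition):
    """Restrict a stack-like object to a season's calendar months.

    Accepts a :class:`GriddedSeries`, :class:`CombinedIndexSeries` or
    :class:`DroughtClassGrid` and returns the same type holding only the
    months in ``season``.
    """
    months = frozenset(season.months)
    if isinstance(obj, GriddedSeries):
        keep = np.array([m in months for _, m in obj.timestamps])
        return obj.select_times(keep)
    if isinstance(obj, CombinedIndexSeries):
        return CombinedIndexSeries(series=seasonal_filter(obj.series, season),
                                   indicator_names=list(obj.indicator_names))
    if isinstance(obj, DroughtClassGrid):
        keep = np.array([m in months for _, m in obj.timestamps])
        return DroughtClassGrid(
            codes=obj.codes[keep],
            timestamps=[t for t, k in zip(obj.timestamps, keep) if k],
            scheme=obj.scheme,
        )
    raise GridError(f"cannot season-filter object of type {type(obj).__name__}")


@dataclass
class HotspotStack:
    """Per-pixel hotspot layers over the study period.

    ``mean_annual_severity`` and ``mean_annual_duration`` divide by the
    number of study years; they are NaN at pixels with no event.  Lower
    mean severity = worse drought.  Counts are nonnegative integers.
    """

    mean_annual_severity: np.ndarray
    mean_annual_duration: np.ndarray
    total_drought_months: np.ndarray
    severe_drought_months: np.ndarray
    propensity: np.ndarray
    seasonal_propensity: dict[str, np.ndarray] = field(default_factory=dict)
    n_years: int = 0


def hotspot_stack(index: CombinedIndexSeries, classes: DroughtClassGrid,
                  cfg: RunConfig,
                  seasons: list[SeasonDefinition] | None = None) -> HotspotStack:
    """Assemble all hotspot layers from the index and its classification."""
    n_years = index.series.n_years
    shape = index.series.grid_shape
    sev = np.full(shape, np.nan)
    dur = np.full(shape, np.nan)
    sev_sum = np.zeros(shape)
    dur_sum = np.zeros(shape)
    has_event = np.zeros(shape, dtype=bool)
    for ev in extract_runs(index, cfg):
        sev_sum[ev.pixel] += ev.severity
        dur_sum[ev.pixel] += ev.duration
        has_event[ev.pixel] = True
    sev[has_event] = sev_sum[has_event] / n_years
    dur[has_event] = dur_sum[has_event] / n_years
    seasonal = {}
    for season in (seasons or []):
        seasonal[season.name] = propensity(seasonal_filter(classes, season))
    return HotspotStack(
        mean_annual_severity=sev,
        mean_annual_duration=dur,
        total_drought_months=drought_months(classes, "all"),
        severe_drought_months=drought_months(classes, "severe"),
        propensity=propensity(classes),
        seasonal_propensity=seasonal,
        n_years=n_years,
    )
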