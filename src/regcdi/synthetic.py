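"""Synthetic gridded scenes with the statistical structure of monsoon
agro-climate records.

The generator emulates, at desk scale, the structure the drought
framework assumes of its inputs: deterministic seasonal cycles (a land
surface temperature sinusoid, a Jun-Sep monsoon precipitation pulse and
soil-moisture recharge, a vegetation green-up), AR(1) Gaussian anomalies
shared within the region plus pixel-level noise, localized multi-month
drought episodes that depress soil moisture and precipitation, elevate
temperature, and propagate into the reflectance bands with a configurable
lead, and district yields coupled to growing-season drought stress.  It
makes no claim of radiative-transfer realism or of matching any actual
regional climatology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from regcdi.grid import GriddedSeries, GridError, YieldTable, ZoneMap

__all__ = ["EpisodeConfig", "SceneConfig", "Scene", "generate_scene",
           "truth_report"]


@dataclass(frozen=True)
class EpisodeConfig:
    """One imposed drought episode.

    ``region`` is a half-open pixel box (row0, row1, col0, col1);
    ``intensity`` in (0, 1] scales every anomaly the episode imposes.
    """

    region: tuple[int, int, int, int]
    start: tuple[int, int]  # (year, month)
    length: int             # months
    intensity: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 < self.intensity <= 1.0:
            raise GridError("episode intensity must lie in (0, 1]")
        if self.length < 1:
            raise GridError("episode length must be >= 1 month")


def _default_episodes() -> list[EpisodeConfig]:
    # One Kharif-season episode and one Rabi/summer episode, mirroring the
    # localized multi-month events the framework is meant to detect.
    return [
        EpisodeConfig(region=(1, 4, 1, 4), start=(2009, 6), length=6, intensity=0.8),
        EpisodeConfig(region=(6, 9, 5, 8), start=(2015, 11), length=5, intensity=0.75),
    ]


@dataclass
class SceneConfig:
    """Study conditions of a synthetic scene.

    Defaults mirror a 19-year (2001-2019) monthly record on a modest
    grid: LST around 300 K with a 6 K pre-monsoon peak, surface soil
    moisture recharged by a Jun-Sep monsoon, monsoon-dominated rainfall,
    and bounded reflectance bands.  Soil-moisture / precipitation /
    temperature anomalies respond to drought stress immediately; the
    vegetation and reflectance response lags by ``veg_lag`` months.
    """

    shape: tuple[int, int] = (10, 10)
    start_year: int = 2001
    years: int = 19
    seed: int = 0
    n_districts: int = 6
    # anomaly process
    ar_rho: float = 0.6            # month-to-month anomaly autocorrelation
    common_weight: float = 0.6     # region-wide share of the anomaly
    pixel_weight: float = 0.8      # pixel-level share of the anomaly
    stress_coef: float = 0.25      # background stress per unit negative anomaly
    # seasonal cycles
    lst_mean: float = 301.0        # K
    lst_amplitude: float = 6.0     # K, peak in May
    lst_stress_gain: float = 5.0   # K added under full stress
    lst_noise_sd: float = 0.6      # K
    ssm_base: float = 0.16         # m3/m3 dry-season surface soil moisture
    ssm_monsoon: float = 0.18      # m3/m3 added at monsoon peak
    ssm_stress_loss: float = 0.6   # multiplicative loss under full stress
    ssm_noise_sd: float = 0.012    # m3/m3
    precip_dry: float = 25.0       # mm/month outside the monsoon
    precip_monsoon: float = 280.0  # mm/month at monsoon peak
    precip_stress_loss: float = 0.7
    # reflectance
    nir_base: float = 0.32
    nir_green: float = 0.10        # monsoon green-up amplitude
    red_base: float = 0.09
    swir1_base: float = 0.21       # 1628-1652 nm channel
    swir2_base: float = 0.26       # 1230-1250 nm channel
    refl_noise_sd: float = 0.008
    veg_lag: int = 1               # months vegetation/reflectance lag stress
    # drought episodes and yield coupling
    episodes: list[EpisodeConfig] = field(default_factory=_default_episodes)
    yield_base: float = 2000.0     # kg/ha
    yield_slope: float = 600.0     # kg/ha lost per unit mean Kharif stress
    yield_noise_sd: float = 60.0   # kg/ha
    resolution: str = "0.25deg"

    @property
    def n_time(self) -> int:
        return self.years * 12

    def timestamps(self) -> list[tuple[int, int]]:
        return [(self.start_year + t // 12, t % 12 + 1)
                for t in range(self.n_time)]

    def time_index(self, year: int, month: int) -> int:
        idx = (year - self.start_year) * 12 + (month - 1)
        if not 0 <= idx < self.n_time:
            raise GridError(f"({year}, {month}) outside the scene time range")
        return idx


@dataclass
class Scene:
    """Generated stacks plus the zone map, yield table and truth fields."""

    lst: GriddedSeries
    ssm: GriddedSeries
    precip: GriddedSeries
    nir: GriddedSeries      # band 2, 841-876 nm
    red: GriddedSeries
    swir1: GriddedSeries    # band 5, 1628-1652 nm
    swir2: GriddedSeries    # band 6, 1230-1250 nm
    zones: ZoneMap
    yields: YieldTable
    stress: np.ndarray      # imposed drought stress in [0, 1], (t, r, c)
    config: SceneConfig


def _zone_tiling(shape: tuple[int, int], n: int) -> np.ndarray:
    """Rectangular tiling of the grid into n districts (ids 1..n)."""
    nr, nc = shape
    rows = int(np.floor(np.sqrt(n)))
    while n % rows:
        rows -= 1
    cols = n // rows
    r_edges = np.linspace(0, nr, rows + 1).astype(int)
    c_edges = np.linspace(0, nc, cols + 1).astype(int)
    labels = np.zeros(shape, dtype=int)
    zid = 1
    for i in range(rows):
        for j in range(cols):
            labels[r_edges[i]:r_edges[i + 1], c_edges[j]:c_edges[j + 1]] = zid
            zid += 1
    return labels


def _ar1(rng: np.random.Generator, rho: float, shape: tuple[int, ...]) -> np.ndarray:
    """Stationary AR(1) series along axis 0 with unit marginal variance."""
    nt = shape[0]
    innov_sd = np.sqrt(1.0 - rho ** 2)
    out = np.empty(shape)
    out[0] = rng.standard_normal(shape[1:]) if len(shape) > 1 else rng.standard_normal()
    for t in range(1, nt):
        e = rng.standard_normal(shape[1:]) if len(shape) > 1 else rng.standard_normal()
        out[t] = rho * out[t - 1] + innov_sd * e
    return out


def _stress_field(cfg: SceneConfig, anomaly: np.ndarray) -> np.ndarray:
    """Drought stress in [0, 1]: imposed episodes + background dry anomalies."""
    stress = cfg.stress_coef * np.clip(-anomaly, 0.0, None)
    for ep in cfg.episodes:
        i0 = cfg.time_index(*ep.start)
        if i0 + ep.length > cfg.n_time:
            raise GridError(f"episode starting {ep.start} runs past the scene end")
        r0, r1, c0, c1 = ep.region
        stress[i0:i0 + ep.length, r0:r1, c0:c1] += ep.intensity
    return np.clip(stress, 0.0, 1.0)


def _lagged(stress: np.ndarray, lag: int) -> np.ndarray:
    """Stress shifted ``lag`` months later (zero before the record starts)."""
    if lag == 0:
        return stress
    out = np.zeros_like(stress)
    out[lag:] = stress[:-lag]
    return out


def generate_scene(cfg: SceneConfig) -> Scene:
    """Generate a deterministic (seeded) synthetic scene."""
    rng = np.random.default_rng(cfg.seed)
    nt = cfg.n_time
    nr, nc = cfg.shape
    ts = cfg.timestamps()
    months = np.array([m for _, m in ts])

    # shared + pixel AR(1) anomaly; negative = dry
    common = _ar1(rng, cfg.ar_rho, (nt,))
    pixel = _ar1(rng, cfg.ar_rho, (nt, nr, nc))
    anomaly = cfg.common_weight * common[:, None, None] + cfg.pixel_weight * pixel

    stress = _stress_field(cfg, anomaly)
    stress_veg = _lagged(stress, cfg.veg_lag)

    # seasonal profiles (per time step, broadcast over the grid)
    lst_cyc = cfg.lst_mean + cfg.lst_amplitude * np.cos(2 * np.pi * (months - 5) / 12)
    monsoon = np.exp(-0.5 * ((months - 7.5) / 1.6) ** 2)  # Jun-Sep pulse
    ssm_cyc = cfg.ssm_base + cfg.ssm_monsoon * monsoon
    precip_cyc = cfg.precip_dry + cfg.precip_monsoon * monsoon
    green = monsoon  # vegetation tracks the monsoon

    def grid(values: np.ndarray, name: str, units: str) -> GriddedSeries:
        return GriddedSeries(values=values, timestamps=ts, variable=name,
                             units=units, resolution=cfg.resolution)

    lst = (lst_cyc[:, None, None] + cfg.lst_stress_gain * stress
           + cfg.lst_noise_sd * rng.standard_normal((nt, nr, nc)))
    ssm = np.clip(ssm_cyc[:, None, None] * (1 - cfg.ssm_stress_loss * stress)
                  + cfg.ssm_noise_sd * rng.standard_normal((nt, nr, nc)),
                  0.01, 0.5)
    precip = np.clip(precip_cyc[:, None, None] * (1 - cfg.precip_stress_loss * stress)
                     * np.exp(0.25 * rng.standard_normal((nt, nr, nc))),
                     0.0, None)
    noise = lambda: cfg.refl_noise_sd * rng.standard_normal((nt, nr, nc))
    nir = np.clip((cfg.nir_base + cfg.nir_green * green[:, None, None])
                  * (1 - 0.4 * stress_veg) + noise(), 0.0, 1.0)
    red = np.clip(cfg.red_base * (1 + 0.3 * stress_veg) + noise(), 0.0, 1.0)
    swir1 = np.clip(cfg.swir1_base * (1 + 0.5 * stress_veg) + noise(), 0.0, 1.0)
    swir2 = np.clip(cfg.swir2_base * (1 + 0.4 * stress_veg) + noise(), 0.0, 1.0)

    zones = ZoneMap(labels=_zone_tiling(cfg.shape, cfg.n_districts))

    # yield: base minus slope * mean Kharif (Jun-Sep) stress over the district
    kharif = np.isin(months, (6, 7, 8, 9))
    years = np.array([y for y, _ in ts])
    rows = []
    for zone in zones.zone_ids:
        pix = zones.pixels(int(zone))
        for y in range(cfg.start_year, cfg.start_year + cfg.years):
            sel = kharif & (years == y)
            s = float(stress[sel][:, pix].mean())
            rows.append({
                "district": int(zone), "year": int(y),
                "yield": cfg.yield_base - cfg.yield_slope * s
                         + cfg.yield_noise_sd * rng.standard_normal(),
            })
    yields = YieldTable(pd.DataFrame(rows))

    return Scene(
        lst=grid(lst, "LST", "K"),
        ssm=grid(ssm, "SSM", "m3/m3"),
        precip=grid(precip, "precip", "mm/month"),
        nir=grid(nir, "NIR", ""),
        red=grid(red, "red", ""),
        swir1=grid(swir1, "SWIR1", ""),
        swir2=grid(swir2, "SWIR2", ""),
        zones=zones,
        yields=yields,
        stress=stress,
        config=cfg,
    )


def truth_report(cfg: SceneConfig) -> pd.DataFrame:
    """Ground truth of the imposed episodes, one row per pixel and merged
    episode interval.

    Columns: pixel_row, pixel_col, start_year, start_month, end_year,
    end_month, months (interval length).  Overlapping or touching episode
    windows at the same pixel are merged (interval union), so ``months``
    summed per pixel equals that pixel's expected drought-month count.
    """
    intervals: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for ep in cfg.episodes:
        i0 = cfg.time_index(*ep.start)
        if i0 + ep.length > cfg.n_time:
            raise GridError(f"episode starting {ep.start} runs past the scene end")
        r0, r1, c0, c1 = ep.region
        for r in range(r0, r1):
            for c in range(c0, c1):
                intervals.setdefault((r, c), []).append((i0, i0 + ep.length))
    ts = cfg.timestamps()
    rows = []
    for (r, c), ivals in sorted(intervals.items()):
        ivals.sort()
        merged = [list(ivals[0])]
        for s, e in ivals[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            rows.append({
                "pixel_row": r, "pixel_col": c,
                "start_year": ts[s][0], "start_month": ts[s][1],
                "end_year": ts[e - 1][0], "end_month": ts[e - 1][1],
                "months": e - s,
            })
    columns = ["pixel_row", "pixel_col", "start_year", "start_month",
               "end_year", "end_month", "months"]
    return pd.DataFrame(rows, columns=columns)
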