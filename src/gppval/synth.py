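"""Synthetic site generation with known truth, plus the packaged per-site
performance fixture (62 sites x per-model R2/RMSE/RPE).

Weather follows latitude-appropriate sinusoidal seasonality with seeded
Gaussian noise; NDVI/LAI co-vary with the seasonal temperature cycle on an
8-day cadence with a configurable fraction of points flagged unreliable;
NEE is manufactured from a chosen true carboxylation rate as

    gpp_obs   = gpp_true + noise
    nee_day   = reco_day - gpp_obs
    nee_night = reco_night + noise'

with respiration following the same exponential temperature law the
partitioning module fits, so generator -> partitioner closure is exact at
zero noise.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from . import partitioning
from .photosynthesis import PhotoParams, forward_gpp
from .site_io import FlaggedSeries, SITE_COLUMNS, SiteSeries, catalog_entry

__all__ = [
    "SyntheticSiteConfig", "Table2Row", "Table2Fixture", "generate_weather",
    "generate_ndvi_lai", "simulate_observations", "generate_site",
    "table2_fixture", "fixture_site_metrics", "annual_mean_temperature",
    "seasonal_temperature",
]

_DATA_DIR = Path(__file__).parent / "data"

#: per-biome site counts of the packaged fixture
FIXTURE_PFT_COUNTS = {"DBF": 14, "EBF": 4, "ENF": 20, "GRA": 11, "MF": 7, "SAV": 6}


@dataclass(frozen=True)
class SyntheticSiteConfig:
    site_id: str = "SYN-001"
    pft: str = "Temperate broadleaf trees"
    latitude: float = 45.0
    n_years: int = 2
    true_vcmax: float = 30e-6      # mol CO2 m-2 s-1
    gpp_noise_sd: float = 0.5      # g C m-2 day-1
    resp_ref: float = 2.0          # g C m-2 day-1 at the fit reference T
    resp_e0: float = 200.0         # K
    seed: int = 0

    def __post_init__(self):
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")
        if self.gpp_noise_sd < 0:
            raise ValueError("gpp_noise_sd must be >= 0")
        entry = catalog_entry(self.pft)
        if not entry.vcmax_lo <= self.true_vcmax <= entry.vcmax_hi:
            raise ValueError(
                f"true_vcmax {self.true_vcmax} outside catalogue bounds "
                f"[{entry.vcmax_lo}, {entry.vcmax_hi}] for {self.pft!r}")


def annual_mean_temperature(latitude: float) -> float:
    """Annual-mean air temperature (degC) of the generating sinusoid."""
    return 28.0 - 0.45 * abs(latitude)


def _seasonal_amplitude(latitude: float) -> float:
    return 2.0 + 0.30 * abs(latitude)


def seasonal_temperature(latitude: float, doy) -> np.ndarray:
    """Noise-free seasonal daily-mean temperature trace (degC)."""
    doy = np.asarray(doy, dtype=float)
    phase = 202.0 if latitude >= 0 else 202.0 - 182.5  # warm-season peak
    return (annual_mean_temperature(latitude)
            + _seasonal_amplitude(latitude) * np.cos(2.0 * np.pi * (doy - phase) / 365.0))


def _dates(n_years: int, start_year: int = 2001) -> list[dt.date]:
    """365 calendar days per year (Feb 29 skipped), strictly increasing."""
    out = []
    for year in range(start_year, start_year + n_years):
        day = dt.date(year, 1, 1)
        while day.year == year:
            if not (day.month == 2 and day.day == 29):
                out.append(day)
            day += dt.timedelta(days=1)
    return out


def generate_weather(config: SyntheticSiteConfig, t_noise_sd: float = 1.5) -> SiteSeries:
    """Daily driver series of n_years x 365 days; deterministic for a given
    seed; all record invariants hold by construction."""
    rng = np.random.default_rng(config.seed)
    dates = _dates(config.n_years)
    n = len(dates)
    doy = np.arange(n) % 365
    lat = config.latitude

    t_avg = seasonal_temperature(lat, doy) + t_noise_sd * rng.standard_normal(n)
    half_range = np.maximum(0.5, 4.0 + 0.8 * rng.standard_normal(n))
    t_max = t_avg + half_range
    t_min = t_avg - half_range

    rh = np.clip(70.0 - 10.0 * np.cos(2.0 * np.pi * (doy - 20) / 365.0)
                 + 8.0 * rng.standard_normal(n), 5.0, 100.0)
    precip = np.where(rng.random(n) < 0.5, 0.0, rng.gamma(0.7, 5.0, n))
    cloud_frac = np.clip(rng.beta(2.0, 3.0, n), 0.0, 1.0)

    phase = 172.0 if lat >= 0 else 172.0 - 182.5  # PAR peaks near solstice
    par_base = max(5.0, 28.0 - 0.10 * abs(lat))
    par_amp = min(20.0, 0.45 * abs(lat))
    par = (par_base + par_amp * np.cos(2.0 * np.pi * (doy - phase) / 365.0))
    par_noise = 1.5 * rng.standard_normal(n)
    par = np.clip(par * (1.0 - 0.4 * cloud_frac)
                  + (par_noise if t_noise_sd > 0 else 0.0), 0.0, None)

    le = np.clip(30.0 + 2.0 * par + 5.0 * rng.standard_normal(n), 1.0, None)
    h = np.clip(20.0 + 1.0 * par + 5.0 * rng.standard_normal(n), 0.0, None)

    data = pd.DataFrame({
        "date": dates, "t_avg": t_avg, "t_max": t_max, "t_min": t_min,
        "rh": rh, "precip": precip, "par": par, "cloud_frac": cloud_frac,
        "le": le, "h": h, "nee_day": np.nan, "nee_night": np.nan,
        "gpp_obs": np.nan,
    })[SITE_COLUMNS]
    return SiteSeries(site_id=config.site_id, pft=config.pft, data=data,
                      latitude=config.latitude)


def generate_ndvi_lai(config: SyntheticSiteConfig, weather: SiteSeries,
                      flag_fraction: float = 0.1, lai_max: float = 5.0
                      ) -> tuple[FlaggedSeries, FlaggedSeries]:
    """8-day NDVI and LAI series with quality flags, co-varying with the
    seasonal temperature cycle. Returns (ndvi, lai)."""
    if not 0 <= flag_fraction <= 1:
        raise ValueError("flag_fraction must be in [0, 1]")
    rng = np.random.default_rng(config.seed + 101)
    n_days = len(weather)
    idx = np.arange(0, n_days, 8)                       # ceil(n_days/8) points
    dates = np.asarray(weather.dates, dtype="datetime64[D]")[idx]
    doy = (np.arange(n_days) % 365)[idx]

    t_season = seasonal_temperature(config.latitude, doy)
    lo, hi = t_season.min(), t_season.max()
    green = (t_season - lo) / (hi - lo) if hi > lo else np.full(len(idx), 0.8)
    ndvi = np.clip(0.15 + 0.70 * green + 0.02 * rng.standard_normal(len(idx)), 0.0, 1.0)
    lai = np.clip(lai_max * (ndvi - 0.10) / 0.80, 0.0, None)

    flagged = rng.random(len(idx)) < flag_fraction
    reliable = ~flagged
    return (FlaggedSeries(dates, ndvi, reliable.copy()),
            FlaggedSeries(dates.copy(), lai, reliable.copy()))


def simulate_observations(config: SyntheticSiteConfig, drivers: SiteSeries,
                          params: PhotoParams | None = None) -> SiteSeries:
    """Fill nee_day, nee_night and gpp_obs from the forward model at the
    configured true carboxylation rate plus seeded Gaussian noise."""
    if drivers.lai is None:
        raise ValueError("drivers need an LAI series; run generate_ndvi_lai first")
    entry = catalog_entry(config.pft)
    if params is None:
        params = PhotoParams(vcmax25=entry.vcmax_default)
    rng = np.random.default_rng(config.seed + 202)

    gpp_true = forward_gpp(drivers, params, pathway=entry.pathway,
                           vcmax=config.true_vcmax)
    day_frac, t_day, t_night = partitioning.day_night_split(drivers)
    reco_day = partitioning.lloyd_taylor(t_day, config.resp_ref, config.resp_e0) * day_frac
    reco_night = (partitioning.lloyd_taylor(t_night, config.resp_ref, config.resp_e0)
                  * (1.0 - day_frac))

    n = len(drivers)
    noise_gpp = config.gpp_noise_sd * rng.standard_normal(n)
    noise_night = config.gpp_noise_sd * rng.standard_normal(n)
    gpp_obs = gpp_true + noise_gpp
    out = drivers.with_columns(
        nee_day=reco_day - gpp_obs,
        nee_night=reco_night + noise_night,
        gpp_obs=gpp_obs,
    )
    return out


def generate_site(config: SyntheticSiteConfig, params: PhotoParams | None = None,
                  flag_fraction: float = 0.1, t_noise_sd: float = 1.5) -> SiteSeries:
    """Full pipeline: weather + flagged NDVI/LAI + manufactured fluxes."""
    series = generate_weather(config, t_noise_sd=t_noise_sd)
    series.ndvi, series.lai = generate_ndvi_lai(config, series, flag_fraction)
    return simulate_observations(config, series, params)


class Table2Row(NamedTuple):
    site_id: str
    pft: str
    ibis_r2: float
    ibis_rmse: float
    ibis_rpe: float
    eclue_r2: float
    eclue_rmse: float
    eclue_rpe: float


@dataclass(frozen=True)
class Table2Fixture:
    """The 62 published per-site validation rows (two models x three
    metrics each)."""

    rows: tuple[Table2Row, ...]

    def __post_init__(self):
        if len(self.rows) != 62:
            raise ValueError(f"expected 62 rows, got {len(self.rows)}")
        counts = pd.Series([r.pft for r in self.rows]).value_counts().to_dict()
        if counts != FIXTURE_PFT_COUNTS:
            raise ValueError(f"bad per-biome counts: {counts}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=Table2Row._fields)

    def row(self, site_id: str) -> Table2Row:
        for r in self.rows:
            if r.site_id == site_id:
                return r
        raise KeyError(site_id)


def table2_fixture() -> Table2Fixture:
    """Load the packaged 62-site performance table."""
    frame = pd.read_csv(_DATA_DIR / "site_performance.tsv", sep="\t")
    rows = tuple(Table2Row(str(r.site_id), str(r.pft), float(r.ibis_r2),
                           float(r.ibis_rmse), float(r.ibis_rpe),
                           float(r.eclue_r2), float(r.eclue_rmse),
                           float(r.eclue_rpe))
                 for r in frame.itertuples(index=False))
    return Table2Fixture(rows=rows)


def fixture_site_metrics(fixture: Table2Fixture, model: str):
    """Flatten one model's columns of the fixture into SiteMetrics rows."""
    from .metrics import SiteMetrics
    key = {"IBIS": "ibis", "EC-LUE": "eclue"}[model]
    return [SiteMetrics(site_id=r.site_id, pft=r.pft, model=model,
                        r2=getattr(r, f"{key}_r2"),
                        rmse=getattr(r, f"{key}_rmse"),
                        rpe=getattr(r, f"{key}_rpe"))
            for r in fixture.rows]
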