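"""Site time-series and catalogue IO.

File dialect: tab-separated UTF-8 with ISO-8601 dates, one row per day.
Optional ``# key: value`` comment headers carry site metadata (site id, PFT
label, latitude). Satellite index series (8-day NDVI / LAI with quality
flags) live in sidecar files ``<stem>.ndvi.tsv`` / ``<stem>.lai.tsv``.
"""

from __future__ import annotations

import datetime as dt
import io
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("gppval")

#: column order of a site file; gpp_obs may be blank
SITE_COLUMNS = [
    "date", "t_avg", "t_max", "t_min", "rh", "precip", "par",
    "cloud_frac", "le", "h", "nee_day", "nee_night", "gpp_obs",
]

#: labels the driving model cannot represent; remapped to C3 grassland on load
PFT_REMAP = {"cropland": "C3 herbaceous", "wetland": "C3 herbaceous"}

#: the six biome codes used in validation
VALIDATION_PFTS = ("DBF", "EBF", "ENF", "GRA", "MF", "SAV")


class SiteFileError(ValueError):
    """Malformed site file (missing column, bad dialect...)."""


class EmptyInputError(SiteFileError):
    """Site file contains no data rows."""


class CatalogError(ValueError):
    """Invalid PFT catalogue (duplicates, bad bounds...)."""


class UnusableSeriesError(ValueError):
    """A flagged series with no reliable values cannot be gap-filled."""


@dataclass
class SiteDailyRecord:
    """One site-day of drivers and fluxes.

    Temperatures in deg C, rh in percent, precip in mm/day, par in
    mol quanta m-2 day-1, fluxes in W m-2, NEE in g C m-2 per period
    (negative = net uptake), gpp_obs in g C m-2 day-1 (NaN = missing).
    """

    date: dt.date
    t_avg: float
    t_max: float
    t_min: float
    rh: float
    precip: float
    par: float
    cloud_frac: float
    le: float
    h: float
    nee_day: float = math.nan
    nee_night: float = math.nan
    gpp_obs: float = math.nan

    def violations(self) -> list[str]:
        """Names of violated invariants (empty list means valid)."""
        out = []
        if not (self.t_min <= self.t_avg <= self.t_max):
            out.append("t_min <= t_avg <= t_max")
        if not self.par >= 0:
            out.append("par >= 0")
        if not self.precip >= 0:
            out.append("precip >= 0")
        if not (0 <= self.cloud_frac <= 1):
            out.append("0 <= cloud_frac <= 1")
        if not (0 <= self.rh <= 100):
            out.append("rh in [0, 100]")
        return out


@dataclass
class FlaggedSeries:
    """Sparse time series with per-point reliability flags (True = reliable)."""

    dates: np.ndarray          # datetime64[D] or list of dates
    values: np.ndarray         # float
    reliable: np.ndarray       # bool

    def __post_init__(self):
        self.dates = np.asarray(self.dates)
        self.values = np.asarray(self.values, dtype=float)
        self.reliable = np.asarray(self.reliable, dtype=bool)
        if not (len(self.dates) == len(self.values) == len(self.reliable)):
            raise ValueError("dates/values/reliable length mismatch")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class SiteSeries:
    """A site's daily records plus optional 8-day satellite series."""

    site_id: str
    pft: str
    data: pd.DataFrame                      # columns SITE_COLUMNS
    ndvi: FlaggedSeries | None = None
    lai: FlaggedSeries | None = None
    latitude: float | None = None

    def __post_init__(self):
        missing = [c for c in SITE_COLUMNS if c not in self.data.columns]
        if missing:
            raise SiteFileError(f"missing column(s): {', '.join(missing)}")
        dates = pd.to_datetime(self.data["date"]).to_numpy()
        if len(dates) > 1 and not (np.diff(dates) > np.timedelta64(0)).all():
            raise SiteFileError("records must be strictly date-ordered without duplicates")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def dates(self) -> np.ndarray:
        return pd.to_datetime(self.data["date"]).to_numpy()

    def doy(self) -> np.ndarray:
        """Day of year for each record."""
        return pd.to_datetime(self.data["date"]).dt.dayofyear.to_numpy()

    def iter_records(self) -> Iterator[SiteDailyRecord]:
        for row in self.data.itertuples(index=False):
            yield SiteDailyRecord(*row)

    def with_columns(self, **cols) -> "SiteSeries":
        data = self.data.copy()
        for name, values in cols.items():
            data[name] = values
        return replace(self, data=data)


@dataclass(frozen=True)
class PFTCatalogEntry:
    """Plant functional type with default maximum carboxylation rate and
    inversion bounds, all in mol CO2 m-2 s-1."""

    name: str
    vcmax_default: float
    vcmax_lo: float
    vcmax_hi: float
    pathway: str  # "C3" | "C4"

    def __post_init__(self):
        if not (self.vcmax_lo < self.vcmax_default < self.vcmax_hi):
            raise CatalogError(
                f"{self.name}: bounds must bracket the default "
                f"({self.vcmax_lo} < {self.vcmax_default} < {self.vcmax_hi})"
            )
        if self.pathway not in ("C3", "C4"):
            raise CatalogError(f"{self.name}: unknown pathway {self.pathway!r}")


_DATA_DIR = Path(__file__).parent / "data"


def canonical_pft(label: str) -> str:
    """Remap vegetation labels the model cannot represent to C3 grassland."""
    return PFT_REMAP.get(label.strip().lower(), label.strip())


def load_pft_catalog(path: str | Path | None = None) -> list[PFTCatalogEntry]:
    """Load the PFT catalogue (builtin nine-entry table when ``path`` is None).

    Values in the file are in 1e-6 mol CO2 m-2 s-1; returned entries are in
    mol CO2 m-2 s-1.
    """
    src = Path(path) if path is not None else _DATA_DIR / "pft_catalog.tsv"
    frame = pd.read_csv(src, sep="\t")
    entries = []
    seen = set()
    for row in frame.itertuples(index=False):
        if row.name in seen:
            raise CatalogError(f"duplicate PFT name: {row.name}")
        seen.add(row.name)
        entries.append(PFTCatalogEntry(
            name=row.name,
            vcmax_default=float(row.vcmax_default_umol) * 1e-6,
            vcmax_lo=float(row.vcmax_lo_umol) * 1e-6,
            vcmax_hi=float(row.vcmax_hi_umol) * 1e-6,
            pathway=str(row.pathway),
        ))
    return entries


def catalog_entry(name: str, catalog: Sequence[PFTCatalogEntry] | None = None) -> PFTCatalogEntry:
    catalog = catalog if catalog is not None else load_pft_catalog()
    name = canonical_pft(name)
    for entry in catalog:
        if entry.name == name:
            return entry
    raise CatalogError(f"unknown PFT: {name!r}")


def _fmt(value: float) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    return repr(float(value))


def write_site_series(series: SiteSeries, path: str | Path, sidecars: bool = True) -> None:
    """Serialize a SiteSeries to its tab-separated dialect.

    Floats are written with ``repr`` so that read -> write round-trips are
    byte-identical. NDVI/LAI go to ``<stem>.ndvi.tsv`` / ``<stem>.lai.tsv``
    when present and ``sidecars`` is true.
    """
    path = Path(path)
    buf = io.StringIO()
    buf.write(f"# site_id: {series.site_id}\n")
    buf.write(f"# pft: {series.pft}\n")
    if series.latitude is not None:
        buf.write(f"# latitude: {_fmt(series.latitude)}\n")
    buf.write("\t".join(SITE_COLUMNS) + "\n")
    for row in series.data[SITE_COLUMNS].itertuples(index=False):
        date = pd.Timestamp(row.date).date().isoformat()
        rest = "\t".join(_fmt(v) for v in row[1:])
        buf.write(f"{date}\t{rest}\n")
    path.write_text(buf.getvalue(), encoding="utf-8")
    if sidecars:
        for attr in ("ndvi", "lai"):
            fs = getattr(series, attr)
            if fs is None:
                continue
            side = path.with_name(path.stem + f".{attr}.tsv")
            with side.open("w", encoding="utf-8") as fh:
                fh.write("date\tvalue\treliable\n")
                for d, v, r in zip(fs.dates, fs.values, fs.reliable):
                    d = pd.Timestamp(d).date().isoformat()
                    fh.write(f"{d}\t{_fmt(v)}\t{int(r)}\n")


def _read_flagged(path: Path) -> FlaggedSeries:
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return FlaggedSeries(
        dates=pd.to_datetime(frame["date"]).to_numpy().astype("datetime64[D]"),
        values=frame["value"].to_numpy(dtype=float),
        reliable=frame["reliable"].to_numpy().astype(bool),
    )


def read_site_series(path: str | Path, pft_label: str | None = None) -> SiteSeries:
    """Read a site file; rows violating record invariants are dropped (count
    logged). Raises :class:`SiteFileError` on missing columns and
    :class:`EmptyInputError` on an empty file."""
    path = Path(path)
    meta: dict[str, str] = {}
    for line in path.read_text(encoding="utf-8").splitlines():
        if not line.startswith("#"):
            break
        key, _, value = line.lstrip("# ").partition(":")
        meta[key.strip()] = value.strip()
    try:
        frame = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: no data") from None
    missing = [c for c in SITE_COLUMNS if c != "gpp_obs" and c not in frame.columns]
    if missing:
        raise SiteFileError(f"{path}: missing column(s): {', '.join(missing)}")
    if frame.empty:
        raise EmptyInputError(f"{path}: no data rows")
    if "gpp_obs" not in frame.columns:
        frame["gpp_obs"] = np.nan
    frame["date"] = pd.to_datetime(frame["date"]).dt.date

    keep = np.ones(len(frame), dtype=bool)
    for i, row in enumerate(frame[SITE_COLUMNS].itertuples(index=False)):
        rec = SiteDailyRecord(*row)
        bad = rec.violations()
        if bad:
            keep[i] = False
            log.info("%s: rejecting row %s (%s)", path.name, rec.date, "; ".join(bad))
    n_rejected = int((~keep).sum())
    if n_rejected:
        log.warning("%s: rejected %d row(s) violating record invariants", path.name, n_rejected)
        frame = frame.loc[keep].reset_index(drop=True)
    if frame.empty:
        raise EmptyInputError(f"{path}: all rows rejected")

    pft = pft_label if pft_label is not None else meta.get("pft", "")
    lat = meta.get("latitude")
    series = SiteSeries(
        site_id=meta.get("site_id", path.stem),
        pft=canonical_pft(pft) if pft else pft,
        data=frame[SITE_COLUMNS],
        latitude=float(lat) if lat not in (None, "") else None,
    )
    for attr in ("ndvi", "lai"):
        side = path.with_name(path.stem + f".{attr}.tsv")
        if side.exists():
            setattr(series, attr, _read_flagged(side))
    return series


def _epoch_days(dates) -> np.ndarray:
    """Dates as float days since epoch (resolution-independent)."""
    return pd.to_datetime(np.asarray(dates)).to_numpy().astype("datetime64[D]").astype(float)


def fill_temporal_gaps(series: FlaggedSeries) -> FlaggedSeries:
    """Replace unreliable values by linear interpolation in time between the
    nearest reliable neighbours; leading/trailing gaps take the nearest
    reliable value. Reliable values (and flags) are untouched; idempotent."""
    ok = series.reliable
    if not ok.any():
        raise UnusableSeriesError("all values flagged unreliable; nothing to interpolate from")
    if ok.all():
        return FlaggedSeries(series.dates.copy(), series.values.copy(), ok.copy())
    t = _epoch_days(series.dates)
    filled = series.values.copy()
    filled[~ok] = np.interp(t[~ok], t[ok], series.values[ok])
    return FlaggedSeries(series.dates.copy(), filled, ok.copy())


def daily_values(series: SiteSeries, which: str = "lai") -> np.ndarray:
    """Gap-fill the 8-day series ``which`` ("lai" or "ndvi") and interpolate
    it to the daily record dates."""
    fs = getattr(series, which)
    if fs is None:
        raise UnusableSeriesError(f"series has no {which} data")
    fs = fill_temporal_gaps(fs)
    return np.interp(_epoch_days(series.data["date"]), _epoch_days(fs.dates), fs.values)


def load_run_config(path: str | Path) -> dict:
    """Read a YAML run-configuration file into a plain dict."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SiteFileError(f"{path}: run configuration must be a mapping")
    log.info("run configuration: %s", cfg)
    return cfg
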