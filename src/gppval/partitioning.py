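"""Derive "observed" daily GPP from NEE.

A temperature-dependent ecosystem-respiration law (Lloyd-Taylor form,
R(T) = r_ref * exp(e0 * (1/(t_ref - t0) - 1/(T - t0)))) is least-squares
fitted to nighttime NEE (positive efflux), extrapolated to daytime
temperature, and daytime NEE is subtracted:

    GPP = Reco_day - NEE_day

with the convention that negative NEE is net uptake. R(T) is expressed as
a whole-day-equivalent rate (g C m-2 day-1); per-period integrals are the
rate scaled by the day/night fraction of the 24 h.

This is a single-fit-per-site simplification of the moving-window
nighttime method used to process tower archives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .site_io import SiteSeries
from .solar import daylength_hours

log = logging.getLogger("gppval")

__all__ = [
    "T_REF", "T0", "RespirationFit", "FitError", "lloyd_taylor",
    "fit_nighttime_respiration", "partition_gpp", "partition_site",
    "day_night_split",
]

T_REF = 15.0     # degC, reference temperature of the fit
T0 = -46.02      # degC, temperature shift constant
MIN_FIT_POINTS = 10


class FitError(RuntimeError):
    """Respiration fit failed (too few points, degenerate design,
    non-convergence)."""


def lloyd_taylor(t, r_ref, e0, t_ref=T_REF, t0=T0):
    """Exponential respiration-temperature law (vectorized)."""
    t = np.asarray(t, dtype=float)
    return r_ref * np.exp(e0 * (1.0 / (t_ref - t0) - 1.0 / (t - t0)))


@dataclass(frozen=True)
class RespirationFit:
    r_ref: float          # g C m-2 day-1 at t_ref
    e0: float             # K, temperature sensitivity
    t_ref: float = T_REF
    t0: float = T0
    rss: float = 0.0
    n_nights: int = 0

    def __post_init__(self):
        if not (self.r_ref > 0 and self.e0 > 0):
            raise ValueError("r_ref and e0 must be > 0")

    def __call__(self, t):
        return lloyd_taylor(t, self.r_ref, self.e0, self.t_ref, self.t0)


def fit_nighttime_respiration(night_t, night_nee,
                              min_points: int = MIN_FIT_POINTS) -> RespirationFit:
    """Least-squares fit of the respiration law to (temperature, nighttime
    respiration rate) pairs. ``night_nee`` must already be a rate in the
    same per-day-equivalent units the fit should return (callers scale
    per-period integrals by the night fraction first).
    """
    t = np.asarray(night_t, dtype=float)
    r = np.asarray(night_nee, dtype=float)
    ok = np.isfinite(t) & np.isfinite(r)
    t, r = t[ok], r[ok]
    if len(t) < min_points:
        raise FitError(f"need >= {min_points} nighttime points, got {len(t)}")
    if np.ptp(t) < 1e-9:
        raise FitError("constant nighttime temperature: e0 is unidentifiable")
    p0 = (max(float(np.median(r)), 1e-3), 200.0)
    try:
        popt, _ = curve_fit(lloyd_taylor, t, r, p0=p0,
                            bounds=([1e-9, 1e-9], [np.inf, np.inf]),
                            maxfev=20000)
    except (RuntimeError, ValueError) as err:
        raise FitError(f"respiration fit did not converge: {err}") from err
    rss = float(np.sum((r - lloyd_taylor(t, *popt)) ** 2))
    return RespirationFit(r_ref=float(popt[0]), e0=float(popt[1]),
                          rss=rss, n_nights=len(t))


def day_night_split(series: SiteSeries):
    """(day_fraction, daytime T, nighttime T) arrays for a series.

    Daytime fraction is daylength/24 from the series latitude (0.5 when no
    latitude is recorded); daytime temperature is approximated by
    (t_avg + t_max)/2 and nighttime by (t_avg + t_min)/2.
    """
    if series.latitude is not None:
        day_frac = daylength_hours(series.latitude, series.doy()) / 24.0
    else:
        day_frac = np.full(len(series), 0.5)
    t_avg = series.data["t_avg"].to_numpy(dtype=float)
    t_day = 0.5 * (t_avg + series.data["t_max"].to_numpy(dtype=float))
    t_night = 0.5 * (t_avg + series.data["t_min"].to_numpy(dtype=float))
    return day_frac, t_day, t_night


def partition_gpp(series: SiteSeries, fit: RespirationFit) -> np.ndarray:
    """Daily GPP (g C m-2 day-1): daytime respiration extrapolated from the
    fit minus daytime NEE, floored at zero (floor count logged)."""
    day_frac, t_day, _ = day_night_split(series)
    reco_day = fit(t_day) * day_frac
    gpp = reco_day - series.data["nee_day"].to_numpy(dtype=float)
    n_floored = int(np.sum(gpp < 0))
    if n_floored:
        log.info("%s: floored %d negative GPP day(s) to zero",
                 series.site_id, n_floored)
    return np.maximum(gpp, 0.0)


def partition_site(series: SiteSeries) -> tuple[np.ndarray, RespirationFit]:
    """Fit nighttime respiration from the series' own nighttime NEE and
    partition: returns (daily GPP, fit)."""
    day_frac, _, t_night = day_night_split(series)
    night_frac = 1.0 - day_frac
    nee_night = series.data["nee_night"].to_numpy(dtype=float)
    ok = night_frac > 0
    rate = np.where(ok, nee_night / np.where(ok, night_frac, 1.0), np.nan)
    fit = fit_nighttime_respiration(t_night[ok], rate[ok])
    log.info("%s: respiration fit r_ref=%.4g e0=%.4g (n=%d, rss=%.4g)",
             series.site_id, fit.r_ref, fit.e0, fit.n_nights, fit.rss)
    return partition_gpp(series, fit), fit
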