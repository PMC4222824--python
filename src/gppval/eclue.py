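"""Light-use-efficiency GPP model driven by NDVI, PAR, air temperature and
the evaporative fraction LE/(LE+H).

GPP = eps_max * fPAR * PAR * min(Ts, Ws), with a quadratic cardinal-
temperature stress Ts, a Bowen-ratio-derived moisture stress Ws, and a
linear NDVI -> fPAR mapping. All coefficients are configurable; the
defaults follow the published LUE-model family, not a claimed calibration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .site_io import SiteSeries, daily_values

log = logging.getLogger("gppval")

__all__ = [
    "LueParams", "UndefinedStressError", "temperature_stress",
    "moisture_stress", "eclue_daily_gpp", "eclue_gpp", "calibrate_eps_max",
]


class UndefinedStressError(ValueError):
    """Moisture stress is undefined when LE + H <= 0."""


@dataclass(frozen=True)
class LueParams:
    """eps_max is in g C per mol quanta here (the PAR driver is
    mol quanta m-2 day-1); declare units in the run configuration if you
    supply your own value."""

    eps_max: float = 0.46
    t_min: float = 0.0
    t_max: float = 40.0
    t_opt: float = 20.33
    fpar_slope: float = 1.24
    fpar_intercept: float = -0.168
    stress_combine: str = "min"   # "min" | "product"

    def __post_init__(self):
        if not self.t_min < self.t_opt < self.t_max:
            raise ValueError("need t_min < t_opt < t_max")
        if not self.eps_max > 0:
            raise ValueError("eps_max must be > 0")
        if self.stress_combine not in ("min", "product"):
            raise ValueError("stress_combine must be 'min' or 'product'")


def temperature_stress(t, params: LueParams):
    """Quadratic cardinal-temperature scalar in [0, 1]; 1 at t_opt, 0 at and
    outside the (t_min, t_max) interval. Vectorized over ``t``."""
    t = np.asarray(t, dtype=float)
    num = (t - params.t_min) * (t - params.t_max)
    den = num - (t - params.t_opt) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        ts = np.where(den != 0, num / den, 0.0)
    ts = np.where((t <= params.t_min) | (t >= params.t_max), 0.0, ts)
    out = np.clip(ts, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def moisture_stress(le, h):
    """Evaporative-fraction moisture scalar LE/(LE+H), clamped to [0, 1].

    Scalar inputs with LE + H <= 0 raise :class:`UndefinedStressError`;
    array inputs yield NaN there (days to be excluded downstream).
    """
    le_a = np.asarray(le, dtype=float)
    h_a = np.asarray(h, dtype=float)
    total = le_a + h_a
    if le_a.ndim == 0:
        if total <= 0:
            raise UndefinedStressError(f"LE + H = {float(total)} <= 0")
        return float(np.clip(le_a / total, 0.0, 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        ws = np.where(total > 0, le_a / total, np.nan)
    n_bad = int(np.sum(total <= 0))
    if n_bad:
        log.warning("moisture stress undefined on %d day(s) (LE + H <= 0)", n_bad)
    return np.clip(ws, 0.0, 1.0)


def fpar_from_ndvi(ndvi, params: LueParams):
    return np.clip(params.fpar_slope * np.asarray(ndvi, dtype=float) + params.fpar_intercept,
                   0.0, 1.0)


def _combined_stress(ts, ws, params: LueParams):
    return np.minimum(ts, ws) if params.stress_combine == "min" else ts * ws


def eclue_daily_gpp(day, ndvi: float, params: LueParams) -> float:
    """GPP (g C m-2 day-1) for one site-day at the given NDVI."""
    if not 0 <= ndvi <= 1:
        raise ValueError("ndvi must be in [0, 1]")
    ts = temperature_stress(day.t_avg, params)
    ws = moisture_stress(day.le, day.h)
    fpar = float(fpar_from_ndvi(ndvi, params))
    return params.eps_max * fpar * day.par * float(_combined_stress(ts, ws, params))


def _series_factors(series: SiteSeries, params: LueParams, ndvi_daily=None):
    if ndvi_daily is None:
        ndvi_daily = daily_values(series, "ndvi")
    ts = temperature_stress(series.data["t_avg"].to_numpy(dtype=float), params)
    ws = moisture_stress(series.data["le"].to_numpy(dtype=float),
                         series.data["h"].to_numpy(dtype=float))
    fpar = fpar_from_ndvi(ndvi_daily, params)
    par = series.data["par"].to_numpy(dtype=float)
    return fpar * par * _combined_stress(ts, ws, params)


def eclue_gpp(series: SiteSeries, params: LueParams,
              ndvi_daily: np.ndarray | None = None) -> np.ndarray:
    """Vectorized daily GPP over a site series; NaN where moisture stress is
    undefined."""
    return params.eps_max * _series_factors(series, params, ndvi_daily)


def calibrate_eps_max(series: SiteSeries, params: LueParams,
                      ndvi_daily: np.ndarray | None = None) -> float:
    """One-parameter least-squares fit of eps_max against the series'
    observed GPP: eps = sum(obs * x) / sum(x^2), x = fPAR * PAR * stress."""
    x = _series_factors(series, params, ndvi_daily)
    obs = series.data["gpp_obs"].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(obs)
    if not ok.any() or not np.any(x[ok] != 0):
        raise ValueError("no usable days for eps_max calibration")
    return float(np.sum(obs[ok] * x[ok]) / np.sum(x[ok] ** 2))
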