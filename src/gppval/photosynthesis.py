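"""Leaf-level C3/C4 gross photosynthesis and big-leaf canopy scaling.

The C3 gross rate is the minimum of a light-limited, a Rubisco-limited and a
triose-phosphate-limited rate; the C4 gross rate is the minimum of three
carbon-fixation capacities (light-, Rubisco- and CO2-limited). Kinetic
constants follow single-Q10 temperature responses around 25 degC, with the
CO2 compensation point Gamma* = O2 / (2 tau).

Canopy scaling is a single big leaf absorbing Beer's-law canopy light
(1 - exp(-k LAI)) at mean daytime PAR flux, evaluated at daily mean air
temperature and integrated over daylength.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np

from .site_io import SiteSeries, daily_values
from .solar import daylength_hours

__all__ = [
    "PhotoParams", "LeafEnv", "LimitingRates", "Kinetics",
    "kinetics_at_temperature", "c3_gross_rate", "c4_gross_rate",
    "colimit_smooth", "canopy_daily_gpp", "forward_gpp",
]

#: grams of carbon per mole of CO2 fixed
GRAMS_C_PER_MOL = 12.011

#: default Beer's-law canopy light-extinction coefficient
DEFAULT_K_EXT = 0.5


@dataclass(frozen=True)
class PhotoParams:
    """Leaf photosynthesis parameters.

    Kinetic constants and quantum efficiencies default to the classic C3/C4
    leaf-model lineage; every value is configurable and none is asserted to
    be a literature-exact site value. ``k_c4`` (initial slope of the C4 CO2
    response, mol m-2 s-1) defaults to 18000 * vcmax25 when left None.
    """

    vcmax25: float = 30e-6      # mol CO2 m-2 s-1 at 25 degC
    alpha3: float = 0.060       # mol CO2 / mol quanta, C3 intrinsic quantum eff.
    alpha4: float = 0.050       # mol CO2 / mol quanta, C4
    kc25: float = 3.0e-4        # mol mol-1, Michaelis constant for CO2
    ko25: float = 0.30          # mol mol-1, Michaelis constant for O2
    tau25: float = 2600.0       # Rubisco specificity, dimensionless
    o2: float = 0.209           # mol mol-1 intercellular O2
    tpu_ratio: float = 0.45     # triose-phosphate capacity as fraction of vm
    k_c4: float | None = None   # mol m-2 s-1; None -> 18000 * vcmax25
    q10_vm: float = 2.0
    q10_kc: float = 2.1
    q10_ko: float = 1.2
    q10_tau: float = 0.57       # tau falls with temperature
    ci_ca_c3: float = 0.7
    ci_ca_c4: float = 0.4
    ca: float = 370e-6          # mol mol-1 ambient CO2

    def __post_init__(self):
        for name in ("vcmax25", "alpha3", "alpha4", "kc25", "ko25", "tau25",
                     "o2", "tpu_ratio", "ca"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("q10_vm", "q10_kc", "q10_ko", "q10_tau"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("ci_ca_c3", "ci_ca_c4"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.k_c4 is not None and self.k_c4 < 0:
            raise ValueError("k_c4 must be >= 0")

    @property
    def k_c4_effective(self) -> float:
        return self.k_c4 if self.k_c4 is not None else 18000.0 * self.vcmax25

    def with_vcmax(self, vcmax25: float) -> "PhotoParams":
        return replace(self, vcmax25=vcmax25)


@dataclass(frozen=True)
class LeafEnv:
    """Leaf microenvironment: absorbed PAR flux (mol quanta m-2 s-1),
    intercellular CO2 (mol mol-1) and leaf temperature (degC)."""

    qp: float
    ci: float
    t_leaf: float = 25.0

    def __post_init__(self):
        if self.qp < 0 or self.ci < 0:
            raise ValueError("qp and ci must be >= 0")


class Kinetics(NamedTuple):
    vm: float
    kc: float
    ko: float
    gamma_star: float


class LimitingRates(NamedTuple):
    """The three capacities, their minimum, and which one was binding."""

    je: float
    jc: float
    js: float
    gross: float
    limiter: str


def kinetics_at_temperature(params: PhotoParams, t_leaf) -> Kinetics:
    """Q10-adjust vm, kc, ko to ``t_leaf`` and return Gamma* = o2/(2 tau)
    with tau likewise Q10-adjusted. Accepts scalar or array temperature."""
    f = lambda q10: q10 ** ((np.asarray(t_leaf, dtype=float) - 25.0) / 10.0)
    tau = params.tau25 * f(params.q10_tau)
    return Kinetics(
        vm=params.vcmax25 * f(params.q10_vm),
        kc=params.kc25 * f(params.q10_kc),
        ko=params.ko25 * f(params.q10_ko),
        gamma_star=params.o2 / (2.0 * tau),
    )


def _c3_capacities(qp, ci, t_leaf, params: PhotoParams):
    """Vectorized C3 capacities (je, jc, js); each floored at zero so that
    sub-compensation-point ci yields zero, not negative, assimilation."""
    vm, kc, ko, gs = kinetics_at_temperature(params, t_leaf)
    qp = np.asarray(qp, dtype=float)
    ci = np.asarray(ci, dtype=float)
    je = params.alpha3 * qp * (ci - gs) / (ci + 2.0 * gs)
    jc = vm * (ci - gs) / (ci + kc * (1.0 + params.o2 / ko))
    js = params.tpu_ratio * vm * np.ones_like(je)
    return np.maximum(je, 0.0), np.maximum(jc, 0.0), np.maximum(js, 0.0)


def _c4_capacities(qp, ci, t_leaf, params: PhotoParams):
    vm = kinetics_at_temperature(params, t_leaf).vm
    qp = np.asarray(qp, dtype=float)
    ci = np.asarray(ci, dtype=float)
    je = params.alpha4 * qp
    jc = vm * np.ones_like(je)
    js = params.k_c4_effective * ci
    return np.maximum(je, 0.0), np.maximum(jc, 0.0), np.maximum(js, 0.0)


def c3_gross_rate(env: LeafEnv, params: PhotoParams) -> LimitingRates:
    """C3 gross rate: min of light-, Rubisco- and triose-phosphate-limited
    capacities (mol CO2 m-2 s-1)."""
    je, jc, js = (float(x) for x in _c3_capacities(env.qp, env.ci, env.t_leaf, params))
    gross = min(je, jc, js)
    # tie preference light > rubisco > triose is cosmetic only
    limiter = "light" if gross == je else ("rubisco" if gross == jc else "triose")
    return LimitingRates(je, jc, js, gross, limiter)


def c4_gross_rate(env: LeafEnv, params: PhotoParams) -> LimitingRates:
    """C4 gross rate: min of light-limited (alpha4 qp), Rubisco-limited (vm)
    and low-CO2 (k ci) capacities."""
    je, jc, js = (float(x) for x in _c4_capacities(env.qp, env.ci, env.t_leaf, params))
    gross = min(je, jc, js)
    if gross == je:
        limiter = "light"
    elif gross == jc:
        limiter = "rubisco"
    else:
        limiter = "co2"
    return LimitingRates(je, jc, js, gross, limiter)


def colimit_smooth(je, jc, js, theta: float = 0.97, beta: float = 0.99):
    """Optional smoothed colimitation: nested lower roots of
    theta x^2 - (je+jc) x + je jc = 0 then beta y^2 - (x+js) y + x js = 0.
    Approaches the hard minimum as theta, beta -> 1."""
    def lower_root(a, b, c):
        disc = np.maximum(b * b - 4.0 * a * c, 0.0)
        return (b - np.sqrt(disc)) / (2.0 * a)

    jp = lower_root(theta, np.asarray(je) + np.asarray(jc), np.asarray(je) * np.asarray(jc))
    return lower_root(beta, jp + np.asarray(js), jp * np.asarray(js))


def _daytime_qp(par_daily, daylength_h, lai, k_ext):
    """Mean daytime canopy-absorbed PAR flux (mol quanta m-2 s-1)."""
    daylength_s = np.asarray(daylength_h, dtype=float) * 3600.0
    absorbed = 1.0 - np.exp(-k_ext * np.asarray(lai, dtype=float))
    with np.errstate(divide="ignore", invalid="ignore"):
        qp = np.where(daylength_s > 0, np.asarray(par_daily, dtype=float) / daylength_s, 0.0)
    return qp * absorbed


def canopy_daily_gpp(day, lai: float, params: PhotoParams, pathway: str = "C3",
                     k_ext: float = DEFAULT_K_EXT, daylength_h: float | None = None,
                     latitude: float | None = None,
                     smoothing: tuple[float, float] | None = None) -> float:
    """Daily canopy GPP (g C m-2 day-1) for one site-day record.

    Daylength comes from ``daylength_h`` if given, else from ``latitude``
    and the record date, else defaults to 12 h.
    """
    if lai < 0:
        raise ValueError("lai must be >= 0")
    if daylength_h is None:
        if latitude is not None:
            import pandas as pd
            doy = pd.Timestamp(day.date).dayofyear
            daylength_h = float(daylength_hours(latitude, doy))
        else:
            daylength_h = 12.0
    qp = float(_daytime_qp(day.par, daylength_h, lai, k_ext))
    if pathway.upper() == "C4":
        ci = params.ci_ca_c4 * params.ca
        rates = c4_gross_rate(LeafEnv(qp, ci, day.t_avg), params)
    else:
        ci = params.ci_ca_c3 * params.ca
        rates = c3_gross_rate(LeafEnv(qp, ci, day.t_avg), params)
    gross = rates.gross if smoothing is None else float(
        colimit_smooth(rates.je, rates.jc, rates.js, *smoothing))
    return gross * daylength_h * 3600.0 * GRAMS_C_PER_MOL


def forward_gpp(series: SiteSeries, params: PhotoParams, pathway: str = "C3",
                vcmax: float | None = None, k_ext: float = DEFAULT_K_EXT,
                lai_daily: np.ndarray | None = None,
                smoothing: tuple[float, float] | None = None) -> np.ndarray:
    """Vectorized daily canopy GPP over a whole site series (g C m-2 day-1).

    Uses the series' gap-filled 8-day LAI interpolated to daily values
    unless ``lai_daily`` is supplied; ``vcmax`` overrides ``params.vcmax25``.
    """
    if vcmax is not None:
        params = params.with_vcmax(vcmax)
    if lai_daily is None:
        lai_daily = daily_values(series, "lai")
    if np.any(np.asarray(lai_daily) < 0):
        raise ValueError("lai must be >= 0")
    t = series.data["t_avg"].to_numpy(dtype=float)
    par = series.data["par"].to_numpy(dtype=float)
    if series.latitude is not None:
        dl = daylength_hours(series.latitude, series.doy())
    else:
        dl = np.full(len(series), 12.0)
    qp = _daytime_qp(par, dl, lai_daily, k_ext)
    if pathway.upper() == "C4":
        je, jc, js = _c4_capacities(qp, params.ci_ca_c4 * params.ca, t, params)
    else:
        je, jc, js = _c3_capacities(qp, params.ci_ca_c3 * params.ca, t, params)
    if smoothing is None:
        gross = np.minimum(np.minimum(je, jc), js)
    else:
        gross = colimit_smooth(je, jc, js, *smoothing)
    return gross * dl * 3600.0 * GRAMS_C_PER_MOL
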