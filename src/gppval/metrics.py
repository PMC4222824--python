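"""Per-site validation statistics (R2, RMSE, relative predictive error),
biome-level aggregation, threshold censuses, paired model comparison and a
toy area-weighted global upscaling.

RPE = (mean(sim) - mean(obs)) / mean(obs) * 100. R2 is the squared Pearson
correlation by default (the scatterplot "variation explained" convention);
``r2_method="ss"`` switches to 1 - SSE/SST.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .site_io import VALIDATION_PFTS

log = logging.getLogger("gppval")

__all__ = [
    "SiteMetrics", "PftSummary", "MetricsError", "LabelingError",
    "PairingError", "compute_metrics", "aggregate_by_pft", "census_rpe",
    "relative_difference", "paired_t", "paired_compare", "upscale_global",
]


class MetricsError(ValueError):
    """Metric undefined for the given inputs."""


class LabelingError(ValueError):
    """Metric row labeled with an unknown biome code."""


class PairingError(ValueError):
    """Site lists cannot be matched one-to-one."""


@dataclass(frozen=True)
class SiteMetrics:
    site_id: str
    pft: str
    model: str        # e.g. "IBIS" | "IBIS-Type" | "EC-LUE"
    r2: float
    rmse: float
    rpe: float        # percent

    def __post_init__(self):
        if self.rmse < 0:
            raise ValueError("rmse must be >= 0")
        if not 0 <= self.r2 <= 1:
            raise ValueError("r2 must be in [0, 1]")


@dataclass(frozen=True)
class PftSummary:
    pft: str
    model: str
    mean_r2: float
    mean_rmse: float
    mean_rpe: float
    n_sites: int


class MetricsTriple(NamedTuple):
    r2: float
    rmse: float
    rpe: float


def compute_metrics(obs, sim, r2_method: str = "pearson") -> MetricsTriple:
    """(R2, RMSE, RPE) of paired daily series."""
    obs = np.asarray(obs, dtype=float)
    sim = np.asarray(sim, dtype=float)
    if obs.shape != sim.shape:
        raise MetricsError("obs and sim must have equal length")
    ok = np.isfinite(obs) & np.isfinite(sim)
    obs, sim = obs[ok], sim[ok]
    if len(obs) < 2:
        raise MetricsError("need at least 2 paired finite values")
    mean_obs = obs.mean()
    if mean_obs == 0:
        raise MetricsError("RPE undefined: observed mean is zero")
    if r2_method == "pearson":
        if obs.std() == 0 or sim.std() == 0:
            raise MetricsError("R2 undefined: zero variance")
        r2 = float(stats.pearsonr(obs, sim).statistic ** 2)
    elif r2_method == "ss":
        sst = float(np.sum((obs - mean_obs) ** 2))
        if sst == 0:
            raise MetricsError("R2 undefined: zero variance")
        r2 = 1.0 - float(np.sum((obs - sim) ** 2)) / sst
    else:
        raise ValueError("r2_method must be 'pearson' or 'ss'")
    rmse = float(np.sqrt(np.mean((sim - obs) ** 2)))
    rpe = float((sim.mean() - mean_obs) / mean_obs * 100.0)
    return MetricsTriple(r2, rmse, rpe)


def aggregate_by_pft(metrics: Iterable[SiteMetrics]) -> list[PftSummary]:
    """Arithmetic per-(pft, model) means at full precision (round only for
    reporting)."""
    rows = list(metrics)
    if not rows:
        raise MetricsError("no metrics to aggregate")
    for m in rows:
        if m.pft not in VALIDATION_PFTS:
            raise LabelingError(f"unknown biome code: {m.pft!r}")
    frame = pd.DataFrame([m.__dict__ for m in rows])
    out = []
    for (pft, model), grp in frame.groupby(["pft", "model"], sort=True):
        out.append(PftSummary(
            pft=pft, model=model,
            mean_r2=float(grp["r2"].mean()),
            mean_rmse=float(grp["rmse"].mean()),
            mean_rpe=float(grp["rpe"].mean()),
            n_sites=int(len(grp)),
        ))
    return out


def census_rpe(metrics: Sequence[SiteMetrics], comparator: str,
               threshold: float) -> int:
    """Count sites whose RPE is strictly below/above ``threshold`` percent."""
    if not metrics:
        raise MetricsError("no metrics to census")
    if comparator == "below":
        return sum(1 for m in metrics if m.rpe < threshold)
    if comparator == "above":
        return sum(1 for m in metrics if m.rpe > threshold)
    raise ValueError("comparator must be 'below' or 'above'")


def relative_difference(a: float, b: float) -> float:
    """(a - b)/b * 100 percent (round to integer when mirroring report
    phrasing)."""
    if b == 0:
        raise MetricsError("relative difference undefined: zero reference")
    return (a - b) / b * 100.0


class PairedTResult(NamedTuple):
    t_stat: float
    p_value: float
    degenerate: bool


def paired_t(a, b) -> PairedTResult:
    """Paired t statistic on per-pair differences with n-1 dof. A constant
    nonzero difference (zero variance) is reported as degenerate infinite t
    rather than an error."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or len(a) < 3:
        raise MetricsError("need >= 3 matched pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return PairedTResult(0.0, 1.0, False)
        log.warning("paired t degenerate: constant nonzero difference")
        return PairedTResult(math.copysign(math.inf, d.mean()), 0.0, True)
    t = d.mean() / (sd / math.sqrt(len(d)))
    p = 2.0 * stats.t.sf(abs(t), df=len(d) - 1)
    return PairedTResult(float(t), float(p), False)


def paired_compare(metrics_a: Sequence[SiteMetrics],
                   metrics_b: Sequence[SiteMetrics],
                   field: str = "r2") -> PairedTResult:
    """Paired t-test of one metric between two models, matched by site_id."""
    by_a = {m.site_id: m for m in metrics_a}
    by_b = {m.site_id: m for m in metrics_b}
    if set(by_a) != set(by_b):
        raise PairingError("site lists do not match one-to-one")
    sites = sorted(by_a)
    return paired_t([getattr(by_a[s], field) for s in sites],
                    [getattr(by_b[s], field) for s in sites])


def upscale_global(cell_gpp, cell_area) -> float:
    """Area-weighted total of per-area annual GPP (g C m-2 yr-1) over cell
    areas (m2), in Pg C yr-1."""
    gpp = np.asarray(cell_gpp, dtype=float)
    area = np.asarray(cell_area, dtype=float)
    if gpp.shape != area.shape:
        raise ValueError("gpp and area grids must be congruent")
    if np.any(area <= 0):
        raise ValueError("cell areas must be > 0")
    return float(np.sum(gpp * area) * 1e-15)
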