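"""Stomatal sensitivity to VPD and its environmental decomposition.

Daytime canopy conductance declines approximately linearly with the
natural log of VPD: G_S = G_Sref − m·lnVPD. The negative slope m is the
stomatal sensitivity (−δG_S/δlnVPD), the intercept G_Sref is the
reference conductance at VPD = 1 kPa, and the ratio m/G_Sref is the
dimensionless sensitivity normalized by reference conductance —
approximately 0.6 under hydraulically optimal (isohydric) regulation.
The decomposition bins days by relative soil moisture or by daily
integrated light, fits the lnVPD response per bin, and regresses the
per-bin sensitivity against the bin midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateInputError,
    InsufficientBinsError,
    InsufficientDataError,
)


@dataclass
class SensitivityFit:
    sensitivity: float  # -dGS/dlnVPD, mol m-2 s-1 ln(kPa)-1
    GSref: float  # mol m-2 s-1 at VPD = 1 kPa
    ratio: float | None  # sensitivity/GSref; None when GSref <= 0
    n: int
    r2: float
    p_value: float


@dataclass
class BinnedSensitivity:
    covariate: str
    bin_edges: np.ndarray
    bin_mid: np.ndarray
    fits: list  # SensitivityFit per retained bin
    slope: float  # cross-bin: d(sensitivity)/d(covariate)
    intercept: float
    r2: float
    p_value: float


def _ols(x: np.ndarray, y: np.ndarray):
    """Slope, intercept, r2 and the classical two-sided slope p-value."""
    n = len(x)
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    if sxx == 0.0:
        raise DegenerateInputError("regressor is constant")
    sxy = float(np.sum((x - xm) * (y - ym)))
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = y - (slope * x + intercept)
    rss = float(np.sum(resid**2))
    syy = float(np.sum((y - ym) ** 2))
    r2 = 1.0 - rss / syy if syy > 0 else 1.0
    if n > 2 and rss > 0:
        se = np.sqrt(rss / (n - 2) / sxx)
        p = 2.0 * stats.t.sf(abs(slope) / se, df=n - 2)
    else:
        p = 0.0 if slope != 0 else 1.0
    return slope, intercept, r2, float(p)


def fit_vpd_response(gs, vpd) -> SensitivityFit:
    """OLS of G_S on ln(VPD): sensitivity, G_Sref and their ratio.

    Accepts the daily mean-daytime table (the field protocol) or any
    paired (G_S, VPD) sample such as the half-hourly qualifying steps.
    """
    gs = np.asarray(gs, dtype=float)
    vpd = np.asarray(vpd, dtype=float)
    mask = np.isfinite(gs) & np.isfinite(vpd)
    gs, vpd = gs[mask], vpd[mask]
    if len(gs) < 3:
        raise InsufficientDataError("need >= 3 (G_S, VPD) points")
    if np.any(vpd <= 0):
        raise ValueError("VPD must be positive for the log transform")
    x = np.log(vpd)
    if np.ptp(x) == 0:
        raise DegenerateInputError("VPD is constant across points")
    slope, intercept, r2, p = _ols(x, gs)
    sens = -slope
    gsref = intercept
    ratio = sens / gsref if gsref > 0 else None
    return SensitivityFit(
        sensitivity=float(sens), GSref=float(gsref), ratio=ratio,
        n=len(gs), r2=r2, p_value=p,
    )


def relative_soil_moisture(theta) -> np.ndarray:
    """Soil moisture as percent of the series maximum (assumed field capacity)."""
    theta = np.asarray(theta, dtype=float)
    peak = np.nanmax(theta) if len(theta) else 0.0
    if not peak > 0:
        raise DegenerateInputError("soil moisture series has no positive value")
    return 100.0 * theta / peak


def daily_ppfd_integral(ppfd: pd.Series, gap_threshold: float = 0.2) -> pd.DataFrame:
    """Daily integrated PPFD (mol m-2 d-1) from a uniform sub-daily series.

    Sum of PPFD·Δt over each calendar day divided by 1e6; days with a gap
    fraction above ``gap_threshold`` are flagged.
    """
    deltas = np.diff(ppfd.index.view("int64")) / 1e9
    if len(deltas) == 0 or not np.allclose(deltas, deltas[0]):
        raise ValueError("PPFD series must have a uniform timestep")
    step = float(deltas[0])
    by_day = ppfd.groupby(ppfd.index.normalize())
    out = pd.DataFrame(
        {
            "PPFD_daily": by_day.sum() * step / 1e6,
            "gap_fraction": by_day.apply(lambda s: s.isna().mean()),
        }
    )
    out["gap_flag"] = out["gap_fraction"] > gap_threshold
    return out


def binned_sensitivity(
    daily: pd.DataFrame,
    covariate: str,
    bin_width: float,
    min_days: int = 5,
    gs_col: str = "GS_mean",
    vpd_col: str = "VPD_mean",
) -> BinnedSensitivity:
    """Stomatal sensitivity across an environmental gradient.

    Days are partitioned into equal-width bins of the covariate (edges
    anchored at zero); bins with fewer than ``min_days`` days are dropped;
    the lnVPD response is fitted per retained bin (days pooled within the
    bin) and the per-bin sensitivities are regressed on bin midpoints.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    cov = daily[covariate].to_numpy(dtype=float)
    idx = np.floor(cov / bin_width).astype(int)
    fits, mids, edges = [], [], set()
    for b in sorted(np.unique(idx)):
        rows = daily[idx == b]
        if len(rows) < min_days:
            continue
        fits.append(fit_vpd_response(rows[gs_col], rows[vpd_col]))
        mids.append((b + 0.5) * bin_width)
        edges.update((b * bin_width, (b + 1) * bin_width))
    if len(fits) < 2:
        raise InsufficientBinsError(
            f"only {len(fits)} bin(s) retain >= {min_days} days"
        )
    mids = np.asarray(mids)
    sens = np.asarray([f.sensitivity for f in fits])
    slope, intercept, r2, p = _ols(mids, sens)
    return BinnedSensitivity(
        covariate=covariate,
        bin_edges=np.asarray(sorted(edges)),
        bin_mid=mids,
        fits=fits,
        slope=float(slope),
        intercept=float(intercept),
        r2=r2,
        p_value=p,
    )


def covariate_response(gs, covariate) -> dict:
    """OLS of daily mean daytime G_S on an environmental covariate."""
    gs = np.asarray(gs, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    mask = np.isfinite(gs) & np.isfinite(covariate)
    gs, covariate = gs[mask], covariate[mask]
    if len(gs) < 3:
        raise InsufficientDataError("need >= 3 days")
    slope, intercept, r2, p = _ols(covariate, gs)
    return {"slope": slope, "intercept": intercept, "r2": r2, "p_value": p, "n": len(gs)}
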