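"""Canopy stomatal conductance from leaf-specific transpiration and VPD.

The simplified inversion G_S = K_G(T)·E_L/VPD holds when the canopy is
aerodynamically well coupled (high boundary-layer conductance, leaf ≈ air
temperature, uniform VPD through the crown, negligible stem water
storage) — conditions argued to hold in open pine/oak stands. K_G is the
temperature-dependent conductance coefficient of Phillips & Oren;
conversion from velocity (m s-1) to molar units divides by the ideal-gas
molar volume 0.0224·T_K/273 m3 mol-1.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MOLAR_VOLUME_273 = 0.0224  # m3 mol-1 at 273 K
DEFAULT_VPD_THRESHOLD = 0.5  # kPa


def conductance_coefficient(t_air_c):
    """K_G (kPa m3 kg-1) = 115.8 + 0.4236·T(°C)."""
    t = np.asarray(t_air_c, dtype=float)
    if np.any((t < -50) | (t > 60)):
        raise ValueError("air temperature outside plausible range (-50..60 C)")
    out = 115.8 + 0.4236 * t
    return float(out) if out.ndim == 0 else out


def molar_volume(t_air_c):
    """Molar volume of water vapor (m3 mol-1): 0.0224·T_K/273, T_K = T + 273.15."""
    t = np.asarray(t_air_c, dtype=float)
    out = MOLAR_VOLUME_273 * (t + 273.15) / 273.0
    return float(out) if out.ndim == 0 else out


def canopy_conductance(e_l, vpd, t_air_c):
    """G_S in velocity and molar form from E_L (kg m-2 s-1), VPD (kPa), T (°C).

    G_S[m s-1] = K_G(T)·E_L/VPD; the molar form divides by the molar
    volume. Steps with VPD <= 0 are undefined and returned as NaN.
    """
    e_l = np.asarray(e_l, dtype=float)
    vpd = np.asarray(vpd, dtype=float)
    t = np.asarray(t_air_c, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        gs_ms = np.where(vpd > 0, conductance_coefficient(t) * e_l / vpd, np.nan)
        gs_mol = gs_ms / molar_volume(t)
    if gs_ms.ndim == 0:
        return {"GS_ms": float(gs_ms), "GS_mol": float(gs_mol)}
    return {"GS_ms": gs_ms, "GS_mol": gs_mol}


def conductance_series(
    e_l: pd.Series, met: pd.DataFrame, vpd_threshold: float = DEFAULT_VPD_THRESHOLD
) -> pd.DataFrame:
    """Half-hourly conductance table aligned to the met series.

    Columns: GS_ms, GS_mol, VPD, T_air, daytime. A step is daytime when
    VPD exceeds the threshold and, if the met table carries PPFD, the sun
    is up (PPFD > 0) — sap-flow-derived G_S is only meaningful while
    stomata are light-activated. G_S is NaN where VPD <= 0 or E_L gapped.
    """
    vpd = met.loc[e_l.index, "VPD"]
    t_air = met.loc[e_l.index, "T_air"]
    gs = canopy_conductance(e_l.to_numpy(), vpd.to_numpy(), t_air.to_numpy())
    daytime = vpd.to_numpy() > vpd_threshold
    if "PPFD" in met.columns:
        daytime = daytime & (met.loc[e_l.index, "PPFD"].to_numpy() > 0)
    return pd.DataFrame(
        {
            "GS_ms": gs["GS_ms"],
            "GS_mol": gs["GS_mol"],
            "VPD": vpd,
            "T_air": t_air,
            "daytime": daytime,
        },
        index=e_l.index,
    )


def daily_daytime_mean(
    series: pd.DataFrame, vpd_threshold: float = DEFAULT_VPD_THRESHOLD
) -> pd.DataFrame:
    """Daily mean daytime G_S (molar) and VPD over steps with VPD > threshold.

    Both means run over the same qualifying steps (the ``daytime`` flag
    when present, else the bare VPD filter). Days with no qualifying step
    are omitted and logged.
    """
    if vpd_threshold <= 0:
        raise ValueError("vpd_threshold must be positive")
    if "daytime" in series.columns:
        ok = series["daytime"] & series["GS_mol"].notna()
    else:
        ok = (series["VPD"] > vpd_threshold) & series["GS_mol"].notna()
    qual = series[ok]
    n_days_total = series.index.normalize().nunique()
    grouped = qual.groupby(qual.index.normalize())
    daily = pd.DataFrame(
        {
            "GS_mean": grouped["GS_mol"].mean(),
            "VPD_mean": grouped["VPD"].mean(),
            "n_steps": grouped["GS_mol"].size(),
        }
    )
    omitted = n_days_total - len(daily)
    if omitted:
        logger.info("omitted %d day(s) with no step above %g kPa", omitted, vpd_threshold)
    return daily
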