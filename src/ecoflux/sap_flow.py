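"""Granier thermal-dissipation sap-flow processing.

Raw signals are half-hourly temperature differences ΔT between a heated
and a reference probe. Processing steps:

1. zero-flow baseline ΔT_max detection from calm, humid nights (VPD below
   0.05 kPa sustained for two hours with a stable signal), linearly
   interpolated between qualifying windows;
2. conversion to sap flux density J_S = 0.119·(ΔT_max/ΔT − 1)^1.23
   (kg m-2 sapwood s-1), with ΔT ≥ ΔT_max clamped to zero flow;
3. an optional ring-porous correction hook for diffuse heat loss in oaks
   (the default is the identity; a multiplicative power law a·J^b can be
   registered with coefficients from an external calibration);
4. area-weighted radial integration across sensor depths;
5. scaling to whole-tree (E_C) and leaf-specific (E_L) transpiration via
   sapwood area and leaf area, with the oak DBH–sapwood-area logistic
   allometry built in and pine allometries accepted as pluggable callables.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    BaselineFailureError,
    ConfigurationError,
    InvalidGeometryError,
    InvalidSignalError,
)

logger = logging.getLogger(__name__)

GRANIER_COEF = 0.119  # kg m-2 s-1
GRANIER_EXP = 1.23

# oak DBH (cm) -> sapwood area (m2) logistic allometry
OAK_AS_ASYMPTOTE = 0.0188
OAK_AS_MIDPOINT = 20.97
OAK_AS_SCALE = 4.791


@dataclass
class TreeGeometry:
    """Per-tree geometry used for flux scaling and radial integration."""

    tree_id: str
    species: str  # "oak" | "pine"
    dbh_cm: float
    sapwood_area_m2: float
    leaf_area_m2: float  # single-sided
    sensor_depths: tuple = ("single",)  # ("outer",), ("outer","inner") or ("single",)
    annulus_areas_m2: tuple | None = None  # explicit per-sensor areas, optional
    deep_sapwood: str = "inner"  # rate for sapwood deeper than the inner sensor

    def __post_init__(self):
        if self.dbh_cm <= 0:
            raise InvalidGeometryError(f"{self.tree_id}: DBH must be positive")
        if self.sapwood_area_m2 <= 0:
            raise InvalidGeometryError(f"{self.tree_id}: sapwood area must be positive")
        if self.leaf_area_m2 <= 0:
            raise InvalidGeometryError(f"{self.tree_id}: leaf area must be positive")
        if self.deep_sapwood not in ("inner", "zero"):
            raise InvalidGeometryError("deep_sapwood must be 'inner' or 'zero'")

    def sapwood_depth_cm(self) -> float:
        """Sapwood depth implied by DBH and sapwood area (bark ignored)."""
        r = self.dbh_cm / 2.0
        a_cm2 = self.sapwood_area_m2 * 1e4
        inner_sq = r * r - a_cm2 / math.pi
        if inner_sq < 0:
            raise InvalidGeometryError(
                f"{self.tree_id}: sapwood area exceeds the stem cross-section"
            )
        return r - math.sqrt(inner_sq)

    def annulus_areas(self, outer_depth_cm: float = 2.0) -> tuple[float, float]:
        """(outer, inner+deeper) sapwood areas (m2) for two-sensor trees.

        The outer annulus spans 0 to ``outer_depth_cm`` below cambium (or
        the full sapwood depth if shallower); everything deeper belongs to
        the inner sensor. Explicit ``annulus_areas_m2`` takes precedence.
        """
        if self.annulus_areas_m2 is not None:
            if len(self.annulus_areas_m2) != 2:
                raise InvalidGeometryError("annulus_areas_m2 must have two entries")
            return tuple(self.annulus_areas_m2)
        r = self.dbh_cm / 2.0
        d = self.sapwood_depth_cm()
        d_outer = min(outer_depth_cm, d)
        a_outer = math.pi * (r * r - (r - d_outer) ** 2) / 1e4
        return a_outer, self.sapwood_area_m2 - a_outer


def oak_sapwood_area(dbh_cm) -> float:
    """Oak sapwood area (m2) from DBH (cm): logistic, asymptote 0.0188 m2."""
    dbh = np.asarray(dbh_cm, dtype=float)
    if np.any(dbh <= 0):
        raise InvalidGeometryError("DBH must be positive")
    out = OAK_AS_ASYMPTOTE / (1.0 + np.exp(-(dbh - OAK_AS_MIDPOINT) / OAK_AS_SCALE))
    return float(out) if out.ndim == 0 else out


def pine_leaf_area(all_sided_m2) -> float:
    """Single-sided pine leaf area: all-sided area divided by π."""
    a = np.asarray(all_sided_m2, dtype=float)
    if np.any(a < 0):
        raise InvalidGeometryError("all-sided leaf area must be non-negative")
    out = a / math.pi
    return float(out) if out.ndim == 0 else out


# --------------------------------------------------------------------------
# baseline detection


def _step_seconds(index: pd.DatetimeIndex) -> float:
    deltas = np.diff(index.view("int64")) / 1e9
    if len(deltas) == 0 or not np.allclose(deltas, deltas[0]):
        raise InvalidSignalError("timestamps must be strictly increasing and uniform")
    return float(deltas[0])


def detect_baseline(
    dT: pd.Series,
    vpd: pd.Series,
    vpd_threshold: float = 0.05,
    min_hours: float = 2.0,
    stability_frac: float = 0.005,
) -> pd.Series:
    """Zero-flow baseline ΔT_max schedule for one sensor.

    Candidate windows are runs of at least ``min_hours`` with VPD below
    ``vpd_threshold`` and a stable signal (ΔT range within
    ``stability_frac`` of the window mean). Each qualifying window
    contributes its maximum ΔT at its midpoint time; the schedule is the
    linear interpolation between those nodes, held flat beyond the first
    and last window.
    """
    if not dT.index.equals(vpd.index):
        raise InvalidSignalError("dT and VPD series must share timestamps")
    step = _step_seconds(dT.index)
    k_min = max(2, int(math.ceil(min_hours * 3600.0 / step)))

    calm = (vpd.to_numpy() < vpd_threshold) & np.isfinite(dT.to_numpy())
    nodes_t, nodes_v = [], []
    near_misses = []
    i, n = 0, len(calm)
    while i < n:
        if not calm[i]:
            i += 1
            continue
        j = i
        while j < n and calm[j]:
            j += 1
        if j - i >= k_min:
            seg = dT.iloc[i:j]
            found = False
            # whole run first, then 2 h sub-windows
            candidates = [(i, j)] if j - i == k_min else [(i, j)] + [
                (s, s + k_min) for s in range(i, j - k_min + 1)
            ]
            best = None
            for s, e in candidates:
                w = dT.iloc[s:e]
                if (w.max() - w.min()) <= stability_frac * w.mean():
                    found = True
                    if best is None or w.max() > best[2]:
                        mid = dT.index[s] + (dT.index[e - 1] - dT.index[s]) / 2
                        best = (s, e, w.max(), mid)
            if found:
                nodes_t.append(best[3].value)
                nodes_v.append(float(best[2]))
            else:
                near_misses.append(
                    {
                        "start": dT.index[i],
                        "steps": j - i,
                        "dT_range": float(seg.max() - seg.min()),
                        "reason": "unstable signal",
                    }
                )
        elif j - i >= 2:
            near_misses.append(
                {
                    "start": dT.index[i],
                    "steps": j - i,
                    "reason": f"calm run shorter than {min_hours} h",
                }
            )
        i = j

    if not nodes_t:
        raise BaselineFailureError(
            "no qualifying zero-flow window in the series", near_misses=near_misses
        )
    t = dT.index.view("int64").astype(float)
    sched = np.interp(t, np.asarray(nodes_t, dtype=float), nodes_v)
    return pd.Series(sched, index=dT.index, name="dTmax")


# --------------------------------------------------------------------------
# flux conversion


def granier_flux(dT, dTmax):
    """Sap flux density J_S = 0.119·(ΔT_max/ΔT − 1)^1.23, kg m-2 s-1.

    ΔT at or above ΔT_max means zero flow. NaN inputs propagate.
    """
    dT = np.asarray(dT, dtype=float)
    dTmax = np.asarray(dTmax, dtype=float)
    if np.any(dT[np.isfinite(dT)] <= 0):
        raise InvalidSignalError("dT must be positive")
    ratio = dTmax / dT
    js = np.where(ratio > 1.0, GRANIER_COEF * np.abs(ratio - 1.0) ** GRANIER_EXP, 0.0)
    js = np.where(np.isfinite(ratio), js, np.nan)
    return float(js) if js.ndim == 0 else js


def flux_series(dT: pd.Series, dTmax: pd.Series) -> pd.DataFrame:
    """Per-step J_S with quality flags ('ok', 'clamped', 'gap')."""
    js = granier_flux(dT.to_numpy(), dTmax.to_numpy())
    flags = np.where(dT.to_numpy() > dTmax.to_numpy(), "clamped", "ok")
    flags = np.where(np.isfinite(dT.to_numpy()), flags, "gap")
    return pd.DataFrame({"J_S": js, "flag": flags}, index=dT.index)


# --------------------------------------------------------------------------
# ring-porous correction hook

_CORRECTIONS: dict = {}


def register_correction(name: str, factory):
    """Register a correction factory: factory(**params) -> callable(J)->J'."""
    _CORRECTIONS[name] = factory


def _identity_factory():
    logger.warning(
        "ring-porous correction 'identity' applied: oak fluxes are uncorrected"
    )
    return lambda j: j


def _power_factory(a: float, b: float):
    return lambda j: a * np.asarray(j, dtype=float) ** b


register_correction("identity", _identity_factory)
register_correction("power", _power_factory)


def apply_ring_porous_correction(js, name: str = "identity", **params):
    """Apply a registered element-wise sap-flux correction by name."""
    if name not in _CORRECTIONS:
        raise ConfigurationError(
            f"unknown correction {name!r}; registered: {sorted(_CORRECTIONS)}"
        )
    fn = _CORRECTIONS[name](**params)
    if isinstance(js, pd.Series):
        return pd.Series(fn(js.to_numpy()), index=js.index, name=js.name)
    return fn(js)


# --------------------------------------------------------------------------
# radial integration and transpiration scaling


def radial_integrate(
    outer: pd.Series, inner: pd.Series | None, geom: TreeGeometry
) -> pd.Series:
    """Sapwood-area-weighted mean flux across sensor depths.

    Single-sensor trees pass through. With an inner sensor, sapwood deeper
    than the inner annulus carries the inner rate (geom.deep_sapwood =
    'inner') or zero ('zero'); the denominator is always the whole
    sapwood area.
    """
    if inner is None:
        return outer
    a_outer, a_rest = geom.annulus_areas()
    if geom.deep_sapwood == "inner":
        j = (outer * a_outer + inner * a_rest) / (a_outer + a_rest)
    else:
        # inner sensor represents only the 2-4 cm annulus; deeper sapwood at 0
        d = geom.sapwood_depth_cm()
        r = geom.dbh_cm / 2.0
        d_in = min(4.0, d)
        a_in = math.pi * ((r - 2.0) ** 2 - (r - d_in) ** 2) / 1e4 if d > 2.0 else 0.0
        j = (outer * a_outer + inner * a_in) / geom.sapwood_area_m2
    return j.rename("J_eff")


def transpiration(
    j_eff: pd.Series, geom: TreeGeometry, gap_threshold: float = 0.2
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scale flux density to tree and leaf-specific transpiration.

    Per step: E_C = J·A_S·Δt (kg per step), E_L = J·A_S/leaf_area
    (kg m-2 leaf s-1). Daily sums run over calendar days; days whose gap
    fraction exceeds ``gap_threshold`` are flagged.
    """
    step = _step_seconds(j_eff.index)
    e_c = j_eff * geom.sapwood_area_m2 * step
    e_l = j_eff * geom.sapwood_area_m2 / geom.leaf_area_m2
    steps = pd.DataFrame({"J_eff": j_eff, "E_C": e_c, "E_L": e_l})

    by_day = steps.groupby(steps.index.normalize())
    daily = pd.DataFrame(
        {
            "E_C_daily": by_day["E_C"].sum(),
            "E_L_daily": by_day["E_L"].sum() * step,
            "gap_fraction": by_day["J_eff"].apply(lambda s: s.isna().mean()),
            "n_steps": by_day["J_eff"].size(),
        }
    )
    daily["gap_flag"] = daily["gap_fraction"] > gap_threshold
    return steps, daily
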