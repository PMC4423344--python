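"""Forward simulation of every input the analysis consumes.

Each generator starts from a known "true" physiology so that every
downstream stage can be verified by parameter recovery — exactly at zero
noise, statistically with noise. The met template is deliberately simple:
sinusoidal temperature and light with relative humidity anti-phased to
temperature, which spans the VPD range (~0.05–3 kPa) the sensitivity
analyses need; soil moisture follows pulse recharge on random rain events
with exponential drawdown between them. At least one calm, near-saturated
night per simulated week guarantees detectable zero-flow baselines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .canopy import conductance_coefficient, molar_volume
from .errors import ConvergenceError, InvalidConfigError, InvalidGeometryError
from .gas_exchange import (
    GasExchangeRecord,
    fvcb_model,
    kinetic_constants,
    light_curve_model,
    temperature_factor,
)
from .micromet import saturation_vapor_pressure, vapor_pressure_deficit
from .sap_flow import GRANIER_COEF, GRANIER_EXP, TreeGeometry, oak_sapwood_area


@dataclass
class TruePhysiology:
    """Generating values for every quantity the pipeline estimates."""

    # FvCB parameters at 25 °C, µmol m-2 s-1
    Vcmax25: float = 60.0
    Jmax25: float = 110.0
    TPU25: float = 8.0
    Rday25: float = 1.0
    # light-response parameters
    Amax: float = 16.0  # µmol m-2 s-1
    phi: float = 0.05  # µmol CO2 per µmol photons
    theta: float = 0.7  # curvature, unitless
    Rd_dark: float = 1.2  # µmol m-2 s-1
    # Ball–Berry
    bb_slope: float = 8.0  # unitless
    g0: float = 0.01  # mol m-2 s-1
    # canopy conductance response
    GSref: float = 0.12  # mol m-2 s-1 at VPD = 1 kPa
    sens_ratio: float = 0.6  # (-dGS/dlnVPD)/GSref
    # leaf composition
    Delta_true: float = 19.1  # permil
    LMA: float = 100.4  # g m-2
    N_pct: float = 2.16
    C_pct: float = 48.0

    def __post_init__(self):
        rates = (self.Vcmax25, self.Jmax25, self.TPU25, self.Rday25,
                 self.Amax, self.phi, self.Rd_dark, self.g0, self.GSref)
        if any(r < 0 for r in rates):
            raise InvalidConfigError("all physiological rates must be >= 0")
        if not 0 < self.theta <= 1:
            raise InvalidConfigError("theta must lie in (0, 1]")
        if self.sens_ratio < 0:
            raise InvalidConfigError("sens_ratio must be >= 0")
        if not 4.4 <= self.Delta_true <= 27.0:
            raise InvalidConfigError("Delta_true must lie in [4.4, 27] permil")


@dataclass
class SyntheticConfig:
    """Shape, diurnal template and noise of the simulated met series."""

    n_days: int = 60
    timestep: int = 1800  # s
    start: str = "2012-06-01"
    t_mean: float = 24.0  # °C, seasonal mean
    t_amp: float = 6.0  # °C, diurnal half-range
    t_day_sd: float = 3.0  # °C, day-to-day anomaly
    rh_min: float = 40.0  # % at the afternoon peak of a clear day
    rh_max: float = 95.0  # % pre-dawn
    ppfd_peak: float = 1800.0  # µmol m-2 s-1, clear-sky noon
    rain_rate: float = 0.12  # events per day
    rain_mm_mean: float = 6.0  # mm per event
    drawdown: float = 0.08  # d-1 soil-moisture decay constant
    theta_fc: float = 0.12  # m3 m-3, field capacity (recharge target)
    theta0: float = 0.10  # m3 m-3 initial
    noise_sd: dict = field(
        default_factory=lambda: {"T": 0.2, "RH": 1.0, "PPFD": 20.0, "theta": 0.0}
    )

    def __post_init__(self):
        if self.n_days < 1:
            raise InvalidConfigError("n_days must be >= 1")
        if self.timestep <= 0 or 86400 % self.timestep != 0:
            raise InvalidConfigError("timestep must divide 86400")
        if any(v < 0 for v in self.noise_sd.values()):
            raise InvalidConfigError("noise standard deviations must be >= 0")


def generate_met_series(cfg: SyntheticConfig, seed: int) -> pd.DataFrame:
    """Half-hourly met/edaphic table: T_air, RH, VPD, PPFD, theta, throughfall.

    VPD is computed from the (noisy) T and RH via Goff–Gratch, so the
    saturation identity VPD = e_s(T)·(1−RH/100) holds exactly in the
    output. One night per week is forced to saturation (RH = 100%) for
    three hours so zero-flow baseline detection always has material.
    """
    rng = np.random.default_rng(seed)
    spd = 86400 // cfg.timestep
    n = cfg.n_days * spd
    index = pd.date_range(cfg.start, periods=n, freq=f"{cfg.timestep}s")
    hour = (index.hour + index.minute / 60.0).to_numpy()
    day = np.repeat(np.arange(cfg.n_days), spd)

    t_anom = rng.normal(0.0, cfg.t_day_sd, cfg.n_days)
    cloud = rng.uniform(0.55, 1.0, cfg.n_days)  # clear-sky fraction per day

    diel = np.cos(2.0 * math.pi * (hour - 14.0) / 24.0)
    t_air = cfg.t_mean + t_anom[day] + cfg.t_amp * diel
    rh_mid = 0.5 * (cfg.rh_min + cfg.rh_max)
    rh_half = 0.5 * (cfg.rh_max - cfg.rh_min)
    rh = rh_mid - rh_half * diel + 10.0 * (1.0 - cloud[day])

    t_air = t_air + rng.normal(0.0, cfg.noise_sd.get("T", 0.0), n)
    rh = rh + rng.normal(0.0, cfg.noise_sd.get("RH", 0.0), n)
    rh = np.clip(rh, 5.0, 100.0)

    # one saturated calm night per week, 00:00-03:00
    for week_start in range(0, cfg.n_days, 7):
        calm_day = week_start + int(rng.integers(0, min(7, cfg.n_days - week_start)))
        rh[(day == calm_day) & (hour < 3.0)] = 100.0

    vpd = vapor_pressure_deficit(t_air, rh)

    sun = np.clip(np.sin(math.pi * (hour - 6.0) / 12.0), 0.0, None)
    ppfd = cfg.ppfd_peak * cloud[day] * sun
    ppfd_noise = rng.normal(0.0, cfg.noise_sd.get("PPFD", 0.0), n)
    ppfd = np.where(sun > 0, np.clip(ppfd + ppfd_noise, 0.0, None), 0.0)

    # rain events: Bernoulli per day, recharge to field capacity at noon
    rain_day = rng.random(cfg.n_days) < cfg.rain_rate
    rain_amount = rng.exponential(cfg.rain_mm_mean, cfg.n_days) * rain_day
    theta = np.empty(n)
    tf = np.zeros(n)
    decay = math.exp(-cfg.drawdown * cfg.timestep / 86400.0)
    th = cfg.theta0
    for i in range(n):
        th *= decay
        if rain_day[day[i]] and hour[i] == 12.0:
            th = cfg.theta_fc
            tf[i] = rain_amount[day[i]]
        theta[i] = th
    theta = theta + rng.normal(0.0, cfg.noise_sd.get("theta", 0.0), n)

    return pd.DataFrame(
        {
            "T_air": t_air,
            "RH": rh,
            "VPD": vpd,
            "PPFD": ppfd,
            "theta": np.clip(theta, 0.0, None),
            "throughfall": tf,
        },
        index=index,
    ).rename_axis("timestamp")


def generate_sapflow_signals(
    met: pd.DataFrame,
    tree: TreeGeometry,
    phys: TruePhysiology,
    noise_sd: float = 0.01,
    seed: int = 0,
    dtmax: float = 10.0,
) -> pd.DataFrame:
    """Thermal-dissipation ΔT series consistent with a known G_S response.

    True conductance follows GS(t) = max(0, GSref·(1 − r·lnVPD(t))) during
    daytime (PPFD > 0) and zero at night; E_L and J_S follow the canopy
    inversion run forwards; ΔT inverts the Granier equation around the
    configured ΔT_max. Gaussian noise is added to ΔT. The returned table
    keeps the generating truth in ``true_*`` columns (the observation is
    the ``dT`` column alone).
    """
    if tree.sapwood_area_m2 <= 0:
        raise InvalidGeometryError("tree has zero sapwood area")
    rng = np.random.default_rng(seed)
    vpd = met["VPD"].to_numpy()
    t_air = met["T_air"].to_numpy()
    daytime = met["PPFD"].to_numpy() > 0

    gs_mol = np.zeros(len(met))
    ok = daytime & (vpd > 0)
    gs_mol[ok] = np.maximum(
        0.0, phys.GSref * (1.0 - phys.sens_ratio * np.log(vpd[ok]))
    )
    gs_ms = gs_mol * molar_volume(t_air)
    e_l = np.where(ok, gs_ms * vpd / conductance_coefficient(t_air), 0.0)
    j_s = e_l * tree.leaf_area_m2 / tree.sapwood_area_m2
    dt_clean = dtmax / (1.0 + (j_s / GRANIER_COEF) ** (1.0 / GRANIER_EXP))
    dt = dt_clean + rng.normal(0.0, noise_sd, len(met))

    return pd.DataFrame(
        {
            "dT": dt,
            "true_dT": dt_clean,
            "true_J_S": j_s,
            "true_E_L": e_l,
            "true_GS_mol": gs_mol,
        },
        index=met.index,
    )


def generate_light_curve(
    phys: TruePhysiology,
    q_levels=None,
    noise_sd: float = 0.0,
    seed: int = 0,
    t_leaf: float = 25.0,
    rh_s: float = 0.425,
) -> list[GasExchangeRecord]:
    """Light-response observations from the non-rectangular hyperbola.

    Chamber CO2 fixed at 400 µmol mol-1; stomatal state filled in from the
    Ball–Berry model so the records carry plausible gs, Ci and E.
    """
    if q_levels is None:
        q_levels = [1500, 1200, 1000, 800, 600, 400, 200, 100, 50, 0]
    if len(q_levels) == 0:
        raise InvalidConfigError("q_levels must not be empty")
    rng = np.random.default_rng(seed)
    ca = 400.0
    gamma = 50.0
    vpd_chamber = saturation_vapor_pressure(t_leaf) * (1.0 - rh_s)
    records = []
    for q in q_levels:
        a = float(
            light_curve_model(q, phys.Amax, phys.phi, phys.Rd_dark, phys.theta)
        ) + rng.normal(0.0, noise_sd)
        gs = max(phys.g0, phys.bb_slope * a * rh_s / (ca - gamma) + phys.g0)
        ci = ca - 1.6 * a / gs if gs > 0 else ca
        e = gs * vpd_chamber / 101.325 * 1000.0  # mmol m-2 s-1
        records.append(
            GasExchangeRecord(
                Q=float(q), Ca=ca, Ci=float(ci), A=a, E=float(e),
                gs=float(gs), T_leaf=t_leaf, rh_s=rh_s, Cs=ca,
            )
        )
    return records


def _solve_aci_step(cs, rh_s, gamma_bb, vc_t, j_t, tpu_t, rd_t, kin, phys, max_iter):
    """Self-consistent (A, gs, Ci) at one chamber CO2 step.

    Balances biochemical demand A(Ci) against supply gs·(Cs−Ci)/1.6 with
    gs from the Ball–Berry relation (clamped below at g0).
    """

    def demand(ci):
        return float(
            fvcb_model(vc_t, j_t, tpu_t, rd_t,
                       kin["gamma_star"], kin["Kc"], kin["Ko"], kin["O"], ci)
        )

    def gs_of(a):
        return max(phys.g0, phys.bb_slope * a * rh_s / (cs - gamma_bb) + phys.g0)

    def residual(ci):
        a = demand(ci)
        return gs_of(a) * (cs - ci) / 1.6 - a

    lo, hi = 1e-3, 5000.0
    if residual(lo) * residual(hi) > 0:
        raise ConvergenceError(f"no self-consistent Ci at Ca = {cs}")
    try:
        ci = optimize.brentq(residual, lo, hi, xtol=1e-10, maxiter=max_iter)
    except RuntimeError as err:  # pragma: no cover - brentq budget exhausted
        raise ConvergenceError(str(err)) from err
    a = demand(ci)
    return a, gs_of(a), ci


def generate_aci_curve(
    phys: TruePhysiology,
    ca_steps=None,
    leaf_T: float = 25.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    rh_s: float = 0.425,
    max_iter: int = 200,
) -> list[GasExchangeRecord]:
    """A/Ci observations from the FvCB forward model at leaf temperature.

    Parameters are scaled from 25 °C to ``leaf_T`` with the same Arrhenius
    functions the fitting uses; Ci is iterated to diffusion/biochemistry
    self-consistency through the Ball–Berry stomatal model; Gaussian noise
    is added to A only.
    """
    if ca_steps is None:
        ca_steps = [400, 300, 200, 100, 50, 400, 600, 800, 1000, 1200, 1600, 2000]
    if len(ca_steps) == 0:
        raise InvalidConfigError("ca_steps must not be empty")
    if phys.bb_slope == 0 and phys.g0 == 0:
        raise InvalidConfigError("bb_slope and g0 both zero: gs would be zero")
    rng = np.random.default_rng(seed)
    kin = kinetic_constants(leaf_T)
    vc_t = phys.Vcmax25 * temperature_factor("Vcmax", leaf_T)
    j_t = phys.Jmax25 * temperature_factor("J", leaf_T)
    tpu_t = phys.TPU25 * temperature_factor("TPU", leaf_T)
    rd_t = phys.Rday25 * temperature_factor("Rday", leaf_T)
    gamma_bb = kin["gamma_star"]
    vpd_chamber = saturation_vapor_pressure(leaf_T) * (1.0 - rh_s)

    records = []
    for ca in ca_steps:
        a, gs, ci = _solve_aci_step(
            float(ca), rh_s, gamma_bb, vc_t, j_t, tpu_t, rd_t, kin, phys, max_iter
        )
        e = gs * vpd_chamber / 101.325 * 1000.0
        records.append(
            GasExchangeRecord(
                Q=1500.0, Ca=float(ca), Ci=float(ci),
                A=a + rng.normal(0.0, noise_sd), E=float(e), gs=float(gs),
                T_leaf=leaf_T, rh_s=rh_s, Cs=float(ca),
            )
        )
    return records


def generate_leaf_traits(
    phys: TruePhysiology,
    delta_air: float = -11.4,
    n_leaves: int = 20,
    noise_sd: float = 0.0,
    seed: int = 0,
    trait_cv: float = 0.05,
) -> pd.DataFrame:
    """Per-leaf trait table with δ13C solved from the target discrimination.

    δ13C_leaf inverts Δ = (δa − δl)/(1000 + δl)·1000 so the noiseless
    round trip through compute_discrimination is exact; LMA and N% vary
    around the generating values with coefficient of variation
    ``trait_cv``; A_sat is the light-response model at saturating light.
    """
    if not 0.0 <= phys.Delta_true < 1000.0:
        raise InvalidConfigError("Delta_true must lie in [0, 1000)")
    rng = np.random.default_rng(seed)
    delta = phys.Delta_true + rng.normal(0.0, noise_sd, n_leaves)
    delta_leaf = 1000.0 * (delta_air - delta) / (1000.0 + delta)
    lma = phys.LMA * (1.0 + trait_cv * rng.standard_normal(n_leaves))
    n_pct = phys.N_pct * (1.0 + trait_cv * rng.standard_normal(n_leaves))
    a_sat = float(
        light_curve_model(1500.0, phys.Amax, phys.phi, phys.Rd_dark, phys.theta)
    )
    return pd.DataFrame(
        {
            "leaf_id": [f"leaf{i:03d}" for i in range(n_leaves)],
            "delta13C_leaf": delta_leaf,
            "delta13C_air": delta_air,
            "C_pct": phys.C_pct,
            "N_pct": n_pct,
            "LMA": lma,
            "A_sat": a_sat,
        }
    )


def generate_tree_geometry(
    n_trees: int = 3,
    species: str = "oak",
    seed: int = 0,
    leaf_to_sapwood: float = 2000.0,
) -> list[TreeGeometry]:
    """Synthetic per-tree geometry with the oak DBH–sapwood allometry."""
    rng = np.random.default_rng(seed)
    trees = []
    for i in range(n_trees):
        dbh = float(rng.uniform(25.0, 40.0))
        a_s = float(oak_sapwood_area(dbh))
        trees.append(
            TreeGeometry(
                tree_id=f"{species}{i:02d}",
                species=species,
                dbh_cm=dbh,
                sapwood_area_m2=a_s,
                leaf_area_m2=a_s * leaf_to_sapwood,
                sensor_depths=("single",),
            )
        )
    return trees
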