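"""Leaf gas-exchange curve fitting and instantaneous efficiency indices.

Covers the three leaf-level models used throughout the analysis:

* light-response curves — non-rectangular hyperbola (Prioul–Chartier form)
  with an exponential fallback, yielding A_max, quantum yield φ, curvature
  θ, dark respiration R_d and the light compensation point;
* A/Ci curves — the Farquhar–von Caemmerer–Berry (FvCB) biochemical model
  with Rubisco-, RuBP-regeneration- and TPU-limited regimes, fitted by an
  exhaustive search over ordered limitation partitions and reported
  normalized to 25 °C;
* the Ball–Berry stomatal model gs = m·A·rh_s/(Cs − Γ) + g0, with Γ taken
  from the x-intercept of the initial linear portion of the A/Ci curve.

Temperature scaling of FvCB parameters and kinetic constants uses the
Arrhenius exp(c − ΔHa/(R·T_K)) parameterisation of Sharkey et al. (2007),
with partial-pressure constants converted to mole fractions at standard
pressure. The constants are module-level and overridable per call.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import (
    DegenerateCurveError,
    FitFailureError,
    InsufficientDataError,
    InsufficientVariationError,
    InvalidParameterError,
    SingularityError,
    UndefinedIndexError,
)

R_GAS = 8.314  # J mol-1 K-1
T25_K = 298.15
STANDARD_PRESSURE_KPA = 101.325

# Arrhenius scaling constants: parameter(T) = exp(c - dHa/(R*T_K)).
# (c, dHa in J mol-1); kinetic constants in partial-pressure form:
# gamma_star and Kc in Pa, Ko in kPa.
SHARKEY_CONSTANTS = {
    "gamma_star": (11.187, 24.46e3),
    "Kc": (35.9774, 80.99e3),
    "Ko": (12.3772, 23.72e3),
    "Vcmax": (26.355, 65.33e3),
    "J": (17.71, 43.9e3),
    "TPU": (21.46, 53.1e3),
    "Rday": (18.7145, 46.39e3),
}

#: Oxygen mole fraction (µmol mol-1) at 21 kPa partial pressure, standard P.
O2_MOLE_FRACTION = 21.0 / STANDARD_PRESSURE_KPA * 1e6


@dataclass
class GasExchangeRecord:
    """One chamber observation from an infra-red gas analyzer.

    Units: Q µmol photons m-2 s-1; Ca, Ci, Cs µmol mol-1; A µmol CO2
    m-2 s-1; E mmol H2O m-2 s-1; gs mol H2O m-2 s-1; T_leaf °C; rh_s is a
    0–1 fraction at the leaf surface.
    """

    Q: float
    Ca: float
    Ci: float
    A: float
    E: float
    gs: float
    T_leaf: float
    rh_s: float
    Cs: float

    def __post_init__(self):
        if self.Q < 0:
            raise InvalidParameterError(f"Q must be >= 0, got {self.Q}")
        if self.Ca <= 0 or self.Cs <= 0:
            raise InvalidParameterError("Ca and Cs must be positive")
        if self.gs < 0:
            raise InvalidParameterError("gs must be >= 0")
        if not 0.0 <= self.rh_s <= 1.0:
            raise InvalidParameterError("rh_s must lie in [0, 1]")


@dataclass
class LightResponseFit:
    Amax: float
    phi: float
    theta: float | None  # None for the exponential form
    Rd: float
    LCP: float
    form: str  # "nrh" | "exponential"
    rss: float
    n: int


@dataclass
class FvCBFit:
    Vcmax25: float
    Jmax25: float
    TPU25: float | None  # None when no point is TPU-limited
    Rday25: float
    gamma_star: float  # at the measurement temperature, µmol mol-1
    limitation: list  # per-point labels, Ci-sorted order of the input
    T_leaf: float
    rss: float
    n: int
    at_bound: bool = False


@dataclass
class BallBerryFit:
    m: float
    g0: float
    gamma: float
    r2: float
    n: int
    excluded: int = 0


# --------------------------------------------------------------------------
# temperature scaling


def arrhenius_value(name: str, t_leaf_c: float, constants: dict | None = None) -> float:
    """Evaluate exp(c − ΔHa/(R·T_K)) for a named constant, native units."""
    c, dha = (constants or SHARKEY_CONSTANTS)[name]
    return math.exp(c - dha / (R_GAS * (t_leaf_c + 273.15)))


def temperature_factor(name: str, t_leaf_c: float, constants: dict | None = None) -> float:
    """Ratio parameter(T)/parameter(25 °C) under the Arrhenius scaling."""
    c, dha = (constants or SHARKEY_CONSTANTS)[name]
    return math.exp(dha / R_GAS * (1.0 / T25_K - 1.0 / (t_leaf_c + 273.15)))


def kinetic_constants(t_leaf_c: float, constants: dict | None = None) -> dict:
    """FvCB kinetic constants at leaf temperature, mole-fraction units.

    Returns gamma_star and Kc in µmol mol-1, Ko in mmol mol-1, O in
    mmol mol-1, converted from partial pressures at standard pressure.
    """
    gamma_star_pa = arrhenius_value("gamma_star", t_leaf_c, constants)
    kc_pa = arrhenius_value("Kc", t_leaf_c, constants)
    ko_kpa = arrhenius_value("Ko", t_leaf_c, constants)
    to_umol = 1e6 / (STANDARD_PRESSURE_KPA * 1e3)  # Pa -> µmol mol-1
    return {
        "gamma_star": gamma_star_pa * to_umol,
        "Kc": kc_pa * to_umol,
        "Ko": ko_kpa / STANDARD_PRESSURE_KPA * 1e3,  # kPa -> mmol mol-1
        "O": O2_MOLE_FRACTION / 1e3,  # mmol mol-1
    }


# --------------------------------------------------------------------------
# forward models


def light_curve_model(Q, Amax, phi, Rd, theta=None, form="nrh"):
    """Net assimilation A(Q) for either light-response form.

    nrh:         A = [φQ + Amax − sqrt((φQ+Amax)² − 4θφQ·Amax)]/(2θ) − Rd
    exponential: A = Amax·(1 − exp(−φQ/Amax)) − Rd
    """
    Q = np.asarray(Q, dtype=float)
    if form == "nrh":
        if theta is None or theta <= 0:
            raise InvalidParameterError("nrh form requires curvature theta > 0")
        s = phi * Q + Amax
        disc = np.maximum(s * s - 4.0 * theta * phi * Q * Amax, 0.0)
        a_gross = (s - np.sqrt(disc)) / (2.0 * theta)
        return a_gross - Rd
    if form == "exponential":
        return Amax * (1.0 - np.exp(-phi * Q / Amax)) - Rd
    raise InvalidParameterError(f"unknown light-response form {form!r}")


def fvcb_model(Vcmax, J, TPU, Rday, gamma_star, Kc, Ko, O, Ci):
    """FvCB net assimilation A = min(Ac, Aj, Ap) at the given Ci.

    Ac = Vcmax·(Ci−Γ*)/(Ci + Kc·(1+O/Ko)) − Rday
    Aj = J·(Ci−Γ*)/(4Ci + 8Γ*) − Rday
    Ap = 3·TPU − Rday                    (TPU=None disables this regime)

    Units must be mutually consistent; ``kinetic_constants`` supplies the
    mole-fraction set used throughout the package.
    """
    Ci = np.asarray(Ci, dtype=float)
    km = Kc * (1.0 + O / Ko)
    denom_c = Ci + km
    if np.any(denom_c == 0):
        raise SingularityError("Ci + Km = 0")
    ac = Vcmax * (Ci - gamma_star) / denom_c - Rday
    aj = J * (Ci - gamma_star) / (4.0 * Ci + 8.0 * gamma_star) - Rday
    a = np.minimum(ac, aj)
    if TPU is not None and np.isfinite(TPU):
        a = np.minimum(a, 3.0 * TPU - Rday)
    return a


# --------------------------------------------------------------------------
# light-response fitting


def _exponential_lcp(Amax, phi, Rd):
    if Rd <= 0:
        return 0.0
    if Rd >= Amax:
        return math.inf
    return -(Amax / phi) * math.log(1.0 - Rd / Amax)


def _nrh_lcp(Amax, phi, theta, Rd):
    if Rd <= 0:
        return 0.0
    f = lambda q: light_curve_model(q, Amax, phi, Rd, theta, form="nrh")
    hi = 10.0
    while f(hi) < 0 and hi < 1e8:
        hi *= 10.0
    if f(hi) < 0:
        return math.inf
    return optimize.brentq(f, 0.0, hi, xtol=1e-12, rtol=1e-14)


def fit_light_response(curve: list[GasExchangeRecord]) -> LightResponseFit:
    """Fit a light-response curve; NRH first, exponential fallback.

    The NRH fit is accepted when it converges with θ in (0, 1] and its
    residual sum of squares does not exceed the exponential fit's;
    otherwise the exponential form is reported. The light compensation
    point is solved for the accepted form.
    """
    q = np.array([r.Q for r in curve], dtype=float)
    a = np.array([r.A for r in curve], dtype=float)
    if len(np.unique(q)) < 5:
        raise InsufficientDataError(
            f"need >= 5 distinct light levels, got {len(np.unique(q))}"
        )
    if q.min() > 50:
        raise InsufficientDataError("curve must include a dark or near-dark point (Q <= 50)")

    rd0 = max(0.0, -a[q == q.min()].mean())
    amax0 = max(a.max() + rd0, 1e-3)
    order = np.argsort(q)
    q_s, a_s = q[order], a[order]
    dq = q_s[1] - q_s[0]
    phi0 = (a_s[1] - a_s[0]) / dq if dq > 0 else 0.05
    phi0 = min(max(phi0, 1e-4), 0.5)

    def residual_nrh(p):
        amax, phi, theta, rd = p
        return light_curve_model(q, amax, phi, rd, theta, form="nrh") - a

    def residual_exp(p):
        amax, phi, rd = p
        return light_curve_model(q, amax, phi, rd, form="exponential") - a

    tol = dict(xtol=1e-15, ftol=1e-15, gtol=1e-15)
    nrh_res = None
    try:
        nrh_res = optimize.least_squares(
            residual_nrh,
            x0=[amax0, phi0, 0.7, rd0],
            bounds=([1e-9, 1e-9, 1e-9, 0.0], [np.inf, 2.0, 1.0, np.inf]),
            **tol,
        )
    except Exception:
        pass
    exp_res = None
    try:
        exp_res = optimize.least_squares(
            residual_exp,
            x0=[amax0, phi0, rd0],
            bounds=([1e-9, 1e-9, 0.0], [np.inf, 2.0, np.inf]),
            **tol,
        )
    except Exception:
        pass

    rss_nrh = float(np.sum(nrh_res.fun**2)) if nrh_res is not None and nrh_res.success else math.inf
    rss_exp = float(np.sum(exp_res.fun**2)) if exp_res is not None and exp_res.success else math.inf

    nrh_ok = (
        nrh_res is not None
        and nrh_res.success
        and 0.0 < nrh_res.x[2] <= 1.0
        and rss_nrh <= rss_exp
    )
    if nrh_ok:
        amax, phi, theta, rd = nrh_res.x
        return LightResponseFit(
            Amax=float(amax), phi=float(phi), theta=float(theta), Rd=float(rd),
            LCP=float(_nrh_lcp(amax, phi, theta, rd)), form="nrh",
            rss=rss_nrh, n=len(curve),
        )
    if exp_res is not None and exp_res.success:
        amax, phi, rd = exp_res.x
        return LightResponseFit(
            Amax=float(amax), phi=float(phi), theta=None, Rd=float(rd),
            LCP=float(_exponential_lcp(amax, phi, rd)), form="exponential",
            rss=rss_exp, n=len(curve),
        )
    raise FitFailureError(
        "neither light-response form converged",
        diagnostics={"nrh": nrh_res, "exponential": exp_res},
    )


# --------------------------------------------------------------------------
# A/Ci fitting


def _partition_design(ci, a, labels, kin):
    """Linear design for (Vcmax, J, TPU, Rday) given fixed limitation labels.

    Within each regime A is linear in the regime's capacity parameter and
    in −Rday, so the partitioned fit is a bounded linear least-squares
    problem.
    """
    km = kin["Kc"] * (1.0 + kin["O"] / kin["Ko"])
    gs = kin["gamma_star"]
    n = len(ci)
    has_tpu = "tpu" in labels
    ncol = 4 if has_tpu else 3
    X = np.zeros((n, ncol))
    for k, (c, lab) in enumerate(zip(ci, labels)):
        if lab == "rubisco":
            X[k, 0] = (c - gs) / (c + km)
        elif lab == "rubp":
            X[k, 1] = (c - gs) / (4.0 * c + 8.0 * gs)
        else:
            X[k, 2] = 3.0
        X[k, -1] = -1.0
    return X


def fit_aci(curve: list[GasExchangeRecord], constants: dict | None = None) -> FvCBFit:
    """Fit the FvCB model to an A/Ci curve by exhaustive partition search.

    Admissible partitions order the regimes along Ci — Rubisco-limited at
    low Ci, then RuBP-regeneration-limited, then an optional TPU-limited
    tail — with at least two points in each of the first two regimes. Each
    partition yields a bounded linear least-squares problem in
    (Vcmax, J, TPU, Rday); the minimum-RSS partition wins and ties break
    toward fewer TPU-limited points. Parameters are reported at 25 °C via
    the Arrhenius scaling; points are labeled in Ci-sorted order.
    """
    if len(curve) < 6:
        raise InsufficientDataError("need >= 6 A/Ci points")
    ci_raw = np.array([r.Ci for r in curve], dtype=float)
    if ci_raw.min() >= 200 or ci_raw.max() <= 500:
        raise InsufficientDataError(
            "A/Ci curve must span Ci below 200 and above 500 µmol mol-1"
        )
    order = np.argsort(ci_raw)
    ci = ci_raw[order]
    a = np.array([r.A for r in curve], dtype=float)[order]
    t_leaf = float(np.mean([r.T_leaf for r in curve]))
    kin = kinetic_constants(t_leaf, constants)

    n = len(ci)
    best = None  # (rss, n_tpu, labels, params, at_bound)
    for i in range(2, n - 1):  # rubisco points: [0, i)
        for j in range(i + 2, n + 1):  # rubp: [i, j); tpu: [j, n)
            labels = ["rubisco"] * i + ["rubp"] * (j - i) + ["tpu"] * (n - j)
            X = _partition_design(ci, a, labels, kin)
            res = optimize.lsq_linear(X, a, bounds=(0.0, np.inf), tol=1e-14)
            rss = float(np.sum(res.fun**2))
            n_tpu = n - j
            at_bound = bool(np.any(np.abs(res.x[:-1]) < 1e-12))
            cand = (rss, n_tpu, labels, res.x, at_bound)
            if best is None or rss < best[0] - 1e-12 or (
                abs(rss - best[0]) <= 1e-12 * max(1.0, best[0]) and n_tpu < best[1]
            ):
                best = cand

    rss, n_tpu, labels, params, at_bound = best
    if n_tpu > 0:
        vcmax_t, j_t, tpu_t, rday_t = params
    else:
        vcmax_t, j_t, rday_t = params
        tpu_t = None

    fit = FvCBFit(
        Vcmax25=float(vcmax_t / temperature_factor("Vcmax", t_leaf, constants)),
        Jmax25=float(j_t / temperature_factor("J", t_leaf, constants)),
        TPU25=(
            float(tpu_t / temperature_factor("TPU", t_leaf, constants))
            if tpu_t is not None
            else None
        ),
        Rday25=float(rday_t / temperature_factor("Rday", t_leaf, constants)),
        gamma_star=kin["gamma_star"],
        limitation=labels,
        T_leaf=t_leaf,
        rss=rss,
        n=n,
        at_bound=at_bound,
    )
    if at_bound:
        warnings.warn("A/Ci fit has a parameter at its lower bound", stacklevel=2)
    return fit


def estimate_gamma(
    curve: list[GasExchangeRecord], ci_max: float = 150.0, min_points: int = 3
) -> float:
    """CO2 compensation point Γ: x-intercept of the initial A/Ci slope.

    Ordinary least squares through the points with Ci <= ``ci_max``;
    Γ = −intercept/slope. A non-positive slope means the curve has no
    rising initial portion and is rejected.
    """
    ci = np.array([r.Ci for r in curve], dtype=float)
    a = np.array([r.A for r in curve], dtype=float)
    mask = ci <= ci_max
    if mask.sum() < min_points:
        raise InsufficientDataError(
            f"need >= {min_points} points with Ci <= {ci_max}, got {int(mask.sum())}"
        )
    x, y = ci[mask], a[mask]
    slope, intercept = np.polyfit(x, y, 1)
    if slope <= 0:
        raise DegenerateCurveError("initial A/Ci slope is not positive")
    return float(-intercept / slope)


def fit_ball_berry(points: list[GasExchangeRecord], gamma: float) -> BallBerryFit:
    """Ball–Berry slope and intercept: gs = m·(A·rh_s/(Cs − Γ)) + g0.

    Points with Cs <= Γ are excluded with a warning; ordinary least
    squares of gs on the Ball–Berry index gives slope m and intercept g0.
    """
    usable = [p for p in points if p.Cs > gamma]
    excluded = len(points) - len(usable)
    if excluded:
        warnings.warn(
            f"excluded {excluded} point(s) with Cs <= gamma ({gamma:g})", stacklevel=2
        )
    if len(usable) < 3:
        raise InsufficientDataError("need >= 3 points with Cs > gamma")
    x = np.array([p.A * p.rh_s / (p.Cs - gamma) for p in usable])
    y = np.array([p.gs for p in usable])
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        raise InsufficientVariationError("Ball–Berry index is constant across points")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    m = sxy / sxx
    g0 = float(y.mean() - m * x.mean())
    resid = y - (m * x + g0)
    syy = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / syy if syy > 0 else 1.0
    return BallBerryFit(m=float(m), g0=g0, gamma=float(gamma), r2=r2, n=len(usable),
                        excluded=excluded)


def instantaneous_indices(rec: GasExchangeRecord) -> dict:
    """Instantaneous efficiency indices of one observation.

    WUE_inst = A/E (µmol CO2 per mmol H2O), iWUE_inst = A/gs
    (µmol CO2 per mol H2O), cica_inst = Ci/Ca.
    """
    if rec.E <= 0:
        raise UndefinedIndexError("E")
    if rec.gs <= 0:
        raise UndefinedIndexError("gs")
    if rec.Ca <= 0:
        raise UndefinedIndexError("Ca")
    return {
        "WUE_inst": rec.A / rec.E,
        "iWUE_inst": rec.A / rec.gs,
        "cica_inst": rec.Ci / rec.Ca,
    }
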