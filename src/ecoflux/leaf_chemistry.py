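"""Isotope- and nitrogen-based leaf efficiency indices.

Carbon-isotope discrimination Δ relates leaf δ¹³C to source-air δ¹³C and
carries a time-integrated record of ci/ca; the simple (non-mesophyll)
discrimination model maps Δ linearly onto ci/ca between the diffusive
(4.4‰) and Rubisco (27‰) fractionation end members, and onto intrinsic
water-use efficiency through the 1.6 diffusivity ratio of water vapor to
CO2. Nitrogen indices scale leaf N to area basis via LMA and express
light-saturated assimilation per unit leaf nitrogen (PNUE).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import SingularityError

#: diffusive fractionation through stomata, permil
A_DIFFUSION = 4.4
#: Rubisco carboxylation fractionation, permil
B_RUBISCO = 27.0
#: ratio of H2O to CO2 diffusivity in air
DIFFUSIVITY_RATIO = 1.6


@dataclass
class LeafTraits:
    """Per-leaf composition and the assimilation rate used for PNUE.

    ``A_sat`` is net assimilation at ambient CO2 (~400 µmol mol-1) and
    saturating light; ``None`` when gas exchange was not measured on the
    same leaf.
    """

    delta13C_leaf: float  # permil vs VPDB
    delta13C_air: float  # permil vs VPDB
    C_pct: float
    N_pct: float
    LMA: float  # g m-2
    A_sat: float | None = None  # µmol m-2 s-1
    ca: float = 400.0  # µmol mol-1

    def __post_init__(self):
        if self.LMA <= 0:
            raise ValueError("LMA must be positive")
        if not 0 < self.N_pct < 100:
            raise ValueError("N_pct must lie in (0, 100)")
        if self.ca <= 0:
            raise ValueError("ca must be positive")


def compute_discrimination(delta_leaf, delta_air):
    """Δ (‰) = (δ_air − δ_leaf)/(1000 + δ_leaf) × 1000."""
    delta_leaf = np.asarray(delta_leaf, dtype=float)
    delta_air = np.asarray(delta_air, dtype=float)
    if np.any(delta_leaf <= -1000.0):
        raise SingularityError("delta13C_leaf <= -1000 permil")
    out = (delta_air - delta_leaf) / (1000.0 + delta_leaf) * 1000.0
    return float(out) if out.ndim == 0 else out


def isotope_indices(Delta, ca=400.0):
    """iWUE_iso and integrated ci/ca from discrimination Δ.

    cica_iso = (Δ − 4.4)/(27 − 4.4); iWUE_iso = (ca/1.6)·(27 − Δ)/(27 − 4.4).
    Δ outside [4.4, 27] produces out-of-range indices and a warning.
    """
    Delta = np.asarray(Delta, dtype=float)
    if np.any((Delta < A_DIFFUSION) | (Delta > B_RUBISCO)):
        warnings.warn(
            "discrimination outside [4.4, 27] permil: indices out of range",
            stacklevel=2,
        )
    span = B_RUBISCO - A_DIFFUSION
    cica = (Delta - A_DIFFUSION) / span
    iwue = (ca / DIFFUSIVITY_RATIO) * (B_RUBISCO - Delta) / span
    if cica.ndim == 0:
        return {"iWUE_iso": float(iwue), "cica_iso": float(cica)}
    return {"iWUE_iso": iwue, "cica_iso": cica}


def nitrogen_indices(traits: LeafTraits) -> dict:
    """Area-based nitrogen, PNUE and the C/N ratio of one leaf.

    N_area = LMA·N%/100 (g m-2); PNUE = A_sat/N_area (µmol CO2 g-1 N s-1);
    C/N = C%/N%. PNUE is omitted (with a warning) when A_sat is missing.
    """
    n_area = traits.LMA * traits.N_pct / 100.0
    out = {"N_area": n_area, "CN_ratio": traits.C_pct / traits.N_pct}
    if traits.A_sat is None:
        warnings.warn("A_sat missing: PNUE omitted", stacklevel=2)
    else:
        out["PNUE"] = traits.A_sat / n_area
    return out
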