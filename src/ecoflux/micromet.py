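"""Basic micrometeorological relations: saturation vapor pressure and VPD.

Saturation vapor pressure over liquid water follows the Goff–Gratch (1946)
formulation, the same relation used to derive vapor pressure deficit from
the air-temperature / relative-humidity sensor pairs this package ingests.
"""

from __future__ import annotations

import numpy as np

_T_STEAM = 373.16  # steam-point temperature, K
_E_STEAM_HPA = 1013.246  # saturation pressure at the steam point, hPa


def saturation_vapor_pressure(t_air_c):
    """Saturation vapor pressure over liquid water (kPa) at air temperature (°C).

    Goff–Gratch (1946): log10 e_w is a sum of powers of the steam-point
    temperature ratio. Valid roughly −50…100 °C; vectorized over arrays.
    """
    t_k = np.asarray(t_air_c, dtype=float) + 273.15
    ratio = _T_STEAM / t_k
    log10_ew = (
        -7.90298 * (ratio - 1.0)
        + 5.02808 * np.log10(ratio)
        - 1.3816e-7 * (np.power(10.0, 11.344 * (1.0 - 1.0 / ratio)) - 1.0)
        + 8.1328e-3 * (np.power(10.0, -3.49149 * (ratio - 1.0)) - 1.0)
        + np.log10(_E_STEAM_HPA)
    )
    es_hpa = np.power(10.0, log10_ew)
    return es_hpa * 0.1  # hPa -> kPa


def vapor_pressure_deficit(t_air_c, rh_pct):
    """VPD (kPa) from air temperature (°C) and relative humidity (%).

    VPD = e_s(T) * (1 - RH/100); RH = 100% gives exactly zero.
    """
    rh = np.asarray(rh_pct, dtype=float)
    return saturation_vapor_pressure(t_air_c) * (1.0 - rh / 100.0)
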