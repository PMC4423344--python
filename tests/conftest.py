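import numpy as np
import pytest

from ecoflux.canopy import conductance_series
from ecoflux.sap_flow import detect_baseline, flux_series, transpiration
from ecoflux.sensitivity import fit_vpd_response
from ecoflux.synthetic import (
    SyntheticConfig,
    TruePhysiology,
    generate_met_series,
    generate_sapflow_signals,
    generate_tree_geometry,
)


@pytest.fixture(scope="session")
def phys():
    return TruePhysiology()


@pytest.fixture(scope="session")
def met30():
    """30 simulated days of half-hourly met at the default template."""
    return generate_met_series(SyntheticConfig(n_days=30), seed=42)


@pytest.fixture(scope="session")
def oak_tree():
    return generate_tree_geometry(1, seed=1)[0]


@pytest.fixture(scope="session")
def sensitivity_chain(met30, oak_tree, phys):
    """Full sap-flow -> G_S -> sensitivity chain as a callable.

    Returns fit_vpd_response on the half-hourly qualifying steps for a
    given (noise_sd, seed).
    """

    def run(noise_sd: float, seed: int):
        sig = generate_sapflow_signals(
            met30, oak_tree, phys, noise_sd=noise_sd, seed=seed
        )
        dtmax = detect_baseline(sig["dT"], met30["VPD"])
        fl = flux_series(sig["dT"], dtmax)
        steps, _ = transpiration(fl["J_S"], oak_tree)
        cond = conductance_series(steps["E_L"], met30)
        ok = cond["daytime"] & cond["GS_mol"].notna()
        return fit_vpd_response(cond.loc[ok, "GS_mol"], cond.loc[ok, "VPD"])

    return run


def ols_oracle(x, y):
    """Normal-equations least squares, independent of the package path."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.column_stack([x, np.ones_like(x)])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return beta[0], beta[1]
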