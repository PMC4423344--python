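import math

import numpy as np
import pandas as pd
import pytest

from ecoflux.errors import (
    BaselineFailureError,
    ConfigurationError,
    InvalidSignalError,
)
from ecoflux.sap_flow import (
    TreeGeometry,
    apply_ring_porous_correction,
    detect_baseline,
    flux_series,
    granier_flux,
    oak_sapwood_area,
    pine_leaf_area,
    radial_integrate,
    transpiration,
)
from ecoflux.synthetic import generate_sapflow_signals


def halfhourly(values, start="2012-06-01"):
    idx = pd.date_range(start, periods=len(values), freq="1800s")
    return pd.Series(np.asarray(values, dtype=float), index=idx)


class TestGranierFlux:
    def test_zero_flow_at_baseline(self):
        assert granier_flux(10.0, 10.0) == 0.0

    def test_unit_ratio_point(self):
        # dTmax/dT = 2 makes the bracket 1, so J_S equals the coefficient
        assert granier_flux(5.0, 10.0) == pytest.approx(0.119, rel=1e-12)

    def test_direct_formula_oracle(self):
        expected = 0.119 * (10.0 / 8.0 - 1.0) ** 1.23
        assert granier_flux(8.0, 10.0) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.02163, abs=5e-5)

    def test_strictly_decreasing_in_dT(self):
        dts = np.linspace(0.5, 10.0, 100)
        js = granier_flux(dts, 10.0)
        assert np.all(np.diff(js) <= 0)
        assert np.all(np.diff(js[dts < 10.0][:-1]) < 0)

    def test_nonpositive_dT_raises_and_clamp_flags(self):
        with pytest.raises(InvalidSignalError):
            granier_flux(0.0, 10.0)
        fl = flux_series(halfhourly([11.0, 9.0]), halfhourly([10.0, 10.0]))
        assert fl["flag"].tolist() == ["clamped", "ok"]
        assert fl["J_S"].iloc[0] == 0.0


class TestDetectBaseline:
    def test_constant_calm_night(self):
        vpd = halfhourly([0.01] * 6 + [1.0] * 6)
        dt = halfhourly([10.0] * 6 + [7.0] * 6)
        sched = detect_baseline(dt, vpd)
        assert np.allclose(sched.to_numpy(), 10.0)

    def test_linear_interpolation_between_nights(self):
        # two qualifying nights at dTmax 10 then 12, one day apart; odd-length
        # calm runs put the interpolation nodes on grid timestamps
        n_day = 48
        vpd = np.ones(2 * n_day)
        dt = np.full(2 * n_day, 8.0)
        vpd[0:5] = 0.01
        dt[0:5] = 10.0
        vpd[n_day : n_day + 5] = 0.01
        dt[n_day : n_day + 5] = 12.0
        sched = detect_baseline(halfhourly(dt), halfhourly(vpd))
        node0 = sched.index[2]  # run midpoints
        node1 = sched.index[n_day + 2]
        midpoint = node0 + (node1 - node0) / 2
        assert sched.loc[midpoint] == pytest.approx(11.0, rel=1e-9)

    def test_no_qualifying_window_raises_with_near_misses(self):
        vpd = halfhourly([0.01] * 6 + [1.0] * 6)
        dt = halfhourly([10.0, 9.0, 10.0, 9.0, 10.0, 9.0] + [7.0] * 6)  # unstable
        with pytest.raises(BaselineFailureError) as err:
            detect_baseline(dt, vpd)
        assert err.value.near_misses

    def test_recovers_generator_baseline_at_zero_noise(self, met30, oak_tree, phys):
        sig = generate_sapflow_signals(met30, oak_tree, phys, noise_sd=0.0, seed=5)
        sched = detect_baseline(sig["dT"], met30["VPD"])
        np.testing.assert_allclose(sched.to_numpy(), 10.0, rtol=1e-9)

    def test_roundtrip_flux_recovery_at_zero_noise(self, met30, oak_tree, phys):
        sig = generate_sapflow_signals(met30, oak_tree, phys, noise_sd=0.0, seed=5)
        sched = detect_baseline(sig["dT"], met30["VPD"])
        js = flux_series(sig["dT"], sched)["J_S"]
        np.testing.assert_allclose(
            js.to_numpy(), sig["true_J_S"].to_numpy(), atol=1e-10
        )


class TestCorrections:
    def test_identity_is_bitwise(self):
        js = halfhourly([0.0, 0.05, 0.119])
        out = apply_ring_porous_correction(js, "identity")
        assert (out == js).all()

    def test_power_transform(self):
        assert apply_ring_porous_correction(np.array([0.05]), "power", a=2.0, b=1.0)[
            0
        ] == pytest.approx(0.10)
        out = apply_ring_porous_correction(np.array([0.119]), "power", a=1.5, b=1.1)
        assert out[0] == pytest.approx(1.5 * 0.119**1.1, rel=1e-12)
        assert out[0] == pytest.approx(0.1443, abs=1e-4)

    def test_unknown_name_raises(self):
        with pytest.raises(ConfigurationError):
            apply_ring_porous_correction(np.array([0.1]), "no-such-correction")


class TestRadialIntegrate:
    def geom(self, areas=None):
        return TreeGeometry(
            tree_id="t", species="pine", dbh_cm=35.0, sapwood_area_m2=0.04,
            leaf_area_m2=50.0, sensor_depths=("outer", "inner"),
            annulus_areas_m2=areas,
        )

    def test_uniform_profile_passthrough(self):
        j = halfhourly([0.07, 0.03])
        out = radial_integrate(j, j.copy(), self.geom((0.013, 0.027)))
        np.testing.assert_allclose(out.to_numpy(), j.to_numpy())

    def test_equal_area_mean(self):
        out = radial_integrate(
            halfhourly([0.10]), halfhourly([0.02]), self.geom((0.02, 0.02))
        )
        assert out.iloc[0] == pytest.approx(0.06)

    def test_weighted_mean_hand_computation(self):
        out = radial_integrate(
            halfhourly([0.10]), halfhourly([0.02]), self.geom((0.03, 0.01))
        )
        assert out.iloc[0] == pytest.approx((0.003 + 0.0002) / 0.04, rel=1e-12)

    def test_bounded_by_inputs(self):
        rng = np.random.default_rng(0)
        outer = halfhourly(rng.uniform(0, 0.1, 48))
        inner = halfhourly(rng.uniform(0, 0.1, 48))
        out = radial_integrate(outer, inner, self.geom())
        assert (out <= np.maximum(outer, inner) + 1e-15).all()
        assert (out >= np.minimum(outer, inner) - 1e-15).all()

    def test_single_sensor_passthrough(self):
        j = halfhourly([0.05])
        assert radial_integrate(j, None, self.geom()) is j


class TestAllometry:
    def test_oak_sapwood_asymptote_and_midpoint(self):
        assert oak_sapwood_area(1e6) == pytest.approx(0.0188, rel=1e-9)
        assert oak_sapwood_area(20.97) == pytest.approx(0.0094, rel=1e-3)

    def test_oak_sapwood_direct_evaluation(self):
        expected = 0.0188 / (1 + math.exp(-(40 - 20.97) / 4.791))
        assert oak_sapwood_area(40.0) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.01845, abs=5e-5)

    def test_oak_sapwood_increasing_and_bounded(self):
        dbh = np.linspace(1, 120, 300)
        a = oak_sapwood_area(dbh)
        assert np.all(np.diff(a) > 0)
        assert np.all((a > 0) & (a < 0.0188))

    def test_pine_leaf_area(self):
        assert pine_leaf_area(0.0) == 0.0
        assert pine_leaf_area(math.pi) == pytest.approx(1.0)
        assert pine_leaf_area(144.3) == pytest.approx(45.93, abs=0.005)


class TestTranspiration:
    def tree(self):
        return TreeGeometry(tree_id="t", species="oak", dbh_cm=30.0,
                            sapwood_area_m2=0.01, leaf_area_m2=8.3)

    def test_zero_flux_gives_zero_daily(self):
        j = halfhourly([0.0] * 48)
        _, daily = transpiration(j, self.tree())
        assert daily["E_C_daily"].iloc[0] == 0.0

    def test_constant_flux_arithmetic(self):
        j = halfhourly([1e-4] * 48)
        steps, daily = transpiration(j, self.tree())
        assert daily["E_C_daily"].iloc[0] == pytest.approx(1e-4 * 0.01 * 86400)
        assert daily["E_L_daily"].iloc[0] == pytest.approx(
            1e-4 * 0.01 / 8.3 * 86400, rel=1e-12
        )

    def test_daily_conservation(self):
        rng = np.random.default_rng(3)
        j = halfhourly(rng.uniform(0, 1e-4, 96))
        steps, daily = transpiration(j, self.tree())
        expected = j.groupby(j.index.normalize()).sum() * 0.01 * 1800
        np.testing.assert_allclose(daily["E_C_daily"].to_numpy(), expected.to_numpy())
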