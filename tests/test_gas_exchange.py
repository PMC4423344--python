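import math

import numpy as np
import pytest
from scipy import optimize

from conftest import ols_oracle
from ecoflux.errors import (
    DegenerateCurveError,
    InsufficientDataError,
    InsufficientVariationError,
    InvalidParameterError,
    UndefinedIndexError,
)
from ecoflux.gas_exchange import (
    GasExchangeRecord,
    estimate_gamma,
    fit_aci,
    fit_ball_berry,
    fit_light_response,
    fvcb_model,
    instantaneous_indices,
    kinetic_constants,
    light_curve_model,
)
from ecoflux.synthetic import TruePhysiology, generate_aci_curve, generate_light_curve


def record(**kw):
    base = dict(Q=1500, Ca=400, Ci=280, A=10, E=2, gs=0.2, T_leaf=25, rh_s=0.5, Cs=400)
    base.update(kw)
    return GasExchangeRecord(**base)


# --------------------------------------------------------------------------
# light-response forward model


class TestLightCurveModel:
    def test_dark_respiration_at_zero_light(self):
        for form, theta in (("nrh", 0.7), ("exponential", None)):
            assert light_curve_model(0.0, 16, 0.05, 1.0, theta, form) == pytest.approx(-1.0)

    def test_blackman_limit_theta_one(self):
        # theta = 1: A_g = min(phi*Q, Amax); here phi*Q = 8 < Amax = 16
        assert light_curve_model(160.0, 16, 0.05, 1.0, 1.0) == pytest.approx(8.0 - 1.0)

    def test_matches_quadratic_root_oracle(self):
        phi, amax, theta, rd, q = 0.05, 16.0, 0.7, 1.0, 500.0
        roots = np.roots([theta, -(phi * q + amax), phi * q * amax])
        a_gross = roots.min()
        assert light_curve_model(q, amax, phi, rd, theta) == pytest.approx(
            a_gross - rd, rel=1e-12
        )

    def test_continuous_in_theta_near_one(self):
        # away from the phi*Q = Amax kink convergence is O(1-theta)
        q = np.array([100.0, 200.0, 1500.0])
        near = light_curve_model(q, 16, 0.05, 1.0, 1 - 1e-8)
        limit = np.minimum(0.05 * q, 16.0) - 1.0
        np.testing.assert_allclose(near, limit, atol=1e-6)
        # at the kink itself convergence degrades to O(sqrt(1-theta))
        kink = light_curve_model(320.0, 16, 0.05, 1.0, 1 - 1e-8)
        assert kink == pytest.approx(15.0, abs=5e-3)

    def test_invalid_theta_raises(self):
        with pytest.raises(InvalidParameterError):
            light_curve_model(100.0, 16, 0.05, 1.0, 0.0, form="nrh")


class TestFitLightResponse:
    def test_recovers_nrh_parameters_exactly(self, phys):
        fit = fit_light_response(generate_light_curve(phys, noise_sd=0.0))
        assert fit.form == "nrh"
        assert fit.Amax == pytest.approx(phys.Amax, rel=1e-6)
        assert fit.phi == pytest.approx(phys.phi, rel=1e-6)
        assert fit.theta == pytest.approx(phys.theta, rel=1e-6)
        assert fit.Rd == pytest.approx(phys.Rd_dark, rel=1e-6)

    def test_exponential_data_selects_exponential_with_correct_lcp(self):
        amax, phi, rd = 16.0, 0.05, 1.0
        q = np.array([0, 50, 100, 200, 400, 800, 1500], dtype=float)
        recs = [
            record(Q=qi, A=float(light_curve_model(qi, amax, phi, rd, form="exponential")))
            for qi in q
        ]
        fit = fit_light_response(recs)
        assert fit.form == "exponential"
        lcp_closed = -(amax / phi) * math.log(1 - rd / amax)
        lcp_bisect = optimize.bisect(
            lambda x: light_curve_model(x, amax, phi, rd, form="exponential"), 1, 100
        )
        assert lcp_closed == pytest.approx(20.66, abs=0.01)
        assert fit.LCP == pytest.approx(lcp_bisect, rel=1e-6)

    def test_too_few_points_raises(self):
        recs = [record(Q=q, A=a) for q, a in [(0, -1), (500, 10), (1500, 14)]]
        with pytest.raises(InsufficientDataError):
            fit_light_response(recs)


# --------------------------------------------------------------------------
# FvCB model and A/Ci fitting


class TestFvCBModel:
    KIN = dict(gamma_star=40.0, Kc=280.0, Ko=200.0, O=300.0)

    def test_compensation_point_gives_minus_rday(self):
        a = fvcb_model(100, 150, 10, 1.0, Ci=40.0, **self.KIN)
        assert a == pytest.approx(-1.0)

    def test_rubisco_limited_direct_substitution(self):
        # Kc*(1+O/Ko) = 700 by construction
        kin = dict(gamma_star=40.0, Kc=350.0, Ko=300.0, O=300.0)
        a = fvcb_model(100, 1e6, None, 1.0, Ci=300.0, **kin)
        assert a == pytest.approx(100 * 260 / 1000 - 1, rel=1e-12)  # = 25.0

    def test_rubp_limited_direct_substitution(self):
        a = fvcb_model(1e6, 150, None, 1.0, Ci=300.0, **self.KIN)
        assert a == pytest.approx(150 * 260 / 1520 - 1, rel=1e-12)  # ~24.658

    def test_monotone_in_ci_within_regimes_and_flat_tpu(self):
        ci = np.linspace(50, 2000, 200)
        a = fvcb_model(60, 110, None, 1.0, Ci=ci, **self.KIN)
        assert np.all(np.diff(a) > 0)
        a_tpu = fvcb_model(1e6, 1e6, 8.0, 1.0, Ci=ci, **self.KIN)
        assert np.ptp(a_tpu) == 0.0


class TestFitAci:
    def test_recovers_parameters_at_25C(self, phys):
        fit = fit_aci(generate_aci_curve(phys, leaf_T=25.0, noise_sd=0.0))
        assert fit.Vcmax25 == pytest.approx(phys.Vcmax25, rel=1e-3)
        assert fit.Jmax25 == pytest.approx(phys.Jmax25, rel=1e-3)
        assert fit.TPU25 == pytest.approx(phys.TPU25, rel=1e-3)
        assert fit.Rday25 == pytest.approx(phys.Rday25, rel=1e-3)

    def test_recovers_parameters_after_temperature_normalization(self, phys):
        # cool leaf keeps a TPU-limited tail; all four parameters identified
        fit = fit_aci(generate_aci_curve(phys, leaf_T=22.0, noise_sd=0.0))
        assert fit.Vcmax25 == pytest.approx(phys.Vcmax25, rel=1e-3)
        assert fit.Jmax25 == pytest.approx(phys.Jmax25, rel=1e-3)
        assert fit.TPU25 == pytest.approx(phys.TPU25, rel=1e-3)
        assert fit.Rday25 == pytest.approx(phys.Rday25, rel=1e-3)

    def test_warm_leaf_vcmax_recovery(self, phys):
        fit = fit_aci(generate_aci_curve(phys, leaf_T=30.0, noise_sd=0.0))
        assert fit.Vcmax25 == pytest.approx(phys.Vcmax25, rel=1e-3)
        assert fit.Jmax25 == pytest.approx(phys.Jmax25, rel=1e-3)

    def test_absent_tpu_regime_reported_unidentified(self, phys):
        no_tpu = TruePhysiology(TPU25=1000.0)
        fit = fit_aci(generate_aci_curve(no_tpu, noise_sd=0.0))
        assert fit.TPU25 is None
        assert "tpu" not in fit.limitation

    def test_limitation_labels_monotone_in_ci(self, phys):
        fit = fit_aci(generate_aci_curve(phys, noise_sd=0.0))
        order = {"rubisco": 0, "rubp": 1, "tpu": 2}
        ranks = [order[l] for l in fit.limitation]
        assert ranks == sorted(ranks)

    def test_insufficient_span_raises(self, phys):
        recs = generate_aci_curve(phys, ca_steps=[300, 350, 400, 450, 500, 550])
        with pytest.raises(InsufficientDataError):
            fit_aci(recs)


class TestEstimateGamma:
    def test_exact_line_intercept(self):
        recs = [record(Ci=ci, A=0.1 * (ci - 50)) for ci in (60, 90, 120, 150)]
        assert estimate_gamma(recs) == pytest.approx(50.0, rel=1e-12)

    def test_closed_form_minus_b_over_m(self):
        recs = [record(Ci=ci, A=0.08 * ci - 4.8) for ci in (50, 90, 130)]
        assert estimate_gamma(recs) == pytest.approx(60.0, rel=1e-12)

    def test_flat_initial_points_raise(self):
        recs = [record(Ci=ci, A=2.0) for ci in (50, 90, 130)]
        with pytest.raises(DegenerateCurveError):
            estimate_gamma(recs)

    def test_invariant_to_uniform_rescaling_of_A(self):
        recs = [record(Ci=ci, A=0.05 * (ci - 45) + 0.3 * (-1) ** i)
                for i, ci in enumerate((40, 70, 100, 130))]
        scaled = [record(Ci=r.Ci, A=3.7 * r.A) for r in recs]
        assert estimate_gamma(scaled) == pytest.approx(estimate_gamma(recs), rel=1e-10)


class TestFitBallBerry:
    def test_exact_recovery_from_three_points(self):
        m, g0, gamma = 8.0, 0.01, 50.0
        recs = []
        for a, rh, cs in [(20, 0.5, 380), (10, 0.6, 400), (15, 0.4, 360)]:
            x = a * rh / (cs - gamma)
            recs.append(record(A=a, rh_s=rh, Cs=cs, gs=m * x + g0))
        fit = fit_ball_berry(recs, gamma)
        assert fit.m == pytest.approx(8.0, rel=1e-12)
        assert fit.g0 == pytest.approx(0.01, rel=1e-9)

    def test_constant_index_raises(self):
        recs = [record(A=10, rh_s=0.5, Cs=400, gs=g) for g in (0.1, 0.2, 0.3)]
        with pytest.raises(InsufficientVariationError):
            fit_ball_berry(recs, 50.0)

    def test_points_below_gamma_excluded_with_warning(self):
        good = [record(A=a, rh_s=0.5, Cs=400, gs=8 * a * 0.5 / 350 + 0.01)
                for a in (5, 10, 15, 20)]
        bad = [record(A=5, rh_s=0.5, Cs=40, gs=0.05)]
        with pytest.warns(UserWarning):
            fit = fit_ball_berry(good + bad, 50.0)
        assert fit.n == 4 and fit.excluded == 1
        assert fit.m == pytest.approx(8.0, rel=1e-9)

    def test_noisy_slope_unbiased_across_seeds(self):
        m, g0, gamma = 8.0, 0.01, 50.0
        rng_master = np.random.default_rng(2024)
        estimates = []
        for _ in range(100):
            rng = np.random.default_rng(rng_master.integers(2**31))
            recs = []
            for _ in range(20):
                a = rng.uniform(2, 20)
                rh = rng.uniform(0.3, 0.8)
                cs = rng.uniform(350, 420)
                x = a * rh / (cs - gamma)
                recs.append(record(A=a, rh_s=rh, Cs=cs,
                                   gs=m * x + g0 + rng.normal(0, 0.005)))
            estimates.append(fit_ball_berry(recs, gamma).m)
        assert np.mean(estimates) == pytest.approx(m, rel=0.05)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        recs = [record(A=rng.uniform(2, 20), rh_s=rng.uniform(0.3, 0.9),
                       Cs=rng.uniform(300, 450), gs=rng.uniform(0.05, 0.4))
                for _ in range(15)]
        fit = fit_ball_berry(recs, 50.0)
        x = np.array([r.A * r.rh_s / (r.Cs - 50.0) for r in recs])
        y = np.array([r.gs for r in recs])
        slope, intercept = ols_oracle(x, y)
        assert fit.m == pytest.approx(slope, abs=1e-10)
        assert fit.g0 == pytest.approx(intercept, abs=1e-10)


class TestInstantaneousIndices:
    def test_values(self):
        out = instantaneous_indices(record(A=5, E=2.5, gs=0.2, Ci=280, Ca=400))
        assert out["WUE_inst"] == pytest.approx(2.0)
        assert out["cica_inst"] == pytest.approx(0.70)
        out = instantaneous_indices(record(A=16, E=2.5, gs=0.2))
        assert out["iWUE_inst"] == pytest.approx(80.0)

    def test_zero_denominator_names_field(self):
        with pytest.raises(UndefinedIndexError) as err:
            instantaneous_indices(record(E=0.0))
        assert err.value.field == "E"
        with pytest.raises(UndefinedIndexError) as err:
            instantaneous_indices(record(gs=0.0))
        assert err.value.field == "gs"
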