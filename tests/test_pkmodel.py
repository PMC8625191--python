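"""Two-compartment infusion kinetics, IIV sampling and residual error."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from meropopk.pkmodel import (
    CL_FLOOR,
    DoseEvent,
    DosingRegimen,
    IndividualParameters,
    PopulationModel,
    apply_residual_error,
    conc_dose_events,
    conc_single_dose,
    individual_from_eta,
    sample_individual,
    sample_population,
    steady_state_profile,
    typical_cl,
)


def ode_concentration(p, dose, t_inf, times):
    """Stiff-ODE oracle for the two-compartment infusion system."""
    k10, k12, k21 = p.cl / p.vc, p.q / p.vc, p.q / p.vp

    def rhs(t, y):
        rate = dose / t_inf if t < t_inf else 0.0
        a1, a2 = y
        return [rate - (k10 + k12) * a1 + k21 * a2, k12 * a1 - k21 * a2]

    sol = solve_ivp(
        rhs, (0.0, float(max(times))), [0.0, 0.0], t_eval=times,
        rtol=1e-11, atol=1e-13, max_step=t_inf / 5, method="LSODA",
    )
    return sol.y[0] / p.vc


class TestCovariateModel:
    def test_typical_cl_at_reference(self, model):
        assert typical_cl(model, 91.57) == pytest.approx(6.37)

    def test_typical_cl_at_high_renal_function(self, model):
        # 6.37 * (1 + 0.00925 * (170 - 91.57))
        assert typical_cl(model, 170.0) == pytest.approx(10.99, abs=0.005)

    def test_covariate_off(self, model):
        flat = model.with_updates(theta_cov=0.0)
        assert typical_cl(flat, 20.0) == typical_cl(flat, 150.0) == model.theta_cl

    def test_floor_prevents_nonpositive_clearance(self, model):
        steep = model.with_updates(theta_cov=0.05)
        assert typical_cl(steep, 0.0) == CL_FLOOR


class TestIndividualParameters:
    def test_typical_individual_is_table_of_estimates(self, model):
        ip = individual_from_eta(model, 91.57)
        assert (ip.cl, ip.vc, ip.vp, ip.q) == pytest.approx((6.37, 9.07, 7.91, 10.7))
        assert ip.vss == pytest.approx(ip.vc + ip.vp)

    def test_exponential_link(self, model):
        base = individual_from_eta(model, 91.57)
        doubled = individual_from_eta(model, 91.57, eta_cl=np.log(2))
        assert doubled.cl == pytest.approx(2 * base.cl)

    def test_lognormal_moments(self, model):
        rng = np.random.default_rng(101)
        pop = sample_population(model, np.full(100_000, 91.57), rng)
        # SD of log CL is omega_cl; median is the typical value
        assert np.std(np.log(pop["cl"])) == pytest.approx(0.314, rel=0.02)
        assert np.median(pop["cl"]) == pytest.approx(6.37, rel=0.01)
        assert np.all(pop["q"] == model.q)  # no IIV on Q

    def test_zero_variability_is_deterministic(self, model):
        quiet = model.with_updates(omega_cl=0.0, omega_vc=0.0, omega_vp=0.0)
        rng = np.random.default_rng(0)
        a = sample_individual(quiet, 91.57, rng)
        b = sample_individual(quiet, 91.57, rng)
        assert a == b == individual_from_eta(model, 91.57)

    def test_fixed_seed_reproducible(self, model):
        a = sample_individual(model, 80.0, np.random.default_rng(5))
        b = sample_individual(model, 80.0, np.random.default_rng(5))
        assert a == b


class TestSingleDose:
    def test_zero_before_infusion_starts(self, model):
        ip = individual_from_eta(model, 91.57)
        assert conc_single_dose(ip, 1000, 0.5, 0.0) == 0.0

    def test_matches_ode_oracle_random_sweep(self):
        rng = np.random.default_rng(2024)
        times = np.array([0.1, 0.25, 0.5, 0.75, 1.0, 2.0, 4.0, 8.0, 12.0])
        for _ in range(20):
            p = IndividualParameters(
                cl=float(np.exp(rng.uniform(np.log(0.5), np.log(30)))),
                vc=float(np.exp(rng.uniform(np.log(2), np.log(40)))),
                vp=float(np.exp(rng.uniform(np.log(2), np.log(40)))),
                q=float(np.exp(rng.uniform(np.log(1), np.log(40)))),
            )
            closed = conc_single_dose(p, 1000.0, 0.5, times)
            oracle = ode_concentration(p, 1000.0, 0.5, times)
            np.testing.assert_allclose(
                closed, oracle, rtol=1e-6, atol=1e-9 * oracle.max()
            )

    def test_continuous_infusion_approaches_rate_over_cl(self, model):
        ip = individual_from_eta(model, 91.57)
        rate = 100.0  # mg/h
        t_inf = 5000.0
        c = conc_single_dose(ip, rate * t_inf, t_inf, 4000.0)
        assert c == pytest.approx(rate / ip.cl, rel=1e-6)

    def test_continuity_at_infusion_end(self, model):
        ip = individual_from_eta(model, 91.57)
        eps = 1e-9
        before = conc_single_dose(ip, 1000, 0.5, 0.5 - eps)
        after = conc_single_dose(ip, 1000, 0.5, 0.5 + eps)
        assert after == pytest.approx(before, rel=1e-6)

    def test_superposed_events_ignore_future_doses(self, model):
        ip = individual_from_eta(model, 91.57)
        events = [DoseEvent(0.0, 1000, 0.5), DoseEvent(8.0, 1000, 0.5)]
        t = np.array([4.0])
        one = conc_dose_events(ip, events[:1], t)
        both = conc_dose_events(ip, events, t)
        np.testing.assert_allclose(one, both)

    @given(
        cl=st.floats(0.5, 30), vc=st.floats(2, 40), vp=st.floats(2, 40),
        q=st.floats(1, 40), t=st.floats(0, 48),
    )
    @settings(max_examples=60, deadline=None)
    def test_concentration_never_negative(self, cl, vc, vp, q, t):
        p = IndividualParameters(cl=cl, vc=vc, vp=vp, q=q)
        assert conc_single_dose(p, 1000.0, 1.0, t) >= 0.0


class TestSteadyState:
    def test_average_concentration_identity(self, model):
        # integral over tau, / tau = dose / (cl * tau):  1000/(6.37*8) = 19.62
        ip = individual_from_eta(model, 91.57)
        prof = steady_state_profile(ip, DosingRegimen(1000, 8, 0.5), grid_step=0.002)
        cavg = np.trapezoid(prof.conc, prof.times) / 8.0
        assert cavg == pytest.approx(1000 / (6.37 * 8), rel=1e-5)
        assert cavg == pytest.approx(19.62, abs=0.01)

    def test_matches_brute_force_superposition(self, model):
        rng = np.random.default_rng(7)
        for _ in range(3):
            ip = sample_individual(model, 80.0, rng)
            reg = DosingRegimen(1000, 12, 1.0)
            prof = steady_state_profile(ip, reg)
            brute = sum(
                conc_single_dose(ip, reg.dose, reg.infusion_duration,
                                 prof.times + k * reg.interval)
                for k in range(30)
            )
            np.testing.assert_allclose(prof.conc, brute, rtol=1e-6)

    def test_periodicity(self, model):
        ip = individual_from_eta(model, 91.57)
        prof = steady_state_profile(ip, DosingRegimen(500, 12, 2.0))
        assert prof.conc[0] == pytest.approx(prof.conc[-1], rel=1e-9)

    def test_profile_nonnegative_with_breakpoint(self, model):
        ip = individual_from_eta(model, 91.57)
        reg = DosingRegimen(2000, 8, 3.0)
        prof = steady_state_profile(ip, reg)
        assert np.all(prof.conc >= 0)
        assert np.any(np.isclose(prof.times, reg.infusion_duration))


class TestRegimen:
    @pytest.mark.parametrize("dose,tau,tinf", [(0, 8, 0.5), (1000, 8, 0), (1000, 8, 9)])
    def test_invalid_regimens_rejected(self, dose, tau, tinf):
        with pytest.raises(ValueError):
            DosingRegimen(dose, tau, tinf)


class TestResidualError:
    def test_zero_sigma_is_identity(self, model):
        quiet = model.with_updates(sigma_prop=0.0)
        rng = np.random.default_rng(1)
        assert apply_residual_error(10.0, quiet, rng) == 10.0

    def test_proportional_cv_at_power_one(self, model):
        prop = model.with_updates(power=1.0)
        rng = np.random.default_rng(2)
        reps = apply_residual_error(np.full(100_000, 10.0), prop, rng)
        cv = np.std(reps) / 10.0
        assert cv == pytest.approx(0.246, rel=0.02)

    def test_power_law_noise_scale(self, model):
        rng = np.random.default_rng(3)
        reps = apply_residual_error(np.full(100_000, 10.0), model, rng)
        assert np.std(reps) == pytest.approx(0.246 * 10**0.865, rel=0.02)

    def test_nonpositive_prediction_rejected(self, model):
        with pytest.raises(ValueError):
            apply_residual_error(0.0, model, np.random.default_rng(0))

    def test_negative_draws_truncated_and_flagged(self, model):
        noisy = model.with_updates(sigma_prop=5.0, power=1.0)
        rng = np.random.default_rng(4)
        with pytest.warns(UserWarning, match="truncated"):
            obs, flags = apply_residual_error(
                np.full(100, 1.0), noisy, rng, return_flags=True
            )
        assert np.all(obs >= 0)
        assert flags.any()
        assert np.all(obs[flags] == 0.0)


class TestModelValidation:
    @pytest.mark.parametrize(
        "kw", [{"theta_cl": 0}, {"vc": -1}, {"omega_cl": -0.1},
               {"f_unbound": 0.0}, {"f_unbound": 1.2}],
    )
    def test_invalid_population_parameters(self, kw):
        with pytest.raises(ValueError):
            PopulationModel(**kw)
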