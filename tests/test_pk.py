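"""Closed-form compartmental kinetics: hand oracles, ODE cross-checks,
superposition and steady-state properties."""

import numpy as np
import pytest

from pippk import (
    DoseEvent,
    PKParameters,
    Regimen,
    macro_constants,
    simulate_profile,
    simulate_profile_ode,
    steady_state_interval,
)


def quadratic_roots_oracle(params):
    """Independent oracle: alpha, beta as roots of
    x^2 - (ke+kcp+kpc) x + ke*kpc."""
    ke = params.cl / params.v
    b = ke + params.kcp + params.kpc
    c = ke * params.kpc
    disc = np.sqrt(b * b - 4 * c)
    return (b + disc) / 2, (b - disc) / 2


class TestMacroConstants:
    def test_one_compartment_degeneracy(self):
        alpha, beta = macro_constants(PKParameters(cl=10.0, v=10.0))
        assert alpha == pytest.approx(1.0, abs=1e-12)
        assert beta == pytest.approx(0.0, abs=1e-12)

    def test_reference_parameters_match_root_oracle(self):
        p = PKParameters(cl=3.33, v=10.69, kcp=1.15, kpc=0.08)
        alpha, beta = macro_constants(p)
        a_ref, b_ref = quadratic_roots_oracle(p)
        assert alpha == pytest.approx(a_ref, rel=1e-12)
        assert beta == pytest.approx(b_ref, rel=1e-12)
        # frozen values from the root oracle
        assert alpha == pytest.approx(1.5252, abs=1e-4)
        assert beta == pytest.approx(0.01634, abs=1e-5)

    @pytest.mark.parametrize("seed", range(5))
    def test_defining_identities(self, seed):
        r = np.random.default_rng(seed)
        p = PKParameters(r.uniform(0.5, 10), r.uniform(3, 40), r.uniform(0, 3), r.uniform(0, 3))
        alpha, beta = macro_constants(p)
        ke = p.cl / p.v
        assert alpha >= beta >= 0
        assert alpha + beta == pytest.approx(ke + p.kcp + p.kpc, rel=1e-10)
        assert alpha * beta == pytest.approx(ke * p.kpc, rel=1e-10, abs=1e-14)

    def test_rejects_nonpositive_cl_or_v(self):
        with pytest.raises(ValueError):
            PKParameters(cl=0.0, v=10.0)
        with pytest.raises(ValueError):
            PKParameters(cl=3.0, v=-1.0)


class TestSimulateProfile:
    def test_one_compartment_bolus_closed_form(self):
        # 1000 mg bolus into 10 L with ke = 0.5/h: C(2) = 100 e^-1
        p = PKParameters(cl=5.0, v=10.0)
        prof = simulate_profile(p, [DoseEvent(0.0, 1000.0)], [2.0])
        assert prof.concentrations[0] == pytest.approx(100.0 * np.exp(-1.0), rel=1e-12)

    def test_mass_balance_with_negligible_elimination(self):
        # all infused drug is still in the central compartment at end of infusion
        p = PKParameters(cl=1e-10, v=10.0)
        prof = simulate_profile(p, [DoseEvent(0.0, 4000.0, 0.5)], [0.5])
        assert prof.concentrations[0] == pytest.approx(400.0, rel=1e-8)

    def test_linear_in_dose(self):
        p = PKParameters(cl=3.33, v=10.69, kcp=1.15, kpc=0.08)
        t = np.linspace(0.25, 24, 40)
        doses = [DoseEvent(i * 6.0, 4000.0, 0.5) for i in range(4)]
        doubled = [DoseEvent(d.start_time, 2 * d.amount, d.duration) for d in doses]
        c1 = simulate_profile(p, doses, t).concentrations
        c2 = simulate_profile(p, doubled, t).concentrations
        np.testing.assert_allclose(c2, 2 * c1, rtol=1e-12)

    def test_superposition_additivity(self):
        p = PKParameters(cl=3.33, v=10.69, kcp=1.15, kpc=0.08)
        t = np.linspace(0.0, 16, 65)
        d1, d2 = DoseEvent(0.0, 4000.0, 0.5), DoseEvent(6.0, 2000.0, 0.25)
        both = simulate_profile(p, [d1, d2], t).concentrations
        single = (
            simulate_profile(p, [d1], t).concentrations
            + simulate_profile(p, [d2], t).concentrations
        )
        np.testing.assert_allclose(both, single, rtol=1e-12, atol=1e-12)

    def test_one_compartment_limit_of_two_compartment(self):
        t = np.linspace(0.0, 12, 49)
        doses = [DoseEvent(0.0, 4000.0, 0.5)]
        full = simulate_profile(PKParameters(3.33, 10.69, 1e-10, 1e-10), doses, t)
        one = simulate_profile(PKParameters(3.33, 10.69), doses, t)
        assert np.max(np.abs(full.concentrations - one.concentrations)) < 1e-6

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_ode_oracle(self, seed):
        """Closed form vs adaptive Runge-Kutta on random 2-cmt parameters
        over a 4 g q6h schedule."""
        r = np.random.default_rng(seed)
        p = PKParameters(
            r.uniform(0.5, 7.0), r.uniform(3.0, 24.0), r.uniform(0.7, 1.6), r.uniform(0.005, 0.35)
        )
        doses = [DoseEvent(i * 6.0, 4000.0, 0.5) for i in range(3)]
        t = np.linspace(0.0, 18.0, 73)
        a = simulate_profile(p, doses, t).concentrations
        b = simulate_profile_ode(p, doses, t).concentrations
        assert np.max(np.abs(a - b)) / a.max() < 1e-6

    def test_continuity_at_infusion_boundaries(self):
        p = PKParameters(3.33, 10.69, 1.15, 0.08)
        doses = [DoseEvent(0.0, 4000.0, 0.5)]
        eps = 1e-9
        prof = simulate_profile(p, doses, [0.5 - eps, 0.5, 0.5 + eps])
        c = prof.concentrations
        assert abs(c[1] - c[0]) < 1e-5 and abs(c[2] - c[1]) < 1e-5
        assert np.all(c >= 0)

    def test_rejects_empty_and_ambiguous_schedules(self):
        p = PKParameters(3.33, 10.69)
        with pytest.raises(ValueError, match="empty"):
            simulate_profile(p, [], [1.0])
        with pytest.raises(ValueError, match="ambiguous"):
            simulate_profile(
                p, [DoseEvent(0.0, 1000.0, 0.5), DoseEvent(0.0, 500.0, 1.0)], [1.0]
            )

    def test_rejects_negative_times(self):
        p = PKParameters(3.33, 10.69)
        with pytest.raises(ValueError):
            simulate_profile(p, [DoseEvent(0.0, 1000.0)], [-1.0])


class TestSteadyState:
    def test_one_compartment_bolus_accumulation_ratio(self):
        # geometric series: C_ss/C_single = 1/(1 - e^{-ke tau})
        ke, tau = 0.3115, 8.0
        p = PKParameters(cl=ke * 10.0, v=10.0)
        reg = Regimen(1000.0, tau, 0.0)
        ss = steady_state_interval(p, reg, times=np.array([1.0, 4.0]))
        single = simulate_profile(p, [DoseEvent(0.0, 1000.0)], [1.0, 4.0])
        ratio = ss.concentrations / single.concentrations
        expected = 1.0 / (1.0 - np.exp(-ke * tau))
        np.testing.assert_allclose(ratio, expected, rtol=1e-10)
        assert expected == pytest.approx(1.0903, abs=2e-4)

    def test_pure_one_compartment_trough_closed_form(self):
        # kcp = kpc = 0: trough = Cmax_ss * e^{-ke (tau - dur)}
        p = PKParameters(cl=3.0, v=12.0)
        reg = Regimen(4000.0, 8.0, 0.5)
        prof = steady_state_interval(p, reg)
        cmax = prof.conc_at(reg.infusion_duration)
        trough = prof.conc_at(reg.interval)
        assert trough == pytest.approx(
            cmax * np.exp(-p.ke * (reg.interval - reg.infusion_duration)), rel=1e-9
        )

    @pytest.mark.parametrize(
        "params",
        [
            PKParameters(3.33, 10.69, 1.15, 0.08),
            PKParameters(6.8, 19.9, 0.9, 0.3),
            PKParameters(1.1, 6.8, 0.0, 0.0),
        ],
        ids=["reference", "fast", "one-compartment"],
    )
    def test_closed_form_matches_long_run_in(self, params):
        """Periodic initial conditions vs an explicit long run-in oracle
        (the run-in length is set so its own residual is < 0.01%)."""
        reg = Regimen(4000.0, 8.0, 0.5, n_run_in_doses=250)
        a = steady_state_interval(params, reg).concentrations
        b = steady_state_interval(params, reg, method="run_in").concentrations
        assert np.max(np.abs(a - b)) / a.max() < 1e-3

    def test_trough_periodicity(self):
        p = PKParameters(3.33, 10.69, 1.15, 0.08)
        prof = steady_state_interval(p, Regimen(4000.0, 6.0, 0.5))
        assert prof.concentrations[0] == pytest.approx(
            prof.concentrations[-1], rel=1e-3
        )

    def test_rejects_interval_not_longer_than_infusion(self):
        with pytest.raises(ValueError):
            Regimen(4000.0, 0.5, 0.5)
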