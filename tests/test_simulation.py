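"""Integration, steady states, hydrolysis budgets and unit conversions."""

import numpy as np
import pytest

from plateletsig import (
    EMPTY_PROTOCOL,
    H2,
    H3,
    BasalConstants,
    DomainError,
    ParameterError,
    PlateletState,
    QuantificationContext,
    StimulusProtocol,
    basal_state,
    calibrated_basal_state,
    hydrolysis_budget,
    integrate,
    mass_concentration,
    simulate_camp_batch,
    solve_active_concentrations,
    solve_active_pde5,
    steady_state,
    steady_state_camp,
)
from plateletsig.synth import true_drug_parameters


class TestIntegrate:
    def test_basal_camp_held_within_two_percent_over_an_hour(self, constants, basal):
        traj = integrate(basal, constants, t_end=60.0)
        assert np.all(np.abs(traj.camp - 4.0) <= 0.02 * 4.0)

    def test_zero_influx_zero_enzymes_is_constant(self):
        k = BasalConstants(camp_influx=0.0, cgmp_influx=0.0)
        state = basal_state(pde2_active=0.0, pde3_active=0.0, pde5_active=0.0,
                            pde2_total=0.0, pde3_total=0.0, pde5_total=0.0)
        traj = integrate(state, k, t_end=30.0)
        np.testing.assert_allclose(traj.camp, 4.0, rtol=1e-9)
        np.testing.assert_allclose(traj.cgmp, 0.4, rtol=1e-9)

    def test_linear_decay_subsystem_matches_closed_form(self):
        # cAMP << Km: pure PDE3 decay is exponential with rate Vmax*c/Km
        k = BasalConstants(camp_influx=0.0, cgmp_influx=0.0,
                           vmax_pde2_camp=0.0, km_pde3_camp=2000.0)
        state = basal_state(camp=1.0, pde3_active=2.3)
        rate = k.vmax_pde3_camp * 2.3 / (k.km_pde3_camp + 1.0)
        grid = np.linspace(0.0, 10.0, 21)
        traj = integrate(state, k, t_end=10.0, grid=grid, rtol=1e-11, atol=1e-13)
        # linearized rate uses c << Km; exact at Km -> infinity
        expected = np.exp(-k.vmax_pde3_camp * 2.3 / k.km_pde3_camp * grid)
        np.testing.assert_allclose(traj.camp, expected, rtol=2e-3)
        assert rate == pytest.approx(k.vmax_pde3_camp * 2.3 / k.km_pde3_camp,
                                     rel=1e-3)

    def test_enzyme_conservation_along_trajectory(self, constants):
        k = constants.copy(pde2_activation=0.5, pde2_deactivation=0.2,
                           pde3_activation=0.1, pde3_deactivation=0.3,
                           pde5_activation=0.2, pde5_deactivation=0.2)
        state = PlateletState()
        traj = integrate(state, k, t_end=20.0)
        for active, inactive, total in ((2, 5, state.pde2_total),
                                        (3, 6, state.pde3_total),
                                        (4, 7, state.pde5_total)):
            pools = traj.states[:, active] + traj.states[:, inactive]
            np.testing.assert_allclose(pools, total, rtol=1e-7)

    def test_grid_refinement_stability(self, constants, basal):
        drugs = true_drug_parameters()
        protocol = StimulusProtocol.single("Iloprost", 50.0)
        end = [10.0]
        a = integrate(basal, constants, drugs, H3, protocol, t_end=10.0,
                      grid=np.array(end), rtol=1e-8, atol=1e-10)
        b = integrate(basal, constants, drugs, H3, protocol, t_end=10.0,
                      grid=np.array(end), rtol=5e-9, atol=5e-11)
        assert abs(a.camp[-1] - b.camp[-1]) / b.camp[-1] < 1e-3

    def test_rejects_bad_window(self, constants, basal):
        with pytest.raises(ParameterError):
            integrate(basal, constants, t_end=-1.0)


class TestSteadyState:
    def test_unstimulated_plateau_near_basal_levels(self, constants):
        state = steady_state(constants)
        assert state.camp == pytest.approx(4.0, rel=0.1)
        assert state.cgmp == pytest.approx(0.4, rel=0.25)

    def test_calibrated_pools_hold_basal_exactly(self, constants):
        state0 = calibrated_basal_state(constants)
        state = steady_state(constants, initial=state0,
                             drugs=None)
        # pools calibrated from the basal constraints: exact stationarity
        assert state.camp == pytest.approx(4.0, abs=1e-6)
        assert state.cgmp == pytest.approx(0.4, abs=1e-6)

    def test_no_influx_drains_to_zero(self):
        k = BasalConstants(camp_influx=0.0, cgmp_influx=0.0)
        state = steady_state(k)
        assert state.camp == pytest.approx(0.0, abs=1e-6)
        assert state.cgmp == pytest.approx(0.0, abs=1e-6)

    def test_plateau_agrees_with_long_time_integration(self, constants, basal):
        drugs = true_drug_parameters()
        protocol = StimulusProtocol.single("Milrinone", 50.0)
        plateau = steady_state(constants, drugs, H3, protocol, initial=basal)
        traj = integrate(basal, constants, drugs, H3, protocol, t_end=200.0,
                         grid=np.array([200.0]))
        assert plateau.camp == pytest.approx(traj.camp[-1], rel=5e-3)

    def test_scalar_plateau_matches_full_solver(self, constants):
        drugs = true_drug_parameters()
        protocol = StimulusProtocol.single("Iloprost", 100.0)
        full = steady_state(constants, drugs, H3, protocol)
        fast = steady_state_camp(constants, drugs, H3, protocol)
        assert fast == pytest.approx(full.camp, rel=1e-8)

    def test_transient_profile_rejected(self, constants):
        from plateletsig import StimulusEntry

        protocol = StimulusProtocol((StimulusEntry(
            "Iloprost", 10.0, profile="transient", half_life=5.0),))
        with pytest.raises(ParameterError):
            steady_state(constants, true_drug_parameters(), H3, protocol)

    def test_monotone_dose_response(self, constants):
        drugs = true_drug_parameters()
        for drug, doses in (("Milrinone", (1.0, 5.0, 10.0, 50.0, 100.0)),
                            ("Iloprost", (1.0, 5.0, 10.0, 50.0, 100.0))):
            plateaus = [steady_state_camp(constants, drugs, H3,
                                          StimulusProtocol.single(drug, d))
                        for d in doses]
            assert np.all(np.diff(plateaus) > 0)


class TestHydrolysisBudget:
    def test_full_measured_pools_give_millimolar_budget(self, constants):
        budget = hydrolysis_budget(4.0, 63.46, 225.0, constants)
        assert budget.total_rate == pytest.approx(2489.0, rel=1e-3)  # ~2.5 mM/min
        assert budget.turnover == pytest.approx(622.2, rel=1e-3)     # ~625 per min
        assert budget.pde2_rate == pytest.approx(1846.1, rel=1e-3)
        assert budget.pde3_rate == pytest.approx(642.9, rel=1e-3)

    def test_active_pools_give_8_micromolar_budget(self, constants):
        budget = hydrolysis_budget(4.0, 0.05, 2.3, constants)
        assert budget.total_rate == pytest.approx(8.0, abs=0.05)
        assert budget.pde2_rate == pytest.approx(1.5, abs=0.05)
        assert budget.pde3_rate == pytest.approx(6.5, abs=0.08)

    def test_no_enzyme_no_hydrolysis(self, constants):
        budget = hydrolysis_budget(4.0, 0.0, 0.0, constants)
        assert budget.total_rate == 0.0

    def test_turnover_undefined_at_zero_camp(self, constants):
        with pytest.raises(DomainError):
            hydrolysis_budget(0.0, 1.0, 1.0, constants)
        assert hydrolysis_budget(0.0, 1.0, 1.0, constants,
                                 with_turnover=False).total_rate == 0.0

    def test_budget_consistency_at_steady_state(self, constants):
        drugs = true_drug_parameters()
        protocol = StimulusProtocol.single("Iloprost", 10.0)
        c = steady_state_camp(constants, drugs, H2, protocol)
        hyd = hydrolysis_budget(c, 0.05, 2.3, constants,
                                with_turnover=False).total_rate
        influx = constants.camp_influx + max(
            drugs.influx_for("Iloprost", 10.0) - drugs.kf2 * c, 0.0)
        assert hyd == pytest.approx(influx, abs=1e-8)


class TestActiveConcentrations:
    def test_recovers_reported_active_pools(self, constants):
        pde2, pde3 = solve_active_concentrations(4.0, 8.0, 0.8, constants)
        assert 2.2 <= pde3 <= 2.3
        assert pde2 == pytest.approx(0.05, abs=0.01)

    def test_share_to_one_removes_pde2(self, constants):
        pde2, _ = solve_active_concentrations(4.0, 8.0, 1 - 1e-9, constants)
        assert pde2 < 1e-8

    def test_closed_form_matches_numerical_inversion(self, constants):
        from scipy.optimize import brentq

        pde2, pde3 = solve_active_concentrations(4.0, 8.0, 0.8, constants)

        def residual_pde3(c):
            return 3.0 * c * 4.0 / (0.2 + 4.0) - 0.8 * 8.0

        assert pde3 == pytest.approx(brentq(residual_pde3, 0, 100), abs=1e-8)

    def test_simulated_basal_stationary_with_solved_pools(self, constants):
        pde2, pde3 = solve_active_concentrations(4.0, 8.0, 0.8, constants)
        pde5 = solve_active_pde5(pde2, pde3, constants=constants)
        state0 = basal_state(pde2_active=pde2, pde3_active=pde3,
                             pde5_active=pde5)
        traj = integrate(state0, constants, t_end=60.0)
        assert np.all(np.abs(traj.camp - 4.0) <= 0.02 * 4.0)
        assert np.all(np.abs(traj.cgmp - 0.4) <= 0.10 * 0.4)

    def test_invalid_share_rejected(self, constants):
        with pytest.raises(ParameterError):
            solve_active_concentrations(4.0, 8.0, 1.0, constants)


class TestMassConcentration:
    @pytest.mark.parametrize("ng,expected", [
        (3.3, 63.46), (11.7, 225.0), (70.7, 1359.6), (0.0, 0.0),
    ])
    def test_reported_conversions(self, ng, expected):
        assert mass_concentration(ng) == pytest.approx(expected, abs=0.05)

    def test_volume_validation(self):
        with pytest.raises(ParameterError):
            QuantificationContext(volume_fl=0.0)


class TestBatchSimulator:
    def test_agrees_with_adaptive_full_system_integrator(self, constants, basal):
        drugs = true_drug_parameters()
        grid = np.linspace(0.0, 10.0, 41)
        protocols = [StimulusProtocol.single("Milrinone", 100.0),
                     StimulusProtocol.single("Forskolin", 500.0),
                     StimulusProtocol.single("Iloprost", 5.0),
                     EMPTY_PROTOCOL]
        batch = simulate_camp_batch(protocols, [grid] * 4, constants, drugs, H3)
        c0 = steady_state_camp(constants, drugs, H3, EMPTY_PROTOCOL)
        for protocol, fast in zip(protocols, batch):
            start = basal_state(camp=c0)
            ref = integrate(start, constants, drugs, H3, protocol,
                            t_end=10.0, grid=grid, rtol=1e-10, atol=1e-12)
            # dominated by linear interpolation between the 0.02-min RK steps
            np.testing.assert_allclose(fast, ref.camp, rtol=2e-4, atol=2e-4)

    def test_initial_state_is_resting_steady_state(self, constants):
        drugs = true_drug_parameters()
        grid = np.array([0.0, 5.0, 10.0])
        flat = simulate_camp_batch([EMPTY_PROTOCOL], [grid], constants,
                                   drugs, H3)[0]
        np.testing.assert_allclose(flat, flat[0], rtol=1e-9)
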