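"""Rate laws, feedback terms and the structure of the ODE right-hand side."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plateletsig import (
    EMPTY_PROTOCOL,
    H0,
    H1,
    H2,
    H3,
    BasalConstants,
    ConfigurationError,
    DomainError,
    DrugParameters,
    ParameterError,
    PlateletState,
    StimulusEntry,
    StimulusProtocol,
    basal_state,
    effective_ac_rate,
    effective_pde3_rate,
    ode_rhs,
    reaction_rates,
)
from plateletsig.model import camp_rhs
from plateletsig.synth import true_drug_parameters


class TestReactionRates:
    def test_basal_pde_rates_match_reported_in_vivo_activities(self, constants, basal):
        # 1.45 uM/min for PDE2 (Hill, h=2) and 6.57 for PDE3 at 4 uM cAMP
        v = reaction_rates(basal, constants)
        assert v[2] == pytest.approx(120 * 0.05 * 16 / 66, rel=1e-12)
        assert v[3] == pytest.approx(3 * 2.3 * 4 / 4.2, rel=1e-12)
        assert v[2] == pytest.approx(1.45, abs=0.01)
        assert v[3] == pytest.approx(6.57, abs=0.01)

    def test_no_substrate_no_hydrolysis(self, constants):
        state = basal_state(camp=0.0, cgmp=0.0)
        v = reaction_rates(state, constants)
        assert v[2] == v[3] == 0.0
        assert np.all(v[4:7] == 0.0)

    def test_influx_rates_are_the_basal_constants(self, constants, basal):
        v = reaction_rates(basal, constants)
        assert v[0] == constants.camp_influx
        assert v[1] == constants.cgmp_influx

    def test_negative_state_component_rejected(self, constants, basal):
        state = basal.to_array()
        state[3] = -0.1
        bad = object.__new__(PlateletState)
        for name, value in zip(
                ("camp", "cgmp", "pde2_active", "pde3_active", "pde5_active",
                 "pde2_inactive", "pde3_inactive", "pde5_inactive", "amp",
                 "gmp"), state):
            object.__setattr__(bad, name, float(value))
        with pytest.raises(DomainError, match="pde3_active"):
            reaction_rates(bad, constants)

    def test_state_constructor_rejects_negative(self):
        with pytest.raises(DomainError):
            PlateletState(camp=-1.0)


class TestEffectivePde3Rate:
    def test_reduces_to_basal_rate_without_inhibitor_or_feedback(self):
        assert effective_pde3_rate(4.0, 2.3) == pytest.approx(6.571, abs=1e-3)

    def test_dose_equal_to_ki_doubles_apparent_km(self):
        # competitive inhibition: u = k_i doubles Km -> 3*2.3*4/(2*0.2+4)
        rate = effective_pde3_rate(4.0, 2.3, inhibitor_dose=5.0, k_i=5.0)
        assert rate == pytest.approx(3 * 2.3 * 4 / (2 * 0.2 + 4), rel=1e-12)
        assert rate == pytest.approx(6.27, abs=0.01)

    def test_full_competitive_inhibition_limit(self):
        assert effective_pde3_rate(4.0, 2.3, inhibitor_dose=1e12, k_i=1.0) < 1e-9

    def test_positive_feedback_raises_vmax(self):
        base = effective_pde3_rate(10.0, 2.3)
        fed = effective_pde3_rate(10.0, 2.3, kf1=0.05)
        assert fed == pytest.approx(base * (3 + 0.5) / 3, rel=1e-12)

    def test_nonpositive_ki_rejected(self):
        with pytest.raises(ParameterError):
            effective_pde3_rate(4.0, 2.3, inhibitor_dose=1.0, k_i=0.0)


class TestEffectiveAcRate:
    def test_no_feedback_identity(self):
        assert effective_ac_rate(10.0, camp=123.0, kf2=0.0) == 10.0

    def test_strong_feedback_clamps_at_zero(self):
        assert effective_ac_rate(5.0, camp=70.0, kf2=0.1) == 0.0

    def test_basal_influx_untouched_by_feedback(self):
        assert effective_ac_rate(5.0, camp=70.0, kf2=0.1, basal_influx=8.0) == 8.0

    def test_plateau_balance_matches_steady_state_solver(self, constants):
        # at the plateau, net drug influx equals the extra hydrolysis
        from plateletsig.simulate import steady_state_camp

        drugs = true_drug_parameters()
        protocol = StimulusProtocol.single("Iloprost", 50.0)
        c_star = steady_state_camp(constants, drugs, H2, protocol)
        x = drugs.influx_for("Iloprost", 50.0)
        net = effective_ac_rate(x, c_star, drugs.kf2)
        from plateletsig.simulate import hydrolysis_budget

        hyd = hydrolysis_budget(c_star, 0.05, 2.3, constants,
                                with_turnover=False).total_rate
        assert net + constants.camp_influx == pytest.approx(hyd, abs=1e-7)


class TestOdeRhs:
    def test_basal_state_near_stationary(self, constants, basal):
        dx = ode_rhs(0.0, basal, constants)
        assert abs(dx[0]) < 0.1  # uM/min
        assert abs(dx[1]) < 0.2

    def test_enzyme_pools_conserved_by_construction(self, constants, basal):
        k = constants.copy(pde2_activation=0.3, pde2_deactivation=0.1,
                           pde3_activation=0.2, pde3_deactivation=0.4,
                           pde5_activation=0.15, pde5_deactivation=0.05)
        dx = ode_rhs(0.0, basal, k)
        assert dx[2] + dx[5] == pytest.approx(0.0, abs=1e-14)
        assert dx[3] + dx[6] == pytest.approx(0.0, abs=1e-14)
        assert dx[4] + dx[7] == pytest.approx(0.0, abs=1e-14)

    def test_camp_bookkeeping_production_only(self, constants, basal):
        # d(cAMP + AMP)/dt equals the production terms alone
        drugs = true_drug_parameters()
        protocol = StimulusProtocol.single("Forskolin", 100.0)
        dx = ode_rhs(0.0, basal, constants, drugs, H3, protocol)
        x = drugs.influx_for("Forskolin", 100.0)
        expected = constants.camp_influx + max(x - drugs.kf2 * basal.camp, 0.0)
        assert dx[0] + dx[8] == pytest.approx(expected, rel=1e-12)

    def test_unknown_drug_rejected(self):
        with pytest.raises(ConfigurationError):
            StimulusProtocol.single("Aspirin", 1.0)

    def test_transient_dose_decays_with_half_life(self):
        entry = StimulusEntry("Iloprost", 10.0, profile="transient", half_life=5.0)
        assert entry.effective_dose(0.0) == 10.0
        assert entry.effective_dose(5.0) == pytest.approx(5.0)
        assert entry.effective_dose(50.0) == pytest.approx(10.0 * 2 ** -10)

    def test_transient_requires_half_life(self):
        with pytest.raises(ParameterError):
            StimulusEntry("Iloprost", 10.0, profile="transient")

    @pytest.mark.parametrize("variant,kf1_used,kf2_used", [
        (H0, False, False), (H1, True, False), (H2, False, True),
        (H3, True, True),
    ])
    def test_variant_gates_the_feedback_terms(self, constants, basal, variant,
                                              kf1_used, kf2_used):
        drugs = true_drug_parameters()
        protocol = StimulusProtocol.single("Iloprost", 10.0)
        dx = ode_rhs(0.0, basal, constants, drugs, variant, protocol)
        ref = DrugParameters(ki=dict(drugs.ki), ac_influx=dict(drugs.ac_influx),
                             kf1=drugs.kf1 if kf1_used else 0.0,
                             kf2=drugs.kf2 if kf2_used else 0.0)
        dx_ref = ode_rhs(0.0, basal, constants, ref, H3, protocol)
        np.testing.assert_allclose(dx, dx_ref, rtol=1e-14)

    def test_variant_nesting_h3_reduces_to_simpler_variants(self, constants, basal):
        # H3 with kf1 = 0 is exactly H2; with kf2 = 0 exactly H1; both 0 -> H0
        base = true_drug_parameters()
        protocol = StimulusProtocol.single("Iloprost", 100.0)

        def rhs(drugs, variant):
            return ode_rhs(2.0, basal, constants, drugs, variant, protocol)

        no_kf1 = DrugParameters(ki=dict(base.ki), ac_influx=dict(base.ac_influx),
                                kf1=0.0, kf2=base.kf2)
        no_kf2 = DrugParameters(ki=dict(base.ki), ac_influx=dict(base.ac_influx),
                                kf1=base.kf1, kf2=0.0)
        neither = DrugParameters(ki=dict(base.ki), ac_influx=dict(base.ac_influx))
        np.testing.assert_array_equal(rhs(no_kf1, H3), rhs(no_kf1, H2))
        np.testing.assert_array_equal(rhs(no_kf2, H3), rhs(no_kf2, H1))
        np.testing.assert_array_equal(rhs(neither, H3), rhs(neither, H0))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(camp=st.floats(0.0, 1000.0), cgmp=st.floats(0.0, 10.0),
           dose=st.floats(0.0, 100.0))
    def test_cgmp_branch_blind_to_camp_pathway_drugs(self, camp, cgmp, dose):
        # structural no-cross-talk: the cGMP derivatives never depend on
        # cAMP-pathway stimulation
        constants = BasalConstants()
        state = basal_state(camp=camp, cgmp=cgmp)
        drugs = true_drug_parameters()
        stim = StimulusProtocol((StimulusEntry("Milrinone", dose),
                                 StimulusEntry("Iloprost", 10.0)))
        dx_drug = ode_rhs(1.0, state, constants, drugs, H3, stim)
        dx_rest = ode_rhs(1.0, state, constants, drugs, H3, EMPTY_PROTOCOL)
        cgmp_rows = [1, 9]  # cGMP and GMP
        np.testing.assert_array_equal(dx_drug[cgmp_rows], dx_rest[cgmp_rows])


class TestReducedCampRhs:
    def test_matches_full_system_camp_row(self, constants, basal):
        drugs = true_drug_parameters()
        for drug, dose in (("Milrinone", 50.0), ("Forskolin", 30.0)):
            protocol = StimulusProtocol.single(drug, dose)
            for c in (0.5, 4.0, 40.0):
                state = basal_state(camp=c)
                full = ode_rhs(1.0, state, constants, drugs, H3, protocol)[0]
                reduced = float(camp_rhs(1.0, c, constants, drugs, H3, protocol))
                assert reduced == pytest.approx(full, rel=1e-12)
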