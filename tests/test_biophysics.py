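"""Unit and property tests for the conductance-based cell model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuroassim import biophysics as bio
from neuroassim.biophysics import (CellParams, CellState, GatingState, IonState,
                                   MicroenvParams, NetworkState, SynapseParams,
                                   SynapseState, bath_flux,
                                   dependent_concentrations, gating_derivatives,
                                   gating_rate_functions, glial_flux,
                                   ion_derivatives, lateral_K_diffusion,
                                   membrane_currents, nernst_reversals,
                                   pump_flux, rhs_coupled_pair, rhs_single_cell,
                                   synaptic_dynamics, synaptic_gate_chi)
from neuroassim.errors import ConfigError, DomainError


def _sympy_rates(V):
    """Independent high-precision evaluation of the six HH rate functions."""
    import sympy as sp
    v = sp.Float(V, 30)
    rates = {
        "alpha_m": sp.Rational(1, 10) * (v + 30) / (1 - sp.exp(-(v + 30) / 10)),
        "beta_m": 4 * sp.exp(-(v + 55) / 18),
        "alpha_h": sp.Rational(7, 100) * sp.exp(-(v + 44) / 20),
        "beta_h": 1 / (1 + sp.exp(-(v + 14) / 10)),
        "alpha_n": sp.Rational(1, 100) * (v + 34) / (1 - sp.exp(-(v + 34) / 10)),
        "beta_n": sp.Rational(1, 8) * sp.exp(-(v + 44) / 80),
    }
    return {k: float(sp.N(expr, 30)) for k, expr in rates.items()}


class TestGatingRates:
    def test_matches_symbolic_evaluation(self):
        got = gating_rate_functions(-65.0)
        want = _sympy_rates(-65.0)
        for key in want:
            assert got[key] == pytest.approx(want[key], abs=1e-12)

    @pytest.mark.parametrize("V_sing, key, limit", [
        (-30.0, "alpha_m", 1.0),     # x/(1-e^-x) -> 1 as x -> 0
        (-34.0, "alpha_n", 0.1),
    ])
    def test_removable_singularities(self, V_sing, key, limit):
        val = gating_rate_functions(V_sing)[key]
        assert np.isfinite(val) and val > 0
        assert val == pytest.approx(limit, rel=1e-9)
        # continuity across the singular voltage
        near = gating_rate_functions(V_sing + 1e-8)[key]
        assert near == pytest.approx(val, rel=1e-6)

    def test_steady_states_bounded(self):
        for V in np.linspace(-100.0, 50.0, 151):
            r = gating_rate_functions(V)
            for x in ("m", "h", "n"):
                xinf = r[f"alpha_{x}"] / (r[f"alpha_{x}"] + r[f"beta_{x}"])
                assert 0.0 < xinf < 1.0

    def test_nonfinite_voltage_rejected(self):
        with pytest.raises(DomainError):
            gating_rate_functions(np.nan)


class TestGatingDerivatives:
    def test_zero_at_steady_state(self):
        r = gating_rate_functions(-52.0)
        g = GatingState(*(r[f"alpha_{x}"] / (r[f"alpha_{x}"] + r[f"beta_{x}"])
                          for x in "mhn"))
        d = gating_derivatives(-52.0, g)
        assert all(abs(v) < 1e-14 for v in d.values())

    def test_boundary_influx(self):
        d = gating_derivatives(-65.0, GatingState(0.0, 0.0, 0.0), phi=3.0)
        r = gating_rate_functions(-65.0)
        for x in "mhn":
            assert d[f"d{x}_dt"] == pytest.approx(3.0 * r[f"alpha_{x}"])
            assert d[f"d{x}_dt"] > 0

    def test_compositional_oracle(self):
        r = gating_rate_functions(-65.0)
        d = gating_derivatives(-65.0, GatingState(0.5, 0.5, 0.5), phi=3.0)
        for x in "mhn":
            expected = 3.0 * (r[f"alpha_{x}"] * 0.5 - r[f"beta_{x}"] * 0.5)
            assert d[f"d{x}_dt"] == pytest.approx(expected, abs=1e-14)

    def test_invalid_gate_rejected(self):
        with pytest.raises(DomainError):
            gating_derivatives(-65.0, GatingState(1.2, 0.5, 0.5))


class TestNernst:
    def test_equal_concentrations_zero(self):
        env = MicroenvParams(beta_vol=0.0)   # keeps Na_o at 144
        ions = IonState(K_o=140.0 + (18.0 - 18.0), Na_i=18.0, Ca_i=0.0)
        ions.K_o = 140.0  # equal to derived K_i at Na_i = 18
        rev = nernst_reversals(ions, CellParams(), env)
        assert rev["E_K"] == pytest.approx(0.0, abs=1e-12)

    def test_closed_forms(self):
        # K_o = 4 with Na_i chosen so K_i = 140
        rev = nernst_reversals(IonState(K_o=4.0, Na_i=18.0), CellParams(),
                               MicroenvParams())
        assert rev["E_K"] == pytest.approx(26.64 * np.log(4.0 / 140.0), rel=1e-12)
        assert rev["E_K"] == pytest.approx(-94.7, abs=0.05)
        # Na_o/Na_i = 8 at rest
        assert rev["E_Na"] == pytest.approx(26.64 * np.log(8.0), rel=1e-12)
        assert rev["E_Na"] == pytest.approx(55.4, abs=0.05)
        assert rev["E_K"] < 0 < rev["E_Na"]

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(DomainError):
            nernst_reversals(IonState(K_o=-1.0, Na_i=18.0), CellParams(),
                             MicroenvParams())


class TestMembraneCurrents:
    def _rev(self):
        return {"E_Na": 55.0, "E_K": -95.0, "E_Cl": -81.9}

    def test_zero_conductances(self):
        p = CellParams(g_Na=0, g_K=0, g_AHP=0, g_KL=0, g_NaL=0, g_ClL=0, g_Ca=0)
        cur = membrane_currents(-60.0, GatingState(0.3, 0.5, 0.4), self._rev(),
                                0.2, p)
        assert all(v == 0 for v in cur.values())

    def test_potassium_reversal(self):
        p = CellParams(g_Na=0, g_AHP=0, g_NaL=0, g_ClL=0)
        cur = membrane_currents(-95.0, GatingState(0.3, 0.5, 0.4), self._rev(),
                                0.0, p)
        assert sum(v for k, v in cur.items() if k != "I_L") == pytest.approx(0.0)

    def test_termwise_oracle(self, rng):
        p = CellParams()
        V = float(rng.uniform(-90, 30))
        g = GatingState(*rng.uniform(0.05, 0.95, 3))
        ca = float(rng.uniform(0, 1))
        rev = self._rev()
        cur = membrane_currents(V, g, rev, ca, p)
        assert cur["I_Na"] == pytest.approx(
            p.g_Na * g.m ** 3 * g.h * (V - rev["E_Na"]), abs=1e-12)
        assert cur["I_K"] == pytest.approx(
            p.g_K * g.n ** 4 * (V - rev["E_K"]), abs=1e-12)
        assert cur["I_AHP"] == pytest.approx(
            p.g_AHP * ca / (1 + ca) * (V - rev["E_K"]), abs=1e-12)
        assert cur["I_L"] == pytest.approx(
            cur["I_KL"] + cur["I_NaL"] + cur["I_ClL"], abs=1e-12)

    def test_interneuron_has_no_ahp(self):
        p = CellParams.interneuron()
        cur = membrane_currents(-60.0, GatingState(0.3, 0.5, 0.4), self._rev(),
                                5.0, p)
        assert cur["I_AHP"] == 0.0
        with pytest.raises(ConfigError):
            CellParams(cell_type="IN", g_AHP=0.01)


class TestFluxes:
    def test_pump_off_and_saturation(self):
        assert pump_flux(18.0, 4.0, 0.0) == 0.0
        assert pump_flux(1000.0, 1000.0, 1.25) == pytest.approx(1.25, rel=1e-2)

    def test_pump_direct_evaluation(self):
        expected = 1.25 / ((1 + np.exp((25 - 18) / 3.0)) * (1 + np.exp(5.5 - 4.0)))
        assert pump_flux(18.0, 4.0, 1.25) == pytest.approx(expected, rel=1e-12)

    def test_pump_negative_rho_rejected(self):
        with pytest.raises(ConfigError):
            pump_flux(18.0, 4.0, -1.0)

    @given(na=st.floats(5, 40), ko=st.floats(1, 30), dna=st.floats(0.01, 5),
           dko=st.floats(0.01, 5))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_pump_monotone(self, na, ko, dna, dko):
        base = pump_flux(na, ko, 1.25)
        assert 0 <= base <= 1.25
        assert pump_flux(na + dna, ko, 1.25) >= base
        assert pump_flux(na, ko + dko, 1.25) >= base

    def test_glia(self):
        assert glial_flux(4.0, 0.0) == 0.0
        assert glial_flux(200.0, 66.0) == pytest.approx(66.0, rel=1e-6)
        expected = 66.0 / (1 + np.exp((18 - 4.0) / 2.5))
        assert glial_flux(4.0, 66.0) == pytest.approx(expected, rel=1e-12)

    def test_bath(self):
        assert bath_flux(3.0, 3.0, 1.2) == 0.0
        assert bath_flux(5.0, 3.0, 1.2) == pytest.approx(2 * bath_flux(4.0, 3.0, 1.2))
        assert bath_flux(7.0, 3.0, 0.9) == pytest.approx(4 * 0.9)


class TestDependentConcentrations:
    def test_resting_values(self):
        d = dependent_concentrations(18.0, 7.0)
        assert d["K_i"] == 140.0 and d["Na_o"] == 144.0

    @pytest.mark.parametrize("na_i, beta, ki, nao", [
        (10.0, 7.0, 148.0, 200.0),
        (20.0, 7.0, 138.0, 130.0),
    ])
    def test_arithmetic(self, na_i, beta, ki, nao):
        d = dependent_concentrations(na_i, beta)
        assert d["K_i"] == pytest.approx(ki)
        assert d["Na_o"] == pytest.approx(nao)

    @given(na=st.floats(1.0, 50.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_electroneutrality_identities(self, na):
        d = dependent_concentrations(na, 7.0)
        assert d["K_i"] + na == pytest.approx(158.0, abs=1e-12)
        assert d["Na_o"] + 7.0 * na == pytest.approx(144.0 + 18.0 * 7.0, abs=1e-10)


class TestIonDerivatives:
    def _state(self, **kw):
        return CellState(kw.get("V", -65.0),
                         GatingState(0.05, 0.95, 0.08),
                         IonState(kw.get("K_o", 3.0), kw.get("Na_i", 18.0),
                                  kw.get("Ca_i", 0.0)))

    def test_pump_stoichiometry_exact(self):
        """Pump contributions to dNa_i and dK_o stand in 3 : 2*beta ratio."""
        cell = CellParams(g_Na=0, g_K=0, g_AHP=0, g_KL=0, g_NaL=0, g_ClL=0, g_Ca=0)
        env = MicroenvParams(G_glia=0.0, epsilon=0.0, K_bath=3.0)
        d = ion_derivatives(self._state(K_o=3.0), cell, env)
        pump = pump_flux(18.0, 3.0, env.rho)
        assert d["dNa_i_dt"] == pytest.approx(-3.0 * pump, rel=1e-14)
        assert d["dK_o_dt"] == pytest.approx(-2.0 * env.beta_vol * pump, rel=1e-14)
        # after removing the volume scaling the magnitudes are exactly 3:2
        assert (abs(d["dNa_i_dt"]) / (abs(d["dK_o_dt"]) / env.beta_vol)
                == pytest.approx(1.5, rel=1e-14))

    def test_quiescent_equilibrium(self):
        cell = CellParams(g_Na=0, g_K=0, g_AHP=0, g_KL=0, g_NaL=0, g_ClL=0, g_Ca=0)
        env = MicroenvParams(rho=0.0, G_glia=0.0, epsilon=1.0, K_bath=3.0)
        d = ion_derivatives(self._state(K_o=3.0, Ca_i=0.5), cell, env)
        assert d["dK_o_dt"] == 0.0 and d["dNa_i_dt"] == 0.0
        # Ca relaxes toward zero with its 80 ms time constant
        assert d["dCa_i_dt"] == pytest.approx(-0.5 / 80.0, rel=1e-3)

    def test_compositional_oracle(self, rng):
        cell, env = CellParams(), MicroenvParams()
        s = self._state(V=float(rng.uniform(-80, 0)),
                        K_o=float(rng.uniform(2, 10)),
                        Na_i=float(rng.uniform(10, 30)),
                        Ca_i=float(rng.uniform(0, 1)))
        s.gating = GatingState(*rng.uniform(0.05, 0.95, 3))
        d = ion_derivatives(s, cell, env, coupling_term=0.7)
        rev = nernst_reversals(s.ions, cell, env)
        cur = membrane_currents(s.V, s.gating, rev, s.ions.Ca_i, cell)
        ik = cur["I_K"] + cur["I_KL"] + cur["I_AHP"]
        ina = cur["I_Na"] + cur["I_NaL"]
        pump = pump_flux(s.ions.Na_i, s.ions.K_o, env.rho)
        glia = glial_flux(s.ions.K_o, env.G_glia)
        bath = bath_flux(s.ions.K_o, env.K_bath, env.epsilon)
        expect_ko = (env.gamma * env.beta_vol * ik - 2 * env.beta_vol * pump
                     - glia - bath + 0.7)
        assert d["dK_o_dt"] == pytest.approx(expect_ko, rel=1e-12)
        assert d["dNa_i_dt"] == pytest.approx(-env.gamma * ina - 3 * pump, rel=1e-12)


class TestSynapse:
    def test_chi_limits_and_monotonicity(self):
        assert synaptic_gate_chi(0.0) >= 0.99
        assert synaptic_gate_chi(5.0) <= 0.01
        grid = np.linspace(0, 2, 101)
        chis = [synaptic_gate_chi(e) for e in grid]
        assert all(a >= b for a, b in zip(chis, chis[1:]))

    @given(e1=st.floats(0, 3), e2=st.floats(0, 3))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_chi_monotone_property(self, e1, e2):
        lo, hi = sorted((e1, e2))
        assert synaptic_gate_chi(lo) >= synaptic_gate_chi(hi)

    def _net(self, **syn_kw):
        cell = CellState(-65.0, GatingState(0.05, 0.95, 0.08),
                         IonState(3.0, 18.0, 0.0))
        return NetworkState(pc=cell, in_=CellState(-65.0,
                            GatingState(0.05, 0.95, 0.08),
                            IonState(3.0, 18.0, 0.0)),
                            syn=SynapseState(**syn_kw))

    def test_zero_strength_zero_current(self):
        p = SynapseParams(g_exc=0.0, g_inh=0.0)
        d = synaptic_dynamics(self._net(s_p=0.5, s_i=0.5), p)
        assert d["I_syn_pc"] == 0.0 and d["I_syn_in"] == 0.0

    def test_depolarization_block_silences_inhibition(self):
        p = SynapseParams()
        active = synaptic_dynamics(self._net(s_i=0.5), p)["I_syn_pc"]
        blocked = synaptic_dynamics(self._net(s_i=0.5, eta_i=1.4), p)["I_syn_pc"]
        assert abs(blocked) <= 0.01 * abs(active)

    def test_s_fixed_point(self):
        p = SynapseParams()
        sinf = 1.0 / (1.0 + np.exp(-(-65.0 - p.s_theta) / p.s_slope))
        d = synaptic_dynamics(self._net(s_p=sinf, s_i=sinf), p)
        assert d["ds_p_dt"] == pytest.approx(0.0, abs=1e-14)
        assert d["ds_i_dt"] == pytest.approx(0.0, abs=1e-14)


class TestLateralDiffusion:
    def test_zero_and_conservation(self):
        assert lateral_K_diffusion(4.0, 4.0, 1.0) == (0.0, 0.0)
        a, b = lateral_K_diffusion(3.0, 9.0, 1.0)
        assert a == pytest.approx(6.0)
        assert a + b == 0.0

    @given(kp=st.floats(1, 40), ki=st.floats(1, 40), d=st.floats(0, 5))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_pairwise_conservation_property(self, kp, ki, d):
        a, b = lateral_K_diffusion(kp, ki, d)
        assert a + b == 0.0


class TestFullRHS:
    def test_resting_fixed_point(self, rest_state_polished):
        dy = rhs_single_cell(rest_state_polished, CellParams(), MicroenvParams())
        assert np.abs(dy).max() < 1e-8

    def test_fixed_ion_mode_contract(self, rest_state):
        dy = rhs_single_cell(rest_state, CellParams(), MicroenvParams(),
                             variant="fixed_ions")
        assert dy[5] == 0.0 and dy[6] == 0.0

    def test_crippled_consistency(self, rest_state):
        am = gating_rate_functions(rest_state.V)["alpha_m"]
        full = rhs_single_cell(rest_state, CellParams(), MicroenvParams())
        crip = rhs_single_cell(rest_state, CellParams(), MicroenvParams(),
                               variant="crippled_alpha_m", alpha_m_const=am)
        np.testing.assert_allclose(crip, full, rtol=0, atol=1e-12)

    def test_unknown_variant_rejected(self, rest_state):
        with pytest.raises(ConfigError):
            rhs_single_cell(rest_state, CellParams(), MicroenvParams(),
                            variant="bogus")

    def test_pair_decouples_to_single_cells(self, rest_state, rng):
        pc_cell = CellParams()
        in_cell = CellParams.interneuron()
        env = MicroenvParams(delta=0.0)
        syn = SynapseParams(g_exc=0.0, g_inh=0.0)
        y = rest_state.to_array()
        y_in = y.copy()
        y_in[0] += 3.0
        net = NetworkState(pc=CellState.from_array(y),
                           in_=CellState.from_array(y_in))
        dnet = rhs_coupled_pair(net, pc_cell, env, in_cell, env, syn)
        d_pc = rhs_single_cell(CellState.from_array(y), pc_cell, env)
        d_in = rhs_single_cell(CellState.from_array(y_in), in_cell, env)
        np.testing.assert_allclose(dnet[0:7], d_pc, atol=1e-12)
        np.testing.assert_allclose(dnet[7:14], d_in, atol=1e-12)

    def test_pair_lateral_conservation(self, rest_state):
        env = MicroenvParams(delta=1.3)
        syn = SynapseParams(g_exc=0.0, g_inh=0.0)
        y_in = rest_state.to_array().copy()
        y_in[5] = 9.0   # K_o gradient between the cells
        net = NetworkState(pc=rest_state, in_=CellState.from_array(y_in))
        dnet = rhs_coupled_pair(net, CellParams(), env,
                                CellParams.interneuron(), env, syn)
        d_pc = rhs_single_cell(rest_state, CellParams(), env)
        d_in = rhs_single_cell(CellState.from_array(y_in),
                               CellParams.interneuron(), env)
        lat_pc = dnet[5] - d_pc[5]
        lat_in = dnet[12] - d_in[5]
        assert lat_pc == pytest.approx(-lat_in, rel=1e-10)
        assert lat_pc > 0  # K+ flows toward the lower concentration


class TestGeometryHelpers:
    def test_gamma_from_radius(self):
        assert bio.gamma_from_radius(7.0) == pytest.approx(0.0445, rel=5e-3)
        # the K_o equation's combined factor gamma*beta is the ~0.3 constant
        assert bio.gamma_from_radius(7.0) * 7.0 == pytest.approx(0.31, abs=0.01)

    def test_epsilon_from_geometry(self):
        assert bio.epsilon_from_geometry(2.5e-6, 20.0) == pytest.approx(1.25)

    def test_stim_density(self):
        # 100 pA over a 20 um effective sphere ~ 2 uA/cm^2
        assert bio.stim_density_from_pA(100.0, 20.0) == pytest.approx(1.99, abs=0.01)
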