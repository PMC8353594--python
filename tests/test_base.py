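"""Fermentation core: hydrolysis, redox control, pathway stoichiometry,
methanogenesis kinetics and gas exchange."""

import numpy as np
import pytest

import rumensim as rs
from rumensim import BaseParameters, ParameterSet, StateVector
from rumensim.base import (
    gas_exchange, hydrolysis_fluxes, methanogenesis_flux_base,
    thermodynamic_factor, vfa_pathway_fluxes, FT_SMOOTH,
)
from rumensim.forcing import DietSpec


def make_state(variant="base", **pools):
    from rumensim.base import n_core, state_names
    y = np.zeros(n_core(variant))
    names = state_names(variant)
    for k, v in pools.items():
        y[names.index(k)] = v
    return StateVector(variant, y)


class TestHydrolysis:
    def test_empty_pool_gives_zero_flux(self, vl_diet):
        st = make_state(q_sg=50.0)
        fx = hydrolysis_fluxes(st, vl_diet)
        assert fx["fg_to_he"] == 0.0
        assert fx["sg_to_he"] > 0.0

    def test_first_order_rate_with_study_constant(self):
        # starch hydrolysis at 0.100 h^-1 on a 100 g pool -> 10 g/h
        diet_o = rs.load_diet("O")
        assert diet_o.k_sg_he == 0.100
        st = make_state(q_sg=100.0)
        assert hydrolysis_fluxes(st, diet_o)["sg_to_he"] == pytest.approx(10.0)

    def test_cumulative_hexose_equals_mass_degraded(self, base_params):
        # closed-form single-pool decay: no intake, only starch present
        diet = DietSpec(fg=0, sg=300, wr=0, k_sg_he=0.09)
        k, k_so = diet.k_sg_he, base_params.k_so_ex
        q0, t = 500.0, 6.0
        q_t = q0 * np.exp(-(k + k_so) * t)
        degraded = k / (k + k_so) * (q0 - q_t)
        # trapezoid of the flux along the analytic trajectory
        ts = np.linspace(0.0, t, 20_000)
        flux = k * q0 * np.exp(-(k + k_so) * ts)
        assert np.trapezoid(flux, ts) == pytest.approx(degraded, rel=1e-6)
        # hexose yield is the mass stream divided by the polymer unit mass
        st = make_state(q_sg=q0)
        fx = hydrolysis_fluxes(st, diet, base_params)
        assert fx["he_in"] == pytest.approx(fx["sg_to_he"] / 162.0)


class TestThermodynamicFactor:
    def test_far_from_equilibrium_limit(self, base_params):
        assert thermodynamic_factor(1e-25, 10.0, base_params) == pytest.approx(
            1.0, abs=1e-12)

    def test_equilibrium_gives_zero(self, base_params):
        # choose p so that dG = 0 exactly: p = r * exp(-dG0 / RT)
        r = 12.0
        rt = 8.314462618 * base_params.temperature
        p_eq = r * np.exp(-base_params.dg0_nadh * 1e3 / rt)
        assert thermodynamic_factor(p_eq, r, base_params) == 0.0
        # beyond equilibrium the factor stays clamped at zero
        assert thermodynamic_factor(2 * p_eq, r, base_params) == 0.0

    def test_monotone_in_pressure_and_ratio(self, base_params):
        p = np.logspace(-6, 0, 200)
        ft = thermodynamic_factor(p, 10.0, base_params)
        assert np.all(np.diff(ft) <= 1e-15)
        r = np.logspace(-2, 3, 200)
        ft_r = thermodynamic_factor(1e-3, r, base_params)
        assert np.all(np.diff(ft_r) >= -1e-15)
        assert np.all((ft >= 0) & (ft <= 1))

    def test_rejects_nonpositive_arguments(self, base_params):
        with pytest.raises(ValueError):
            thermodynamic_factor(0.0, 1.0, base_params)
        with pytest.raises(ValueError):
            thermodynamic_factor(1e-3, -1.0, base_params)


class TestPathwayAllocation:
    def test_low_nad_ratio_shuts_down_pathway_h2(self):
        # NADH saturated (r -> 0) routes hexose to the propionate pathway;
        # with a vanishing butyrate share the pathway H2 production vanishes
        pset = ParameterSet(BaseParameters(f_bu_min=1e-9, f_bu_amp=1e-9),
                            rs.InhibitorParameters())
        cap = pset.base.nad_pool * 400.0
        st = make_state(q_he=5.0, q_mi=400.0, q_nadh=cap * (1 - 1e-9),
                        q_h2=1e-3, q_h2g=1e-2)
        fx = vfa_pathway_fluxes(st, pset)
        assert fx.u_he > 0
        # residual bounded by the (vanishing) acetate + butyrate shares
        assert fx.p_h2_ac + fx.p_h2_bu < 4.0 * 2e-9 * fx.u_he
        assert fx.u_ap == pytest.approx(fx.u_he * (1 - pset.base.f_anab),
                                        rel=1e-6)

    def test_thermodynamic_block_stops_hydrogenase(self, base_params):
        # p_H2 far above equilibrium: exact F_T is 0, the smoothed ODE
        # factor is bounded by the smoothing half-width
        pset = ParameterSet(base_params, rs.InhibitorParameters())
        st = make_state(q_he=5.0, q_mi=400.0, q_nadh=5e-3,
                        q_h2=0.5, q_h2g=2.0)
        fx = vfa_pathway_fluxes(st, pset)
        gx = gas_exchange(st, base_params)
        assert thermodynamic_factor(gx.p_h2, fx.r_nad, base_params) == 0.0
        assert fx.f_t <= FT_SMOOTH
        assert fx.u_hyd <= base_params.k_hyd * st.q_nadh * FT_SMOOTH

    def test_hexose_carbon_balance(self, base_params):
        # recover the pathway split from the VFA productions:
        # He_AP = (3/4) Pr, He_A = (Ac - Ac_AP)/2, He_B = Bu
        pset = ParameterSet(base_params, rs.InhibitorParameters())
        st = make_state(q_he=3.0, q_mi=350.0, q_nadh=2e-2,
                        q_h2=2e-4, q_h2g=2e-3)
        fx = vfa_pathway_fluxes(st, pset)
        vfa = fx.vfa_production
        u_ap = 0.75 * vfa["pr"]
        u_a = (vfa["ac"] - (2.0 / 3.0) * u_ap) / 2.0
        u_b = vfa["bu"]
        assert u_a + u_ap + u_b == pytest.approx(
            (1 - base_params.f_anab) * fx.u_he, rel=1e-12)
        assert (u_a, u_ap, u_b) == pytest.approx((fx.u_a, fx.u_ap, fx.u_b))


class TestMethanogenesis:
    def test_half_saturation(self, base_params):
        u = methanogenesis_flux_base(base_params.m_h2_ch4, 10.0, base_params)
        assert u == pytest.approx(base_params.v_h2_ch4 * 10.0 / 2.0)

    def test_no_methanogens_no_flux(self, base_params):
        assert methanogenesis_flux_base(1e-5, 0.0, base_params) == 0.0

    def test_hand_arithmetic(self):
        # v = 0.01, Q_Me = 100, M/C = 3 -> 0.01*100/4 = 0.25 mol/h
        b = BaseParameters(v_h2_ch4=0.01, m_h2_ch4=3.0e-6)
        assert methanogenesis_flux_base(1.0e-6, 100.0, b) == pytest.approx(0.25)

    def test_saturates_at_capacity(self, base_params):
        u = methanogenesis_flux_base(1.0, 5.0, base_params)
        assert u == pytest.approx(base_params.v_h2_ch4 * 5.0, rel=1e-5)

    def test_rejects_nonpositive_concentration(self, base_params):
        with pytest.raises(ValueError):
            methanogenesis_flux_base(0.0, 1.0, base_params)


class TestGasExchange:
    def test_no_dissolved_h2_no_henry_pressure(self, base_params):
        st = make_state(q_mi=100.0)
        gx = gas_exchange(st, base_params, mode="equilibrium")
        assert gx.p_h2 == 0.0
        assert gx.absorption == 0.0

    def test_equilibrium_pressure_is_linear(self, base_params):
        a = gas_exchange(make_state(q_h2=1e-4), base_params, "equilibrium")
        b = gas_exchange(make_state(q_h2=2e-4), base_params, "equilibrium")
        assert b.p_h2 == pytest.approx(2 * a.p_h2)

    def test_headspace_pressure_follows_ideal_gas(self, base_params):
        q_g = 2.0e-3
        gx = gas_exchange(make_state(q_h2g=q_g), base_params, "ideal-gas")
        expected = q_g * 0.0820573661 * base_params.temperature \
            / base_params.v_head
        assert gx.p_h2 == pytest.approx(expected)
        assert gx.emission == pytest.approx(base_params.k_vent * q_g)

    def test_transfer_vanishes_at_henry_equilibrium(self, base_params):
        # headspace in equilibrium with the fluid: no net transfer
        q_h2 = 3.0e-4
        p = (q_h2 / base_params.v_fl) / base_params.henry_h2
        q_g = p * base_params.v_head / (0.0820573661 * base_params.temperature)
        gx = gas_exchange(make_state(q_h2=q_h2, q_h2g=q_g), base_params)
        assert gx.transfer == pytest.approx(0.0, abs=1e-12)

    def test_unknown_mode_rejected(self, base_params):
        with pytest.raises(ValueError):
            gas_exchange(make_state(), base_params, "bogus")
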