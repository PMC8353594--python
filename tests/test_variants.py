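"""Variant flux laws, inhibition kinetics and right-hand-side assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rumensim as rs
from rumensim import (
    BaseParameters, DosingSchedule, ParameterSet, first_order_outflux,
    h2_sink_coupling, mass_action_flux, methanogenesis_flux_base,
    methanogenesis_flux_inhibited,
)
from rumensim.base import n_core, state_names
from rumensim.variants import (
    NumericalStateError, audit_names, flux_report, n_states, rhs, rhs_kernel,
)

KINDS = {"3nop": "3nop", "3nop-no2": "3nop", "no3": "no3", "no3-no2": "no3"}


class TestElementaryFluxes:
    def test_first_order_examples(self):
        assert first_order_outflux(0.0, 0.3) == 0.0
        # slow nitrate absorption: 0.30 h^-1 on a 0.01 mol pool
        assert first_order_outflux(0.01, 0.30) == pytest.approx(3.0e-3)
        with pytest.raises(ValueError):
            first_order_outflux(-1.0, 0.3)

    def test_mass_action_table_value(self):
        # NO3- -> NH3 at the tabulated rate constant
        assert mass_action_flux(6.99, [1.0, 0.1, 0.01]) == pytest.approx(
            6.99e-3)

    def test_mass_action_zero_substrate(self):
        assert mass_action_flux(5.0, [2.0, 0.0, 1.0]) == 0.0

    @settings(max_examples=25, derandomize=True)
    @given(q=st.floats(1e-6, 10.0), scale=st.floats(0.1, 10.0))
    def test_mass_action_linearity(self, q, scale):
        base = mass_action_flux(1.5, [300.0, q, 2e-4])
        assert mass_action_flux(1.5, [300.0, scale * q, 2e-4]) == \
            pytest.approx(scale * base, rel=1e-12)

    def test_inert_pool_decays_at_summed_rate(self, vl_diet):
        """3-NOP between meals decays like exp(-(k_ab + k_fl_ex) t)."""
        pset = ParameterSet.default("3nop")
        sch = DosingSchedule(supplement_kind="3nop", c_supp=1e-3)
        grid = np.arange(230.0, 239.0, 0.25)  # no intake in this window
        traj = rs.simulate("3nop", pset, vl_diet, sch, sampling=grid,
                           audit=False)
        q = traj.col("q_3nop")
        slope = np.polyfit(traj.times, np.log(q), 1)[0]
        expected = -(pset.inhibitor.k_3nop_ab + pset.base.k_fl_ex)
        assert slope == pytest.approx(expected, rel=1e-3)


class TestInhibitedMethanogenesis:
    def test_zero_inhibitor_is_base_flux(self, base_params):
        for c in (1e-7, 1e-6, 1e-5, 1e-4):
            inhibited = methanogenesis_flux_inhibited(
                c, 3.0, 0.0, 1.93e-5, base_params)
            assert inhibited == methanogenesis_flux_base(c, 3.0, base_params)

    def test_denominator_hand_arithmetic(self, base_params):
        # inhibitor at J and M/C = 1: v Q / 3
        c = base_params.m_h2_ch4
        u = methanogenesis_flux_inhibited(c, 2.0, 5e-4, 5e-4, base_params)
        assert u == pytest.approx(base_params.v_h2_ch4 * 2.0 / 3.0)

    def test_inhibitor_at_j_adds_one_to_denominator(self, base_params):
        # the tabulated MCR constant: C_3NOP = J -> denominator + 1
        j = 1.93e-5
        c = 1e-5
        u = methanogenesis_flux_inhibited(c, 1.0, j, j, base_params)
        expected = base_params.v_h2_ch4 / (1 + base_params.m_h2_ch4 / c + 1)
        assert u == pytest.approx(expected, rel=1e-14)

    @settings(max_examples=25, derandomize=True)
    @given(lo=st.floats(0.0, 1e-3), hi=st.floats(1.1e-3, 1e-1))
    def test_strictly_decreasing_in_inhibitor(self, base_params, lo, hi):
        args = (1e-5, 2.0)
        u_lo = methanogenesis_flux_inhibited(*args, lo, 1.93e-5, base_params)
        u_hi = methanogenesis_flux_inhibited(*args, hi, 1.93e-5, base_params)
        assert u_hi < u_lo

    def test_invalid_inhibition_constant(self, base_params):
        with pytest.raises(ValueError, match="configuration"):
            methanogenesis_flux_inhibited(1e-5, 1.0, 1e-5, 0.0, base_params)


class TestH2SinkCoupling:
    def test_direct_route_uses_four_equivalents(self):
        assert h2_sink_coupling(u_no3_nh3=0.1) == pytest.approx(0.4)

    def test_split_route_total_matches_direct(self):
        assert h2_sink_coupling(u_no3_no2=0.1, u_no2_nh3=0.1) == \
            pytest.approx(0.4)

    @settings(max_examples=25, derandomize=True)
    @given(flux=st.floats(1e-6, 10.0))
    def test_route_split_equivalence(self, flux):
        """A fully reduced split stream consumes the same H2 as direct
        reduction of the same molar nitrate stream."""
        direct = h2_sink_coupling(u_no3_nh3=flux)
        split = h2_sink_coupling(u_no3_no2=flux, u_no2_nh3=flux)
        assert split == pytest.approx(direct, rel=1e-12)


class TestRhsAssembly:
    @pytest.mark.parametrize("variant", ["base"] + list(KINDS))
    @pytest.mark.parametrize("audit", [False, True])
    def test_kernel_matches_reference_implementation(
            self, variant, audit, vl_diet, random_states):
        """The compiled kernel and the readable flux-based RHS agree to
        near machine precision on random physical states."""
        pset = ParameterSet.default(variant)
        kind = KINDS.get(variant, "none")
        sch = DosingSchedule(supplement_kind=kind,
                             c_supp=0.1 if kind == "no3" else
                             (1e-3 if kind == "3nop" else 0.0))
        for gas_mode in ("ideal-gas", "equilibrium"):
            f = rhs_kernel(variant, pset, vl_diet, sch, audit, gas_mode)
            for y_core in random_states[variant]:
                y = np.concatenate(
                    [y_core, np.zeros(len(audit_names(variant)))]) \
                    if audit else y_core
                for t in (0.3, 7.7):
                    dy_k = f(t, y)
                    dy_p = rhs(variant, t, y, pset, vl_diet, sch,
                               audit=audit, gas_mode=gas_mode)
                    scale = np.maximum(np.abs(dy_p), 1e-30)
                    assert np.max(np.abs(dy_k - dy_p) / scale) < 1e-12

    def test_nan_state_identifies_offending_flux(self, vl_diet):
        pset = ParameterSet.default("no3")
        sch = DosingSchedule(supplement_kind="no3", c_supp=0.1)
        y = np.ones(n_states("no3"))
        y[state_names("no3").index("q_no3")] = np.nan
        with pytest.raises(NumericalStateError, match="u_no3"):
            rhs("no3", 1.0, y, pset, vl_diet, sch)

    def test_dimension_mismatch_rejected(self, vl_diet):
        pset = ParameterSet.default("no3")
        sch = DosingSchedule(supplement_kind="no3", c_supp=0.1)
        with pytest.raises(ValueError, match="dimension"):
            rhs("no3", 1.0, np.ones(3), pset, vl_diet, sch)

    def test_nitrogen_moiety_closure_is_structural(self, vl_diet,
                                                   random_states):
        """In the 3-NOP+nitrite model, d(Q_3NOP + Q_NO2 + Q_NO3i)/dt plus
        absorption, passage and nitrite exit equals the influx exactly."""
        variant = "3nop-no2"
        pset = ParameterSet.default(variant)
        sch = DosingSchedule(supplement_kind="3nop", c_supp=1e-3)
        names = state_names(variant)
        i0 = names.index("q_3nop")
        for y in random_states[variant]:
            for t in (0.2, 6.0):
                dy = rhs(variant, t, y, pset, vl_diet, sch)
                fx = flux_report(variant, t, y, pset, vl_diet, sch)
                lhs = dy[i0] + dy[i0 + 1] + dy[i0 + 2] \
                    + fx["u_3nop_ab"] + fx["u_3nop_ex"] + fx["u_no2_ex"]
                assert lhs == pytest.approx(fx["supp_in"], abs=1e-12)

    def test_flux_signs_balance_h2_pool(self, vl_diet, random_states):
        """dQ_H2/dt equals production minus every named H2 sink."""
        for variant in ("no3", "no3-no2"):
            pset = ParameterSet.default(variant)
            sch = DosingSchedule(supplement_kind="no3", c_supp=0.16)
            for y in random_states[variant][:3]:
                fx = flux_report(variant, 0.5, y, pset, vl_diet, sch)
                dy = rhs(variant, 0.5, y, pset, vl_diet, sch)
                expected = (fx["h2_prod"] - fx["u_meth"] - fx["h2_transfer"]
                            - fx["h2_absorb"] - fx["h2_passage"]
                            - fx["h2_sink"])
                assert dy[state_names(variant).index("q_h2")] == \
                    pytest.approx(expected, rel=1e-14)
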