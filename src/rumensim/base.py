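"""The shared fermentation core: pools, flux laws and redox control.

This module reconstructs the un-supplemented rumen fermentation model the
four inhibitor variants extend: first-order hydrolysis of feed
carbohydrates to hexose, microbial hexose fermentation split over three
VFA pathways whose allocation responds to the NAD+/NADH ratio,
hydrogenase-mediated NADH oxidation under thermodynamic control by the
hydrogen partial pressure, Michaelis-Menten hydrogenotrophic
methanogenesis, and gas exchange of dissolved H2 with the headspace.

Pathway stoichiometry per mol hexose catabolized
------------------------------------------------
========  ============================  =====  ==========
pathway   products                      H2     net NADH
========  ============================  =====  ==========
A         2 Ac-                         +2     +2
AP        2/3 Ac- + 4/3 Pr-             0      -2/3
B         1 Bu-                         +2     0
========  ============================  =====  ==========

Pathway A is promoted at a high NAD+/NADH ratio r (it reduces NAD+), AP
at a low ratio (it reoxidizes NADH); the butyrate pathway, an alternative
electron sink, takes the share ``f_bu_min + f_bu_amp*(1 - g)`` with
``g = r/(K_r + r)``, i.e. it too is promoted when NADH accumulates.  A
hydrogenase flux ``k_hyd * Q_NADH * F_T`` reoxidizes NADH to H2 under
control of the thermodynamic potential factor F_T.

All functions here are pure and operate on state snapshots; the ODE
right-hand sides are assembled in :mod:`rumensim.variants`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List

import numpy as np

from . import params as P
from .forcing import DietSpec
from .params import BaseParameters, ParameterSet, Variant

__all__ = [
    "BASE_STATE_NAMES", "state_names", "n_core", "StateVector",
    "hydrolysis_fluxes", "thermodynamic_factor", "vfa_pathway_fluxes",
    "methanogenesis_flux_base", "gas_exchange",
    "PathwayFluxes", "GasExchange", "DEFAULT_GAS_MODE",
]

#: Default gas handling: dynamic headspace pool (see :func:`gas_exchange`).
DEFAULT_GAS_MODE = "ideal-gas"

# ---------------------------------------------------------------------------
# State layout
# ---------------------------------------------------------------------------

#: Pools of the fermentation core, in state-vector order.
BASE_STATE_NAMES: List[str] = [
    "q_fg",    # degradable fiber [g]
    "q_sg",    # degradable starch [g]
    "q_wr",    # soluble sugars [g]
    "q_pg",    # degradable protein [g] (inert mass stream)
    "q_he",    # hexose [mol]
    "q_mi",    # fermentative microbes [g]
    "q_me",    # methanogens [g]
    "q_ac",    # acetate [mol]
    "q_pr",    # propionate [mol]
    "q_bu",    # butyrate [mol]
    "q_h2",    # dissolved H2 [mol]
    "q_h2g",   # headspace H2 [mol]
    "q_nadh",  # reduced NAD [mol]; NAD+ = nad_pool*q_mi - q_nadh
]

N_BASE = len(BASE_STATE_NAMES)

# index constants for the core pools
(I_FG, I_SG, I_WR, I_PG, I_HE, I_MI, I_ME, I_AC, I_PR, I_BU,
 I_H2, I_H2G, I_NADH) = range(N_BASE)

#: Supplement pools appended per variant, after the core pools.
VARIANT_STATE_NAMES: Dict[Variant, List[str]] = {
    Variant.BASE: [],
    Variant.NOP: ["q_3nop"],
    Variant.NOP_NO2: ["q_3nop", "q_no2", "q_no3_i"],  # q_no3_i: intracellular
    Variant.NO3: ["q_no3"],
    Variant.NO3_NO2: ["q_no3", "q_no2"],
}


def state_names(variant: Variant) -> List[str]:
    """Names of the core pools of one variant, in state-vector order."""
    return BASE_STATE_NAMES + VARIANT_STATE_NAMES[Variant.parse(variant)]


def n_core(variant: Variant) -> int:
    return len(state_names(variant))


@dataclass
class StateVector:
    """A named view of one model variant's pools at one instant."""

    variant: Variant
    y: np.ndarray

    def __post_init__(self) -> None:
        self.variant = Variant.parse(self.variant)
        self.y = np.asarray(self.y, float)
        if self.y.shape[0] < n_core(self.variant):
            raise ValueError(
                f"state of {self.variant.value} needs >= "
                f"{n_core(self.variant)} entries, got {self.y.shape[0]}")

    def __getattr__(self, name: str) -> float:
        names = state_names(self.variant)
        try:
            return float(self.y[names.index(name)])
        except ValueError:
            raise AttributeError(name) from None

    def nad_cap(self, base: BaseParameters) -> float:
        return base.nad_pool * self.q_mi

    def q_nad(self, base: BaseParameters) -> float:
        return self.nad_cap(base) - self.q_nadh

    def r_nad(self, base: BaseParameters) -> float:
        """NAD+/NADH ratio, with guards at the pool boundaries."""
        return float(_r_nad(self.y[I_MI], self.y[I_NADH], base.nad_pool))

    def c(self, name: str, base: BaseParameters) -> float:
        """Concentration Q_i / V_Fl [M] of a molar pool."""
        return getattr(self, name) / base.v_fl


def _r_nad(q_mi, q_nadh, nad_pool):
    """NAD+/NADH with the NADH pool clamped inside (0, cap)."""
    cap = nad_pool * np.maximum(q_mi, 1e-300)
    nadh = np.clip(q_nadh, 1e-12 * cap, (1.0 - 1e-12) * cap)
    return (cap - nadh) / nadh


# ---------------------------------------------------------------------------
# Flux laws
# ---------------------------------------------------------------------------

def hydrolysis_fluxes(state: StateVector, diet: DietSpec,
                      base: BaseParameters | None = None) -> Dict[str, float]:
    """First-order hydrolysis of the three carbohydrate pools.

    Returns mass degradation rates [g h^-1] and the summed hexose
    generation ``he_in`` [mol h^-1]; polymers count 162 g per mol hexose
    (anhydro-glucose), soluble sugars 180.  Fiber and starch rates come
    from the diet; soluble sugars hydrolyze at the diet-independent rate
    ``base.k_wr_he``.
    """
    base = base or BaseParameters()
    u_fg, u_sg, u_wr, he_in = _hydrolysis(state.y, diet, base)
    return {"fg_to_he": u_fg, "sg_to_he": u_sg, "wr_to_he": u_wr,
            "he_in": he_in}


def _hydrolysis(y, diet: DietSpec, base: BaseParameters):
    u_fg = diet.k_fg_he * max(y[I_FG], 0.0)
    u_sg = diet.k_sg_he * max(y[I_SG], 0.0)
    u_wr = base.k_wr_he * max(y[I_WR], 0.0)
    he_in = (u_fg + u_sg) / P.MW_POLY_HEXOSE + u_wr / P.MW_SOL_HEXOSE
    return u_fg, u_sg, u_wr, he_in


def thermodynamic_factor(p_h2, r_nad, base: BaseParameters):
    """Thermodynamic potential factor F_T in [0, 1].

    Scales the hydrogenase rate (NADH -> NAD+ + H2) by how far the
    reaction is from equilibrium:

        dG = dG0 + R*T*ln(p_H2 / r_NAD),
        F_T = max(0, 1 - exp(dG / (chi*R*T))).

    F_T -> 1 far from equilibrium (low p_H2, high NAD+/NADH); F_T = 0 at
    or beyond equilibrium, i.e. complete thermodynamic inhibition.  F_T
    is non-increasing in p_H2 and non-decreasing in r_NAD.
    """
    p_h2 = np.asarray(p_h2, float)
    r_nad = np.asarray(r_nad, float)
    if (p_h2 <= 0).any() or (r_nad <= 0).any():
        raise ValueError("p_h2 and r_nad must be > 0")
    rt = P.R_GAS * base.temperature
    dg = base.dg0_nadh * 1e3 + rt * np.log(p_h2 / r_nad)
    ft = 1.0 - np.exp(dg / (base.ft_chi * rt))
    ft = np.clip(ft, 0.0, 1.0)
    return ft if ft.ndim else float(ft)


#: Half-width of the quadratic smoothing of F_T's clamp at zero.  The
#: exact law max(0, 1-exp(.)) has a derivative jump at equilibrium that
#: makes the stiff solver chatter when a trajectory rides the F_T = 0
#: manifold (which inhibited runs do for hours); the smoothed positive
#: part 0.5*(f + sqrt(f^2 + delta^2)) differs from it by < delta/2.
FT_SMOOTH = 0.03


def _ft_kernel(p_h2: float, r_nad: float, dg0_j: float, chi: float, t_k: float) -> float:
    """Scalar F_T (smoothed at the zero clamp) with a floor on p_h2 so a
    vanishing H2 pool maps to F_T = 1."""
    rt = P.R_GAS * t_k
    p = max(p_h2, 1e-30)
    dg = dg0_j + rt * np.log(p / r_nad)
    f = 1.0 - np.exp(min(dg / (chi * rt), 50.0))
    ft = 0.5 * (f + np.sqrt(f * f + FT_SMOOTH * FT_SMOOTH))
    return min(ft, 1.0)


@dataclass
class PathwayFluxes:
    """Hexose pathway allocation and the coupled H2/NADH fluxes.

    ``u_a``/``u_ap``/``u_b`` are hexose catabolism rates [mol h^-1];
    ``p_h2_ac``/``p_h2_bu`` the H2 productions coupled to acetate and
    butyrate formation; ``u_hyd`` the hydrogenase NADH->H2 flux;
    ``d_nadh`` the net NADH production of fermentation plus hydrogenase.
    """

    u_he: float
    u_a: float
    u_ap: float
    u_b: float
    p_h2_ac: float
    p_h2_bu: float
    u_hyd: float
    d_nadh: float
    f_t: float
    r_nad: float

    @property
    def vfa_production(self) -> Dict[str, float]:
        return {
            "ac": 2.0 * self.u_a + (2.0 / 3.0) * self.u_ap,
            "pr": (4.0 / 3.0) * self.u_ap,
            "bu": self.u_b,
        }


def vfa_pathway_fluxes(state: StateVector, pset: ParameterSet,
                       gas_mode: str = DEFAULT_GAS_MODE) -> PathwayFluxes:
    """Allocate hexose catabolism over the three VFA pathways.

    The acetate pathway share rises with the NAD+/NADH ratio r (it needs
    NAD+ as electron acceptor) and the acetate+propionate pathway share
    falls with it, via the Monod factor g = r/(K_r + r); the butyrate
    pathway takes the share ``f_bu_min + f_bu_amp*(1-g)``, growing when
    NADH accumulates.  The hydrogenase flux ``k_hyd * Q_NADH * F_T``
    converts NADH to H2.
    """
    b = pset.base
    c_he = max(state.q_he, 0.0) / b.v_fl
    u_he = b.v_he * max(state.q_mi, 0.0) * c_he / (b.m_he + c_he) \
        if c_he > 0 else 0.0
    u_cat = (1.0 - b.f_anab) * u_he
    r = state.r_nad(b)
    g = r / (b.k_r_alloc + r)
    f_b = b.f_bu_min + b.f_bu_amp * (1.0 - g)
    u_a = (1.0 - f_b) * g * u_cat
    u_ap = (1.0 - f_b) * (1.0 - g) * u_cat
    u_b = f_b * u_cat
    gx = gas_exchange(state, b, gas_mode)
    ft = _ft_kernel(gx.p_h2, r, b.dg0_nadh * 1e3, b.ft_chi, b.temperature)
    cap = state.nad_cap(b)
    nadh = min(max(state.q_nadh, 0.0), cap)
    u_hyd = b.k_hyd * nadh * ft
    d_nadh = 2.0 * u_a - (2.0 / 3.0) * u_ap - u_hyd
    return PathwayFluxes(
        u_he=u_he, u_a=u_a, u_ap=u_ap, u_b=u_b,
        p_h2_ac=2.0 * u_a, p_h2_bu=2.0 * u_b,
        u_hyd=u_hyd, d_nadh=d_nadh, f_t=ft, r_nad=r)


def methanogenesis_flux_base(c_h2: float, q_me: float,
                             base: BaseParameters) -> float:
    """Uninhibited hydrogenotrophic methanogenesis [mol H2 h^-1].

    Michaelis-Menten in the dissolved H2 concentration:
    ``v * Q_Me / (1 + M/C_H2)``.  The CH4 emission rate is one quarter of
    this flux (4 H2 per CH4).
    """
    if c_h2 <= 0:
        raise ValueError("c_h2 must be > 0")
    if q_me < 0:
        raise ValueError("q_me must be >= 0")
    return base.v_h2_ch4 * q_me / (1.0 + base.m_h2_ch4 / c_h2)


@dataclass
class GasExchange:
    """Dissolved/headspace H2 exchange at one instant."""

    p_h2: float        # H2 partial pressure used by the model [atm]
    transfer: float    # net liquid -> headspace flux [mol h^-1]
    emission: float    # headspace washout (measured emission) [mol h^-1]
    absorption: float  # absorption across the rumen wall [mol h^-1]


def gas_exchange(state: StateVector, base: BaseParameters,
                 mode: str = DEFAULT_GAS_MODE) -> GasExchange:
    """Gas-phase handling of H2.

    The liquid exchanges H2 with the headspace through a two-film flux
    ``k_h2_em * (Q_H2 - henry_H2 * p_head * V_Fl)`` (positive when the
    fluid is supersaturated relative to the headspace), the headspace is
    washed out (eructation) at ``k_vent`` -- that washout is the measured
    emission -- and the fluid additionally loses H2 by absorption
    (``k_h2_ab``) and passage.

    ``mode`` selects the partial pressure the thermodynamic control and
    the reported p_H2 use: ``"ideal-gas"`` (default) reads the dynamic
    headspace pool, p_H2 = Q_H2g*R*T/V_head, which low-pass filters the
    fast dissolved pool with the vent time constant; ``"equilibrium"``
    assumes instant Henry's-law equilibrium, p_H2 = C_H2/henry_H2.  The
    exchange fluxes are identical in both modes.
    """
    q_h2 = max(state.q_h2, 0.0)
    q_h2g = max(state.q_h2g, 0.0)
    p_head = q_h2g * P.R_L_ATM * base.temperature / base.v_head
    if mode == "equilibrium":
        p = (q_h2 / base.v_fl) / base.henry_h2
    elif mode == "ideal-gas":
        p = p_head
    else:
        raise ValueError("mode must be 'equilibrium' or 'ideal-gas'")
    return GasExchange(
        p_h2=p,
        transfer=base.k_h2_em * (q_h2 - base.henry_h2 * p_head * base.v_fl),
        emission=base.k_vent * q_h2g,
        absorption=base.k_h2_ab * q_h2,
    )
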