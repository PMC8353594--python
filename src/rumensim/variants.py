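"""Supplement-specific extensions and the assembled ODE right-hand sides.

Four variants extend the fermentation core of :mod:`rumensim.base`:

* ``3nop`` -- a 3-NOP pool fed by intake, lost by absorption and fluid
  passage; 3-NOP inhibits methanogenesis through an extra
  ``C_3NOP / J_MCR`` term in the Michaelis-Menten denominator.
* ``3nop-no2`` -- additionally converts 3-NOP to nitrate and nitrite
  inside the archaea (mass action in Q_Me and Q_3NOP); the intracellular
  nitrite adds to the MCR inhibition term and leaves only with the
  methanogen passage stream; the intracellular nitrate is a sink-only
  bookkeeping pool.
* ``no3`` -- a nitrate pool reduced to ammonia by the fermentative
  microbes (mass action in Q_Mi, Q_NO3 and Q_H2), consuming 4 mol H2 per
  mol NO3-; no methanogenic inhibition.
* ``no3-no2`` -- splits the reduction into NO3- -> NO2- (1 H2) and
  NO2- -> NH3 (3 H2); ruminal nitrite inhibits methanogenesis through
  ``C_NO2 / J_NO2``.

Two equivalent right-hand-side implementations are provided: a readable
pure-Python one built from the public flux operations (:func:`rhs`,
:func:`flux_report`) that also performs finite-ness diagnostics, and a
numba-compiled kernel (:func:`rhs_kernel`) used by the integration
engine.  A test asserts they agree to near machine precision.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Tuple

import numpy as np

from . import params as P
from .base import (
    DEFAULT_GAS_MODE, I_AC, I_BU, I_FG, I_H2, I_H2G, I_HE, I_ME, I_MI,
    I_NADH, I_PG, I_PR, I_SG, I_WR, N_BASE, StateVector, _ft_kernel,
    _hydrolysis, _r_nad, n_core, state_names,
)
from .forcing import DietSpec, DosingSchedule, intake_rate
from .params import BaseParameters, ParameterSet, Variant

try:  # numba accelerates the kernel; the python path remains authoritative
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]

__all__ = [
    "NumericalStateError",
    "first_order_outflux", "mass_action_flux",
    "methanogenesis_flux_inhibited", "h2_sink_coupling",
    "rhs", "flux_report", "rhs_kernel", "pack_problem",
    "audit_names", "n_states", "VARIANT_CODES",
]

VARIANT_CODES = {
    Variant.BASE: 0, Variant.NOP: 1, Variant.NOP_NO2: 2,
    Variant.NO3: 3, Variant.NO3_NO2: 4,
}

GAS_MODE_CODES = {"equilibrium": 0, "ideal-gas": 1}

#: H2 bookkeeping integrals, shared by all variants (audit block head).
H2_AUDIT_NAMES = [
    "cum_h2_prod",   # pathway + hydrogenase H2 production
    "cum_h2_meth",   # H2 used by methanogenesis
    "cum_h2_em",     # liquid -> headspace transfer
    "cum_h2_ab",     # absorbed across the rumen wall
    "cum_h2_ex",     # passed with the fluid
    "cum_h2_sink",   # consumed by nitrate/nitrite reduction
]

SUPPLEMENT_AUDIT_NAMES: Dict[Variant, List[str]] = {
    Variant.BASE: [],
    Variant.NOP: ["cum_in", "cum_ab", "cum_ex"],
    Variant.NOP_NO2: ["cum_in", "cum_ab", "cum_ex",
                      "cum_to_no3", "cum_to_no2", "cum_no2_ex"],
    Variant.NO3: ["cum_in", "cum_no3_ab", "cum_no3_ex", "cum_no3_nh3"],
    Variant.NO3_NO2: ["cum_in", "cum_no3_ab", "cum_no3_ex", "cum_no3_no2",
                      "cum_no2_ab", "cum_no2_ex", "cum_no2_nh3"],
}


class NumericalStateError(ValueError):
    """A flux evaluated to NaN/Inf; the message names the offending flux."""


def audit_names(variant: Variant) -> List[str]:
    variant = Variant.parse(variant)
    return H2_AUDIT_NAMES + SUPPLEMENT_AUDIT_NAMES[variant]


def n_states(variant: Variant, audit: bool = False) -> int:
    variant = Variant.parse(variant)
    return n_core(variant) + (len(audit_names(variant)) if audit else 0)


def full_state_names(variant: Variant, audit: bool = False) -> List[str]:
    names = state_names(variant)
    return names + audit_names(variant) if audit else names


# ---------------------------------------------------------------------------
# Elementary flux operations
# ---------------------------------------------------------------------------

def first_order_outflux(q: float, k: float) -> float:
    """First-order removal flux k*Q (absorption or passage) [mol h^-1]."""
    if q < 0 or k < 0:
        raise ValueError("first_order_outflux requires q >= 0 and k >= 0")
    return k * q


def mass_action_flux(k: float, factors: Iterable[float]) -> float:
    """Product of a rate constant and any number of pool sizes.

    Used for the microbially mediated reductions (e.g. NO3- -> NH3 is
    ``k * Q_Mi * Q_NO3 * Q_H2``) and the archaeal 3-NOP conversions
    (``k * Q_Me * Q_3NOP``).  Zero whenever any factor is zero.
    """
    if k < 0:
        raise ValueError("rate constant must be >= 0")
    out = k
    for f in factors:
        if f < 0:
            raise ValueError("mass-action factors must be >= 0")
        out *= f
    return out


def methanogenesis_flux_inhibited(c_h2: float, q_me: float,
                                  inhibitor_conc: float, j: float,
                                  base: BaseParameters) -> float:
    """Methanogenic H2 uptake with competitive-style inhibition [mol h^-1].

    ``v * Q_Me / (1 + M/C_H2 + C_inh/J)``: strictly decreasing in the
    inhibitor concentration and identical to the uninhibited flux at
    ``inhibitor_conc = 0``.  ``j`` is the inhibition constant [M]; for
    the 3-NOP variants the inhibitor concentration is C_3NOP (plus the
    intracellular C_NO2 in the nitrite extension), for the
    nitrate+nitrite variant the ruminal C_NO2.
    """
    if j <= 0:
        raise ValueError("inhibition constant j must be > 0 (configuration)")
    if c_h2 <= 0:
        raise ValueError("c_h2 must be > 0")
    if q_me < 0 or inhibitor_conc < 0:
        raise ValueError("q_me and inhibitor_conc must be >= 0")
    return base.v_h2_ch4 * q_me / (1.0 + base.m_h2_ch4 / c_h2
                                   + inhibitor_conc / j)


def h2_sink_coupling(u_no3_nh3: float = 0.0, u_no3_no2: float = 0.0,
                     u_no2_nh3: float = 0.0) -> float:
    """H2 consumed by the nitrate reduction routes [mol H2 h^-1].

    Direct reduction NO3- -> NH3 consumes 4 H2 per NO3-; the split route
    consumes 1 H2 for NO3- -> NO2- and 3 H2 for NO2- -> NH3, so a fully
    reduced split stream consumes the same 4 H2 in total.
    """
    if min(u_no3_nh3, u_no3_no2, u_no2_nh3) < 0:
        raise ValueError("reduction fluxes must be >= 0")
    return 4.0 * u_no3_nh3 + 1.0 * u_no3_no2 + 3.0 * u_no2_nh3


# ---------------------------------------------------------------------------
# Pure-python right-hand side (authoritative / diagnostic path)
# ---------------------------------------------------------------------------

def _meth_safe(c_h2: float, q_me: float, inh: float, base: BaseParameters) -> float:
    """Inhibited methanogenesis in the division-safe form v*Me*C/(C+M+C*inh)."""
    if c_h2 <= 0.0:
        return 0.0
    return (base.v_h2_ch4 * q_me * c_h2
            / (c_h2 + base.m_h2_ch4 + c_h2 * inh))


def flux_report(variant: Variant, t: float, y: np.ndarray,
                pset: ParameterSet, diet: DietSpec,
                schedule: DosingSchedule,
                gas_mode: str = DEFAULT_GAS_MODE) -> Dict[str, float]:
    """All instantaneous fluxes of one variant at state ``y`` [per hour].

    This is the readable reference implementation the compiled kernel
    mirrors; it is also used to identify the offending flux when the
    system goes non-finite.
    """
    variant = Variant.parse(variant)
    b, inh_p = pset.base, pset.inhibitor
    y = np.asarray(y, float)
    st = StateVector(variant, y)

    d_dm = float(intake_rate(t, schedule))
    fx: Dict[str, float] = {"d_dm": d_dm}

    # hydrolysis and intake of solids
    u_fg, u_sg, u_wr, he_in = _hydrolysis(y, diet, b)
    fx.update(u_fg_he=u_fg, u_sg_he=u_sg, u_wr_he=u_wr, he_in=he_in)

    # hexose uptake and pathway allocation
    q_mi = max(y[I_MI], 0.0)
    c_he = max(y[I_HE], 0.0) / b.v_fl
    u_he = b.v_he * q_mi * c_he / (b.m_he + c_he) if c_he > 0 else 0.0
    u_cat = (1.0 - b.f_anab) * u_he
    r = float(_r_nad(y[I_MI], y[I_NADH], b.nad_pool))
    g = r / (b.k_r_alloc + r)
    f_b = b.f_bu_min + b.f_bu_amp * (1.0 - g)
    u_a = (1.0 - f_b) * g * u_cat
    u_ap = (1.0 - f_b) * (1.0 - g) * u_cat
    u_b = f_b * u_cat
    fx.update(u_he=u_he, u_a=u_a, u_ap=u_ap, u_b=u_b, r_nad=r)

    # gas state and hydrogenase
    q_h2 = max(y[I_H2], 0.0)
    q_h2g = max(y[I_H2G], 0.0)
    c_h2 = q_h2 / b.v_fl
    p_head = q_h2g * P.R_L_ATM * b.temperature / b.v_head
    p_h2 = c_h2 / b.henry_h2 if gas_mode == "equilibrium" else p_head
    ft = _ft_kernel(p_h2, r, b.dg0_nadh * 1e3, b.ft_chi, b.temperature)
    cap = b.nad_pool * q_mi
    nadh = min(max(y[I_NADH], 0.0), cap)
    u_hyd = b.k_hyd * nadh * ft
    fx.update(p_h2=p_h2, f_t=ft, u_hyd=u_hyd, nadh_eff=nadh)

    # variant pools, inhibition term and H2 sinks
    inh = 0.0
    if variant is Variant.NOP:
        q3 = max(y[N_BASE], 0.0)
        inh = (q3 / b.v_fl) / inh_p.j_mcr
        fx.update(
            supp_in=d_dm * schedule.c_supp,
            u_3nop_ab=inh_p.k_3nop_ab * q3,
            u_3nop_ex=b.k_fl_ex * q3,
        )
    elif variant is Variant.NOP_NO2:
        q3 = max(y[N_BASE], 0.0)
        qno2 = max(y[N_BASE + 1], 0.0)
        q_me = max(y[I_ME], 0.0)
        inh = ((q3 + qno2) / b.v_fl) / inh_p.j_mcr
        fx.update(
            supp_in=d_dm * schedule.c_supp,
            u_3nop_ab=inh_p.k_3nop_ab * q3,
            u_3nop_ex=b.k_fl_ex * q3,
            u_3nop_no3=inh_p.k_3nop_no3 * q_me * q3,
            u_3nop_no2=inh_p.k_3nop_no2 * q_me * q3,
            u_no2_ex=b.k_me_ex * qno2,
        )
    elif variant is Variant.NO3:
        qno3 = max(y[N_BASE], 0.0)
        u_red = inh_p.k_no3_nh3 * q_mi * qno3 * q_h2
        fx.update(
            supp_in=d_dm * schedule.c_supp,
            u_no3_ab=inh_p.k_nox_ab * qno3,
            u_no3_ex=b.k_fl_ex * qno3,
            u_no3_nh3=u_red,
            h2_sink=4.0 * u_red,
        )
    elif variant is Variant.NO3_NO2:
        qno3 = max(y[N_BASE], 0.0)
        qno2 = max(y[N_BASE + 1], 0.0)
        inh = (qno2 / b.v_fl) / inh_p.j_no2
        u_red1 = inh_p.k_no3_no2 * q_mi * qno3 * q_h2
        u_red2 = inh_p.k_no2_nh3 * q_mi * qno2 * q_h2
        fx.update(
            supp_in=d_dm * schedule.c_supp,
            u_no3_ab=inh_p.k_nox_ab * qno3,
            u_no3_ex=b.k_fl_ex * qno3,
            u_no3_no2=u_red1,
            u_no2_ab=inh_p.k_nox_ab * qno2,
            u_no2_ex=b.k_fl_ex * qno2,
            u_no2_nh3=u_red2,
            h2_sink=1.0 * u_red1 + 3.0 * u_red2,
        )

    # methanogenesis and gas exchange
    q_me = max(y[I_ME], 0.0)
    u_meth = _meth_safe(c_h2, q_me, inh, b)
    fx.update(
        u_meth=u_meth,
        ch4_rate=u_meth / 4.0,
        h2_transfer=b.k_h2_em * (q_h2 - b.henry_h2 * p_head * b.v_fl),
        h2_absorb=b.k_h2_ab * q_h2,
        h2_passage=b.k_fl_ex * q_h2,
        h2_vent=b.k_vent * q_h2g,
        h2_prod=2.0 * u_a + 2.0 * u_b + u_hyd,
    )
    return fx


def rhs(variant: Variant, t: float, y: np.ndarray, pset: ParameterSet,
        diet: DietSpec, schedule: DosingSchedule,
        audit: bool = False, gas_mode: str = DEFAULT_GAS_MODE,
        check: bool = True) -> np.ndarray:
    """Time derivative of the full state of one variant [per hour].

    Every flux appears with opposite sign in its donor and (where one
    exists) recipient pool.  With ``audit=True`` the state carries
    cumulative-flux bookkeeping integrals (see :func:`audit_names`)
    alongside the physical pools.  Raises :class:`NumericalStateError`
    naming the offending flux if any flux is non-finite.
    """
    variant = Variant.parse(variant)
    b = pset.base
    y = np.asarray(y, float)
    nc = n_core(variant)
    if y.shape[0] != n_states(variant, audit):
        raise ValueError(
            f"state dimension {y.shape[0]} does not match variant "
            f"{variant.value} (expected {n_states(variant, audit)})")
    fx = flux_report(variant, t, y, pset, diet, schedule, gas_mode)
    if check:
        for name, v in fx.items():
            if not np.isfinite(v):
                raise NumericalStateError(
                    f"flux {name!r} is non-finite ({v}) at t={t:.4f} h")

    dy = np.zeros_like(y)
    d_dm = fx["d_dm"]
    k_bio = b.k_me_ex + b.k_mi_death  # microbial passage + decay

    dy[I_FG] = d_dm * diet.fg - fx["u_fg_he"] - b.k_so_ex * max(y[I_FG], 0.0)
    dy[I_SG] = d_dm * diet.sg - fx["u_sg_he"] - b.k_so_ex * max(y[I_SG], 0.0)
    dy[I_WR] = d_dm * diet.wr - fx["u_wr_he"] - b.k_fl_ex * max(y[I_WR], 0.0)
    dy[I_PG] = (d_dm * diet.pg - diet.k_pg_ps * max(y[I_PG], 0.0)
                - b.k_so_ex * max(y[I_PG], 0.0))
    dy[I_HE] = fx["he_in"] - fx["u_he"] - b.k_fl_ex * max(y[I_HE], 0.0)
    dy[I_MI] = (P.MW_POLY_HEXOSE * b.f_anab * fx["u_he"]
                - k_bio * max(y[I_MI], 0.0))
    dy[I_ME] = b.y_me * fx["u_meth"] - b.k_me_ex * max(y[I_ME], 0.0)
    dy[I_AC] = (2.0 * fx["u_a"] + (2.0 / 3.0) * fx["u_ap"]
                + d_dm * diet.ac / P.MW_ACETATE
                - (b.k_vfa_ab + b.k_fl_ex) * max(y[I_AC], 0.0))
    dy[I_PR] = ((4.0 / 3.0) * fx["u_ap"]
                + d_dm * (diet.pr / P.MW_PROPIONATE + diet.la / P.MW_LACTATE)
                - (b.k_vfa_ab + b.k_fl_ex) * max(y[I_PR], 0.0))
    dy[I_BU] = (fx["u_b"] + d_dm * diet.bu / P.MW_BUTYRATE
                - (b.k_vfa_ab + b.k_fl_ex) * max(y[I_BU], 0.0))
    h2_sink = fx.get("h2_sink", 0.0)
    dy[I_H2] = (fx["h2_prod"] - fx["u_meth"] - fx["h2_transfer"]
                - fx["h2_absorb"] - fx["h2_passage"] - h2_sink)
    dy[I_H2G] = fx["h2_transfer"] - fx["h2_vent"]
    dy[I_NADH] = (2.0 * fx["u_a"] - (2.0 / 3.0) * fx["u_ap"] - fx["u_hyd"]
                  - k_bio * fx["nadh_eff"])

    if variant is Variant.NOP:
        dy[N_BASE] = fx["supp_in"] - fx["u_3nop_ab"] - fx["u_3nop_ex"]
    elif variant is Variant.NOP_NO2:
        dy[N_BASE] = (fx["supp_in"] - fx["u_3nop_no3"] - fx["u_3nop_no2"]
                      - fx["u_3nop_ab"] - fx["u_3nop_ex"])
        dy[N_BASE + 1] = fx["u_3nop_no2"] - fx["u_no2_ex"]
        dy[N_BASE + 2] = fx["u_3nop_no3"]
    elif variant is Variant.NO3:
        dy[N_BASE] = (fx["supp_in"] - fx["u_no3_ab"] - fx["u_no3_ex"]
                      - fx["u_no3_nh3"])
    elif variant is Variant.NO3_NO2:
        dy[N_BASE] = (fx["supp_in"] - fx["u_no3_ab"] - fx["u_no3_ex"]
                      - fx["u_no3_no2"])
        dy[N_BASE + 1] = (fx["u_no3_no2"] - fx["u_no2_ab"] - fx["u_no2_ex"]
                          - fx["u_no2_nh3"])

    if audit:
        a = nc
        dy[a + 0] = fx["h2_prod"]
        dy[a + 1] = fx["u_meth"]
        dy[a + 2] = fx["h2_transfer"]
        dy[a + 3] = fx["h2_absorb"]
        dy[a + 4] = fx["h2_passage"]
        dy[a + 5] = h2_sink
        s = a + 6
        if variant is Variant.NOP:
            dy[s:s + 3] = (fx["supp_in"], fx["u_3nop_ab"], fx["u_3nop_ex"])
        elif variant is Variant.NOP_NO2:
            dy[s:s + 6] = (fx["supp_in"], fx["u_3nop_ab"], fx["u_3nop_ex"],
                           fx["u_3nop_no3"], fx["u_3nop_no2"], fx["u_no2_ex"])
        elif variant is Variant.NO3:
            dy[s:s + 4] = (fx["supp_in"], fx["u_no3_ab"], fx["u_no3_ex"],
                           fx["u_no3_nh3"])
        elif variant is Variant.NO3_NO2:
            dy[s:s + 7] = (fx["supp_in"], fx["u_no3_ab"], fx["u_no3_ex"],
                           fx["u_no3_no2"], fx["u_no2_ab"], fx["u_no2_ex"],
                           fx["u_no2_nh3"])
    return dy


# ---------------------------------------------------------------------------
# Compiled kernel (fast path used by the engine)
# ---------------------------------------------------------------------------

# parameter-array layout consumed by the kernel
_P_FIELDS = [
    # base
    "v_h2_ch4", "m_h2_ch4", "k_fl_ex", "k_so_ex", "v_fl", "k_h2_ab",
    "k_h2_em", "k_vent", "v_head", "nad_pool", "ft_chi", "dg0_j",
    "temperature", "henry_h2", "k_wr_he", "v_he", "m_he", "f_anab",
    "k_mi_death", "k_r_alloc", "f_bu_min", "k_hyd", "y_me", "k_vfa_ab",
    # inhibitor
    "k_3nop_ab", "k_nox_ab", "k_no3_nh3", "k_no3_no2", "k_no2_nh3",
    "k_3nop_no3", "k_3nop_no2", "j_mcr", "j_no2",
    # diet
    "fg", "sg", "wr", "pg", "ac", "pr", "bu", "la",
    "k_fg_he", "k_sg_he", "k_pg_ps",
    # schedule
    "c_supp",
    # appended base constants
    "f_bu_amp",
]
_PI = {name: i for i, name in enumerate(_P_FIELDS)}


def pack_problem(pset: ParameterSet, diet: DietSpec,
                 schedule: DosingSchedule
                 ) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pack parameters, diet and intake profile into kernel arrays."""
    b, i = pset.base, pset.inhibitor
    pa = np.empty(len(_P_FIELDS))
    vals = {
        "dg0_j": b.dg0_nadh * 1e3,
        "fg": diet.fg, "sg": diet.sg, "wr": diet.wr, "pg": diet.pg,
        "ac": diet.ac, "pr": diet.pr, "bu": diet.bu, "la": diet.la,
        "k_fg_he": diet.k_fg_he, "k_sg_he": diet.k_sg_he,
        "k_pg_ps": diet.k_pg_ps, "c_supp": schedule.c_supp,
    }
    for name, idx in _PI.items():
        if name in vals:
            pa[idx] = vals[name]
        elif hasattr(b, name):
            pa[idx] = getattr(b, name)
        else:
            pa[idx] = getattr(i, name)
    starts, ends, rates = schedule.segments()
    return pa, starts, ends, rates


@njit(cache=True)
def _kernel(t, y, pa, starts, ends, rates, vcode, audit, gmode):  # pragma: no cover - exercised via tests comparing to rhs()
    (v_h2_ch4, m_h2_ch4, k_fl_ex, k_so_ex, v_fl, k_h2_ab, k_h2_em, k_vent,
     v_head, nad_pool, ft_chi, dg0_j, temp, henry_h2, k_wr_he, v_he, m_he,
     f_anab, k_mi_death, k_r_alloc, f_bu_min, k_hyd, y_me, k_vfa_ab,
     k_3nop_ab, k_nox_ab, k_no3_nh3, k_no3_no2, k_no2_nh3, k_3nop_no3,
     k_3nop_no2, j_mcr, j_no2, c_fg, c_sg, c_wr, c_pg, c_ac, c_pr, c_bu,
     c_la, k_fg_he, k_sg_he, k_pg_ps, c_supp) = (
        pa[0], pa[1], pa[2], pa[3], pa[4], pa[5], pa[6], pa[7], pa[8],
        pa[9], pa[10], pa[11], pa[12], pa[13], pa[14], pa[15], pa[16],
        pa[17], pa[18], pa[19], pa[20], pa[21], pa[22], pa[23], pa[24],
        pa[25], pa[26], pa[27], pa[28], pa[29], pa[30], pa[31], pa[32],
        pa[33], pa[34], pa[35], pa[36], pa[37], pa[38], pa[39], pa[40],
        pa[41], pa[42], pa[43], pa[44])
    f_bu_amp = pa[45]

    t24 = t % 24.0
    d_dm = 0.0
    for m in range(starts.shape[0]):
        if starts[m] <= t24 < ends[m]:
            d_dm += rates[m]

    q_fg = y[0] if y[0] > 0.0 else 0.0
    q_sg = y[1] if y[1] > 0.0 else 0.0
    q_wr = y[2] if y[2] > 0.0 else 0.0
    q_pg = y[3] if y[3] > 0.0 else 0.0
    q_he = y[4] if y[4] > 0.0 else 0.0
    q_mi = y[5] if y[5] > 0.0 else 0.0
    q_me = y[6] if y[6] > 0.0 else 0.0
    q_ac = y[7] if y[7] > 0.0 else 0.0
    q_pr = y[8] if y[8] > 0.0 else 0.0
    q_bu = y[9] if y[9] > 0.0 else 0.0
    q_h2 = y[10] if y[10] > 0.0 else 0.0
    q_h2g = y[11] if y[11] > 0.0 else 0.0

    u_fg = k_fg_he * q_fg
    u_sg = k_sg_he * q_sg
    u_wr = k_wr_he * q_wr
    he_in = (u_fg + u_sg) / 162.0 + u_wr / 180.0

    c_he = q_he / v_fl
    u_he = v_he * q_mi * c_he / (m_he + c_he) if c_he > 0.0 else 0.0
    u_cat = (1.0 - f_anab) * u_he

    cap = nad_pool * (q_mi if q_mi > 1e-300 else 1e-300)
    nadh_r = y[12]
    lo = 1e-12 * cap
    hi = (1.0 - 1e-12) * cap
    if nadh_r < lo:
        nadh_r = lo
    elif nadh_r > hi:
        nadh_r = hi
    r = (cap - nadh_r) / nadh_r
    g = r / (k_r_alloc + r)
    f_b = f_bu_min + f_bu_amp * (1.0 - g)
    u_a = (1.0 - f_b) * g * u_cat
    u_ap = (1.0 - f_b) * (1.0 - g) * u_cat
    u_b = f_b * u_cat

    c_h2 = q_h2 / v_fl
    p_head = q_h2g * 0.0820573661 * temp / v_head
    if gmode == 0:
        p_h2 = c_h2 / henry_h2
    else:
        p_h2 = p_head
    rt = 8.314462618 * temp
    p_eff = p_h2 if p_h2 > 1e-30 else 1e-30
    dg = dg0_j + rt * np.log(p_eff / r)
    ex = dg / (ft_chi * rt)
    if ex > 50.0:
        ex = 50.0
    fraw = 1.0 - np.exp(ex)
    ft = 0.5 * (fraw + np.sqrt(fraw * fraw + 9.0e-4))  # smoothed clamp
    if ft > 1.0:
        ft = 1.0
    nadh = y[12]
    if nadh < 0.0:
        nadh = 0.0
    elif nadh > cap:
        nadh = cap
    u_hyd = k_hyd * nadh * ft

    # variant pools and inhibition
    inh = 0.0
    supp_in = 0.0
    u3_ab = 0.0; u3_ex = 0.0; u3_no3 = 0.0; u3_no2 = 0.0; uno2_exm = 0.0
    uno3_ab = 0.0; uno3_ex = 0.0; uno3_nh3 = 0.0; uno3_no2 = 0.0
    uno2_ab = 0.0; uno2_ex = 0.0; uno2_nh3 = 0.0
    h2_sink = 0.0
    k_me_ex = 0.4 * (k_fl_ex + k_so_ex)
    if vcode == 1:
        q3 = y[13] if y[13] > 0.0 else 0.0
        inh = (q3 / v_fl) / j_mcr
        supp_in = d_dm * c_supp
        u3_ab = k_3nop_ab * q3
        u3_ex = k_fl_ex * q3
    elif vcode == 2:
        q3 = y[13] if y[13] > 0.0 else 0.0
        qno2 = y[14] if y[14] > 0.0 else 0.0
        inh = ((q3 + qno2) / v_fl) / j_mcr
        supp_in = d_dm * c_supp
        u3_ab = k_3nop_ab * q3
        u3_ex = k_fl_ex * q3
        u3_no3 = k_3nop_no3 * q_me * q3
        u3_no2 = k_3nop_no2 * q_me * q3
        uno2_exm = k_me_ex * qno2
    elif vcode == 3:
        qno3 = y[13] if y[13] > 0.0 else 0.0
        supp_in = d_dm * c_supp
        uno3_ab = k_nox_ab * qno3
        uno3_ex = k_fl_ex * qno3
        uno3_nh3 = k_no3_nh3 * q_mi * qno3 * q_h2
        h2_sink = 4.0 * uno3_nh3
    elif vcode == 4:
        qno3 = y[13] if y[13] > 0.0 else 0.0
        qno2 = y[14] if y[14] > 0.0 else 0.0
        inh = (qno2 / v_fl) / j_no2
        supp_in = d_dm * c_supp
        uno3_ab = k_nox_ab * qno3
        uno3_ex = k_fl_ex * qno3
        uno3_no2 = k_no3_no2 * q_mi * qno3 * q_h2
        uno2_ab = k_nox_ab * qno2
        uno2_ex = k_fl_ex * qno2
        uno2_nh3 = k_no2_nh3 * q_mi * qno2 * q_h2
        h2_sink = 1.0 * uno3_no2 + 3.0 * uno2_nh3

    if c_h2 > 0.0:
        u_meth = v_h2_ch4 * q_me * c_h2 / (c_h2 + m_h2_ch4 + c_h2 * inh)
    else:
        u_meth = 0.0

    h2_prod = 2.0 * u_a + 2.0 * u_b + u_hyd
    h2_tr = k_h2_em * (q_h2 - henry_h2 * p_head * v_fl)
    h2_ab = k_h2_ab * q_h2
    h2_ex = k_fl_ex * q_h2
    h2_vent = k_vent * q_h2g
    k_bio = k_me_ex + k_mi_death

    dy = np.zeros(y.shape[0])
    dy[0] = d_dm * c_fg - u_fg - k_so_ex * q_fg
    dy[1] = d_dm * c_sg - u_sg - k_so_ex * q_sg
    dy[2] = d_dm * c_wr - u_wr - k_fl_ex * q_wr
    dy[3] = d_dm * c_pg - k_pg_ps * q_pg - k_so_ex * q_pg
    dy[4] = he_in - u_he - k_fl_ex * q_he
    dy[5] = 162.0 * f_anab * u_he - k_bio * q_mi
    dy[6] = y_me * u_meth - k_me_ex * q_me
    dy[7] = (2.0 * u_a + (2.0 / 3.0) * u_ap + d_dm * c_ac / 60.05
             - (k_vfa_ab + k_fl_ex) * q_ac)
    dy[8] = ((4.0 / 3.0) * u_ap + d_dm * (c_pr / 74.08 + c_la / 90.08)
             - (k_vfa_ab + k_fl_ex) * q_pr)
    dy[9] = (u_b + d_dm * c_bu / 88.11 - (k_vfa_ab + k_fl_ex) * q_bu)
    dy[10] = (h2_prod - u_meth - h2_tr - h2_ab - h2_ex - h2_sink)
    dy[11] = h2_tr - h2_vent
    dy[12] = 2.0 * u_a - (2.0 / 3.0) * u_ap - u_hyd - k_bio * nadh

    nc = 13
    if vcode == 1:
        dy[13] = supp_in - u3_ab - u3_ex
        nc = 14
    elif vcode == 2:
        dy[13] = supp_in - u3_no3 - u3_no2 - u3_ab - u3_ex
        dy[14] = u3_no2 - uno2_exm
        dy[15] = u3_no3
        nc = 16
    elif vcode == 3:
        dy[13] = supp_in - uno3_ab - uno3_ex - uno3_nh3
        nc = 14
    elif vcode == 4:
        dy[13] = supp_in - uno3_ab - uno3_ex - uno3_no2
        dy[14] = uno3_no2 - uno2_ab - uno2_ex - uno2_nh3
        nc = 15

    if audit == 1:
        dy[nc + 0] = h2_prod
        dy[nc + 1] = u_meth
        dy[nc + 2] = h2_tr
        dy[nc + 3] = h2_ab
        dy[nc + 4] = h2_ex
        dy[nc + 5] = h2_sink
        s = nc + 6
        if vcode == 1:
            dy[s] = supp_in; dy[s + 1] = u3_ab; dy[s + 2] = u3_ex
        elif vcode == 2:
            dy[s] = supp_in; dy[s + 1] = u3_ab; dy[s + 2] = u3_ex
            dy[s + 3] = u3_no3; dy[s + 4] = u3_no2; dy[s + 5] = uno2_exm
        elif vcode == 3:
            dy[s] = supp_in; dy[s + 1] = uno3_ab; dy[s + 2] = uno3_ex
            dy[s + 3] = uno3_nh3
        elif vcode == 4:
            dy[s] = supp_in; dy[s + 1] = uno3_ab; dy[s + 2] = uno3_ex
            dy[s + 3] = uno3_no2; dy[s + 4] = uno2_ab; dy[s + 5] = uno2_ex
            dy[s + 6] = uno2_nh3
    return dy


def rhs_kernel(variant: Variant, pset: ParameterSet, diet: DietSpec,
               schedule: DosingSchedule, audit: bool = False,
               gas_mode: str = DEFAULT_GAS_MODE):
    """Bind a variant's problem data into a fast ``f(t, y) -> dy`` callable."""
    variant = Variant.parse(variant)
    pa, starts, ends, rates = pack_problem(pset, diet, schedule)
    vcode = VARIANT_CODES[variant]
    acode = 1 if audit else 0
    gcode = GAS_MODE_CODES[gas_mode]

    def f(t, y):
        return _kernel(t, y, pa, starts, ends, rates, vcode, acode, gcode)

    return f
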