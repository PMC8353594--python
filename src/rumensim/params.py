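"""Parameter containers for the rumen fermentation models.

Two groups of constants drive the simulator:

* :class:`BaseParameters` -- the shared fermentation core (hydrolysis,
  hexose fermentation to VFA under NAD redox control, hydrogenotrophic
  methanogenesis, passage/absorption/gas exchange).  These are
  reconstruction constants: defaults are documented, physiologically
  plausible values for a lactating dairy cow, not literature estimates.
* :class:`InhibitorParameters` -- the supplement-specific rate and
  inhibition constants of the four model variants (3-NOP, 3-NOP+nitrite,
  nitrate, nitrate+nitrite).  Defaults are the preliminary values shipped
  in the package's parameter fixture table.

Both are frozen dataclasses so parameter sets can be hashed and cached
(e.g. for control-run steady-state caching).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, fields, replace

import numpy as np

__all__ = [
    "Variant",
    "BaseParameters",
    "InhibitorParameters",
    "ParameterSet",
    "R_GAS",
    "R_L_ATM",
]

#: Gas constant [J mol^-1 K^-1].
R_GAS = 8.314462618
#: Gas constant [L atm mol^-1 K^-1].
R_L_ATM = 0.0820573661

# Molar masses [g mol^-1] used to convert feed mass streams to molar pools.
MW_POLY_HEXOSE = 162.0   # anhydro-glucose unit in fiber/starch polymers
MW_SOL_HEXOSE = 180.0    # free hexose equivalent of soluble sugars
MW_ACETATE = 60.05
MW_PROPIONATE = 74.08
MW_BUTYRATE = 88.11
MW_LACTATE = 90.08


class Variant(str, enum.Enum):
    """Model variant: which supplement pools and inhibition laws apply."""

    BASE = "base"          # un-supplemented fermentation core (control)
    NOP = "3nop"           # 3-NOP simple
    NOP_NO2 = "3nop-no2"   # 3-NOP + intracellular nitrite
    NO3 = "no3"            # nitrate simple (H2 sink only)
    NO3_NO2 = "no3-no2"    # nitrate + nitrite (H2 sink and inhibition)

    @classmethod
    def parse(cls, value: "str | Variant") -> "Variant":
        if isinstance(value, cls):
            return value
        for v in cls:
            if v.value == value or v.name == str(value).upper():
                return v
        raise ValueError(
            f"unknown model variant {value!r}; valid: "
            + ", ".join(v.value for v in cls)
        )


@dataclass(frozen=True)
class BaseParameters:
    """Constants of the shared fermentation core.

    All rates are first-order fractional rates [h^-1] unless noted.
    """

    # Methanogenesis (Michaelis-Menten in dissolved H2)
    v_h2_ch4: float = 5.0       # max archaeal H2 utilization [mol g^-1 h^-1]
    m_h2_ch4: float = 2.0e-6    # H2 saturation constant [M]
    y_me: float = 0.054         # methanogen yield on H2 [g mol^-1]

    # Passage and rumen geometry
    k_fl_ex: float = 0.10       # fluid fractional outflow [h^-1]
    k_so_ex: float = 0.035      # solid fractional outflow [h^-1]
    v_fl: float = 90.0          # rumen fluid volume [L]
    v_head: float = 20.0        # headspace volume [L] (ideal-gas mode)

    # H2 gas handling
    k_h2_ab: float = 0.10       # H2 absorption across rumen wall [h^-1]
    k_h2_em: float = 500.0      # liquid<->headspace mass transfer [h^-1]
    k_vent: float = 5.0         # headspace washout (eructation) [h^-1]
    henry_h2: float = 7.8e-4    # Henry coefficient for H2 [M atm^-1]
    temperature: float = 312.0  # rumen temperature [K]

    # NAD redox pool and thermodynamic control
    nad_pool: float = 5.0e-4    # effective redox-carrier pool [mol g^-1]
    ft_chi: float = 1.0         # thermodynamic averaging factor [-], >= 1
    dg0_nadh: float = 18.1      # standard energy, NADH -> NAD+ + H2 [kJ mol^-1]
    k_hyd: float = 300.0        # hydrogenase NADH turnover [h^-1]

    # Hexose uptake and pathway allocation
    k_wr_he: float = 0.30       # soluble-sugar hydrolysis [h^-1]
    v_he: float = 8.0e-3        # max hexose uptake [mol g^-1 h^-1]
    m_he: float = 2.0e-3        # hexose saturation constant [M]
    f_anab: float = 0.20        # hexose fraction to microbial anabolism [-]
    k_r_alloc: float = 16.0     # NAD-ratio half constant of allocation [-]
    f_bu_min: float = 0.10      # butyrate pathway share at high NAD+/NADH
    f_bu_amp: float = 0.15      # extra butyrate share as NAD+/NADH -> 0

    # Microbial turnover and VFA absorption
    k_mi_death: float = 0.02    # fermentative-microbe decay [h^-1]
    k_vfa_ab: float = 0.35      # VFA absorption [h^-1]

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"BaseParameters.{f.name} must be > 0, got {v}")
        if self.ft_chi < 1:
            raise ValueError("ft_chi must be >= 1")
        if not 0 < self.f_anab < 1:
            raise ValueError("f_anab must lie in (0, 1)")
        if not 0 < self.f_bu_min + self.f_bu_amp < 1:
            raise ValueError("butyrate shares must satisfy 0 < f_bu_min + f_bu_amp < 1")

    @property
    def k_me_ex(self) -> float:
        """Methanogen (and microbe) passage rate, 0.4*(k_fl_ex + k_so_ex)."""
        return 0.4 * (self.k_fl_ex + self.k_so_ex)

    def replace(self, **kw) -> "BaseParameters":
        return replace(self, **kw)


@dataclass(frozen=True)
class InhibitorParameters:
    """Supplement-specific rate and inhibition constants.

    Defaults are the preliminary per-variant values of the shipped
    parameter fixture table; :meth:`for_variant` applies the
    variant-specific MCR inhibition constant.
    """

    k_3nop_ab: float = 0.30      # 3-NOP absorption [h^-1]
    k_nox_ab: float = 0.30       # NO3-/NO2- absorption [h^-1]
    k_no3_nh3: float = 6.99      # NO3- -> NH3 (simple model) [mol^-1 g^-1 h^-1]
    k_no3_no2: float = 1.5       # NO3- -> NO2- [mol^-1 g^-1 h^-1]
    k_no2_nh3: float = 0.113     # NO2- -> NH3 [mol^-1 g^-1 h^-1]
    k_3nop_no3: float = 1.55     # 3-NOP -> NO3- in archaea [g^-1 h^-1]
    k_3nop_no2: float = 0.44     # 3-NOP -> NO2- in archaea [g^-1 h^-1]
    j_mcr: float = 1.93e-5       # MCR inhibition constant [M]
    j_no2: float = 1.17e-3       # membrane-level NO2- inhibition constant [M]

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(
                    f"InhibitorParameters.{f.name} must be > 0, got {v}"
                )

    @classmethod
    def for_variant(cls, variant: "str | Variant", **overrides) -> "InhibitorParameters":
        """Variant defaults: the 3-NOP+nitrite model uses its own J_MCR."""
        variant = Variant.parse(variant)
        kw = {}
        if variant is Variant.NOP_NO2:
            kw["j_mcr"] = 2.10e-5
        kw.update(overrides)
        return cls(**kw)

    def replace(self, **kw) -> "InhibitorParameters":
        return replace(self, **kw)


@dataclass(frozen=True)
class ParameterSet:
    """Complete parameterization of one model variant."""

    base: BaseParameters = field(default_factory=BaseParameters)
    inhibitor: InhibitorParameters = field(default_factory=InhibitorParameters)

    @classmethod
    def default(cls, variant: "str | Variant" = Variant.BASE) -> "ParameterSet":
        v = Variant.parse(variant)
        inh = (InhibitorParameters() if v is Variant.BASE
               else InhibitorParameters.for_variant(v))
        return cls(BaseParameters(), inh)

    def replace(self, **kw) -> "ParameterSet":
        """Replace any base or inhibitor field by name."""
        base_names = {f.name for f in fields(BaseParameters)}
        inh_names = {f.name for f in fields(InhibitorParameters)}
        bkw = {k: v for k, v in kw.items() if k in base_names}
        ikw = {k: v for k, v in kw.items() if k in inh_names}
        unknown = set(kw) - base_names - inh_names
        if unknown:
            raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
        return ParameterSet(
            self.base.replace(**bkw) if bkw else self.base,
            self.inhibitor.replace(**ikw) if ikw else self.inhibitor,
        )

    def get(self, name: str) -> float:
        if hasattr(self.base, name):
            return getattr(self.base, name)
        return getattr(self.inhibitor, name)
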