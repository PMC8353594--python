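"""Feed-intake forcing: diets, dosing schedules and intake/supplement rates.

The simulator is driven by the dry-matter intake rate D_DM(t) [kg DM h^-1],
a 24-h periodic function defined by a :class:`DosingSchedule`.  Supplement
(3-NOP or nitrate) enters the rumen proportionally to intake,
``D_DM(t) * c_supp`` [mol h^-1], i.e. the supplement is assumed to be mixed
homogeneously into the ration.

Two profile shapes are supported:

* discrete meals -- rectangular pulses of configurable start, fraction and
  duration (default: two meals at 0 h and 12 h, half the daily intake each,
  1 h long), emulating a twice-daily restricted feeding regime;
* an hourly-fraction vector -- 24 fractions of daily intake consumed per
  clock hour, for ad-libitum-like profiles.

Internally every profile is reduced to piecewise-constant segments
``(starts, ends, rates)`` on [0, 24), which is also the representation the
compiled ODE kernel consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .params import Variant

__all__ = ["DietSpec", "DosingSchedule", "intake_rate", "supplement_influx"]

SUPPLEMENT_KINDS = ("none", "3nop", "no3")


@dataclass(frozen=True)
class DietSpec:
    """Dietary nutrient contents [g (kg DM)^-1] and hydrolysis rates [h^-1].

    ``fg``/``sg``/``wr`` are degradable fiber, degradable starch and soluble
    sugars; ``pg`` is degradable protein (an inert mass stream in this
    model); ``ac``/``pr``/``bu``/``la`` are preformed fermentation acids in
    the feed, routed directly into the corresponding VFA pools at intake
    (lactate into propionate).
    """

    fg: float
    sg: float
    wr: float
    pg: float = 0.0
    ac: float = 0.0
    pr: float = 0.0
    bu: float = 0.0
    la: float = 0.0
    k_fg_he: float = 0.04
    k_sg_he: float = 0.09
    k_pg_ps: float = 0.05
    label: str = ""

    def __post_init__(self) -> None:
        masses = (self.fg, self.sg, self.wr, self.pg,
                  self.ac, self.pr, self.bu, self.la)
        if any(m < 0 or not np.isfinite(m) for m in masses):
            raise ValueError("diet mass contents must be >= 0")
        if sum(masses) > 1000.0:
            raise ValueError("diet mass contents exceed 1000 g per kg DM")
        for name in ("k_fg_he", "k_sg_he", "k_pg_ps"):
            k = getattr(self, name)
            if not 0 <= k < 1:
                raise ValueError(f"{name} must be a fractional rate in [0, 1) h^-1")


@dataclass(frozen=True)
class DosingSchedule:
    """Feeding pattern and supplement inclusion.

    ``c_supp`` is the supplement content of the feed [mol (kg DM)^-1]; the
    kind selects which pool it feeds (3-NOP or NO3-).
    """

    daily_dmi: float = 20.0                    # [kg DM d^-1]
    meal_times: Tuple[float, ...] = (0.0, 12.0)   # clock hours of meal starts
    meal_fractions: Tuple[float, ...] = (0.5, 0.5)
    meal_duration: float = 1.0                 # [h]
    supplement_kind: str = "none"
    c_supp: float = 0.0                        # [mol (kg DM)^-1]
    hourly_fractions: Optional[Tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if self.daily_dmi <= 0:
            raise ValueError("daily_dmi must be > 0")
        if self.supplement_kind not in SUPPLEMENT_KINDS:
            raise ValueError(
                f"supplement_kind must be one of {SUPPLEMENT_KINDS}")
        if self.c_supp < 0:
            raise ValueError("c_supp must be >= 0")
        if self.c_supp > 0 and self.supplement_kind == "none":
            raise ValueError("nonzero c_supp requires a supplement kind")
        if self.hourly_fractions is not None:
            hf = np.asarray(self.hourly_fractions, float)
            if hf.shape != (24,) or (hf < 0).any():
                raise ValueError("hourly_fractions must be 24 nonnegative values")
            if abs(hf.sum() - 1.0) > 1e-9:
                raise ValueError("hourly_fractions must sum to 1")
            return
        if len(self.meal_times) != len(self.meal_fractions):
            raise ValueError("meal_times and meal_fractions length mismatch")
        if not self.meal_times:
            raise ValueError("at least one meal is required")
        fr = np.asarray(self.meal_fractions, float)
        if (fr < 0).any() or abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError("meal_fractions must be >= 0 and sum to 1")
        if not 0 < self.meal_duration <= 12.0:
            raise ValueError("meal_duration must lie in (0, 12] h")
        starts = np.asarray(self.meal_times, float)
        if (starts < 0).any() or (starts >= 24).any():
            raise ValueError("meal_times must lie in [0, 24)")
        # meal windows must not overlap (also across the midnight wrap)
        order = np.argsort(starts)
        s, e = starts[order], starts[order] + self.meal_duration
        for i in range(len(s) - 1):
            if e[i] > s[i + 1]:
                raise ValueError("meal windows overlap")
        if len(s) and e[-1] - 24.0 > s[0]:
            raise ValueError("meal windows overlap across midnight")

    def segments(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Piecewise-constant intake profile on [0, 24).

        Returns ``(starts, ends, rates)`` with rates in kg DM h^-1.  Meal
        windows crossing midnight are split at 24 h.
        """
        if self.hourly_fractions is not None:
            hf = np.asarray(self.hourly_fractions, float)
            keep = hf > 0
            starts = np.arange(24.0)[keep]
            ends = starts + 1.0
            rates = self.daily_dmi * hf[keep]  # fraction/h * dmi
            return starts, ends, rates
        starts, ends, rates = [], [], []
        for t0, frac in zip(self.meal_times, self.meal_fractions):
            if frac == 0:
                continue
            rate = self.daily_dmi * frac / self.meal_duration
            t1 = t0 + self.meal_duration
            if t1 <= 24.0:
                starts.append(t0); ends.append(t1); rates.append(rate)
            else:  # wraps past midnight
                starts.append(t0); ends.append(24.0); rates.append(rate)
                starts.append(0.0); ends.append(t1 - 24.0); rates.append(rate)
        order = np.argsort(starts)
        return (np.asarray(starts, float)[order],
                np.asarray(ends, float)[order],
                np.asarray(rates, float)[order])

    def breakpoints(self, t_end: float) -> np.ndarray:
        """All profile discontinuity times in [0, t_end]."""
        s, e, _ = self.segments()
        day = np.unique(np.concatenate([s, e]))
        pts = [day + 24.0 * k for k in range(int(np.ceil(t_end / 24.0)) + 1)]
        pts = np.concatenate([[0.0], np.concatenate(pts), [t_end]])
        pts = np.unique(pts)
        return pts[(pts >= 0.0) & (pts <= t_end)]

    def zero_dose(self) -> "DosingSchedule":
        """The matching control schedule (same feeding, no supplement)."""
        return DosingSchedule(
            daily_dmi=self.daily_dmi, meal_times=self.meal_times,
            meal_fractions=self.meal_fractions,
            meal_duration=self.meal_duration, supplement_kind="none",
            c_supp=0.0, hourly_fractions=self.hourly_fractions)

    def variant_kind(self, variant: Variant) -> "DosingSchedule":
        """Coerce the supplement kind to match a model variant."""
        kind = {"base": "none", "3nop": "3nop", "3nop-no2": "3nop",
                "no3": "no3", "no3-no2": "no3"}[Variant.parse(variant).value]
        if kind == self.supplement_kind:
            return self
        if kind == "none":
            return self.zero_dose()
        return DosingSchedule(
            daily_dmi=self.daily_dmi, meal_times=self.meal_times,
            meal_fractions=self.meal_fractions,
            meal_duration=self.meal_duration, supplement_kind=kind,
            c_supp=self.c_supp, hourly_fractions=self.hourly_fractions)


def intake_rate(t, schedule: DosingSchedule):
    """Dry-matter intake rate D_DM(t) [kg DM h^-1].

    Periodic with period 24 h; its integral over any 24-h window equals
    ``schedule.daily_dmi``.  ``t`` may be a scalar or array of times [h].
    """
    t = np.asarray(t, float)
    if (t < 0).any():
        raise ValueError("time must be >= 0")
    starts, ends, rates = schedule.segments()
    t24 = np.mod(t, 24.0)
    out = np.zeros_like(t24)
    for s, e, r in zip(starts, ends, rates):
        out += np.where((t24 >= s) & (t24 < e), r, 0.0)
    return out if out.ndim else float(out)


def supplement_influx(t, schedule: DosingSchedule):
    """Supplement influx D_DM(t) * c_supp [mol h^-1].

    Zero whenever intake is zero, for the control treatment (c_supp = 0),
    and for schedules without a supplement.
    """
    if schedule.supplement_kind == "none" or schedule.c_supp == 0.0:
        d = intake_rate(t, schedule)
        return d * 0.0
    return intake_rate(t, schedule) * schedule.c_supp
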