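"""Packaged reference tables and synthetic observation generation.

Two delimited tables ship inside the package:

* ``data/diets.csv`` -- dietary nutrient contents and hydrolysis rates of
  the nine study/treatment diets, keyed by their ExpTr labels
  (O, VZ, VM, Hn1, Hv, Hn2, Ls, VW, VL);
* ``data/inhibitor_params.csv`` -- the preliminary inhibition/reduction
  constants of the four model variants, with units.

The in-vivo emission records behind the original parameter estimates are
not redistributable, so :func:`generate_observations` produces synthetic
calibration datasets: model-generated emission outputs with multiplicative
Gaussian noise at a configurable coefficient of variation, including the
matching zero-dose control observation every treatment requires.
"""

from __future__ import annotations

import functools
import importlib.resources
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .calibration import CalibrationDataset
from .engine import daily_emission, simulate
from .forcing import DietSpec, DosingSchedule
from .params import InhibitorParameters, ParameterSet, Variant

__all__ = [
    "diet_table", "load_diet", "inhibitor_table", "load_inhibitor_params",
    "load_fixture", "export_fixtures", "generate_observations",
    "DOSE_GRIDS",
]

#: Supplement inclusion-rate grids [mol (kg DM)^-1] of the simulation
#: scenarios: 0/0.5/1.0 mmol kg^-1 for 3-NOP, 0/0.16/0.32 mol kg^-1 for
#: nitrate.
DOSE_GRIDS = {
    "3nop": (0.0, 0.5e-3, 1.0e-3),
    "no3": (0.0, 0.16, 0.32),
}


def _data_path(name: str):
    return importlib.resources.files("rumensim").joinpath("data", name)


@functools.lru_cache(maxsize=None)
def diet_table() -> pd.DataFrame:
    """The diet fixture table, indexed by ExpTr label."""
    with importlib.resources.as_file(_data_path("diets.csv")) as p:
        df = pd.read_csv(p)
    return df.set_index("exptr")


@functools.lru_cache(maxsize=None)
def inhibitor_table() -> pd.DataFrame:
    """The per-variant inhibitor parameter table, indexed by parameter."""
    with importlib.resources.as_file(_data_path("inhibitor_params.csv")) as p:
        df = pd.read_csv(p)
    return df.set_index("parameter")


def load_diet(key: str) -> DietSpec:
    """Build a validated :class:`DietSpec` from a fixture table row."""
    tbl = diet_table()
    if key not in tbl.index:
        raise KeyError(
            f"unknown diet {key!r}; valid keys: {', '.join(tbl.index)}")
    r = tbl.loc[key]
    return DietSpec(
        fg=float(r.fg), sg=float(r.sg), wr=float(r.wr), pg=0.0,
        ac=float(r.ac), pr=float(r.pr), bu=float(r.bu), la=float(r.la),
        k_fg_he=float(r.k_fg_he), k_sg_he=float(r.k_sg_he),
        k_pg_ps=float(r.k_pg_ps), label=str(key))


def load_inhibitor_params(variant: Union[str, Variant]) -> InhibitorParameters:
    """Inhibitor parameters of one variant from the fixture table.

    Entries the table leaves blank for a variant (constants that play no
    role in it) keep their cross-variant defaults, so the returned set is
    always complete and positive.
    """
    variant = Variant.parse(variant)
    if variant is Variant.BASE:
        return InhibitorParameters()
    col = inhibitor_table()[variant.value]
    overrides = {name: float(v) for name, v in col.items() if pd.notna(v)}
    return InhibitorParameters.for_variant(variant, **overrides)


def load_fixture(key: Union[str, Variant]):
    """Dispatch: an ExpTr label returns a diet, a variant its parameters."""
    if isinstance(key, Variant) or str(key) in [v.value for v in Variant]:
        return load_inhibitor_params(key)
    return load_diet(str(key))


def export_fixtures(directory) -> list:
    """Copy the packaged fixture tables into a user directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name in ("diets.csv", "inhibitor_params.csv"):
        target = directory / name
        target.write_text(_data_path(name).read_text())
        written.append(target)
    return written


# ---------------------------------------------------------------------------
# Synthetic observations
# ---------------------------------------------------------------------------

def _noisy(values: np.ndarray, cv: float, rng: np.random.Generator):
    """Multiplicative Gaussian noise with coefficient of variation ``cv``."""
    values = np.asarray(values, float)
    if cv == 0.0:
        return values.copy()
    return values * (1.0 + cv * rng.standard_normal(values.shape))


def generate_observations(variant: Union[str, Variant],
                          pset: Optional[ParameterSet] = None,
                          diet_label: str = "VL",
                          doses: Optional[Sequence[float]] = None,
                          noise_cv: float = 0.05,
                          seed: int = 0,
                          obs_type: str = "daily",
                          daily_dmi: float = 20.0,
                          t_end: float = 240.0,
                          study: Optional[str] = None,
                          sampling="final-day") -> CalibrationDataset:
    """Synthesize a calibration dataset from model runs plus noise.

    For ``obs_type="daily"`` each non-zero dose yields one daily-mean CH4
    observation [mol d^-1]; for ``"diurnal"`` hourly CH4 and H2 emission
    rates [mol h^-1] over the final 24 h, with ``time`` counted from the
    feeding event that opens the reporting window.  Every treatment row
    carries the (equally noisy) zero-dose control observation of the same
    variable, as a paired control measurement would.  Deterministic for a
    fixed seed; ``noise_cv=0`` returns the model outputs exactly.
    """
    variant = Variant.parse(variant)
    if variant is Variant.BASE:
        raise ValueError("observations require a supplemented variant")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    kind = "3nop" if variant in (Variant.NOP, Variant.NOP_NO2) else "no3"
    if doses is None:
        doses = [d for d in DOSE_GRIDS[kind] if d > 0]
    if pset is None:
        pset = ParameterSet.default(variant)
    diet = load_diet(diet_label)
    study = study or f"{diet_label}-{variant.value}"
    rng = np.random.default_rng(seed)

    def run(dose):
        sched = DosingSchedule(daily_dmi=daily_dmi, supplement_kind=kind,
                               c_supp=dose)
        return simulate(variant, pset, diet, sched, t_end=t_end,
                        sampling=sampling, audit=False)

    rows = []
    control = run(0.0)
    if obs_type == "daily":
        ctrl_obs = float(_noisy(daily_emission(control, "ch4_rate"),
                                noise_cv, rng))
        for dose in doses:
            val = float(_noisy(daily_emission(run(dose), "ch4_rate"),
                               noise_cv, rng))
            rows.append(dict(study=study, treatment=f"dose-{dose:g}",
                             diet=diet_label, daily_dmi=daily_dmi,
                             dose=dose, time=np.nan, variable="CH4",
                             value=val, control_value=ctrl_obs))
    elif obs_type == "diurnal":
        hours = np.arange(0.0, 24.0, 1.0)
        t_grid = t_end - 24.0 + hours
        ctrl = {
            var: _noisy(np.interp(t_grid, control.times, control[ser]),
                        noise_cv, rng)
            for var, ser in (("CH4", "ch4_rate"), ("H2", "h2_emission"))
        }
        for dose in doses:
            traj = run(dose)
            for var, ser in (("CH4", "ch4_rate"), ("H2", "h2_emission")):
                vals = _noisy(np.interp(t_grid, traj.times, traj[ser]),
                              noise_cv, rng)
                for h, val, cv_ in zip(hours, vals, ctrl[var]):
                    rows.append(dict(
                        study=study, treatment=f"dose-{dose:g}",
                        diet=diet_label, daily_dmi=daily_dmi, dose=dose,
                        time=float(h), variable=var, value=float(val),
                        control_value=float(cv_)))
    else:
        raise ValueError("obs_type must be 'daily' or 'diurnal'")
    return CalibrationDataset(pd.DataFrame(rows))
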