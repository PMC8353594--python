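"""Parameter estimation against (synthetic or user-supplied) emission data.

The free parameters of the inhibition/reduction kinetics are estimated by
minimizing the sum of squared residuals (SSE) between model outputs and
observed methane/hydrogen emissions with a quasi-Newton (BFGS) search on
the log scale, which keeps every rate and inhibition constant positive.

Observations come in two kinds, mirroring the data the models were
designed for: average daily CH4 emissions [mol d^-1] per dietary
treatment, and diurnal hourly CH4/H2 emission-rate series [mol h^-1]
over a quasi-steady day.  Before fitting, treatment observations are
rescaled by the ratio of predicted to observed *control* (zero-dose)
values per study and variable, so the control run is residual-free by
construction and the fit targets the supplement response rather than the
base model's accuracy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .engine import SolverFailure, Trajectory, daily_emission, simulate
from .forcing import DosingSchedule
from .params import ParameterSet, Variant

__all__ = [
    "CalibrationDataset", "scale_observations", "control_predictions",
    "sse_objective", "fit", "FitResult",
]

log = logging.getLogger(__name__)

#: DataFrame columns of a calibration dataset.
DATASET_COLUMNS = ["study", "treatment", "diet", "daily_dmi", "dose",
                   "time", "variable", "value", "control_value"]

_SERIES = {"CH4": "ch4_rate", "H2": "h2_emission"}

#: Objective value returned when the solver fails inside the objective.
PENALTY_SSE = 1.0e12


@dataclass
class CalibrationDataset:
    """Tabular emission observations with per-study controls.

    One row per observation: ``time`` is blank (NaN) for daily means and
    the hour from feeding for diurnal points; ``control_value`` is the
    observed zero-dose value of the same variable (the same quantity for
    every row of a study/variable pair for daily means, the same hour for
    diurnal series).
    """

    data: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in DATASET_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"dataset missing columns: {missing}")
        if (self.data["dose"] < 0).any():
            raise ValueError("doses must be >= 0")
        if self.data["control_value"].isna().any():
            raise ValueError("every observation needs a control value")
        bad = ~self.data["variable"].isin(_SERIES)
        if bad.any():
            raise ValueError(
                f"unknown variables: {sorted(self.data['variable'][bad].unique())}")

    def __len__(self) -> int:
        return len(self.data)

    def copy_with(self, values: np.ndarray) -> "CalibrationDataset":
        df = self.data.copy()
        df["value"] = values
        return CalibrationDataset(df)

    def treatments(self) -> pd.DataFrame:
        """Unique (study, diet, daily_dmi, dose) simulation conditions."""
        return (self.data[["study", "diet", "daily_dmi", "dose"]]
                .drop_duplicates().reset_index(drop=True))

    @classmethod
    def concat(cls, datasets) -> "CalibrationDataset":
        """Pool several studies' observations into one dataset."""
        return cls(pd.concat([d.data for d in datasets],
                             ignore_index=True))

    @classmethod
    def read_csv(cls, path) -> "CalibrationDataset":
        return cls(pd.read_csv(path))

    def write_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def _schedule_for(variant: Variant, daily_dmi: float,
                  dose: float) -> DosingSchedule:
    kind = ("3nop" if variant in (Variant.NOP, Variant.NOP_NO2)
            else "no3" if variant in (Variant.NO3, Variant.NO3_NO2)
            else "none")
    if dose == 0.0:
        kind = "none"
    return DosingSchedule(daily_dmi=daily_dmi, supplement_kind=kind,
                         c_supp=dose)


def _extract(traj: Trajectory, rows: pd.DataFrame) -> np.ndarray:
    """Model counterpart of each observation row from one trajectory."""
    out = np.empty(len(rows))
    t0 = traj.times[-1] - 24.0
    for j, (_, r) in enumerate(rows.iterrows()):
        series = _SERIES[r["variable"]]
        if np.isnan(r["time"]):
            out[j] = daily_emission(traj, series)
        else:
            out[j] = np.interp(t0 + float(r["time"]), traj.times,
                               traj[series])
    return out


def predict(dataset: CalibrationDataset, variant: Variant,
            pset: ParameterSet, *, t_end: float = 240.0,
            sampling="final-day", diets: Optional[Dict] = None,
            rtol: float = 1e-7, atol: float = 1e-12) -> np.ndarray:
    """Model predictions for every dataset row (final-24-h window)."""
    from .fixtures import load_diet  # local import to avoid a cycle
    variant = Variant.parse(variant)
    diets = diets or {}
    preds = np.empty(len(dataset))
    df = dataset.data
    for (_, diet_label, dmi, dose), rows in df.groupby(
            ["study", "diet", "daily_dmi", "dose"], dropna=False):
        diet = diets.get(diet_label) or load_diet(diet_label)
        sched = _schedule_for(variant, float(dmi), float(dose))
        traj = simulate(variant, pset, diet, sched, t_end=t_end,
                        sampling=sampling, audit=False, rtol=rtol, atol=atol)
        preds[df.index.get_indexer(rows.index)] = _extract(traj, rows)
    return preds


def control_predictions(dataset: CalibrationDataset, variant: Variant,
                        pset: ParameterSet, **kw) -> Dict[Tuple[str, str], float]:
    """Predicted zero-dose value per (study, variable).

    Diurnal controls are summarized by their 24-h mean so the rescaling
    ratio is a scalar per study and variable.
    """
    df = dataset.data
    ctrl_rows = df.copy()
    ctrl_rows["dose"] = 0.0
    ctrl = CalibrationDataset(ctrl_rows)
    preds = predict(ctrl, variant, pset, **kw)
    out: Dict[Tuple[str, str], float] = {}
    for (study, var), rows in df.groupby(["study", "variable"]):
        out[(study, var)] = float(
            np.mean(preds[df.index.get_indexer(rows.index)]))
    return out


def scale_observations(dataset: CalibrationDataset,
                       control_preds: Dict[Tuple[str, str], float]
                       ) -> CalibrationDataset:
    """Rescale observations by predicted/observed control per study.

    Each observation is multiplied by ``predicted_control /
    observed_control`` of its (study, variable) pair, which makes the
    control residual exactly zero and corrects treatment observations for
    the model's base-level inaccuracy on that study.
    """
    df = dataset.data
    scaled = df["value"].to_numpy(float).copy()
    for (study, var), rows in df.groupby(["study", "variable"]):
        obs_ctrl = float(np.mean(rows["control_value"]))
        if obs_ctrl == 0.0:
            raise ValueError(
                f"observed control of ({study}, {var}) is zero")
        ratio = control_preds[(study, var)] / obs_ctrl
        scaled[df.index.get_indexer(rows.index)] *= ratio
    return dataset.copy_with(scaled)


def sse_objective(theta: Sequence[float], free_names: Sequence[str],
                  dataset: CalibrationDataset, variant: Variant,
                  pset: ParameterSet, **predict_kw) -> float:
    """Sum of squared residuals of a candidate parameter vector.

    ``theta`` holds natural-scale values of the ``free_names`` inhibitor
    parameters; all other parameters come from ``pset``.  Solver failures
    inside the objective yield a large penalty instead of an exception so
    the optimizer can back away.
    """
    theta = np.asarray(theta, float)
    if (theta <= 0).any() or not np.isfinite(theta).all():
        return PENALTY_SSE
    trial = pset.replace(**dict(zip(free_names, theta)))
    try:
        preds = predict(dataset, variant, trial, **predict_kw)
    except SolverFailure as err:
        log.warning("solver failure in objective at theta=%s: %s",
                    theta, err)
        return PENALTY_SSE
    resid = dataset.data["value"].to_numpy(float) - preds
    return float(np.dot(resid, resid))


@dataclass
class FitResult:
    """Outcome of a parameter estimation."""

    estimates: Dict[str, float]
    sse: float
    n_iter: int
    converged: bool
    message: str
    starts: pd.DataFrame = field(repr=False, default=None)

    def __getitem__(self, name: str) -> float:
        return self.estimates[name]


def fit(dataset: CalibrationDataset, variant: Variant,
        free_names: Sequence[str], pset: Optional[ParameterSet] = None,
        theta0: Optional[Sequence[float]] = None, n_starts: int = 3,
        rescale: bool = True, **predict_kw) -> FitResult:
    """Estimate inhibitor parameters by log-scale BFGS on the SSE.

    ``theta0`` defaults to the current values in ``pset``.  ``n_starts``
    quasi-Newton searches are launched from ``theta0`` and from it scaled
    by 3 and 1/3 (multi-start mitigates local minima); the best final SSE
    wins.  With ``rescale`` (default) the observations are first scaled
    by the predicted/observed control ratio.  Non-convergence is reported
    in the result, not raised.
    """
    variant = Variant.parse(variant)
    pset = pset or ParameterSet.default(variant)
    free_names = list(free_names)
    for name in free_names:
        pset.get(name)  # raises on unknown names
    if theta0 is None:
        theta0 = np.array([pset.get(n) for n in free_names])
    theta0 = np.asarray(theta0, float)
    if (theta0 <= 0).any():
        raise ValueError("theta0 must be positive")

    if rescale:
        ctrl = control_predictions(dataset, variant, pset, **predict_kw)
        dataset = scale_observations(dataset, ctrl)

    def obj_log(x):
        return sse_objective(np.exp(x), free_names, dataset, variant,
                             pset, **predict_kw)

    factors = [1.0, 3.0, 1.0 / 3.0][:max(1, n_starts)]
    rows = []
    best = None
    for fac in factors:
        x0 = np.log(theta0 * fac)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # BFGS line-search chatter
            # finite-difference step large enough that the objective
            # change dominates the ODE-solver noise floor
            res = minimize(obj_log, x0, method="BFGS",
                           options={"gtol": 1e-6, "eps": 1e-3})
        rows.append({"factor": fac, "sse": float(res.fun),
                     "n_iter": int(res.nit), "converged": bool(res.success)})
        if best is None or res.fun < best.fun:
            best = res
    estimates = dict(zip(free_names, np.exp(best.x)))
    return FitResult(
        estimates=estimates, sse=float(best.fun), n_iter=int(best.nit),
        converged=bool(best.success), message=str(best.message),
        starts=pd.DataFrame(rows))
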