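"""Shared fixtures: parameter sets, diets and the scenario run cache.

The expensive 240-h simulations over the full dose grids are computed
once per session and shared by the response-matrix, mass-balance and
fate-budget tests.
"""

import numpy as np
import pytest

import rumensim as rs
from rumensim import DosingSchedule, ParameterSet

#: Supplement kind per variant.
DOSE_KIND = {"3nop": "3nop", "3nop-no2": "3nop",
             "no3": "no3", "no3-no2": "no3"}

VARIANTS = tuple(DOSE_KIND)


@pytest.fixture(scope="session")
def vl_diet():
    return rs.load_diet("VL")


@pytest.fixture(scope="session")
def base_params():
    return rs.BaseParameters()


@pytest.fixture(scope="session")
def dose_runs(vl_diet):
    """Trajectory per (variant, dose) over the scenario dose grids.

    240-h runs on the evaluation diet with flux bookkeeping enabled;
    dose 0 is the control treatment of each variant.
    """
    runs = {}
    for variant in VARIANTS:
        kind = DOSE_KIND[variant]
        pset = ParameterSet.default(variant)
        for dose in rs.DOSE_GRIDS[kind]:
            sch = DosingSchedule(supplement_kind=kind, c_supp=dose)
            runs[(variant, dose)] = rs.simulate(
                variant, pset, vl_diet, sch, sampling="coarse", audit=True)
    return runs


@pytest.fixture(scope="session")
def base_run(vl_diet):
    """Control run of the un-supplemented fermentation core."""
    return rs.simulate("base", ParameterSet.default("base"), vl_diet,
                       DosingSchedule(), sampling="coarse", audit=True)


@pytest.fixture(scope="session")
def random_states():
    """Reproducible random physical states per variant for RHS checks."""
    rng = np.random.default_rng(1234)
    scales = np.array([2e3, 1e3, 2e2, 3e2, 5.0, 4e2, 1.0, 4.0, 2.0, 1.0,
                       5e-3, 5e-2, 1e-4])
    out = {}
    for variant in ("base",) + VARIANTS:
        from rumensim.base import n_core, state_names
        n = n_core(variant)
        extra = n - len(scales)
        sc = np.concatenate([scales, np.full(extra, 0.05)])
        ys = sc * rng.uniform(0.05, 1.5, size=(8, n))
        # keep NADH inside its pool bound (cap = nad_pool * q_mi)
        cap = rs.BaseParameters().nad_pool * ys[:, 5]
        ys[:, 12] = np.minimum(ys[:, 12], 0.8 * cap)
        out[variant] = ys
    return out
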