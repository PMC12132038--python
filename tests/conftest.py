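import numpy as np
import pandas as pd
import pytest

from hexinvade import glmselect, zoo
from hexinvade.pressure import PressureConfig, pressure_surface
from hexinvade.simdata import LandscapeConfig, simulate_study

#: the multivariable predictor set with the expected sign structure
FINAL_COLUMNS = [
    "spatial", "elev", "slope", "campgrounds", "popdensity_log10",
    "crown", "landcover", "deg_days",
]


@pytest.fixture(scope="session")
def default_study():
    """The default simulated invasion scenario (seeded)."""
    return simulate_study(LandscapeConfig(seed=0))


@pytest.fixture(scope="session")
def default_design(default_study):
    """Response + pressure + predictors for the default scenario."""
    cfg = default_study.truth
    occ = default_study.occurrences
    pcfg = PressureConfig(a=cfg.true_a, cutoff_m=cfg.cutoff_m, lags=cfg.lags)
    first = int(occ["year"].min())
    years = sorted(y for y in occ["year"].unique() if y - max(cfg.lags) >= first)
    surf = pressure_surface(occ, default_study.grid, pcfg, years)
    design = glmselect.build_design(
        occ[occ["year"].isin(years)], surf, default_study.predictors
    )
    return design.reset_index(drop=True)


@pytest.fixture(scope="session")
def zoo_design(default_design):
    cols = ["hex_id", "year", "presence"] + FINAL_COLUMNS
    return default_design[cols].reset_index(drop=True)


@pytest.fixture(scope="session")
def zoo_plan(zoo_design):
    return zoo.make_split_plan(zoo_design, seed=0, n_absence_sets=3, n_cv=1)


@pytest.fixture(scope="session")
def zoo_runs(zoo_design, zoo_plan):
    """A small factorial (3 families x 3 sets x 1 cv) reused across tests."""
    return zoo.run_zoo(zoo_plan, zoo_design, families=("GLM", "RF", "CTA"))


class StubModel:
    """Deterministic stand-in learner returning preset probabilities.

    Synthetic: used to test voting/importance machinery in isolation.
    """

    def __init__(self, fn):
        self.fn = fn

    def predict_prob(self, X):
        return self.fn(np.asarray(X, dtype=float))


def stub_run(fn, feature_names, threshold=0.5, tss_validation=0.9):
    return zoo.ModelRun(
        family="GLM", absence_set_index=0, cv_index=0, model=StubModel(fn),
        threshold=threshold, tss_validation=tss_validation, tss_evaluation=None,
        status="ok", feature_names=tuple(feature_names),
    )
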