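"""Reusable validation experiments: parameter-recovery and coverage studies.

These are Monte-Carlo experiments the package runs against itself: simulate
data with known truth, run the inference path, and measure how often the
truth is recovered. They back both the test suite and the acceptance
summary script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .glmselect import fit_logistic, select_kernel_shape
from .pressure import PressureConfig
from .simdata import LandscapeConfig, simulate_colonization_trial


def kernel_recovery_experiment(
    true_a: float,
    n_replicates: int = 20,
    seed: int = 0,
    a_values=(1.0, 3.0, 5.0, 10.0),
) -> int:
    """How often AIC selects the generating kernel shape.

    Each replicate runs a scattered-foci dispersal trial (~2,000 hexagon-year
    rows) generated with ``true_a``, then screens the candidate shapes with
    single-predictor logistic AIC. Returns the number of replicates whose
    selected shape equals the truth.
    """
    correct = 0
    for rep in range(n_replicates):
        rep_seed = (seed * 1009 + rep * 7919) % (2**31 - 1)
        cfg = LandscapeConfig(seed=rep_seed, true_a=true_a)
        response, sources, grid = simulate_colonization_trial(cfg, seed=rep_seed)
        base = PressureConfig(
            a=a_values[0], cutoff_m=cfg.cutoff_m, lags=cfg.lags, form=cfg.kernel_form
        )
        best, _ = select_kernel_shape(
            response, grid, a_values, base, source_occ=sources
        )
        correct += int(best == true_a)
    return correct


def wald_coverage_experiment(
    n_replicates: int = 100, n: int = 2000, seed: int = 0
) -> dict[str, float]:
    """Coverage of 95% Wald intervals when fitting the generating logit model.

    Simulates binary responses from a fixed four-coefficient logistic model
    and fits it back; returns the per-coefficient fraction of replicates
    whose interval covers the truth.
    """
    true = {"const": -1.0, "x1": 0.6, "x2": -0.4, "x3": 0.8}
    hits = {k: 0 for k in true}
    for rep in range(n_replicates):
        rng = np.random.default_rng([seed % (2**31 - 1), rep, 55])
        X = rng.standard_normal((n, 2))
        x3 = (rng.random(n) < 0.3).astype(float)
        lp = true["const"] + true["x1"] * X[:, 0] + true["x2"] * X[:, 1] + true["x3"] * x3
        y = (rng.random(n) < 1.0 / (1.0 + np.exp(-lp))).astype(int)
        design = pd.DataFrame({"presence": y, "x1": X[:, 0], "x2": X[:, 1], "x3": x3})
        fit = fit_logistic(design, columns=["x1", "x2", "x3"])
        for k, b in true.items():
            lo = fit.params[k] - 1.96 * fit.bse[k]
            hi = fit.params[k] + 1.96 * fit.bse[k]
            hits[k] += int(lo <= b <= hi)
    return {k: h / n_replicates for k, h in hits.items()}
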