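"""Logistic-regression model building and AIC-based selection.

The response is the binary hexagon-year presence/absence; candidate models
combine the infestation-pressure term with predictor sets from the driver
groups. Selection follows the classical workflow: pick the kernel shape a by
AIC among single-predictor spatial models, screen collinear predictors
(pairwise |r| then VIF), backward-eliminate terms by AIC, and compare the
surviving candidates with delta-AIC and Akaike weights.

AIC here always counts every estimated coefficient including the intercept
(aic = 2*K_total - 2*LL). Comparison tables sometimes print K as the number
of predictors only; the constant offset cancels in delta-AIC, which is what
selection uses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .pressure import PressureConfig, pressure_surface

logger = logging.getLogger(__name__)

_KEY_COLS = ("hex_id", "year", "presence")


@dataclass
class FittedLogistic:
    """A fitted logit model: coefficients, SEs, likelihood and AIC."""

    params: pd.Series
    bse: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    log_likelihood: float
    nobs: int
    converged: bool
    feature_names: tuple[str, ...]

    @property
    def k_params(self) -> int:
        """Number of estimated coefficients, intercept included."""
        return len(self.params)

    @property
    def aic(self) -> float:
        return 2.0 * self.k_params - 2.0 * self.log_likelihood

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Probabilities for new rows (inverse-logit of the linear predictor)."""
        lp = np.full(len(X), self.params["const"], dtype=float)
        for name in self.feature_names:
            lp += self.params[name] * X[name].to_numpy(dtype=float)
        return 1.0 / (1.0 + np.exp(-lp))

    def coefficient_table(self) -> pd.DataFrame:
        """Estimate, SE, z, p, odds ratio and Wald 95% CI per term."""
        rows = []
        for name in self.params.index:
            beta, se = float(self.params[name]), float(self.bse[name])
            orow = odds_ratio(beta, se) if se > 0 else (np.exp(beta), np.nan, np.nan)
            rows.append(
                {
                    "term": name,
                    "estimate": beta,
                    "se": se,
                    "z": float(self.zvalues[name]),
                    "p": float(self.pvalues[name]),
                    "odds_ratio": orow[0],
                    "or_ci_low": orow[1],
                    "or_ci_high": orow[2],
                }
            )
        return pd.DataFrame(rows)


def predictor_columns(design: pd.DataFrame) -> list[str]:
    """Columns of a design table that act as predictors (keys excluded)."""
    return [c for c in design.columns if c not in _KEY_COLS]


def fit_logistic(
    design: pd.DataFrame, columns=None, response: str = "presence"
) -> FittedLogistic:
    """Maximum-likelihood logit fit (IRLS) of ``response`` on ``columns``.

    ``columns=None`` uses every non-key column; ``columns=[]`` fits the
    intercept-only model. Raises on a single-class response or an exactly
    collinear design; flags (rather than raises) likely complete separation.
    """
    y = design[response].to_numpy(dtype=float)
    if not ((y == 0) | (y == 1)).all():
        raise ValueError("response must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("need at least one presence and one absence")
    cols = list(columns) if columns is not None else predictor_columns(design)
    if len(set(cols)) != len(cols):
        raise ValueError("duplicate predictor names in design")
    X = design[cols].to_numpy(dtype=float) if cols else np.empty((len(y), 0))
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("design matrix contains missing values")
    Xc = np.column_stack([np.ones(len(y)), X])
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        # name the offending columns: those whose removal restores full rank
        bad = [
            c
            for i, c in enumerate(cols)
            if np.linalg.matrix_rank(np.delete(Xc, i + 1, axis=1)) == np.linalg.matrix_rank(Xc)
        ]
        raise ValueError(f"singular design matrix; collinear columns: {bad or cols}")

    names = ["const"] + cols
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, Xc, family=sm.families.Binomial()).fit(maxiter=100, tol=1e-8)
    params = pd.Series(res.params, index=names)
    bse = pd.Series(res.bse, index=names)
    converged = bool(getattr(res, "converged", True))
    if np.abs(params.to_numpy()).max() > 15.0 or not np.isfinite(bse.to_numpy()).all():
        converged = False
        logger.warning("possible complete separation: diverging coefficients %s", dict(params))
    z = params / bse.replace(0.0, np.nan)
    from scipy.stats import norm

    p = pd.Series(2.0 * norm.sf(np.abs(z.to_numpy())), index=names)
    return FittedLogistic(
        params=params,
        bse=bse,
        zvalues=z,
        pvalues=p,
        log_likelihood=float(res.llf),
        nobs=int(len(y)),
        converged=converged,
        feature_names=tuple(cols),
    )


def odds_ratio(beta: float, se: float) -> tuple[float, float, float]:
    """exp(beta) with the Wald 95% interval exp(beta +/- 1.96 se)."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    return (
        float(np.exp(beta)),
        float(np.exp(beta - 1.96 * se)),
        float(np.exp(beta + 1.96 * se)),
    )


def balanced_design(
    design: pd.DataFrame, seed: int, response: str = "presence", stratify_spatially: bool = False,
    grid=None,
) -> pd.DataFrame:
    """All presences plus an equal-size seeded draw of absences.

    The default draw is uniform over surveyed absence rows. With
    ``stratify_spatially=True`` (and a grid), absences are allocated across
    coarse row/column blocks in proportion to the spatial distribution of
    the absence pool, so the sample is not skewed geographically.
    """
    rng = np.random.default_rng(seed)
    pres = design[design[response] == 1]
    abs_pool = design[design[response] == 0]
    n = len(pres)
    if len(abs_pool) < n:
        raise ValueError("absence pool smaller than presence count")
    if not stratify_spatially or grid is None:
        idx = rng.choice(abs_pool.index.to_numpy(), size=n, replace=False)
    else:
        pos = {int(h): i for i, h in enumerate(grid.hex_id)}
        rows = np.array([grid.row[pos[int(h)]] for h in abs_pool["hex_id"]])
        cols = np.array([grid.col[pos[int(h)]] for h in abs_pool["hex_id"]])
        blocks = (
            np.digitize(rows, np.quantile(rows, [0.25, 0.5, 0.75])) * 4
            + np.digitize(cols, np.quantile(cols, [0.25, 0.5, 0.75]))
        )
        idx_parts = []
        uniq, counts = np.unique(blocks, return_counts=True)
        alloc = np.floor(counts / counts.sum() * n).astype(int)
        # distribute the remainder to the largest blocks
        for i in np.argsort(-counts)[: n - alloc.sum()]:
            alloc[i] += 1
        for b, k in zip(uniq, alloc):
            pool_b = abs_pool.index.to_numpy()[blocks == b]
            k = min(k, len(pool_b))
            if k > 0:
                idx_parts.append(rng.choice(pool_b, size=k, replace=False))
        idx = np.concatenate(idx_parts)
    out = pd.concat([pres, abs_pool.loc[idx]], ignore_index=True)
    return out.sample(frac=1.0, random_state=int(rng.integers(2**31 - 1))).reset_index(drop=True)


def build_design(
    occ: pd.DataFrame, spatial: pd.DataFrame, predictors: pd.DataFrame
) -> pd.DataFrame:
    """Join the response with the pressure term and the per-hexagon predictors."""
    d = occ.merge(spatial, on=["hex_id", "year"], how="inner")
    d = d.merge(predictors, on="hex_id", how="left")
    if d.isna().any().any():
        missing = d.columns[d.isna().any()].tolist()
        raise ValueError(f"design has missing predictor values in {missing}")
    return d


def select_kernel_shape(
    occ: pd.DataFrame,
    grid,
    a_values=PressureConfig.CANDIDATE_A,
    base_cfg: PressureConfig = PressureConfig(),
    years=None,
    source_occ: pd.DataFrame | None = None,
) -> tuple[float, dict[float, FittedLogistic]]:
    """Choose the kernel shape a by AIC of single-predictor spatial logits.

    Fits presence ~ Spatial(a) for each candidate a on the occurrence rows
    whose lag years are fully covered, and returns the argmin-AIC a (ties
    within 1e-6 break to the smallest a) plus every per-a fit. By default the
    lagged neighbourhoods are built from ``occ`` itself; ``source_occ`` lets
    callers supply a separate source table (e.g. a designed dispersal trial
    where the source cohorts are known rather than inferred from detections).
    """
    a_values = sorted(float(a) for a in a_values)
    if len(a_values) < 2:
        raise ValueError("need at least two candidate a values")
    sources = occ if source_occ is None else source_occ
    first = int(sources["year"].min())
    if years is None:
        years = sorted(
            y for y in occ["year"].unique() if y - max(base_cfg.lags) >= first
        )
    rows = occ[occ["year"].isin(years)]
    fits: dict[float, FittedLogistic] = {}
    for a in a_values:
        cfg = replace(base_cfg, a=a)
        surf = pressure_surface(sources, grid, cfg, years)
        design = rows.merge(surf, on=["hex_id", "year"], how="left")
        if design["spatial"].nunique() <= 1:
            # degenerate: no pressure variation (e.g. no sources in range);
            # the spatial coefficient is unidentified, fit the null model
            fits[a] = fit_logistic(design, columns=[])
        else:
            fits[a] = fit_logistic(design, columns=["spatial"])
    best = min(fits, key=lambda a: (round(fits[a].aic / 1e-6) * 1e-6, a))
    return best, fits


def _vif(X: np.ndarray) -> np.ndarray:
    """Variance inflation factors 1/(1 - R^2_j) via least squares."""
    n, p = X.shape
    out = np.empty(p)
    for j in range(p):
        yj = X[:, j]
        Z = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(Z, yj, rcond=None)
        resid = yj - Z @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        out[j] = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
    return out


def screen_predictors(
    design: pd.DataFrame,
    columns=None,
    response: str = "presence",
    r_max: float = 0.75,
    vif_max: float = 5.0,
    keep=(),
) -> tuple[list[str], dict]:
    """Drop collinear predictors: pairwise |r| screen, then a VIF loop.

    For each pair with |r| >= r_max, the member whose single-predictor
    logistic model has the larger AIC is dropped (competing-model rule);
    then the max-VIF column is dropped iteratively while any VIF >= vif_max.
    Columns in ``keep`` survive both screens; constant columns are dropped
    with a warning.
    """
    cols = list(columns) if columns is not None else predictor_columns(design)
    keep = set(keep)
    report: dict = {"dropped": [], "pairs": [], "vif": {}}
    for c in list(cols):
        if design[c].nunique() <= 1:
            if c in keep:
                continue
            logger.warning("dropping constant predictor column %r", c)
            cols.remove(c)
            report["dropped"].append({"column": c, "reason": "constant"})

    def single_aic(c: str) -> float:
        return fit_logistic(design, columns=[c], response=response).aic

    while True:
        if len(cols) < 2:
            break
        corr = design[cols].corr().to_numpy()
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.abs(corr).argmax(), corr.shape)
        if np.abs(corr[i, j]) < r_max:
            break
        ci, cj = cols[i], cols[j]
        if ci in keep and cj in keep:
            report["pairs"].append({"pair": (ci, cj), "r": float(corr[i, j]), "kept_both": True})
            break
        if ci in keep:
            drop = cj
        elif cj in keep:
            drop = ci
        else:
            drop = ci if single_aic(ci) > single_aic(cj) else cj
        cols.remove(drop)
        report["pairs"].append({"pair": (ci, cj), "r": float(corr[i, j]), "dropped": drop})
        report["dropped"].append({"column": drop, "reason": f"|r|>= {r_max} with pair"})

    while len(cols) >= 2:
        vifs = _vif(design[cols].to_numpy(dtype=float))
        report["vif"] = {c: float(v) for c, v in zip(cols, vifs)}
        order = np.argsort(-vifs)
        droppable = [k for k in order if vifs[k] >= vif_max and cols[k] not in keep]
        if not droppable:
            break
        drop = cols[droppable[0]]
        report["dropped"].append({"column": drop, "reason": f"VIF {vifs[droppable[0]]:.2f} >= {vif_max}"})
        cols.remove(drop)
    if len(cols) >= 2:
        report["vif"] = {
            c: float(v) for c, v in zip(cols, _vif(design[cols].to_numpy(dtype=float)))
        }
    return cols, report


def backward_eliminate(
    design: pd.DataFrame, columns=None, keep=(), response: str = "presence"
) -> FittedLogistic:
    """Stepwise single-term deletion minimising AIC.

    At each step the one removal that most decreases AIC is taken; stops
    when no removal helps. ``keep`` columns (e.g. the spatial term) are
    never considered for removal.
    """
    cols = list(columns) if columns is not None else predictor_columns(design)
    keep = set(keep)
    current = fit_logistic(design, columns=cols, response=response)
    while True:
        best_fit, best_cols = None, None
        for c in cols:
            if c in keep:
                continue
            trial_cols = [x for x in cols if x != c]
            trial = fit_logistic(design, columns=trial_cols, response=response)
            if best_fit is None or trial.aic < best_fit.aic:
                best_fit, best_cols = trial, trial_cols
        if best_fit is not None and best_fit.aic < current.aic:
            current, cols = best_fit, best_cols
        else:
            return current


def compare_models(fits: dict[str, FittedLogistic]) -> pd.DataFrame:
    """Delta-AIC / Akaike-weight comparison of candidate fits."""
    if len(fits) < 2:
        raise ValueError("need at least two candidate models")
    nobs = {f.nobs for f in fits.values()}
    if len(nobs) != 1:
        raise ValueError("candidate models were fitted to different response lengths")
    return comparison_table(
        {name: (f.k_params, f.aic, f.log_likelihood) for name, f in fits.items()}
    )


def comparison_table(entries: dict[str, tuple[int, float, float]]) -> pd.DataFrame:
    """Build the comparison table from (K, AIC, LL) triples.

    Accepts externally reported AICs too, so published model sets can be
    re-ranked without refitting.
    """
    df = pd.DataFrame(
        [
            {"model": name, "K": k, "AIC": aic, "LL": ll}
            for name, (k, aic, ll) in entries.items()
        ]
    )
    df["delta_AIC"] = df["AIC"] - df["AIC"].min()
    w = np.exp(-df["delta_AIC"].to_numpy() / 2.0)
    df["akaike_weight"] = w / w.sum()
    return df.sort_values("AIC", kind="stable").reset_index(drop=True)
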