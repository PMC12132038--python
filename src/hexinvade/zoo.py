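"""Multi-model comparison: balanced sets, six learners, TSS, ensemble, VI.

The stage mirrors the standard species-distribution-model workflow: split
presences and absences 80/20 into training and evaluation pools, draw
balanced pseudo-absence sets (all training presences + an equal-size absence
draw, repeated ``n_absence_sets`` times), fit each model family on a 70/30
calibration/validation split (``n_cv`` repeats), score everything with the
True Skill Statistic (sensitivity + specificity - 1) at the TSS-maximising
calibration threshold, build a committee-averaging ensemble from members
with validation TSS above 0.6, and compare families by one-way ANOVA with
Welch-t/Holm pairwise contrasts. Variable importance is permutation-based:
1 - Pearson correlation between predictions before and after shuffling one
predictor.

Every random draw derives from one master seed through a fixed
SeedSequence stream-splitting scheme, so reruns are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier
from statsmodels.stats.multitest import multipletests

from .glmselect import predictor_columns
from .mars import HingeBasisMars

logger = logging.getLogger(__name__)

FAMILIES = ("GLM", "MARS", "ANN", "CTA", "GBM", "RF")

#: fixed, logged hyperparameters per model family
FAMILY_DEFAULTS: dict[str, dict] = {
    "GLM": {"C": np.inf, "max_iter": 2000},
    "MARS": {"max_terms": 15, "n_knots": 9, "penalty": 3.0},
    "ANN": {"hidden_layer_sizes": (8,), "max_iter": 2000},
    "CTA": {"ccp_alpha": 0.01},
    "GBM": {"n_estimators": 1000, "learning_rate": 0.01},
    "RF": {"n_estimators": 500},
}


class _Member:
    """A fitted learner with a uniform predict-probability surface."""

    def __init__(self, family: str, model, scaled: bool):
        self.family = family
        self.model = model
        self.scaled = scaled

    def predict_prob(self, X: np.ndarray) -> np.ndarray:
        if self.family == "MARS":
            return self.model.predict(X)
        return self.model.predict_proba(X)[:, 1]


def _make_member(family: str, seed: int) -> _Member:
    cfg = FAMILY_DEFAULTS[family]
    if family == "GLM":
        return _Member(family, LogisticRegression(**cfg), False)
    if family == "MARS":
        return _Member(family, HingeBasisMars(**cfg), False)
    if family == "ANN":
        est = make_pipeline(
            StandardScaler(), MLPClassifier(random_state=seed, **cfg)
        )
        return _Member(family, est, True)
    if family == "CTA":
        return _Member(family, DecisionTreeClassifier(random_state=seed, **cfg), False)
    if family == "GBM":
        return _Member(family, GradientBoostingClassifier(random_state=seed, **cfg), False)
    if family == "RF":
        return _Member(family, RandomForestClassifier(random_state=seed, n_jobs=1, **cfg), False)
    raise ValueError(f"unknown model family {family!r}")


# ---------------------------------------------------------------------------
# split plan and balanced sets


@dataclass
class SplitPlan:
    """80/20 presence/absence training-evaluation split plus repetition plan."""

    train_presence_ids: np.ndarray
    eval_presence_ids: np.ndarray
    train_absence_pool_ids: np.ndarray
    eval_absence_pool_ids: np.ndarray
    n_absence_sets: int = 10
    n_cv: int = 3
    cv_calibration_fraction: float = 0.70
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.cv_calibration_fraction < 1.0):
            raise ValueError("calibration fraction must lie in (0, 1)")
        sets = [
            set(np.asarray(a).tolist())
            for a in (
                self.train_presence_ids,
                self.eval_presence_ids,
                self.train_absence_pool_ids,
                self.eval_absence_pool_ids,
            )
        ]
        for i in range(4):
            for j in range(i + 1, 4):
                if sets[i] & sets[j]:
                    raise ValueError("split id sets must be disjoint")


def make_split_plan(
    design: pd.DataFrame,
    seed: int,
    train_fraction: float = 0.80,
    n_absence_sets: int = 10,
    n_cv: int = 3,
    cv_calibration_fraction: float = 0.70,
    response: str = "presence",
) -> SplitPlan:
    """Randomised 80/20 split of presences and absences into train/eval pools."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    pres = design.index.to_numpy()[design[response] == 1]
    absn = design.index.to_numpy()[design[response] == 0]
    pres = rng.permutation(pres)
    absn = rng.permutation(absn)
    n_tp = int(round(train_fraction * len(pres)))
    n_ta = int(round(train_fraction * len(absn)))
    return SplitPlan(
        train_presence_ids=np.sort(pres[:n_tp]),
        eval_presence_ids=np.sort(pres[n_tp:]),
        train_absence_pool_ids=np.sort(absn[:n_ta]),
        eval_absence_pool_ids=np.sort(absn[n_ta:]),
        n_absence_sets=n_absence_sets,
        n_cv=n_cv,
        cv_calibration_fraction=cv_calibration_fraction,
        seed=seed,
    )


def make_balanced_sets(presence_ids, absence_pool_ids, n_sets: int, seed: int) -> list[np.ndarray]:
    """Balanced training sets: all presences + an equal without-replacement
    absence draw per set (absences may recur across sets, never within one)."""
    presence_ids = np.asarray(presence_ids)
    pool = np.asarray(absence_pool_ids)
    n = len(presence_ids)
    if len(pool) < n:
        raise ValueError("absence pool smaller than the presence count")
    ss = np.random.SeedSequence([seed, 23])
    out = []
    for child in ss.spawn(n_sets):
        rng = np.random.default_rng(child)
        draw = rng.choice(pool, size=n, replace=False)
        out.append(np.concatenate([presence_ids, draw]))
    return out


# ---------------------------------------------------------------------------
# True Skill Statistic


def tss(predicted_prob, observed, threshold: float) -> float:
    """Sensitivity + specificity - 1 at a binarisation threshold."""
    p = np.asarray(predicted_prob, dtype=float)
    y = np.asarray(observed)
    if len(p) != len(y):
        raise ValueError("prediction and observation vectors differ in length")
    pos = y == 1
    neg = y == 0
    if not pos.any() or not neg.any():
        raise ValueError("TSS undefined: observations contain a single class")
    pred = p >= threshold
    sens = float((pred & pos).sum()) / float(pos.sum())
    spec = float((~pred & neg).sum()) / float(neg.sum())
    return sens + spec - 1.0


def best_threshold(predicted_prob, observed) -> tuple[float, float]:
    """TSS-maximising cutoff; candidates are midpoints of sorted unique
    predictions plus {0, 1}; ties break to the smallest threshold."""
    p = np.asarray(predicted_prob, dtype=float)
    y = np.asarray(observed)
    uniq = np.unique(p)
    cand = np.concatenate([[0.0], (uniq[:-1] + uniq[1:]) / 2.0, [1.0]]) if len(uniq) > 1 else np.array([0.0, 1.0])
    cand = np.unique(cand)
    pos = (y == 1).astype(float)
    neg = (y == 0).astype(float)
    if pos.sum() == 0 or neg.sum() == 0:
        raise ValueError("TSS undefined: observations contain a single class")
    pred = p[None, :] >= cand[:, None]
    sens = (pred * pos[None, :]).sum(axis=1) / pos.sum()
    spec = ((~pred) * neg[None, :]).sum(axis=1) / neg.sum()
    scores = sens + spec - 1.0
    best = int(np.argmax(scores))  # argmax returns the first (smallest) tie
    return float(cand[best]), float(scores[best])


# ---------------------------------------------------------------------------
# model runs


@dataclass
class ModelRun:
    """One fitted (family, absence set, cv) combination with its scores."""

    family: str
    absence_set_index: int
    cv_index: int
    model: object | None
    threshold: float | None
    tss_validation: float | None
    tss_evaluation: float | None
    status: str
    feature_names: tuple[str, ...] = ()
    calibration_ids: np.ndarray | None = None
    validation_ids: np.ndarray | None = None
    error: str | None = None

    def predict_prob(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if self.status != "ok":
            raise RuntimeError("cannot predict from a failed run")
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.feature_names if c not in X.columns]
            if missing:
                raise KeyError(f"predictor table missing columns: {missing}")
            X = X[list(self.feature_names)].to_numpy(dtype=float)
        return self.model.predict_prob(np.asarray(X, dtype=float))


def run_zoo(
    plan: SplitPlan,
    design: pd.DataFrame,
    families=FAMILIES,
    response: str = "presence",
    fail_hook=None,
) -> list[ModelRun]:
    """The full factorial: families x absence sets x cv runs.

    Each run fits on the 70% calibration slice of its balanced set, picks the
    TSS-maximising threshold on calibration predictions, scores
    ``tss_validation`` on the 30% slice and ``tss_evaluation`` on the held-out
    evaluation table (evaluation presences + an equal seeded absence draw).
    Exceptions are contained as status='failed' runs. ``fail_hook(family,
    set_idx, cv_idx)`` may force a failure (used to test containment).
    """
    feats = predictor_columns(design)
    ss = np.random.SeedSequence([plan.seed, 37])
    eval_rng = np.random.default_rng(ss.spawn(1)[0])
    n_eval_p = len(plan.eval_presence_ids)
    eval_abs = eval_rng.choice(plan.eval_absence_pool_ids, size=n_eval_p, replace=False)
    eval_ids = np.concatenate([plan.eval_presence_ids, eval_abs])
    X_eval = design.loc[eval_ids, feats].to_numpy(dtype=float)
    y_eval = design.loc[eval_ids, response].to_numpy()

    sets = make_balanced_sets(
        plan.train_presence_ids, plan.train_absence_pool_ids, plan.n_absence_sets, plan.seed
    )
    runs: list[ModelRun] = []
    for s_idx, ids in enumerate(sets):
        for cv_idx in range(plan.n_cv):
            split_rng = np.random.default_rng(
                np.random.SeedSequence([plan.seed, 53, s_idx, cv_idx])
            )
            perm = split_rng.permutation(ids)
            n_cal = int(round(plan.cv_calibration_fraction * len(perm)))
            cal_ids, val_ids = perm[:n_cal], perm[n_cal:]
            X_cal = design.loc[cal_ids, feats].to_numpy(dtype=float)
            y_cal = design.loc[cal_ids, response].to_numpy()
            X_val = design.loc[val_ids, feats].to_numpy(dtype=float)
            y_val = design.loc[val_ids, response].to_numpy()
            for family in families:
                seed = int(
                    np.random.SeedSequence(
                        [plan.seed, 71, s_idx, cv_idx, FAMILIES.index(family)]
                    ).generate_state(1)[0]
                    % (2**31 - 1)
                )
                try:
                    if fail_hook is not None and fail_hook(family, s_idx, cv_idx):
                        raise RuntimeError("forced failure")
                    member = _make_member(family, seed)
                    member.model.fit(X_cal, y_cal)
                    thr, _ = best_threshold(member.predict_prob(X_cal), y_cal)
                    runs.append(
                        ModelRun(
                            family=family,
                            absence_set_index=s_idx,
                            cv_index=cv_idx,
                            model=member,
                            threshold=thr,
                            tss_validation=tss(member.predict_prob(X_val), y_val, thr),
                            tss_evaluation=tss(member.predict_prob(X_eval), y_eval, thr),
                            status="ok",
                            feature_names=tuple(feats),
                            calibration_ids=cal_ids,
                            validation_ids=val_ids,
                        )
                    )
                except Exception as exc:  # failure containment is the contract
                    logger.warning(
                        "model run failed (family=%s set=%d cv=%d): %s",
                        family, s_idx, cv_idx, exc,
                    )
                    runs.append(
                        ModelRun(
                            family=family,
                            absence_set_index=s_idx,
                            cv_index=cv_idx,
                            model=None,
                            threshold=None,
                            tss_validation=None,
                            tss_evaluation=None,
                            status="failed",
                            feature_names=tuple(feats),
                            error=str(exc),
                        )
                    )
    if all(r.status == "failed" for r in runs):
        raise RuntimeError("every model run failed; check the design matrix")
    return runs


def runs_table(runs: list[ModelRun]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "family": r.family,
                "absence_set": r.absence_set_index,
                "cv": r.cv_index,
                "status": r.status,
                "threshold": r.threshold,
                "tss_validation": r.tss_validation,
                "tss_evaluation": r.tss_evaluation,
                "error": r.error,
            }
            for r in runs
        ]
    )


# ---------------------------------------------------------------------------
# committee-averaging ensemble


@dataclass
class EnsembleSpec:
    """Committee of qualifying runs voting thresholded binary predictions."""

    members: list[ModelRun]
    member_tss_min: float = 0.6
    # even splits (vote fraction exactly 0.5) resolve to absence


def make_ensemble(runs: list[ModelRun], member_tss_min: float = 0.6) -> EnsembleSpec:
    members = [
        r for r in runs if r.status == "ok" and r.tss_validation is not None
        and r.tss_validation > member_tss_min
    ]
    if not members:
        raise ValueError(
            f"no runs passed the TSS > {member_tss_min} filter; lower member_tss_min"
        )
    return EnsembleSpec(members=members, member_tss_min=member_tss_min)


def committee_predict(spec: EnsembleSpec, X) -> tuple[np.ndarray, np.ndarray]:
    """Majority vote of members' thresholded predictions.

    Returns (consensus binary vector, vote fraction). Consensus is presence
    iff the presence-vote fraction strictly exceeds 0.5; exact ties are
    conservative (absence), and the fraction lets users re-threshold.
    """
    if not spec.members:
        raise ValueError("ensemble has no members")
    votes = np.stack(
        [(r.predict_prob(X) >= r.threshold).astype(float) for r in spec.members]
    )
    frac = votes.mean(axis=0)
    return (frac > 0.5).astype(int), frac


def ensemble_runs(
    runs: list[ModelRun],
    design: pd.DataFrame,
    plan: SplitPlan,
    member_tss_min: float = 0.6,
    response: str = "presence",
) -> list[ModelRun]:
    """One committee per (absence set, cv) from that combination's qualifying
    family runs, scored like any other run (family = 'ENSEMBLE').

    The committee's vote fraction serves as its prediction score and 0.5 as
    its threshold when computing TSS.
    """
    feats = predictor_columns(design)
    ss = np.random.SeedSequence([plan.seed, 37])
    eval_rng = np.random.default_rng(ss.spawn(1)[0])
    eval_abs = eval_rng.choice(
        plan.eval_absence_pool_ids, size=len(plan.eval_presence_ids), replace=False
    )
    eval_ids = np.concatenate([plan.eval_presence_ids, eval_abs])
    out: list[ModelRun] = []
    groups: dict[tuple[int, int], list[ModelRun]] = {}
    for r in runs:
        if r.status == "ok":
            groups.setdefault((r.absence_set_index, r.cv_index), []).append(r)
    for (s_idx, cv_idx), group in sorted(groups.items()):
        members = [r for r in group if r.tss_validation > member_tss_min]
        if not members:
            out.append(
                ModelRun(
                    family="ENSEMBLE", absence_set_index=s_idx, cv_index=cv_idx,
                    model=None, threshold=None, tss_validation=None,
                    tss_evaluation=None, status="failed",
                    error="no members passed the TSS filter",
                )
            )
            continue
        spec = EnsembleSpec(members=members, member_tss_min=member_tss_min)
        val_ids = members[0].validation_ids
        _, frac_val = committee_predict(spec, design.loc[val_ids, feats].to_numpy(dtype=float))
        _, frac_eval = committee_predict(spec, design.loc[eval_ids, feats].to_numpy(dtype=float))
        y_val = design.loc[val_ids, response].to_numpy()
        y_eval = design.loc[eval_ids, response].to_numpy()
        out.append(
            ModelRun(
                family="ENSEMBLE",
                absence_set_index=s_idx,
                cv_index=cv_idx,
                model=spec,
                threshold=0.5,
                tss_validation=tss(np.where(frac_val > 0.5, 1.0, 0.0), y_val, 0.5),
                tss_evaluation=tss(np.where(frac_eval > 0.5, 1.0, 0.0), y_eval, 0.5),
                status="ok",
                feature_names=tuple(feats),
                validation_ids=val_ids,
            )
        )
    return out


# ---------------------------------------------------------------------------
# permutation variable importance and response curves


def permutation_importance(
    run: ModelRun, train_table: pd.DataFrame, n_rep: int = 6, seed: int = 0
) -> pd.Series:
    """VI = 1 - Pearson corr(original predictions, shuffled-column predictions).

    Averaged over ``n_rep`` seeded shuffles and clamped to [0, 1]; constant
    original predictions give VI = 0 (the correlation is degenerate).
    """
    if run.status != "ok":
        raise ValueError("cannot compute importance for a failed run")
    if n_rep < 1:
        raise ValueError("n_rep must be at least 1")
    feats = list(run.feature_names)
    X = train_table[feats].to_numpy(dtype=float)
    base = run.predict_prob(X)
    out = {}
    if np.std(base) < 1e-12:  # constant predictions: correlation degenerate
        return pd.Series({f: 0.0 for f in feats})
    for j, f in enumerate(feats):
        vals = []
        for child in np.random.SeedSequence([seed, 97, j]).spawn(n_rep):
            rng = np.random.default_rng(child)
            Xs = X.copy()
            Xs[:, j] = rng.permutation(Xs[:, j])
            pred = run.predict_prob(Xs)
            if np.std(pred) < 1e-12:
                corr = 0.0
            else:
                corr = float(np.corrcoef(base, pred)[0, 1])
            vals.append(1.0 - corr)
        out[f] = float(np.clip(np.mean(vals), 0.0, 1.0))
    return pd.Series(out)


def marginal_response(
    runs: list[ModelRun] | ModelRun,
    predictor: str,
    train_table: pd.DataFrame,
    grid_points: int = 25,
) -> pd.DataFrame:
    """Mean predicted probability along one predictor, others at reference.

    Reference values are the training medians of the continuous predictors
    and 0 for the dichotomous landcover flag. With several runs the curves
    are averaged and the standard error across runs reported.
    """
    if isinstance(runs, ModelRun):
        runs = [runs]
    runs = [r for r in runs if r.status == "ok"]
    if not runs:
        raise ValueError("no successful runs supplied")
    feats = list(runs[0].feature_names)
    if predictor not in feats:
        raise ValueError(f"unknown predictor name {predictor!r}")
    ref = {}
    for f in feats:
        ref[f] = 0.0 if f == "landcover" else float(train_table[f].median())
    vals = np.linspace(
        float(train_table[predictor].min()), float(train_table[predictor].max()), grid_points
    )
    X = pd.DataFrame({f: np.full(grid_points, ref[f]) for f in feats})
    X[predictor] = vals
    preds = np.stack([r.predict_prob(X) for r in runs])
    se = preds.std(axis=0, ddof=1) / np.sqrt(len(runs)) if len(runs) > 1 else np.zeros(grid_points)
    return pd.DataFrame(
        {"value": vals, "mean_prob": preds.mean(axis=0), "se": se, "predictor": predictor}
    )


# ---------------------------------------------------------------------------
# TSS comparison across families


def compare_tss(runs: list[ModelRun], which: str = "validation") -> dict:
    """One-way ANOVA of TSS by model family plus Welch-t/Holm pairwise tests."""
    if which not in ("validation", "evaluation"):
        raise ValueError("which must be 'validation' or 'evaluation'")
    col = f"tss_{which}"
    tab = runs_table(runs)
    tab = tab[tab["status"] == "ok"]
    groups = {}
    for fam, g in tab.groupby("family"):
        scores = g[col].dropna().to_numpy()
        if len(scores) < 2:
            logger.warning("family %s has <2 ok runs; excluded from comparison", fam)
            continue
        groups[fam] = scores
    if len(groups) < 2:
        raise ValueError("need at least two families with >= 2 runs each")
    fams = sorted(groups)
    F, p = stats.f_oneway(*[groups[f] for f in fams])
    n_total = sum(len(groups[f]) for f in fams)
    pairs = []
    for i in range(len(fams)):
        for j in range(i + 1, len(fams)):
            a, b = groups[fams[i]], groups[fams[j]]
            t, pt = stats.ttest_ind(a, b, equal_var=False)
            pairs.append(
                {
                    "family_a": fams[i],
                    "family_b": fams[j],
                    "mean_diff": float(a.mean() - b.mean()),
                    "t": float(t),
                    "p_raw": float(pt),
                }
            )
    pairwise = pd.DataFrame(pairs)
    pairwise["p_holm"] = multipletests(pairwise["p_raw"], method="holm")[1]
    return {
        "anova": {
            "F": float(F),
            "df1": len(fams) - 1,
            "df2": n_total - len(fams),
            "p": float(p),
        },
        "pairwise": pairwise,
        "means": {f: float(groups[f].mean()) for f in fams},
    }
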