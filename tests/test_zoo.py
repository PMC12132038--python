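"""Balanced sets, TSS scoring, the model factorial, committee ensemble,
permutation importance and family comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.linear_model import LogisticRegression

from conftest import FINAL_COLUMNS, StubModel, stub_run
from hexinvade import zoo
from hexinvade.mars import HingeBasisMars
from hexinvade.zoo import (
    EnsembleSpec,
    SplitPlan,
    best_threshold,
    committee_predict,
    compare_tss,
    make_balanced_sets,
    make_ensemble,
    make_split_plan,
    marginal_response,
    permutation_importance,
    run_zoo,
    runs_table,
    tss,
)


class TestSplitPlan:
    def test_eighty_twenty_presence_split(self, zoo_design):
        plan = make_split_plan(zoo_design, seed=1)
        n_pres = int(zoo_design["presence"].sum())
        assert len(plan.train_presence_ids) == round(0.8 * n_pres)
        assert len(plan.train_presence_ids) + len(plan.eval_presence_ids) == n_pres

    def test_id_sets_disjoint_and_exhaustive(self, zoo_design):
        plan = make_split_plan(zoo_design, seed=2)
        all_ids = np.concatenate(
            [plan.train_presence_ids, plan.eval_presence_ids,
             plan.train_absence_pool_ids, plan.eval_absence_pool_ids]
        )
        assert len(np.unique(all_ids)) == len(all_ids) == len(zoo_design)

    def test_invalid_calibration_fraction_rejected(self):
        with pytest.raises(ValueError):
            SplitPlan(
                train_presence_ids=np.array([0]), eval_presence_ids=np.array([1]),
                train_absence_pool_ids=np.array([2]), eval_absence_pool_ids=np.array([3]),
                cv_calibration_fraction=1.5,
            )


class TestBalancedSets:
    def test_set_size_doubles_presences(self):
        sets = make_balanced_sets(np.arange(1060), np.arange(2000, 20000), 10, seed=3)
        assert len(sets) == 10
        assert all(len(s) == 2120 for s in sets)

    def test_pool_equal_to_presences_returns_whole_pool(self):
        pres = np.arange(50)
        pool = np.arange(100, 150)
        (s,) = make_balanced_sets(pres, pool, 1, seed=4)
        assert set(s) == set(pres) | set(pool)

    def test_absences_distinct_within_a_set(self):
        sets = make_balanced_sets(np.arange(200), np.arange(500, 2000), 5, seed=5)
        for s in sets:
            absences = s[200:]
            assert len(np.unique(absences)) == len(absences)

    def test_pool_too_small_rejected(self):
        with pytest.raises(ValueError):
            make_balanced_sets(np.arange(100), np.arange(200, 250), 1, seed=6)


class TestTSS:
    def test_hand_tallied_contingency_table(self):
        # TP=40, FN=10, TN=35, FP=15 -> sens 0.8 + spec 0.7 - 1 = 0.5
        obs = np.array([1] * 50 + [0] * 50)
        pred = np.concatenate(
            [np.full(40, 0.9), np.full(10, 0.1), np.full(35, 0.1), np.full(15, 0.9)]
        )
        assert tss(pred, obs, 0.5) == pytest.approx(0.5)

    def test_perfect_separation_scores_one(self):
        obs = np.array([0, 0, 1, 1])
        assert tss(np.array([0.1, 0.2, 0.8, 0.9]), obs, 0.5) == 1.0

    def test_constant_predicted_class_scores_zero(self):
        obs = np.array([0, 1, 0, 1])
        assert tss(np.full(4, 0.9), obs, 0.5) == pytest.approx(0.0)
        assert tss(np.full(4, 0.1), obs, 0.5) == pytest.approx(0.0)

    def test_single_class_observations_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            tss(np.array([0.2, 0.8]), np.array([1, 1]), 0.5)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_invariant_under_joint_permutation(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        obs = np.array([0, 1] * (n // 2))
        pred = rng.random(n)
        perm = rng.permutation(n)
        assert tss(pred, obs, 0.4) == pytest.approx(tss(pred[perm], obs[perm], 0.4))


class TestBestThreshold:
    def test_binary_correct_predictions_score_one(self):
        obs = np.array([0, 0, 1, 1])
        thr, score = best_threshold(np.array([0.0, 0.0, 1.0, 1.0]), obs)
        assert score == 1.0
        assert 0.0 < thr <= 1.0

    def test_never_worse_than_half_threshold(self):
        rng = np.random.default_rng(20)
        for _ in range(20):
            obs = rng.integers(0, 2, 60)
            if obs.min() == obs.max():
                continue
            pred = rng.random(60)
            _, score = best_threshold(pred, obs)
            assert score >= tss(pred, obs, 0.5) - 1e-12

    def test_null_predictions_give_low_optimised_tss(self):
        rng = np.random.default_rng(21)
        obs = rng.integers(0, 2, 10_000)
        pred = rng.random(10_000)  # independent of obs
        _, score = best_threshold(pred, obs)
        assert score < 0.1


class TestRunZoo:
    def test_product_of_factorial_dimensions(self, zoo_design):
        plan = make_split_plan(zoo_design, seed=7, n_absence_sets=2, n_cv=1)
        runs = run_zoo(plan, zoo_design, families=("GLM", "CTA"))
        assert len(runs) == 4

    def test_scores_within_bounds_and_thresholds_recorded(self, zoo_runs):
        for r in zoo_runs:
            assert r.status == "ok"
            assert -1.0 <= r.tss_validation <= 1.0
            assert -1.0 <= r.tss_evaluation <= 1.0
            assert 0.0 <= r.threshold <= 1.0

    def test_failure_contained_without_aborting_batch(self, zoo_design):
        plan = make_split_plan(zoo_design, seed=8, n_absence_sets=2, n_cv=1)
        fail = lambda fam, s, cv: fam == "CTA" and s == 0 and cv == 0
        runs = run_zoo(plan, zoo_design, families=("GLM", "CTA"), fail_hook=fail)
        tab = runs_table(runs)
        assert (tab["status"] == "failed").sum() == 1
        assert (tab["status"] == "ok").sum() == 3
        failed = [r for r in runs if r.status == "failed"][0]
        assert failed.tss_validation is None and failed.threshold is None

    def test_rf_beats_the_skill_free_baseline(self, zoo_runs):
        # an intercept-only model has TSS ~ 0; RF should clear it by >= 0.3
        rf = [r.tss_evaluation for r in zoo_runs if r.family == "RF"]
        assert np.median(rf) >= 0.3

    def test_deterministic_under_master_seed(self, zoo_design):
        plan = make_split_plan(zoo_design, seed=9, n_absence_sets=1, n_cv=1)
        r1 = run_zoo(plan, zoo_design, families=("GLM",))
        r2 = run_zoo(plan, zoo_design, families=("GLM",))
        assert r1[0].tss_validation == r2[0].tss_validation
        assert r1[0].threshold == r2[0].threshold


class TestCommittee:
    def _member(self, votes, feature="x"):
        probs = np.asarray(votes, dtype=float)
        return stub_run(lambda X, p=probs: p[: len(X)], (feature,), threshold=0.5)

    def test_unanimous_members_return_their_label(self):
        X = np.zeros((3, 1))
        spec = EnsembleSpec(members=[self._member([1, 1, 0])] * 3)
        consensus, frac = committee_predict(spec, X)
        np.testing.assert_array_equal(consensus, [1, 1, 0])
        np.testing.assert_array_equal(frac, [1.0, 1.0, 0.0])

    def test_two_to_one_majority(self):
        X = np.zeros((1, 1))
        spec = EnsembleSpec(
            members=[self._member([1]), self._member([1]), self._member([0])]
        )
        consensus, frac = committee_predict(spec, X)
        assert consensus[0] == 1
        assert frac[0] == pytest.approx(2 / 3)

    def test_even_tie_resolves_to_absence(self):
        X = np.zeros((1, 1))
        spec = EnsembleSpec(members=[self._member([1]), self._member([0])])
        consensus, frac = committee_predict(spec, X)
        assert consensus[0] == 0
        assert frac[0] == 0.5

    def test_consensus_matches_independent_vote_count_oracle(self):
        rng = np.random.default_rng(33)
        for _ in range(100):
            n_members = int(rng.integers(1, 9))
            n_rows = int(rng.integers(1, 30))
            votes = rng.integers(0, 2, size=(n_members, n_rows))
            members = [self._member(v) for v in votes]
            consensus, frac = committee_predict(
                EnsembleSpec(members=members), np.zeros((n_rows, 1))
            )
            # oracle: literal per-row tally
            for j in range(n_rows):
                ones = sum(int(votes[i, j]) for i in range(n_members))
                expect = 1 if ones > n_members - ones else 0
                assert consensus[j] == expect

    def test_empty_filter_advises_lowering_threshold(self, zoo_runs):
        with pytest.raises(ValueError, match="member_tss_min"):
            make_ensemble(zoo_runs, member_tss_min=1.0)

    def test_filter_keeps_only_qualifying_runs(self, zoo_runs):
        spec = make_ensemble(zoo_runs, member_tss_min=0.6)
        assert all(r.tss_validation > 0.6 for r in spec.members)


class TestPermutationImportance:
    def test_ignored_predictor_has_zero_importance(self):
        rng = np.random.default_rng(40)
        table = pd.DataFrame({"x1": rng.standard_normal(500),
                              "x2": rng.standard_normal(500)})
        run = stub_run(lambda X: 1 / (1 + np.exp(-2 * X[:, 0])), ("x1", "x2"))
        vi = permutation_importance(run, table, n_rep=3, seed=1)
        assert vi["x2"] == pytest.approx(0.0, abs=1e-6)
        assert vi["x1"] > 0.0

    def test_constant_predictions_define_zero_importance(self):
        table = pd.DataFrame({"x1": np.arange(50.0)})
        run = stub_run(lambda X: np.full(len(X), 0.3), ("x1",))
        vi = permutation_importance(run, table, n_rep=2, seed=2)
        assert vi["x1"] == 0.0

    def test_strong_effect_matches_direct_recomputation_oracle(self):
        rng = np.random.default_rng(41)
        n = 2000
        x = rng.standard_normal(n)
        table = pd.DataFrame({"x": x})
        est = LogisticRegression(C=np.inf, max_iter=2000)
        y = (rng.random(n) < 1 / (1 + np.exp(-3 * x))).astype(int)
        est.fit(x.reshape(-1, 1), y)
        run = stub_run(lambda X: est.predict_proba(X)[:, 1], ("x",))
        vi = permutation_importance(run, table, n_rep=1, seed=7)
        # independent oracle: recompute 1 - corr with the same seeded shuffle
        rng_o = np.random.default_rng(np.random.SeedSequence([7, 97, 0]).spawn(1)[0])
        base = est.predict_proba(x.reshape(-1, 1))[:, 1]
        shuffled = est.predict_proba(rng_o.permutation(x).reshape(-1, 1))[:, 1]
        oracle = 1 - np.corrcoef(base, shuffled)[0, 1]
        assert vi["x"] > 0.5
        assert vi["x"] == pytest.approx(np.clip(oracle, 0, 1), abs=1e-12)

    def test_dominant_predictor_ranks_first_across_replicates(self):
        wins = 0
        for rep in range(20):
            rng = np.random.default_rng([rep, 43])
            n = 500
            X = rng.standard_normal((n, 3))
            y = (rng.random(n) < 1 / (1 + np.exp(-(2.5 * X[:, 0] + 0.2 * X[:, 1])))).astype(int)
            est = LogisticRegression(C=np.inf, max_iter=2000).fit(X, y)
            run = stub_run(lambda Z, e=est: e.predict_proba(Z)[:, 1], ("a", "b", "c"))
            table = pd.DataFrame(X, columns=["a", "b", "c"])
            vi = permutation_importance(run, table, n_rep=3, seed=rep)
            wins += int(vi.idxmax() == "a")
        assert wins >= 18


class TestMarginalResponse:
    def test_positive_glm_coefficient_gives_increasing_curve(self):
        rng = np.random.default_rng(50)
        table = pd.DataFrame({"x1": rng.standard_normal(300),
                              "x2": rng.standard_normal(300)})
        run = stub_run(lambda X: 1 / (1 + np.exp(-(0.3 + 1.5 * X[:, 0]))), ("x1", "x2"))
        curve = marginal_response(run, "x1", table, grid_points=15)
        assert (np.diff(curve["mean_prob"]) > 0).all()

    def test_intercept_only_model_gives_flat_curve(self):
        table = pd.DataFrame({"x1": np.linspace(-2, 2, 100)})
        run = stub_run(lambda X: np.full(len(X), 0.42), ("x1",))
        curve = marginal_response(run, "x1", table)
        assert curve["mean_prob"].nunique() == 1

    def test_curve_passes_through_all_median_prediction(self):
        rng = np.random.default_rng(51)
        table = pd.DataFrame({"x1": rng.standard_normal(101),
                              "x2": rng.standard_normal(101)})
        fn = lambda X: 1 / (1 + np.exp(-(0.2 + 0.8 * X[:, 0] - 0.5 * X[:, 1])))
        run = stub_run(fn, ("x1", "x2"))
        curve = marginal_response(run, "x1", table, grid_points=11)
        ref = np.array([[table["x1"].median(), table["x2"].median()]])
        expect = float(fn(ref)[0])
        med_val = table["x1"].median()
        interp = np.interp(med_val, curve["value"], curve["mean_prob"])
        assert interp == pytest.approx(expect, abs=5e-3)

    def test_unknown_predictor_rejected(self):
        run = stub_run(lambda X: np.full(len(X), 0.5), ("x1",))
        with pytest.raises(ValueError, match="unknown predictor"):
            marginal_response(run, "zz", pd.DataFrame({"x1": [1.0, 2.0]}))

    def test_landcover_held_at_zero(self):
        table = pd.DataFrame({"x1": np.linspace(0, 1, 20), "landcover": np.ones(20)})
        run = stub_run(lambda X: X[:, 1], ("x1", "landcover"))  # echoes landcover
        curve = marginal_response(run, "x1", table)
        assert (curve["mean_prob"] == 0).all()


def _fixed_runs(values_by_family):
    runs = []
    for fam, values in values_by_family.items():
        for i, v in enumerate(values):
            runs.append(
                zoo.ModelRun(
                    family=fam, absence_set_index=i, cv_index=0, model=None,
                    threshold=0.5, tss_validation=v, tss_evaluation=v, status="ok",
                )
            )
    return runs


class TestCompareTSS:
    def test_equal_family_means_give_zero_f(self):
        runs = _fixed_runs({"GLM": [0.5, 0.7], "RF": [0.6, 0.6], "CTA": [0.4, 0.8]})
        out = compare_tss(runs, "validation")
        assert out["anova"]["F"] == pytest.approx(0.0, abs=1e-12)

    def test_two_families_t_squared_equals_f(self):
        runs = _fixed_runs({"GLM": [0.52, 0.61, 0.55], "RF": [0.70, 0.66, 0.73]})
        out = compare_tss(runs, "validation")
        t = out["pairwise"].iloc[0]["t"]
        # with equal group sizes the Welch t equals the pooled t, so t^2 = F
        assert t**2 == pytest.approx(out["anova"]["F"], abs=1e-9)

    def test_f_matches_textbook_sums_of_squares_oracle(self):
        vals = {
            "GLM": [0.50, 0.55, 0.52, 0.58],
            "RF": [0.70, 0.72, 0.69, 0.74],
            "CTA": [0.60, 0.63, 0.61, 0.59],
        }
        out = compare_tss(_fixed_runs(vals), "evaluation")
        all_vals = np.concatenate([np.asarray(v) for v in vals.values()])
        grand = all_vals.mean()
        ss_between = sum(len(v) * (np.mean(v) - grand) ** 2 for v in vals.values())
        ss_within = sum(((np.asarray(v) - np.mean(v)) ** 2).sum() for v in vals.values())
        f_oracle = (ss_between / 2) / (ss_within / (12 - 3))
        assert out["anova"]["F"] == pytest.approx(f_oracle, rel=1e-12)
        assert out["anova"]["df1"] == 2
        assert out["anova"]["df2"] == 9

    def test_family_with_single_run_excluded(self):
        runs = _fixed_runs({"GLM": [0.5, 0.6], "RF": [0.7, 0.8], "ANN": [0.4]})
        out = compare_tss(runs, "validation")
        assert "ANN" not in out["means"]

    def test_holm_adjustment_is_monotone(self):
        runs = _fixed_runs(
            {"GLM": [0.50, 0.51, 0.52], "RF": [0.70, 0.71, 0.72], "CTA": [0.60, 0.61, 0.62]}
        )
        out = compare_tss(runs, "validation")
        assert (out["pairwise"]["p_holm"] >= out["pairwise"]["p_raw"] - 1e-15).all()


class TestEnsembleRuns:
    def test_one_committee_per_set_and_cv(self, zoo_runs, zoo_design, zoo_plan):
        ens = zoo.ensemble_runs(zoo_runs, zoo_design, zoo_plan, member_tss_min=0.3)
        assert len(ens) == zoo_plan.n_absence_sets * zoo_plan.n_cv
        for r in ens:
            assert r.family == "ENSEMBLE"
            assert r.status == "ok"
            assert -1 <= r.tss_validation <= 1


class TestMars:
    def test_learns_monotone_signal_and_bounds_predictions(self):
        rng = np.random.default_rng(60)
        X = rng.uniform(-2, 2, (400, 2))
        y = (rng.random(400) < 1 / (1 + np.exp(-3 * X[:, 0]))).astype(float)
        m = HingeBasisMars(max_terms=8).fit(X, y)
        pred = m.predict(X)
        assert pred.min() >= 0.0 and pred.max() <= 1.0
        lo = pred[X[:, 0] < -1].mean()
        hi = pred[X[:, 0] > 1].mean()
        assert hi - lo > 0.5

    def test_predict_before_fit_rejected(self):
        with pytest.raises(RuntimeError):
            HingeBasisMars().predict(np.zeros((2, 2)))
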