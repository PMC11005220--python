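import numpy as np
import pandas as pd
import pytest
from sklearn.tree import DecisionTreeRegressor

from eeai.clock import (
    ForestHyperparams,
    clock_to_json,
    fit_forest,
    importance_incnodepurity,
    load_clock,
    predict_ee_age,
    predict_serialized,
    save_clock,
    split_cohort,
    train_sparse_clock,
)
from eeai.errors import ParameterError, SchemaError
from eeai.features import FEATURE_COLUMNS


def brute_force_depth1(x: np.ndarray, y: np.ndarray):
    """Exhaustive best single split on one feature: (threshold, delta_sse)."""
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    sse = lambda v: float(np.sum((v - v.mean()) ** 2)) if len(v) else 0.0
    best = (None, 0.0)
    for i in range(1, len(xs)):
        if xs[i] == xs[i - 1]:
            continue
        thr = (xs[i] + xs[i - 1]) / 2.0
        delta = sse(ys) - sse(ys[:i]) - sse(ys[i:])
        if delta > best[1]:
            best = (thr, delta)
    return best


def ladder_table(n_per_age=4, seed=0, ages=(6, 20, 56, 64, 80)):
    """Synthetic feature table with age-informative and pure-noise columns."""
    rng = np.random.default_rng(seed)
    rows = []
    for age in ages:
        for i in range(n_per_age):
            row = {c: rng.normal() for c in FEATURE_COLUMNS}
            row["Weight"] = 20 + 0.2 * age + rng.normal(0, 0.5)
            row["EE"] = 0.6 - 0.004 * age + rng.normal(0, 0.01)
            row["VO2"] = 120 - 0.6 * age + rng.normal(0, 2.0)
            row["age_weeks"] = float(age)
            row["group"] = f"{age}w"
            rows.append(row)
    table = pd.DataFrame(rows)
    table.index = [f"m{i:02d}" for i in range(len(table))]
    return table


class TestSplitCohort:
    def test_17_animals_split_11_6(self):
        strata = [6] * 4 + [20] * 4 + [56] * 3 + [64] * 3 + [80] * 3
        ids = [f"m{i}" for i in range(17)]
        train, test = split_cohort(ids, strata, seed=0)
        assert (len(train), len(test)) == (11, 6)

    def test_floor_arithmetic(self):
        ids = [f"m{i}" for i in range(10)]
        train, test = split_cohort(ids, [1] * 10, train_frac=0.7, seed=1)
        assert (len(train), len(test)) == (7, 3)

    def test_deterministic(self):
        strata = [6, 6, 20, 20, 80, 80]
        ids = list("abcdef")
        assert split_cohort(ids, strata, seed=5) == split_cohort(ids, strata, seed=5)

    def test_every_stratum_reaches_training(self):
        strata = [6] * 4 + [20] * 4 + [56] * 3 + [64] * 3 + [80] * 3
        ids = [f"m{i}" for i in range(17)]
        train, _ = split_cohort(ids, strata, seed=2)
        train_strata = {strata[int(t[1:])] for t in train}
        assert train_strata == {6, 20, 56, 64, 80}

    def test_singleton_stratum_warns_into_train(self):
        ids = list("abcdefg")
        strata = [1, 1, 1, 2, 2, 2, 3]
        with pytest.warns(UserWarning, match="single animal"):
            train, _ = split_cohort(ids, strata, seed=0)
        assert "g" in train


class TestFitForest:
    def test_constant_target_predicts_constant(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 3))
        y = np.full(12, 40.0)
        model = fit_forest(X, y, ForestHyperparams(n_trees=20, seed=0))
        np.testing.assert_allclose(model.predict(X), 40.0)
        imp = importance_incnodepurity(model)
        np.testing.assert_allclose(imp.to_numpy(), 0.0)

    def test_informative_feature_ranked_first(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(30, 4))
            y = np.where(X[:, 2] > 0, 6.0, 0.0)  # step function of feature 2
            model = fit_forest(X, y, ForestHyperparams(n_trees=50, seed=seed))
            imp = importance_incnodepurity(model, ["a", "b", "c", "d"])
            hits += imp.index[0] == "c"
        assert hits >= 9

    def test_predictions_within_target_range(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 3))
        y = rng.uniform(6, 80, 20)
        model = fit_forest(X, y, ForestHyperparams(n_trees=30, seed=1))
        pred = model.predict(rng.normal(scale=5, size=(50, 3)))
        assert pred.min() >= y.min() - 1e-9
        assert pred.max() <= y.max() + 1e-9


class TestIncNodePurity:
    def test_hand_computed_single_split(self):
        # {(x=0,y=0)x3, (x=1,y=6)x3}: root SSE = 54, children pure -> delta 54
        X = np.array([[0.0]] * 3 + [[1.0]] * 3)
        y = np.array([0.0] * 3 + [6.0] * 3)
        model = fit_forest(
            X, y,
            ForestHyperparams(n_trees=1, min_leaf=3, bootstrap=False, seed=0),
        )
        imp = importance_incnodepurity(model, ["x"])
        assert imp["x"] == pytest.approx(54.0)

    def test_never_split_feature_zero(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.repeat([0.0, 1.0], 6), np.zeros(12)])
        y = np.repeat([0.0, 6.0], 6)
        model = fit_forest(
            X, y, ForestHyperparams(n_trees=10, m_try=2, bootstrap=False, seed=1)
        )
        imp = importance_incnodepurity(model, ["informative", "constant"])
        assert imp["constant"] == 0.0

    def test_depth1_matches_exhaustive_brute_force(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(5, 13))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            tree = DecisionTreeRegressor(max_depth=1, random_state=0)
            tree.fit(x[:, None], y)
            thr_bf, delta_bf = brute_force_depth1(x, y)
            if tree.tree_.node_count == 1:
                assert delta_bf == pytest.approx(0.0, abs=1e-12)
                continue
            # sklearn stores features as float32, so thresholds carry ~1e-7
            assert tree.tree_.threshold[0] == pytest.approx(thr_bf, abs=1e-6)
            t = tree.tree_
            node_sse = t.weighted_n_node_samples * t.impurity
            delta_tree = node_sse[0] - node_sse[1] - node_sse[2]
            assert delta_tree == pytest.approx(delta_bf, abs=1e-8)

    def test_duplicated_feature_splits_importance(self):
        totals, split_totals = [], []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=40)
            y = 2.0 * x + rng.normal(0, 0.3, 40)
            noise = rng.normal(size=40)
            # m_try = p so split choice is unaffected by the duplicate column
            # (with m_try < p the duplicate would raise the feature's
            # sampling probability and inflate the total)
            base = fit_forest(
                np.column_stack([x, noise]), y,
                ForestHyperparams(n_trees=100, m_try=2, seed=seed),
            )
            dup = fit_forest(
                np.column_stack([x, x, noise]), y,
                ForestHyperparams(n_trees=100, m_try=3, seed=seed),
            )
            totals.append(importance_incnodepurity(base)["x0"])
            d = importance_incnodepurity(dup)
            split_totals.append(d["x0"] + d["x1"])
        ratio = np.mean(split_totals) / np.mean(totals)
        assert ratio == pytest.approx(1.0, abs=0.10)


@pytest.fixture(scope="module")
def small_clock():
    table = ladder_table(n_per_age=4, seed=5)
    return table, train_sparse_clock(
        table, n_trees=60, cv_repeats=2, cv_folds=5, seed=5
    )


class TestSparseClock:

    def test_uses_exactly_six_features(self, small_clock):
        _, fit = small_clock
        assert len(fit.selected_features) == 6
        assert fit.sparse_model.n_features_in_ == 6

    def test_split_sizes_and_membership(self, small_clock):
        table, fit = small_clock
        assert len(fit.train_ids) == int(np.floor(0.7 * len(table)))
        assert set(fit.train_ids) | set(fit.test_ids) == set(table.index)
        assert not set(fit.train_ids) & set(fit.test_ids)

    def test_k_larger_than_p_rejected(self):
        with pytest.raises(ParameterError):
            train_sparse_clock(ladder_table(), k=15, n_trees=10)

    def test_determinism_bitwise(self):
        table = ladder_table(n_per_age=3, seed=2)
        kw = dict(n_trees=30, cv_repeats=1, cv_folds=3, seed=9)
        a = train_sparse_clock(table, **kw)
        b = train_sparse_clock(table, **kw)
        assert a.selected_features == b.selected_features
        np.testing.assert_array_equal(
            a.sparse_model.predict(table[a.selected_features].to_numpy()),
            b.sparse_model.predict(table[b.selected_features].to_numpy()),
        )
        pd.testing.assert_series_equal(a.importance, b.importance)

    def test_small_train_set_runs_folds_with_warning(self):
        # 17 animals -> train n=11 < 2*10: folds of size 1-2, flagged
        table = ladder_table(n_per_age=4, seed=1).iloc[:17]
        fit = train_sparse_clock(table, n_trees=20, cv_repeats=1, cv_folds=10,
                                 seed=3)
        assert any("folds" in w for w in fit.warnings_)

    def test_serialization_round_trip(self, tmp_path, small_clock):
        table, fit = small_clock
        path = tmp_path / "clock.json"
        save_clock(fit, path)
        payload = load_clock(path)
        X = table[fit.selected_features].to_numpy(float)
        np.testing.assert_allclose(
            predict_serialized(payload, X), fit.sparse_model.predict(X),
            rtol=0, atol=1e-9,
        )

    def test_predictions_within_training_range(self, small_clock):
        table, fit = small_clock
        per_animal, _, _ = predict_ee_age(fit, table)
        assert per_animal["ee_age_weeks"].between(6.0, 80.0).all()


class TestPredictEEAge:
    def test_empty_table_rejected(self, ):
        table = ladder_table(n_per_age=3, seed=0)
        fit = train_sparse_clock(table, n_trees=20, cv_repeats=1, cv_folds=3,
                                 seed=0)
        with pytest.raises(SchemaError):
            predict_ee_age(fit, table.iloc[:0])

    def test_missing_selected_feature_named(self):
        table = ladder_table(n_per_age=3, seed=0)
        fit = train_sparse_clock(table, n_trees=20, cv_repeats=1, cv_folds=3,
                                 seed=0)
        broken = table.drop(columns=[fit.selected_features[0]])
        with pytest.raises(SchemaError, match=fit.selected_features[0]):
            predict_ee_age(fit, broken)

    def test_group_summary_and_deltas(self):
        table = ladder_table(n_per_age=3, seed=4)
        fit = train_sparse_clock(table, n_trees=30, cv_repeats=1, cv_folds=3,
                                 seed=4)
        per_animal, summary, deltas = predict_ee_age(fit, table)
        assert set(summary.columns) == {"mean", "sd", "n"}
        row = deltas[(deltas.group_a == "80w") & (deltas.group_b == "6w")]
        assert row["delta_weeks"].iloc[0] > 0
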