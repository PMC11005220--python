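"""The energy-expenditure age clock: a sparse random-forest regression of age.

Construction mirrors a two-stage design common in biological-age clocks:

1. a *comprehensive* regression forest on all 14 candidate predictors, fitted
   on a stratified 70% training split of the untreated age-ladder animals;
2. predictors ranked by **IncNodePurity** — the total decrease in node
   sum-of-squared-errors attributable to splits on each feature, summed over
   every tree (the un-normalised impurity importance of a regression forest);
3. a *sparse* forest on the top-6 predictors, with mtry and minimum leaf size
   tuned by 5 repetitions of 10-fold cross-validation (mean RMSE) on the
   training split, refitted on the whole training split and evaluated on the
   held-out 30%.

Predicting a treated arm with the sparse model yields its "EE age"; the
difference of group means against aged controls is the rejuvenation delta.

The forest itself is scikit-learn's ``RandomForestRegressor`` with the
conventional regression defaults (500 trees, mtry = floor(p/3), minimum leaf
5, bootstrap on); IncNodePurity is computed here by walking each fitted
tree's node arrays, because the library's ``feature_importances_`` is
normalised and averaged, which is a different statistic.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import RepeatedKFold

from .errors import ParameterError, SchemaError
from .features import FEATURE_COLUMNS

SERIALIZATION_VERSION = 1


@dataclass
class ForestHyperparams:
    n_trees: int = 500
    m_try: int | None = None   # None -> floor(p/3), min 1
    min_leaf: int = 5
    bootstrap: bool = True
    seed: int = 0

    def resolve_m_try(self, p: int) -> int:
        m = self.m_try if self.m_try is not None else max(p // 3, 1)
        if not 1 <= m <= p:
            raise ParameterError(f"m_try {m} outside [1, {p}]")
        return m


@dataclass
class ClockFit:
    full_model: RandomForestRegressor
    importance: pd.Series              # IncNodePurity, sorted descending
    selected_features: list[str]
    sparse_model: RandomForestRegressor
    best_hyperparams: ForestHyperparams
    cv_results: pd.DataFrame           # per (config, repeat, fold) RMSE/MAE
    cv_rmse: float                     # mean CV RMSE of the chosen config
    train_ids: list[str]
    test_ids: list[str]
    test_metrics: dict[str, float]     # RMSE / MAE / R2 on held-out 30%
    seed: int = 0
    oob_rmse: float | None = None
    warnings_: list[str] = field(default_factory=list)


def split_cohort(
    ids: Sequence[str],
    strata: Sequence,
    train_frac: float = 0.7,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Stratified train/test partition with |train| = floor(train_frac * n).

    Training slots are allocated across strata (age groups) by largest
    remainder so every stratum reaches the training set when its size
    permits; a stratum of size 1 goes entirely to training with a warning.
    Deterministic given ``seed``.  A 17-animal ladder yields (11, 6).
    """
    ids = [str(i) for i in ids]
    n = len(ids)
    if n < 2:
        raise ParameterError("need at least 2 animals to split")
    n_train = int(np.floor(train_frac * n))
    rng = np.random.default_rng(seed)
    strata = np.asarray(strata)
    labels = pd.unique(strata)

    sizes = {lab: int(np.sum(strata == lab)) for lab in labels}
    ideal = {lab: train_frac * sizes[lab] for lab in labels}
    alloc = {lab: min(int(np.floor(ideal[lab])), sizes[lab]) for lab in labels}
    # every stratum with >1 member keeps at least one training animal;
    # singletons are forced into training (cannot be both split)
    for lab in labels:
        if sizes[lab] == 1:
            if alloc[lab] == 0:
                warnings.warn(
                    f"stratum {lab!r} has a single animal; assigned to train"
                )
            alloc[lab] = 1
        elif alloc[lab] == 0:
            alloc[lab] = 1
    while sum(alloc.values()) > n_train:
        lab = max(
            (l for l in labels if alloc[l] > 1),
            key=lambda l: alloc[l] - ideal[l],
            default=None,
        )
        if lab is None:
            break
        alloc[lab] -= 1
    remainders = sorted(
        labels,
        key=lambda l: (ideal[l] - alloc[l], sizes[l]),
        reverse=True,
    )
    i = 0
    while sum(alloc.values()) < n_train:
        lab = remainders[i % len(remainders)]
        if alloc[lab] < sizes[lab]:
            alloc[lab] += 1
        i += 1

    train: list[str] = []
    for lab in labels:
        members = [ids[j] for j in np.flatnonzero(strata == lab)]
        chosen = rng.choice(len(members), size=alloc[lab], replace=False)
        train.extend(members[j] for j in sorted(chosen))
    train_set = set(train)
    test = [i for i in ids if i not in train_set]
    train = [i for i in ids if i in train_set]  # stable original order
    return train, test


def fit_forest(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    hp: ForestHyperparams | None = None,
) -> RandomForestRegressor:
    """Grow a bagged regression forest (SSE split criterion, mean prediction)."""
    hp = hp or ForestHyperparams()
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if np.isnan(X).any() or np.isnan(y).any():
        raise ParameterError("fit_forest requires complete data")
    if len(y) < 2:
        raise ParameterError("need at least 2 samples")
    model = RandomForestRegressor(
        n_estimators=hp.n_trees,
        max_features=hp.resolve_m_try(X.shape[1]),
        min_samples_leaf=hp.min_leaf,
        bootstrap=hp.bootstrap,
        oob_score=hp.bootstrap,
        criterion="squared_error",
        random_state=int(hp.seed) % 2**31,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # small-n OOB coverage warnings
        model.fit(X, y)
    return model


def importance_incnodepurity(
    model: RandomForestRegressor,
    feature_names: Sequence[str] | None = None,
) -> pd.Series:
    """Total decrease in node SSE per feature, summed over all trees.

    For every internal node, the SSE decrease is ``N*imp - N_l*imp_l -
    N_r*imp_r`` on the tree's (in-bag) samples, where ``imp`` is the node's
    mean squared error and ``N`` its weighted sample count.  Features never
    split on score 0.  Sorted descending.
    """
    p = model.n_features_in_
    names = list(feature_names) if feature_names is not None else [
        f"x{i}" for i in range(p)
    ]
    total = np.zeros(p)
    for est in model.estimators_:
        t = est.tree_
        internal = t.children_left != -1
        node_sse = t.weighted_n_node_samples * t.impurity
        delta = (
            node_sse[internal]
            - node_sse[t.children_left[internal]]
            - node_sse[t.children_right[internal]]
        )
        np.add.at(total, t.feature[internal], delta)
    s = pd.Series(total, index=names, name="IncNodePurity")
    return s.sort_values(ascending=False, kind="stable")


def _rmse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean((a - b) ** 2)))


def train_sparse_clock(
    table: pd.DataFrame,
    k: int = 6,
    cv_repeats: int = 5,
    cv_folds: int = 10,
    hp_grid: Sequence[ForestHyperparams] | None = None,
    n_trees: int = 500,
    seed: int = 0,
    train_frac: float = 0.7,
) -> ClockFit:
    """Fit the two-stage sparse EE-age clock on an age-ladder feature table.

    ``table`` must carry the 14 feature columns plus ``age_weeks`` (and is
    expected to contain untreated animals only — treated arms are scored
    later, never trained on).  See the module docstring for the procedure.
    """
    missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"feature table lacks columns {missing}")
    if "age_weeks" not in table.columns:
        raise SchemaError("feature table lacks 'age_weeks'")
    p = len(FEATURE_COLUMNS)
    if k > p:
        raise ParameterError(f"k = {k} exceeds the {p} available features")

    warns: list[str] = []
    ids = [str(i) for i in table.index]
    train_ids, test_ids = split_cohort(
        ids, table["age_weeks"].to_numpy(), train_frac=train_frac, seed=seed
    )
    train = table.loc[train_ids]
    test = table.loc[test_ids]
    X_train = train[list(FEATURE_COLUMNS)].to_numpy(float)
    y_train = train["age_weeks"].to_numpy(float)

    full_hp = ForestHyperparams(n_trees=n_trees, seed=seed)
    full_model = fit_forest(X_train, y_train, full_hp)
    importance = importance_incnodepurity(full_model, FEATURE_COLUMNS)
    # ties broken by the canonical predictor order for reproducibility
    order = sorted(
        FEATURE_COLUMNS,
        key=lambda f: (-importance[f], FEATURE_COLUMNS.index(f)),
    )
    selected = order[:k]

    if hp_grid is None:
        hp_grid = [
            ForestHyperparams(n_trees=n_trees, m_try=m, min_leaf=leaf, seed=seed)
            for m in range(1, k + 1)
            for leaf in (2, 5)
        ]
    n_train = len(train_ids)
    folds = cv_folds
    if n_train < folds:
        folds = max(2, n_train)
        warns.append(f"reduced CV folds from {cv_folds} to {folds} (n={n_train})")
    elif n_train < 2 * folds:
        warns.append(f"CV folds of size 1–2 with n={n_train}; executed as-is")

    Xs = train[selected].to_numpy(float)
    cv_rows = []
    for ci, hp in enumerate(hp_grid):
        splitter = RepeatedKFold(
            n_splits=folds, n_repeats=cv_repeats, random_state=seed
        )
        for fi, (tr, va) in enumerate(splitter.split(Xs)):
            model = fit_forest(Xs[tr], y_train[tr], hp)
            pred = model.predict(Xs[va])
            cv_rows.append(
                {
                    "config": ci,
                    "m_try": hp.resolve_m_try(k),
                    "min_leaf": hp.min_leaf,
                    "repeat": fi // folds,
                    "fold": fi % folds,
                    "rmse": _rmse(pred, y_train[va]),
                    "mae": float(np.mean(np.abs(pred - y_train[va]))),
                }
            )
    cv_results = pd.DataFrame(cv_rows)
    mean_rmse = cv_results.groupby("config")["rmse"].mean()
    best_ci = int(mean_rmse.idxmin())  # ties -> lowest config index
    best_hp = hp_grid[best_ci]

    sparse_model = fit_forest(Xs, y_train, best_hp)
    X_test = test[selected].to_numpy(float)
    y_test = test["age_weeks"].to_numpy(float)
    pred_test = sparse_model.predict(X_test)
    ss_res = float(np.sum((y_test - pred_test) ** 2))
    ss_tot = float(np.sum((y_test - y_test.mean()) ** 2))
    test_metrics = {
        "rmse": _rmse(pred_test, y_test),
        "mae": float(np.mean(np.abs(pred_test - y_test))),
        "r2": 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan,
    }
    oob = getattr(sparse_model, "oob_prediction_", None)
    oob_rmse = _rmse(oob, y_train) if oob is not None else None

    return ClockFit(
        full_model=full_model,
        importance=importance,
        selected_features=selected,
        sparse_model=sparse_model,
        best_hyperparams=best_hp,
        cv_results=cv_results,
        cv_rmse=float(mean_rmse.loc[best_ci]),
        train_ids=train_ids,
        test_ids=test_ids,
        test_metrics=test_metrics,
        seed=seed,
        oob_rmse=oob_rmse,
        warnings_=warns,
    )


def predict_ee_age(
    clock: ClockFit | Mapping, table: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Score animals with the sparse clock.

    Returns (per-animal predictions, per-group mean ± SD, pairwise group
    deltas ``meanA - meanB``).  ``table`` needs the clock's selected feature
    columns and a ``group`` column.
    """
    if isinstance(clock, Mapping):
        clock_features = list(clock["selected_features"])
        predict = lambda X: predict_serialized(clock, X)  # noqa: E731
    else:
        clock_features = clock.selected_features
        predict = clock.sparse_model.predict
    if len(table) == 0:
        raise SchemaError("empty feature table")
    missing = [c for c in clock_features if c not in table.columns]
    if missing:
        raise SchemaError(f"feature table lacks selected feature(s) {missing}")
    X = table[clock_features].to_numpy(float)
    pred = np.asarray(predict(X), float)
    per_animal = pd.DataFrame(
        {
            "ee_age_weeks": pred,
            "group": table["group"].to_numpy() if "group" in table else "all",
        },
        index=table.index,
    )
    if "age_weeks" in table:
        per_animal["age_weeks"] = table["age_weeks"].to_numpy()
    summary = per_animal.groupby("group")["ee_age_weeks"].agg(
        mean="mean", sd=lambda s: s.std(ddof=1), n="count"
    )
    groups = list(summary.index)
    deltas = pd.DataFrame(
        [
            {
                "group_a": a,
                "group_b": b,
                "delta_weeks": summary.loc[a, "mean"] - summary.loc[b, "mean"],
            }
            for a in groups
            for b in groups
            if a != b
        ]
    )
    return per_animal, summary, deltas


# ---------------------------------------------------------------------------
# JSON serialization: trees as flat node-array records, library-independent
# ---------------------------------------------------------------------------

def _tree_to_dict(est) -> dict:
    t = est.tree_
    return {
        "children_left": t.children_left.tolist(),
        "children_right": t.children_right.tolist(),
        "feature": t.feature.tolist(),
        "threshold": t.threshold.tolist(),
        "value": t.value.reshape(-1).tolist(),
    }


def clock_to_json(clock: ClockFit) -> dict:
    """Serialize the sparse clock (features + trees) to a JSON-able dict."""
    hp = clock.best_hyperparams
    return {
        "version": SERIALIZATION_VERSION,
        "selected_features": clock.selected_features,
        "hyperparams": {
            "n_trees": hp.n_trees,
            "m_try": hp.resolve_m_try(len(clock.selected_features)),
            "min_leaf": hp.min_leaf,
            "seed": hp.seed,
        },
        "seed": clock.seed,
        "cv_rmse": clock.cv_rmse,
        "test_metrics": clock.test_metrics,
        "train_ids": clock.train_ids,
        "test_ids": clock.test_ids,
        "importance": {k: float(v) for k, v in clock.importance.items()},
        "trees": [_tree_to_dict(est) for est in clock.sparse_model.estimators_],
    }


def save_clock(clock: ClockFit, path) -> None:
    with open(path, "w") as fh:
        json.dump(clock_to_json(clock), fh)


def load_clock(path) -> dict:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("version") != SERIALIZATION_VERSION:
        raise SchemaError(
            f"unsupported clock serialization version {payload.get('version')}"
        )
    return payload


def _predict_tree(tree: dict, X: np.ndarray) -> np.ndarray:
    left = np.asarray(tree["children_left"])
    right = np.asarray(tree["children_right"])
    feat = np.asarray(tree["feature"])
    thr = np.asarray(tree["threshold"])
    val = np.asarray(tree["value"])
    out = np.empty(X.shape[0])
    for i, x in enumerate(X):
        node = 0
        while left[node] != -1:
            node = left[node] if x[feat[node]] <= thr[node] else right[node]
        out[i] = val[node]
    return out


def predict_serialized(payload: Mapping, X: np.ndarray) -> np.ndarray:
    """Predict from a JSON-round-tripped clock by direct tree traversal."""
    X = np.asarray(X, float)
    preds = np.stack([_predict_tree(t, X) for t in payload["trees"]])
    return preds.mean(axis=0)
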