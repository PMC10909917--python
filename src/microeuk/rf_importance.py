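"""Permutation-based significance of random-forest predictor importance.

A bagged regression forest predicts a functional-group share from the
environment matrix.  Importance is the percent increase in out-of-bag
(OOB) mean squared error when one predictor's values are permuted
(%IncMSE); its significance comes from a response-permutation null: the
whole forest is refit ``n_null`` times with y shuffled and each observed
%IncMSE is compared with its own null distribution.  Model-level summaries
are the OOB explained variance and a k-fold cross-validated R².

The tree learner is scikit-learn's; the contribution here is the
permutation-null inference and cross-validation around it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import BaggingRegressor
from sklearn.model_selection import KFold, cross_val_predict
from sklearn.tree import DecisionTreeRegressor


@dataclass
class ImportanceResult:
    importances: pd.DataFrame  # per predictor: mse_increase_pct, p_value
    explained_variance_pct: float
    cv_r2: float
    n_null_permutations: int


def _make_forest(n_trees: int, n_predictors: int, seed) -> BaggingRegressor:
    mtry = max(1, n_predictors // 3)
    return BaggingRegressor(
        estimator=DecisionTreeRegressor(max_features=mtry, random_state=0),
        n_estimators=n_trees,
        bootstrap=True,
        random_state=seed,
    )


def _oob_predictions(forest: BaggingRegressor, x32: np.ndarray,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-sample OOB prediction sums: baseline and per-permuted-predictor.

    Each predictor is permuted per tree over that tree's OOB rows,
    mirroring the classical forest importance definition.  float32 inputs
    allow validation-free tree prediction.
    """
    n, p = x32.shape
    pred_sum = np.zeros(n)
    pred_sum_perm = np.zeros((p, n))
    pred_cnt = np.zeros(n)
    for tree, samples in zip(forest.estimators_, forest.estimators_samples_):
        oob = np.ones(n, dtype=bool)
        oob[samples] = False
        if not oob.any():
            continue
        x_oob = x32[oob]
        pred_sum[oob] += tree.predict(x_oob, check_input=False)
        pred_cnt[oob] += 1
        for j in range(p):
            x_perm = x_oob.copy()
            x_perm[:, j] = rng.permutation(x_perm[:, j])
            pred_sum_perm[j, oob] += tree.predict(x_perm, check_input=False)
    return pred_sum, pred_sum_perm, pred_cnt


def _pct_inc_mse(x32: np.ndarray, y: np.ndarray, n_trees: int, seed,
                 rng: np.random.Generator) -> tuple[np.ndarray, float]:
    forest = _make_forest(n_trees, x32.shape[1], seed)
    forest.fit(x32, y)
    pred_sum, pred_sum_perm, pred_cnt = _oob_predictions(forest, x32, rng)
    have = pred_cnt > 0
    base = float(((y[have] - pred_sum[have] / pred_cnt[have]) ** 2).mean())
    inc = np.empty(x32.shape[1])
    for j in range(x32.shape[1]):
        mse_j = float(((y[have] - pred_sum_perm[j, have] / pred_cnt[have]) ** 2).mean())
        inc[j] = 100.0 * (mse_j - base) / base
    var_y = float(((y - y.mean()) ** 2).mean())
    explained = 100.0 * (1.0 - base / var_y)
    return inc, explained


def rf_importance(
    x_env,
    y,
    n_trees: int = 1000,
    n_null: int = 999,
    cv_folds: int = 5,
    seed: int | None = None,
) -> ImportanceResult:
    """%IncMSE importance of each environment variable with permutation p.

    p = (1 + #{null %IncMSE >= observed}) / (1 + n_null); the null refits
    the forest on a permuted response.  Fixed seed gives bit-identical
    results.
    """
    xdf = pd.DataFrame(x_env).astype(float)
    y = np.asarray(y, dtype=float)
    if len(y) < 20:
        raise ValueError("need at least 20 samples")
    if np.ptp(y) == 0:
        raise ValueError("constant response")
    if not np.all(np.isfinite(xdf.to_numpy())):
        raise ValueError("non-finite predictors")
    x = np.ascontiguousarray(xdf.to_numpy(), dtype=np.float32)
    rng = np.random.default_rng(seed)

    obs_inc, explained = _pct_inc_mse(x, y, n_trees, int(rng.integers(2**31)), rng)

    ge = np.zeros(x.shape[1])
    for _ in range(n_null):
        y_null = rng.permutation(y)
        null_inc, _ = _pct_inc_mse(x, y_null, n_trees, int(rng.integers(2**31)), rng)
        ge += null_inc >= obs_inc - 1e-12
    p = (1 + ge) / (1 + n_null)

    cv = KFold(n_splits=cv_folds, shuffle=True, random_state=int(rng.integers(2**31)))
    forest_cv = _make_forest(n_trees, x.shape[1], int(rng.integers(2**31)))
    pred = cross_val_predict(forest_cv, x, y, cv=cv)
    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    cv_r2 = 1.0 - ss_res / ss_tot

    table = pd.DataFrame(
        {"mse_increase_pct": obs_inc, "p_value": p},
        index=pd.Index(xdf.columns, name="predictor"),
    ).sort_values("mse_increase_pct", ascending=False)
    return ImportanceResult(table, explained, cv_r2, n_null)
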