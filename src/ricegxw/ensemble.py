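"""Two-layer stacked ensemble of ten learners for county-year yield.

Layer 1 holds ten regressors drawn from two families — five tree-based
(two gradient-boosting variants, random forest, AdaBoost, and an
extreme-gradient-boosting model) and five regression-based (LASSO,
elastic net, Bayesian ridge, support-vector, and stochastic-gradient
regression). Layer 2 combines their predictions; the meta-learner is
non-negative least squares over base predictions plus an intercept, so
stacking weights are interpretable as a convex-ish blend. The meta-learner
is fitted on out-of-fold layer-1 predictions (k-fold within the training
set) to avoid leakage, after which base learners are refitted on the full
training set.

All learners are seeded and single-threaded, so fit + predict is
reproducible bit-for-bit under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.base import clone
from sklearn.compose import TransformedTargetRegressor
from sklearn.ensemble import (
    AdaBoostRegressor,
    GradientBoostingRegressor,
    HistGradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.linear_model import BayesianRidge, ElasticNet, Lasso, SGDRegressor
from sklearn.model_selection import KFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor
from xgboost import XGBRegressor

from .features import FeatureMatrix, PCATransform, as_frame, fit_pca
from .metrics import MetricReport

#: learner slot -> family; the roster spans boosting, bagging and
#: regularized/kernel regression so ensemble uncertainty is not dominated
#: by one algorithm class.
LEARNER_FAMILIES: dict[str, str] = {
    "hist_boost": "tree",
    "gradient_boost": "tree",
    "random_forest": "tree",
    "adaboost": "tree",
    "xgboost": "tree",
    "lasso": "regression",
    "elastic_net": "regression",
    "bayesian_ridge": "regression",
    "svr": "regression",
    "sgd": "regression",
}


def make_base_learners(
    seed: int = 0, hyperparameters: Mapping[str, Mapping] | None = None
) -> dict[str, object]:
    """The ten layer-1 regressors with modest default hyperparameters.

    ``hyperparameters`` maps slot name to keyword overrides for that
    learner (e.g. loaded from a config file). Scale-sensitive learners are
    wrapped with input (and for SVR/SGD, target) standardization.
    """
    hp = {k: dict(v) for k, v in (hyperparameters or {}).items()}

    def params(name, **defaults):
        defaults.update(hp.get(name, {}))
        return defaults

    learners: dict[str, object] = {
        "hist_boost": HistGradientBoostingRegressor(
            **params("hist_boost", max_iter=200, learning_rate=0.1, random_state=seed)
        ),
        "gradient_boost": GradientBoostingRegressor(
            **params("gradient_boost", n_estimators=200, max_depth=3, random_state=seed)
        ),
        "random_forest": RandomForestRegressor(
            **params(
                "random_forest",
                n_estimators=200,
                max_features=0.5,
                n_jobs=1,
                random_state=seed,
            )
        ),
        "adaboost": AdaBoostRegressor(
            estimator=DecisionTreeRegressor(max_depth=4, random_state=seed),
            **params("adaboost", n_estimators=100, learning_rate=0.5, random_state=seed),
        ),
        "xgboost": XGBRegressor(
            **params(
                "xgboost",
                n_estimators=200,
                max_depth=4,
                learning_rate=0.1,
                n_jobs=1,
                random_state=seed,
                verbosity=0,
            )
        ),
        "lasso": make_pipeline(
            StandardScaler(), Lasso(**params("lasso", alpha=1.0, max_iter=5000))
        ),
        "elastic_net": make_pipeline(
            StandardScaler(),
            ElasticNet(**params("elastic_net", alpha=1.0, l1_ratio=0.5, max_iter=5000)),
        ),
        "bayesian_ridge": make_pipeline(StandardScaler(), BayesianRidge(**params("bayesian_ridge"))),
        "svr": TransformedTargetRegressor(
            regressor=make_pipeline(
                StandardScaler(), SVR(**params("svr", C=10.0, epsilon=0.1))
            ),
            transformer=StandardScaler(),
        ),
        "sgd": TransformedTargetRegressor(
            regressor=make_pipeline(
                StandardScaler(),
                SGDRegressor(
                    **params("sgd", max_iter=2000, tol=1e-4, random_state=seed)
                ),
            ),
            transformer=StandardScaler(),
        ),
    }
    return learners


def _fit_meta(base_preds: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Non-negative least squares stacking weights plus free intercept."""
    p_mean = base_preds.mean(axis=0)
    y_mean = y.mean()
    w, _ = nnls(base_preds - p_mean, y - y_mean)
    return w, float(y_mean - p_mean @ w)


@dataclass
class StackedEnsemble:
    """A fitted two-layer stack: frozen preprocessing (standardizer + PCA),
    ten fitted base learners, and NNLS meta-weights over their predictions."""

    pca: PCATransform
    base_learners: dict[str, object]
    meta_weights: np.ndarray
    meta_intercept: float
    feature_columns: pd.Index
    seed: int
    n_folds: int

    def __post_init__(self) -> None:
        if not self.base_learners:
            raise ValueError("the stack needs at least one base learner")

    def base_predictions(self, features) -> pd.DataFrame:
        df = as_frame(features)
        if isinstance(df, pd.DataFrame) and not df.columns.equals(self.feature_columns):
            raise KeyError("feature columns do not match the fitted model")
        Z = self.pca.transform(df)
        return pd.DataFrame(
            {name: est.predict(Z) for name, est in self.base_learners.items()},
            index=df.index if isinstance(df, pd.DataFrame) else None,
        )

    def predict(self, features) -> np.ndarray:
        """Meta-learner output (kg/ha) for feature rows."""
        P = self.base_predictions(features).to_numpy()
        return self.meta_intercept + P @ self.meta_weights

    @property
    def stacking_weights(self) -> pd.Series:
        return pd.Series(self.meta_weights, index=list(self.base_learners))


def fit_ensemble(
    features,
    yields,
    n_components: int = 85,
    n_folds: int = 5,
    seed: int = 0,
    hyperparameters: Mapping | None = None,
    learners: dict[str, object] | None = None,
) -> StackedEnsemble:
    """Fit preprocessing, base learners, and the stacking meta-learner.

    The PCA (and its standardizer) is fitted on the supplied training rows;
    out-of-fold base predictions from a seeded ``n_folds`` split train the
    meta-learner; base learners are then refitted on all rows. Requested
    components are capped at the rank bound of the training block.
    """
    df = as_frame(features)
    y = np.asarray(yields, float)
    if len(df) != len(y):
        raise ValueError("features and yields must align row-wise")
    if not np.isfinite(y).all():
        raise ValueError("non-finite targets")
    if len(y) < n_folds:
        raise ValueError(f"need at least {n_folds} rows for {n_folds}-fold stacking")

    if learners is None:
        learners = make_base_learners(seed=seed, hyperparameters=hyperparameters)

    n_varying = int((df.to_numpy(float).std(axis=0) > 0).sum())
    pca = fit_pca(df, n_components=min(n_components, len(df), n_varying))
    Z = pca.transform(df)

    names = list(learners)
    oof = np.full((len(y), len(names)), np.nan)
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for tr, te in kf.split(Z):
        for j, name in enumerate(names):
            est = clone(learners[name])
            est.fit(Z[tr], y[tr])
            oof[te, j] = est.predict(Z[te])
    w, b = _fit_meta(oof, y)
    if w.sum() == 0.0:  # degenerate: fall back to equal weights
        w = np.full(len(names), 1.0 / len(names))
        b = float(y.mean() - oof.mean(axis=0) @ w)

    fitted = {}
    for name in names:
        est = clone(learners[name])
        est.fit(Z, y)
        fitted[name] = est

    return StackedEnsemble(
        pca=pca,
        base_learners=fitted,
        meta_weights=w,
        meta_intercept=b,
        feature_columns=df.columns,
        seed=seed,
        n_folds=n_folds,
    )


def cross_validate(
    features,
    yields,
    split: float = 0.75,
    seed: int = 0,
    n_components: int = 85,
    n_folds: int = 5,
    hyperparameters: Mapping | None = None,
    repeats: int = 1,
):
    """Single seeded 75/25 development/test evaluation (optionally repeated).

    Returns a dict with the fitted model from the first repeat, ensemble
    train/test MetricReports, and per-learner reports for both phases.
    With ``repeats > 1`` the reports list covers all repeats (fresh splits)
    for variance estimates.
    """
    if not 0 < split < 1:
        raise ValueError("split must lie in (0, 1)")
    df = as_frame(features)
    y = np.asarray(yields, float)
    n = len(y)
    n_train = int(round(split * n))
    if n_train < 2 or n - n_train < 2:
        raise ValueError("degenerate split sizes")

    reports: list[MetricReport] = []
    model0 = None
    for rep in range(repeats):
        rng = np.random.default_rng(seed + rep)
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        model = fit_ensemble(
            df.iloc[tr],
            y[tr],
            n_components=n_components,
            n_folds=n_folds,
            seed=seed + rep,
            hyperparameters=hyperparameters,
        )
        if model0 is None:
            model0 = model
        for phase, idx in (("train", tr), ("test", te)):
            X_phase = df.iloc[idx]
            reports.append(
                MetricReport.from_predictions(y[idx], model.predict(X_phase), phase)
            )
            base = model.base_predictions(X_phase)
            for name in base.columns:
                reports.append(
                    MetricReport.from_predictions(
                        y[idx], base[name].to_numpy(), phase, learner=name
                    )
                )
    ens = [r for r in reports if r.learner == "ensemble"]
    return {
        "model": model0,
        "train": [r for r in ens if r.phase == "train"][0],
        "test": [r for r in ens if r.phase == "test"][0],
        "reports": reports,
    }


def reports_to_frame(reports) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "learner": r.learner,
                "phase": r.phase,
                "nse": r.nse,
                "r": r.r,
                "rmse": r.rmse,
                "n": r.n,
            }
            for r in reports
        ]
    )
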