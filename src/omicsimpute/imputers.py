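"""Eight imputation methods behind one dispatch.

Five constant fills (feature minimum, minimum/5, maximum, median, mean) and
three multivariate methods (k-nearest-neighbour, chained random forest,
chained equations) are exposed as sklearn-style transformers operating on a
samples x features table with NaN-coded missing cells. ``impute`` dispatches
a :class:`MethodSpec` onto an :class:`OmicsMatrix`, imputing each declared
feature group independently.

All transformers guarantee: observed cells are returned unchanged, and the
output contains no missing cells.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer, KNNImputer
from sklearn.linear_model import BayesianRidge
from sklearn.utils.validation import check_is_fitted

from .data_model import OmicsMatrix
from .exceptions import (
    HyperparameterError,
    NeedsCovariatesError,
    UninformativeFeatureError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Method",
    "MethodSpec",
    "METHOD_ORDER",
    "ConstantFillImputer",
    "KNNSampleImputer",
    "ChainedForestImputer",
    "ChainedEquationsImputer",
    "make_imputer",
    "impute",
    "impute_knn",
    "impute_rf",
    "impute_mice",
]


class Method(str, Enum):
    MIN = "MIN"
    MIN5 = "MIN5"
    MAX = "MAX"
    MEDIAN = "MEDIAN"
    MEAN = "MEAN"
    KNN = "KNN"
    RF = "RF"
    MICE = "MICE"


#: canonical method order; ties in method selection break toward the earlier entry
METHOD_ORDER: tuple[Method, ...] = (
    Method.MIN, Method.MIN5, Method.MAX, Method.MEDIAN,
    Method.MEAN, Method.KNN, Method.RF, Method.MICE,
)

MULTIVARIATE: frozenset[Method] = frozenset({Method.KNN, Method.RF, Method.MICE})


@dataclass(frozen=True)
class MethodSpec:
    """One imputation method plus its hyperparameters.

    Defaults (k=10 neighbours, 500 trees, 2 chained-equation sweeps) are the
    simple-optimization settings.
    """

    method: Method
    k: int = 10
    n_trees: int = 500
    n_iter: int = 2

    def __post_init__(self) -> None:
        object.__setattr__(self, "method", Method(self.method))
        if self.k < 1:
            raise HyperparameterError(f"k must be >= 1, got {self.k}")
        if self.n_trees < 1:
            raise HyperparameterError(f"n_trees must be >= 1, got {self.n_trees}")
        if self.n_iter < 1:
            raise HyperparameterError(f"n_iter must be >= 1, got {self.n_iter}")

    @property
    def hyperparameter(self) -> int | None:
        """The active hyperparameter for the multivariate methods, else None."""
        return {Method.KNN: self.k, Method.RF: self.n_trees,
                Method.MICE: self.n_iter}.get(self.method)

    def with_hyperparameter(self, value: int) -> "MethodSpec":
        field = {Method.KNN: "k", Method.RF: "n_trees", Method.MICE: "n_iter"}[self.method]
        return replace(self, **{field: int(value)})


# ---------------------------------------------------------------------------
# array-level helpers
# ---------------------------------------------------------------------------

def _as_array(X) -> np.ndarray:
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D samples x features array, got shape {arr.shape}")
    return arr


def _check_informative(arr: np.ndarray) -> None:
    dead = np.flatnonzero(np.all(np.isnan(arr), axis=0))
    if dead.size:
        raise UninformativeFeatureError(
            f"feature column(s) {dead.tolist()} contain no observed values"
        )


class _MatrixImputer(TransformerMixin, BaseEstimator):
    """Shared transformer plumbing: validation and frame round-trip."""

    def fit_transform(self, X, y=None, **kwargs):
        frame = X if isinstance(X, pd.DataFrame) else None
        out = self.fit(X, y)._transform_array(_as_array(X))
        if frame is not None:
            return pd.DataFrame(out, index=frame.index, columns=frame.columns)
        return out

    def transform(self, X):
        check_is_fitted(self)
        frame = X if isinstance(X, pd.DataFrame) else None
        out = self._transform_array(_as_array(X))
        if frame is not None:
            return pd.DataFrame(out, index=frame.index, columns=frame.columns)
        return out

    def _transform_array(self, arr: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class ConstantFillImputer(_MatrixImputer):
    """Fill each feature's missing cells with a per-feature constant.

    Parameters
    ----------
    strategy : {"min", "min5", "max", "median", "mean"}
        Statistic of the feature's observed values ("min5" is the observed
        minimum divided by 5).
    """

    _STATS = {
        "min": np.nanmin,
        "min5": lambda a, axis: np.nanmin(a, axis=axis) / 5.0,
        "max": np.nanmax,
        "median": np.nanmedian,
        "mean": np.nanmean,
    }

    def __init__(self, strategy: str = "mean"):
        self.strategy = strategy

    def fit(self, X, y=None):
        if self.strategy not in self._STATS:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        arr = _as_array(X)
        _check_informative(arr)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            self.statistics_ = self._STATS[self.strategy](arr, axis=0)
        self.n_features_in_ = arr.shape[1]
        return self

    def _transform_array(self, arr: np.ndarray) -> np.ndarray:
        out = arr.copy()
        miss = np.isnan(out)
        out[miss] = np.broadcast_to(self.statistics_, out.shape)[miss]
        return out


class KNNSampleImputer(_MatrixImputer):
    """k-nearest-neighbour imputation in z-scored feature space.

    Features are standardised (observed mean/SD), neighbours found by
    nan-Euclidean distance over mutually observed features, the missing cell
    filled with the unweighted mean of the k nearest samples' values, and
    the result scaled back. A sample sharing no observed feature with any
    neighbour falls back to the feature mean.
    """

    def __init__(self, n_neighbors: int = 10):
        self.n_neighbors = n_neighbors

    def fit(self, X, y=None):
        arr = _as_array(X)
        _check_informative(arr)
        if self.n_neighbors >= arr.shape[0]:
            raise HyperparameterError(
                f"k={self.n_neighbors} must be smaller than the number of samples "
                f"({arr.shape[0]})"
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            self.center_ = np.nanmean(arr, axis=0)
            scale = np.nanstd(arr, axis=0)
        scale[~np.isfinite(scale) | (scale == 0.0)] = 1.0
        self.scale_ = scale
        self._imputer = KNNImputer(n_neighbors=self.n_neighbors, weights="uniform")
        self._imputer.fit((arr - self.center_) / self.scale_)
        self.n_features_in_ = arr.shape[1]
        return self

    def _transform_array(self, arr: np.ndarray) -> np.ndarray:
        z = (arr - self.center_) / self.scale_
        filled = self._imputer.transform(z) * self.scale_ + self.center_
        out = arr.copy()
        miss = np.isnan(out)
        out[miss] = filled[miss]
        return out


class ChainedForestImputer(_MatrixImputer):
    """Chained random-forest imputation (missForest-style).

    Missing cells are initialised with feature means; features are visited
    in increasing-missingness order, each regressed on all other features
    with a random forest of ``n_estimators`` bagged random trees and its
    missing cells overwritten with the forest's predictions. Sweeps repeat
    until the imputed values stop changing (relative successive change
    below ``tol``, or increasing — the missForest stopping family) or
    ``max_sweeps`` sweeps have run.

    The per-feature forests are LightGBM's random-forest mode (bagging
    fraction 0.632 per tree, ``sqrt(p)`` feature subsampling as in
    ranger), which keeps per-tree overhead low enough for the full
    tree-count grid search.
    """

    def __init__(self, n_estimators: int = 500, max_sweeps: int = 10,
                 tol: float = 1e-3, random_state: int | None = None):
        self.n_estimators = n_estimators
        self.max_sweeps = max_sweeps
        self.tol = tol
        self.random_state = random_state

    def _forest_seed(self, sweep: int, j: int) -> int:
        base = 0 if self.random_state is None else int(self.random_state)
        ss = np.random.SeedSequence([base, 5, sweep, j])
        return int(ss.generate_state(1)[0] % (2**31))

    def _make_forest(self, n_covariates: int, seed: int):
        import lightgbm as lgb

        frac = max(np.sqrt(n_covariates) / n_covariates, 1.0 / n_covariates)
        return lgb.LGBMRegressor(
            boosting_type="rf",
            n_estimators=self.n_estimators,
            bagging_fraction=0.632,
            bagging_freq=1,
            feature_fraction=min(frac, 0.9999) if n_covariates > 1 else 0.9999,
            min_child_samples=2,
            min_data_in_bin=1,
            n_jobs=1,
            deterministic=True,
            random_state=seed,
            verbose=-1,
        )

    @staticmethod
    def _safe_predict(model, X: np.ndarray, fallback: np.ndarray) -> np.ndarray:
        """Forest predictions, falling back to the current fill where the
        forest yields no finite value (too few rows survived bagging)."""
        pred = np.asarray(model.predict(X), dtype=float)
        bad = ~np.isfinite(pred)
        if bad.any():
            pred[bad] = fallback[bad]
        return pred

    def fit(self, X, y=None):
        arr = _as_array(X)
        if arr.shape[1] < 2:
            raise NeedsCovariatesError(
                "chained random-forest imputation needs at least 2 features"
            )
        _check_informative(arr)
        miss = np.isnan(arr)
        self.statistics_ = np.nanmean(arr, axis=0)
        filled = arr.copy()
        for j in range(arr.shape[1]):
            filled[miss[:, j], j] = self.statistics_[j]

        order = [j for j in np.argsort(miss.sum(axis=0), kind="stable") if miss[:, j].any()]
        self.order_ = [int(j) for j in order]
        self.sweeps_: list[dict[int, object]] = []
        prev_delta = np.inf
        denom = max(float(np.nansum(arr**2)), 1e-12)
        for sweep in range(self.max_sweeps):
            models: dict[int, object] = {}
            before = filled.copy()
            for j in self.order_:
                obs = ~miss[:, j]
                if obs.sum() < 2:
                    # not enough observed rows to regress on; keep the mean fill
                    logger.warning("feature column %d has %d observed value(s); "
                                   "mean fill retained", j, int(obs.sum()))
                    models[j] = None
                    continue
                others = np.delete(np.arange(arr.shape[1]), j)
                rf = self._make_forest(len(others), self._forest_seed(sweep, j))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rf.fit(filled[np.ix_(obs, others)], arr[obs, j])
                    models[j] = rf
                    filled[miss[:, j], j] = self._safe_predict(
                        rf, filled[np.ix_(miss[:, j], others)], filled[miss[:, j], j])
            self.sweeps_.append(models)
            delta = float(((filled - before) ** 2).sum()) / denom
            if delta >= prev_delta or delta < self.tol * 1e-3:
                break
            prev_delta = delta
        self.n_features_in_ = arr.shape[1]
        return self

    def _transform_array(self, arr: np.ndarray) -> np.ndarray:
        miss = np.isnan(arr)
        filled = arr.copy()
        for j in range(arr.shape[1]):
            filled[miss[:, j], j] = self.statistics_[j]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for models in self.sweeps_:
                for j in self.order_:
                    col_miss = miss[:, j]
                    if not col_miss.any() or models[j] is None:
                        continue
                    others = np.delete(np.arange(arr.shape[1]), j)
                    filled[col_miss, j] = self._safe_predict(
                        models[j], filled[np.ix_(col_miss, others)], filled[col_miss, j])
        out = arr.copy()
        out[miss] = filled[miss]
        return out


class ChainedEquationsImputer(_MatrixImputer):
    """Chained-equations single imputation.

    ``n_iter`` full sweeps of per-feature Bayesian linear regression on all
    other features, with posterior-draw noise, returning one completed
    dataset (no multiple-imputation pooling).
    """

    def __init__(self, n_iter: int = 2, random_state: int | None = None):
        self.n_iter = n_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        arr = _as_array(X)
        if arr.shape[1] < 2:
            raise NeedsCovariatesError(
                "chained-equations imputation needs at least 2 features"
            )
        if self.n_iter < 1:
            raise HyperparameterError(f"n_iter must be >= 1, got {self.n_iter}")
        _check_informative(arr)
        self._imputer = IterativeImputer(
            estimator=BayesianRidge(),
            sample_posterior=True,
            max_iter=self.n_iter,
            random_state=0 if self.random_state is None else int(self.random_state) % (2**31),
            skip_complete=True,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", UserWarning)
            self._imputer.fit(arr)
        self.n_features_in_ = arr.shape[1]
        return self

    def _transform_array(self, arr: np.ndarray) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", UserWarning)
            filled = self._imputer.transform(arr)
        out = arr.copy()
        miss = np.isnan(out)
        out[miss] = filled[miss]
        return out


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def make_imputer(spec: MethodSpec, seed: int = 0) -> _MatrixImputer:
    """Build the transformer matching a :class:`MethodSpec`."""
    m = spec.method
    if m in (Method.MIN, Method.MIN5, Method.MAX, Method.MEDIAN, Method.MEAN):
        return ConstantFillImputer(strategy=m.value.lower())
    if m is Method.KNN:
        return KNNSampleImputer(n_neighbors=spec.k)
    if m is Method.RF:
        return ChainedForestImputer(n_estimators=spec.n_trees, random_state=seed)
    return ChainedEquationsImputer(n_iter=spec.n_iter, random_state=seed)


def impute(m: OmicsMatrix, spec: MethodSpec, seed: int = 0) -> OmicsMatrix:
    """Impute every missing cell of ``m`` with the given method.

    When feature groups are declared each group is imputed independently,
    so values in one group can never influence imputations in another.
    """
    blocks = m.group_columns()
    pieces: dict[str, pd.DataFrame] = {}
    for g_idx, label in enumerate(sorted(blocks)):
        sub = m.values[blocks[label]]
        est = make_imputer(spec, seed=_group_seed(seed, g_idx))
        pieces[label] = est.fit_transform(sub)
    out = pd.concat([pieces[label] for label in sorted(blocks)], axis=1)
    out = out[m.feature_ids]
    return OmicsMatrix(out, None if m.groups is None else dict(m.groups))


def _group_seed(seed: int, g_idx: int) -> int:
    return int(np.random.SeedSequence([int(seed), 7, g_idx]).generate_state(1)[0] % (2**31))


def impute_knn(m: OmicsMatrix, k: int = 10, seed: int = 0) -> OmicsMatrix:
    return impute(m, MethodSpec(Method.KNN, k=k), seed)


def impute_rf(m: OmicsMatrix, n_trees: int = 500, seed: int = 0) -> OmicsMatrix:
    return impute(m, MethodSpec(Method.RF, n_trees=n_trees), seed)


def impute_mice(m: OmicsMatrix, n_iter: int = 2, seed: int = 0) -> OmicsMatrix:
    return impute(m, MethodSpec(Method.MICE, n_iter=n_iter), seed)
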