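"""Imputation-method selection by held-out MAPE across missingness simulations.

The optimization workflow: extract a fully observed submatrix of the user's
data (falling back down a ladder of selection rules when no complete sample
exists), simulate MCAR / MAR / MNAR missingness on it at a threshold
(default 30% of cells), impute each simulated dataset with all eight
methods, score every method on the hidden cells by mean absolute percentage
error, and recommend the method with the lowest mean MAPE across the three
mechanisms. The original matrix is then imputed with the recommendation.

``ImputationOptimizer`` wraps the workflow as an sklearn-style estimator:
``fit`` runs the selection, ``transform`` applies the recommended method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .data_model import OmicsMatrix
from .exceptions import (
    BudgetError,
    EligibilityError,
    OptimizationImpossibleError,
    UndefinedMAPEError,
)
from .imputers import METHOD_ORDER, MULTIVARIATE, Method, MethodSpec, impute
from .missingness import Mechanism, SimulatedDataset, simulate

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_THRESHOLD",
    "MIN_SAMPLES",
    "MIN_FEATURES",
    "MIN_OBSERVED",
    "KNN_COARSE_GRID",
    "RF_TREE_GRID",
    "MICE_ITER_GRID",
    "Eligibility",
    "SubsetPath",
    "CompleteSubset",
    "OptimizationReport",
    "check_eligibility",
    "extract_complete_subset",
    "mape",
    "search_hyperparameters",
    "run_optimization",
    "ImputationOptimizer",
]

DEFAULT_THRESHOLD = 0.30
MIN_SAMPLES = 6
MIN_FEATURES = 3
MIN_OBSERVED = 18
#: reduced-selection rung drops features with >= this percent missing
REDUCTION_PCT = 80.0

#: coarse k grid "10 to 100 in steps of 20" (100 itself is unreachable by
#: step 20 from 10); a refined +/-4 search follows around the coarse best
KNN_COARSE_GRID: tuple[int, ...] = (10, 30, 50, 70, 90)
KNN_REFINE_SPAN = 4
RF_TREE_GRID: tuple[int, ...] = (5, 10, 20, 50, 100, 150, 200, 500)
MICE_ITER_GRID: tuple[int, ...] = (1, 2, 3)

MECHANISMS: tuple[Mechanism, ...] = (Mechanism.MCAR, Mechanism.MAR, Mechanism.MNAR)


# ---------------------------------------------------------------------------
# eligibility and complete-subset extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Eligibility:
    eligible: bool
    reason: str | None = None

    def __bool__(self) -> bool:
        return self.eligible


def check_eligibility(m: OmicsMatrix) -> Eligibility:
    """Is the dataset big enough for method optimization?

    Requires at least 6 samples, 3 features, and 18 observed values.
    """
    if m.n_samples < MIN_SAMPLES:
        return Eligibility(False, f"needs >= {MIN_SAMPLES} samples, has {m.n_samples}")
    if m.n_features < MIN_FEATURES:
        return Eligibility(False, f"needs >= {MIN_FEATURES} features, has {m.n_features}")
    if m.n_observed < MIN_OBSERVED:
        return Eligibility(
            False, f"needs >= {MIN_OBSERVED} observed values, has {m.n_observed}"
        )
    return Eligibility(True)


class SubsetPath(str, Enum):
    ROWS = "ROWS"
    COLS = "COLS"
    REDUCED_ROWS = "REDUCED_ROWS"
    REDUCED_COLS = "REDUCED_COLS"


@dataclass
class CompleteSubset:
    """A fully observed submatrix and the ladder rung that produced it."""

    submatrix: OmicsMatrix
    path: SubsetPath
    dropped_samples: list[str] = field(default_factory=list)
    dropped_features: list[str] = field(default_factory=list)


def _complete_dims_ok(m: OmicsMatrix) -> bool:
    return m.n_samples >= MIN_SAMPLES and m.n_features >= MIN_FEATURES


def extract_complete_subset(m: OmicsMatrix) -> CompleteSubset:
    """Extract the complete submatrix used for missingness simulation.

    Ladder: (1) samples with no missing values; (2) features with no
    missing values; (3) drop features with >= 80% missing, then retry (1)
    and (2) on the reduced matrix. The first rung whose complete submatrix
    still spans >= 6 samples and >= 3 features wins.
    """
    mask = m.mask

    def rows_rung(mat: OmicsMatrix, reduced_drop: list[str], reduced: bool):
        keep = ~mat.mask.any(axis=1)
        sub = mat.subset(samples=mat.values.index[keep])
        if _complete_dims_ok(sub):
            path = SubsetPath.REDUCED_ROWS if reduced else SubsetPath.ROWS
            dropped = [str(s) for s in mat.values.index[~keep]]
            return CompleteSubset(sub, path, dropped, list(reduced_drop))
        return None

    def cols_rung(mat: OmicsMatrix, reduced_drop: list[str], reduced: bool):
        keep = ~mat.mask.any(axis=0)
        sub = mat.subset(features=mat.values.columns[keep])
        if _complete_dims_ok(sub):
            path = SubsetPath.REDUCED_COLS if reduced else SubsetPath.COLS
            dropped = [str(f) for f in mat.values.columns[~keep]]
            return CompleteSubset(sub, path, [], list(reduced_drop) + dropped)
        return None

    for rung in (rows_rung, cols_rung):
        found = rung(m, [], reduced=False)
        if found is not None:
            return found

    pct_missing = 100.0 * mask.to_numpy().mean(axis=0)
    keep = pct_missing < REDUCTION_PCT
    reduced_drop = [str(f) for f in m.values.columns[~keep]]
    reduced = m.subset(features=m.values.columns[keep]) if keep.any() else None
    if reduced is not None:
        for rung in (rows_rung, cols_rung):
            found = rung(reduced, reduced_drop, reduced=True)
            if found is not None:
                return found
    raise OptimizationImpossibleError(
        "no selection rung yields a complete submatrix with at least "
        f"{MIN_SAMPLES} samples and {MIN_FEATURES} features; "
        "optimization of imputation cannot be done"
    )


# ---------------------------------------------------------------------------
# MAPE
# ---------------------------------------------------------------------------

def mape(truth, predicted, *, return_excluded: bool = False):
    """Mean absolute percentage error, ``100/N * sum(|x - y| / x)``.

    Pairs with a non-positive truth value are excluded (with a logged
    count) because the relative error is undefined there; if every pair is
    excluded a :class:`UndefinedMAPEError` is raised.
    """
    x = np.asarray(truth, dtype=float)
    y = np.asarray(predicted, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size == 0:
        raise ValueError("truth and predicted must be equal-length non-empty vectors")
    valid = x > 0
    n_excluded = int((~valid).sum())
    if n_excluded:
        logger.warning("MAPE: excluded %d pair(s) with non-positive truth values", n_excluded)
    if not valid.any():
        raise UndefinedMAPEError("every truth value is non-positive; MAPE undefined")
    value = float(100.0 * np.mean(np.abs(x[valid] - y[valid]) / x[valid]))
    if return_excluded:
        return value, n_excluded
    return value


def _score(sim: SimulatedDataset, spec: MethodSpec, seed: int) -> float:
    """Impute one simulated dataset and score it on the hidden cells."""
    filled = impute(sim.masked, spec, seed=seed)
    return mape(sim.holdout_truth, sim.holdout_predictions(filled))


# ---------------------------------------------------------------------------
# hyperparameter search
# ---------------------------------------------------------------------------

def _knn_grids(n_samples: int) -> list[int]:
    grid = [k for k in KNN_COARSE_GRID if k < n_samples]
    if not grid:
        grid = [max(1, n_samples - 1)]
        logger.warning(
            "every coarse k exceeds n_samples-1=%d; clipped grid to %s",
            n_samples - 1, grid,
        )
    return grid


def search_hyperparameters(
    sims: SimulatedDataset | list[SimulatedDataset],
    method: Method,
    mode: str = "simple",
    seed: int = 0,
) -> tuple[int, float, dict[int, list[float]]]:
    """Grid-search the multivariate method's hyperparameter on simulated data.

    ``sims`` may be one simulated dataset or one per mechanism; each grid
    value is scored per dataset by held-out MAPE. Simple mode evaluates
    only the default (k=10 / 500 trees / 2 iterations). Full mode scans the
    printed grids — k in {10, 30, 50, 70, 90} (clipped to feasible values)
    plus a refined k*-4..k*+4 pass, trees in {5, 10, 20, 50, 100, 150,
    200, 500}, iterations in {1, 2, 3} — with ties going to the smaller
    value.

    Returns ``(best_value, best_mean_mape, evaluations)`` where
    ``evaluations`` maps each evaluated grid value to its per-dataset MAPEs.
    """
    if isinstance(sims, SimulatedDataset):
        sims = [sims]
    method = Method(method)
    if method not in MULTIVARIATE:
        raise ValueError(f"{method} has no hyperparameter to search")
    base = MethodSpec(method)
    evaluations: dict[int, list[float]] = {}

    def evaluate(value: int) -> float:
        if value not in evaluations:
            spec = base.with_hyperparameter(value)
            evaluations[value] = [_score(s, spec, seed) for s in sims]
        return float(np.mean(evaluations[value]))

    def best_of(values) -> int:
        # ties break toward the smaller hyperparameter
        return min(sorted(set(values)), key=lambda v: (evaluate(v), v))

    n_samples = sims[0].masked.n_samples
    if mode == "simple":
        best = base.hyperparameter
        if method is Method.KNN and best >= n_samples:
            best = n_samples - 1
            logger.warning("default k=%d infeasible for %d samples; clipped to %d",
                           base.hyperparameter, n_samples, best)
        evaluate(best)
    elif method is Method.KNN:
        coarse = _knn_grids(n_samples)
        k_star = best_of(coarse)
        lo = max(1, k_star - KNN_REFINE_SPAN)
        hi = min(n_samples - 1, k_star + KNN_REFINE_SPAN)
        best = best_of(list(range(lo, hi + 1)) + [k_star])
    elif method is Method.RF:
        best = best_of(RF_TREE_GRID)
    else:
        best = best_of(MICE_ITER_GRID)
    return best, float(np.mean(evaluations[best])), evaluations


# ---------------------------------------------------------------------------
# the full optimization run
# ---------------------------------------------------------------------------

@dataclass
class OptimizationReport:
    """Outcome of one optimization run.

    ``mape`` is an 8 methods x 3 mechanisms table of percentages;
    ``recommended`` minimizes the mean MAPE across mechanisms (ties break
    by method order); ``imputed`` is the original matrix completed with the
    recommended method.
    """

    mape: pd.DataFrame
    best_params: dict[Method, MethodSpec]
    recommended: MethodSpec
    threshold_used: float
    mode: str
    subset: CompleteSubset
    seed: int
    imputed: OmicsMatrix
    evaluated: dict[Method, list[int]] = field(default_factory=dict)
    log: list[str] = field(default_factory=list)

    @property
    def selection_statistic(self) -> pd.Series:
        return self.mape.mean(axis=1)

    def to_dict(self) -> dict:
        return {
            "recommended": {
                "method": self.recommended.method.value,
                "k": self.recommended.k,
                "n_trees": self.recommended.n_trees,
                "n_iter": self.recommended.n_iter,
            },
            "mape": {m: dict(row) for m, row in self.mape.round(6).iterrows()},
            "best_params": {
                m.value: s.hyperparameter for m, s in self.best_params.items()
                if s.hyperparameter is not None
            },
            "threshold_used": self.threshold_used,
            "mode": self.mode,
            "subset_path": self.subset.path.value,
            "dropped_samples": self.subset.dropped_samples,
            "dropped_features": self.subset.dropped_features,
            "evaluated_grids": {m.value: v for m, v in self.evaluated.items()},
            "seed": self.seed,
            "log": self.log,
        }


def _replicate_seed(seed: int, replicate: int) -> int:
    return int(np.random.SeedSequence([int(seed), 11, replicate]).generate_state(1)[0] % (2**31))


def run_optimization(
    m: OmicsMatrix,
    threshold: float | None = None,
    mode: str = "simple",
    seed: int = 0,
    replicates: int = 1,
) -> OptimizationReport:
    """Select the best imputation method for ``m`` and apply it.

    Simulates each missingness mechanism on the complete submatrix at
    ``threshold`` (default 0.30), scores all eight methods by held-out
    MAPE (averaged over ``replicates`` simulation seeds), recommends the
    mean-MAPE minimizer, and imputes the original matrix with it.
    """
    if mode not in ("simple", "full"):
        raise ValueError(f"mode must be 'simple' or 'full', got {mode!r}")
    verdict = check_eligibility(m)
    if not verdict:
        raise EligibilityError(verdict.reason)
    threshold_used = DEFAULT_THRESHOLD if threshold is None else float(threshold)
    subset = extract_complete_subset(m)
    log = [f"complete subset via {subset.path.value}: "
           f"{subset.submatrix.n_samples} samples x {subset.submatrix.n_features} features"]

    sims: dict[Mechanism, list[SimulatedDataset]] = {}
    for mech in MECHANISMS:
        try:
            sims[mech] = [
                simulate(subset.submatrix, mech, threshold_used, _replicate_seed(seed, r))
                for r in range(replicates)
            ]
        except BudgetError as exc:
            raise BudgetError(
                f"{mech.value} simulation failed at threshold {threshold_used}: {exc}; "
                "try a lower threshold"
            ) from exc

    table = pd.DataFrame(
        index=[meth.value for meth in METHOD_ORDER],
        columns=[mech.value for mech in MECHANISMS],
        dtype=float,
    )
    best_params: dict[Method, MethodSpec] = {}
    evaluated: dict[Method, list[int]] = {}
    for meth in METHOD_ORDER:
        if meth in MULTIVARIATE:
            all_sims = [s for mech in MECHANISMS for s in sims[mech]]
            best, _, evals = search_hyperparameters(all_sims, meth, mode=mode, seed=seed)
            best_params[meth] = MethodSpec(meth).with_hyperparameter(best)
            evaluated[meth] = sorted(evals)
            # per-cell best: minimum over the evaluated grid for that mechanism
            n_each = replicates
            for c, mech in enumerate(MECHANISMS):
                sl = slice(c * n_each, (c + 1) * n_each)
                table.loc[meth.value, mech.value] = min(
                    float(np.mean(scores[sl])) for scores in evals.values()
                )
        else:
            spec = MethodSpec(meth)
            best_params[meth] = spec
            for mech in MECHANISMS:
                table.loc[meth.value, mech.value] = float(
                    np.mean([_score(s, spec, seed) for s in sims[mech]])
                )

    means = table.mean(axis=1)
    recommended_method = next(
        meth for meth in METHOD_ORDER if means[meth.value] == means.min()
    )
    recommended = best_params[recommended_method]
    log.append(f"recommended {recommended_method.value} "
               f"(mean MAPE {means[recommended_method.value]:.4f}%)")

    imputed = impute(m, recommended, seed=seed) if m.n_missing else m.copy()
    return OptimizationReport(
        mape=table,
        best_params=best_params,
        recommended=recommended,
        threshold_used=threshold_used,
        mode=mode,
        subset=subset,
        seed=int(seed),
        imputed=imputed,
        evaluated=evaluated,
        log=log,
    )


class ImputationOptimizer(TransformerMixin, BaseEstimator):
    """sklearn-style wrapper around :func:`run_optimization`.

    ``fit`` selects the imputation method on a samples x features table
    (NaN-coded missing cells); ``transform`` completes a table with the
    recommended method. Fitted attributes: ``mape_table_``,
    ``recommended_``, ``best_params_``, ``report_``.
    """

    def __init__(self, threshold: float | None = None, mode: str = "simple",
                 replicates: int = 1, random_state: int = 0):
        self.threshold = threshold
        self.mode = mode
        self.replicates = replicates
        self.random_state = random_state

    @staticmethod
    def _as_matrix(X, groups=None) -> OmicsMatrix:
        if isinstance(X, OmicsMatrix):
            return X
        frame = pd.DataFrame(X)
        if not isinstance(X, pd.DataFrame):
            frame.index = [f"s{i}" for i in range(frame.shape[0])]
            frame.columns = [f"f{j}" for j in range(frame.shape[1])]
        return OmicsMatrix(frame, groups)

    def fit(self, X, y=None, groups: dict[str, str] | None = None):
        m = self._as_matrix(X, groups)
        self.report_ = run_optimization(
            m, threshold=self.threshold, mode=self.mode,
            seed=self.random_state, replicates=self.replicates,
        )
        self.mape_table_ = self.report_.mape
        self.recommended_ = self.report_.recommended
        self.best_params_ = self.report_.best_params
        self.n_features_in_ = m.n_features
        return self

    def transform(self, X):
        m = self._as_matrix(X)
        if m.n_missing == 0:
            return m.values.copy()
        return impute(m, self.recommended_, seed=self.random_state).values
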