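import logging

import numpy as np
import pytest

from omicsimpute import (
    FixtureSpec,
    ImputationOptimizer,
    MethodSpec,
    generate,
    impute,
    mape,
    run_optimization,
    search_hyperparameters,
    simulate,
    simulate_mcar,
)
from omicsimpute.exceptions import (
    BudgetError,
    EligibilityError,
    OptimizationImpossibleError,
    UndefinedMAPEError,
)
from omicsimpute.optimizer import (
    KNN_COARSE_GRID,
    MICE_ITER_GRID,
    RF_TREE_GRID,
    SubsetPath,
    check_eligibility,
    extract_complete_subset,
)

from conftest import make_matrix

nan = np.nan


class TestEligibility:
    def test_boundary_18_values(self, golden):
        assert check_eligibility(golden["eligibility_boundary"]).eligible

    def test_17_values_rejected(self, golden):
        verdict = check_eligibility(golden["eligibility_below"])
        assert not verdict.eligible
        assert "observed values" in verdict.reason

    def test_too_few_samples(self):
        m = make_matrix([[1.0] * 10] * 5)
        verdict = check_eligibility(m)
        assert not verdict.eligible
        assert "samples" in verdict.reason

    def test_too_few_features(self):
        m = make_matrix([[1.0, 2.0]] * 10)
        verdict = check_eligibility(m)
        assert not verdict.eligible
        assert "features" in verdict.reason


class TestCompleteSubset:
    def test_rows_path(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(1, 9, size=(10, 5))
        for i in (0, 3, 5, 8):
            vals[i, i % 5] = nan
        sub = extract_complete_subset(make_matrix(vals.tolist()))
        assert sub.path is SubsetPath.ROWS
        assert sub.submatrix.shape == (6, 5)
        assert sub.submatrix.is_complete()

    def test_cols_path(self):
        # every sample has a hole, but 3 features are fully observed
        rng = np.random.default_rng(2)
        vals = rng.uniform(1, 9, size=(8, 5))
        for i in range(8):
            vals[i, 3 + (i % 2)] = nan
        sub = extract_complete_subset(make_matrix(vals.tolist()))
        assert sub.path is SubsetPath.COLS
        assert sub.submatrix.shape == (8, 3)

    def test_reduced_rows_path(self, golden):
        sub = extract_complete_subset(golden["ladder"])
        assert sub.path is SubsetPath.REDUCED_ROWS
        assert sub.submatrix.shape == (9, 3)
        assert "f4" in sub.dropped_features

    def test_80_pct_column_dropped_79_retained(self):
        """The reduced rung drops a column at exactly 80% missing and keeps
        one at 79% (strict < 80% bound)."""
        def build(k):
            # f4 is k% missing; f5 (90%) always forces the reduced rung;
            # f1 holes in the last 10 rows kill the plain-rows rung
            rng = np.random.default_rng(4)
            vals = rng.uniform(1, 9, size=(100, 5))
            vals[:k, 3] = nan
            vals[:90, 4] = nan
            vals[90:, 0] = nan
            return make_matrix(vals.tolist())

        at_80 = extract_complete_subset(build(80))
        assert at_80.path is SubsetPath.REDUCED_ROWS
        assert "f4" in at_80.dropped_features
        assert "f4" not in at_80.submatrix.feature_ids

        at_79 = extract_complete_subset(build(79))
        assert at_79.path is SubsetPath.REDUCED_ROWS
        assert "f4" not in at_79.dropped_features
        assert "f4" in at_79.submatrix.feature_ids

    def test_impossible_raises(self):
        vals = np.full((6, 3), nan)
        vals[:, 0] = 1.0
        vals[0, :] = 1.0
        with pytest.raises(OptimizationImpossibleError):
            extract_complete_subset(make_matrix(vals.tolist()))


class TestMape:
    def test_hand_example(self):
        assert mape([100, 200], [110, 180]) == pytest.approx(10.0)

    def test_identity_is_zero(self):
        assert mape([3.5, 7.0, 9.1], [3.5, 7.0, 9.1]) == 0.0

    def test_non_positive_truth_excluded(self, caplog):
        with caplog.at_level(logging.WARNING):
            value, excluded = mape([0, 5], [1, 5], return_excluded=True)
        assert value == 0.0
        assert excluded == 1
        assert any("excluded" in r.message for r in caplog.records)

    def test_all_excluded_is_undefined(self):
        with pytest.raises(UndefinedMAPEError):
            mape([0.0, -1.0], [1.0, 1.0])


@pytest.fixture(scope="module")
def sim50():
    m = generate(FixtureSpec(n_samples=50, n_features=8, n_latent=1,
                             noise_sd=0.1, marginal="linear", seed=3))
    return simulate_mcar(m, 0.3, seed=3)


class TestHyperparameterSearch:

    def test_simple_mode_single_default_evaluation(self, sim50):
        for meth, default in [("KNN", 10), ("RF", 500), ("MICE", 2)]:
            best, _, evals = search_hyperparameters(sim50, meth, mode="simple")
            assert best == default
            assert list(evals) == [default]

    def test_full_knn_grid_and_refinement(self, sim50):
        best, _, evals = search_hyperparameters(sim50, "KNN", mode="full")
        coarse = [k for k in evals if k in KNN_COARSE_GRID]
        assert set(coarse) <= set(KNN_COARSE_GRID)
        assert max(evals) <= 100
        refinement = [k for k in evals if k not in KNN_COARSE_GRID]
        assert len(refinement) <= 9
        assert 1 <= best < sim50.masked.n_samples

    def test_full_rf_grid_exact(self, sim50):
        best, _, evals = search_hyperparameters(sim50, "RF", mode="full")
        assert sorted(evals) == sorted(RF_TREE_GRID)
        assert best in RF_TREE_GRID

    def test_full_mice_grid_exact(self, sim50):
        best, _, evals = search_hyperparameters(sim50, "MICE", mode="full")
        assert sorted(evals) == sorted(MICE_ITER_GRID)
        assert best in MICE_ITER_GRID

    def test_constant_method_has_no_grid(self, sim50):
        with pytest.raises(ValueError):
            search_hyperparameters(sim50, "MEAN", mode="full")


class TestRunOptimization:
    def test_constant_matrix_ties_break_to_min(self):
        m = make_matrix([[7.0] * 3 for _ in range(8)])
        m.values.iloc[1, 1] = nan
        m.values.iloc[4, 2] = nan
        rep = run_optimization(m, threshold=0.3, seed=1)
        for meth in ["MIN", "MAX", "MEDIAN", "MEAN"]:
            assert (rep.mape.loc[meth] == 0).all()
        assert rep.recommended.method.value == "MIN"
        assert (rep.imputed.to_numpy() == 7.0).all()

    def test_default_threshold_is_30_pct(self, correlated_matrix):
        sim = simulate_mcar(correlated_matrix, 0.05, seed=2)
        rep = run_optimization(sim.masked, seed=2)
        assert rep.threshold_used == 0.30
        ns, nf = rep.subset.submatrix.shape
        # MCAR masks round(0.3 * cells) of the complete subset
        expected = int(np.floor(0.3 * ns * nf + 0.5))
        resim = simulate(rep.subset.submatrix, "MCAR", 0.30, seed=0)
        assert resim.masked.n_missing == expected

    def test_simple_mode_uses_defaults(self, correlated_matrix):
        sim = simulate_mcar(correlated_matrix, 0.05, seed=4)
        rep = run_optimization(sim.masked, mode="simple", seed=4)
        from omicsimpute.imputers import Method
        assert rep.best_params[Method.KNN].k == 10
        assert rep.best_params[Method.RF].n_trees == 500
        assert rep.best_params[Method.MICE].n_iter == 2

    def test_recovery_oracle_exact(self, correlated_matrix):
        """Each simple-mode table entry equals an independent impute+mape."""
        sim = simulate_mcar(correlated_matrix, 0.05, seed=6)
        rep = run_optimization(sim.masked, seed=6)
        for mech in ("MCAR", "MAR", "MNAR"):
            resim = simulate(rep.subset.submatrix, mech, rep.threshold_used,
                             seed=_first_replicate_seed(6))
            for meth, spec in rep.best_params.items():
                filled = impute(resim.masked, spec, seed=6)
                expected = mape(resim.holdout_truth,
                                resim.holdout_predictions(filled))
                assert rep.mape.loc[meth.value, mech] == expected

    def test_seed_determinism_of_report(self, correlated_matrix):
        sim = simulate_mcar(correlated_matrix, 0.05, seed=8)
        a = run_optimization(sim.masked, seed=9)
        b = run_optimization(sim.masked, seed=9)
        assert a.mape.equals(b.mape)
        assert a.recommended == b.recommended
        assert a.imputed == b.imputed

    def test_ineligible_matrix_rejected(self):
        m = make_matrix([[1.0, 2.0, 3.0]] * 4)
        m.values.iloc[0, 0] = nan
        with pytest.raises(EligibilityError):
            run_optimization(m, seed=1)

    def test_budget_error_hints_threshold(self, correlated_matrix):
        sim = simulate_mcar(correlated_matrix, 0.05, seed=10)
        with pytest.raises(BudgetError, match="lower"):
            run_optimization(sim.masked, threshold=0.999, seed=10)

    def test_multivariate_recommended_on_correlated_data(self):
        """On one-factor linear fixtures the recommendation is KNN, RF or
        MICE in at least 80% of 20 seeded runs."""
        hits = 0
        for s in range(20):
            m = generate(FixtureSpec(n_samples=30, n_features=10, n_latent=1,
                                     noise_sd=0.05, marginal="linear", seed=100 + s))
            sim = simulate_mcar(m, 0.04, seed=100 + s)
            rep = run_optimization(sim.masked, seed=s)
            hits += rep.recommended.method.value in ("KNN", "RF", "MICE")
        assert hits >= 16

    def test_parameter_recovery_as_noise_vanishes(self):
        """RF and MICE holdout MAPE decreases monotonically as the planted
        noise shrinks."""
        results = {"RF": [], "MICE": []}
        for sd in (0.5, 0.1, 0.02):
            per_method = {"RF": [], "MICE": []}
            for s in range(3):
                m = generate(FixtureSpec(n_samples=30, n_features=8, n_latent=1,
                                         noise_sd=sd, marginal="linear", seed=40 + s))
                sim = simulate_mcar(m, 0.2, seed=40 + s)
                for meth in per_method:
                    spec = MethodSpec(meth, n_trees=100, n_iter=2)
                    v = mape(sim.holdout_truth, sim.holdout_predictions(
                        impute(sim.masked, spec, seed=s)))
                    per_method[meth].append(v)
            for meth in results:
                results[meth].append(np.mean(per_method[meth]))
        for meth, series in results.items():
            assert series[0] > series[1] > series[2], (meth, series)


class TestEstimatorInterface:
    def test_fit_transform_completes_matrix(self, correlated_matrix):
        sim = simulate_mcar(correlated_matrix, 0.05, seed=12)
        est = ImputationOptimizer(random_state=12)
        out = est.fit_transform(sim.masked.values)
        assert not np.isnan(out.to_numpy()).any()
        assert est.mape_table_.shape == (8, 3)
        assert est.recommended_ is not None

    def test_get_set_params_round_trip(self):
        est = ImputationOptimizer(threshold=0.2, mode="full")
        params = est.get_params()
        assert params["threshold"] == 0.2
        est2 = ImputationOptimizer().set_params(**params)
        assert est2.mode == "full"


def make_wrapped(frame):
    from omicsimpute import OmicsMatrix
    return OmicsMatrix(frame)


def _first_replicate_seed(seed):
    return int(np.random.SeedSequence([int(seed), 11, 0]).generate_state(1)[0] % (2**31))
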