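"""LASSO-Cox solver, lambda selection, stability ensemble, LR score, cutpoint."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lrcrosstalk.exceptions import ValidationError
from lrcrosstalk.io import SurvivalRecord
from lrcrosstalk.model import (
    CoxLasso,
    LRScoreModel,
    StabilityCoxLasso,
    SurvivalTreeCut,
    _fit_arrays,
    _penalized_objective,
    _sort_survival,
    _standardize,
    lambda_grid,
    lambda_max,
    lr_score,
    partition_cut,
    published_model,
    select_lambda,
    stability_ensemble,
)
from tests.conftest import make_survival_data


def to_records(t, e):
    return [SurvivalRecord(f"P{i}", ti, ei) for i, (ti, ei) in enumerate(zip(t, e))]


class TestCoxLasso:
    def test_unpenalized_matches_lifelines(self, rng):
        from lifelines import CoxPHFitter

        t, e, X = make_survival_data(rng, 120, [0.8, -0.5, 0.3])
        fit = CoxLasso(alpha=0.0).fit(X, np.c_[t, e])
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        df["t"], df["e"] = t, e
        cph = CoxPHFitter().fit(df, "t", "e")
        np.testing.assert_allclose(fit.coef_, cph.params_.values, atol=1e-4)

    def test_lambda_max_gives_exact_zero(self, rng):
        t, e, X = make_survival_data(rng, 100, [0.8, -0.5, 0.3])
        lmax = lambda_max(t, e, X)
        fit = CoxLasso(alpha=lmax).fit(X, np.c_[t, e])
        assert (fit.coef_ == 0.0).all()
        fit2 = CoxLasso(alpha=lmax * 2).fit(X, np.c_[t, e])
        assert (fit2.coef_ == 0.0).all()

    def test_objective_not_worse_than_zero_vector(self, rng):
        t, e, X = make_survival_data(rng, 80, [0.6, 0.0, -0.4])
        lam = lambda_max(t, e, X) * 0.2
        fit, _ = _fit_arrays(t, e, X, lam, ["a", "b", "c"])
        order, _, es, gs, ge = _sort_survival(t, e)
        Xs, _, _ = _standardize(X[order])
        assert fit.objective <= _penalized_objective(es, gs, ge, Xs, np.zeros(3), lam) + 1e-9

    def test_matches_direct_minimizer(self, rng):
        from scipy.optimize import minimize

        t, e, X = make_survival_data(rng, 60, [0.7, -0.6, 0.0, 0.0, 0.4])
        p = X.shape[1]
        lam = lambda_max(t, e, X) * 0.3
        fit, _ = _fit_arrays(t, e, X, lam, [f"x{j}" for j in range(p)])
        order, _, es, gs, ge = _sort_survival(t, e)
        Xs, _, _ = _standardize(X[order])

        def obj(ab):
            b = ab[:p] - ab[p:]
            return _penalized_objective(es, gs, ge, Xs, b, 0.0) + lam * ab.sum()

        res = minimize(obj, np.zeros(2 * p), method="SLSQP",
                       bounds=[(0, None)] * (2 * p), options={"maxiter": 1000, "ftol": 1e-14})
        assert fit.objective == pytest.approx(res.fun, abs=1e-6)

    def test_kkt_residual_small(self, rng):
        t, e, X = make_survival_data(rng, 90, [0.5, -0.5, 0.2, 0.0])
        lam = lambda_max(t, e, X) * 0.4
        fit, _ = _fit_arrays(t, e, X, lam, list("abcd"))
        assert fit.kkt_residual < 1e-6

    def test_negative_alpha_rejected(self, rng):
        t, e, X = make_survival_data(rng, 30, [0.5])
        with pytest.raises(ValidationError):
            CoxLasso(alpha=-1.0).fit(X, np.c_[t, e])

    def test_sklearn_params_round_trip(self):
        est = CoxLasso(alpha=0.5)
        assert est.get_params() == {"alpha": 0.5}
        est.set_params(alpha=1.0)
        assert est.alpha == 1.0


class TestSelectLambda:
    def test_grid_of_length_one(self, rng):
        t, e, X = make_survival_data(rng, 60, [0.5, 0.0])
        assert select_lambda(t, e, X, k=3, grid=[0.7]) == 0.7

    def test_strong_covariate_survives_selection(self, rng):
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            t, e, X = make_survival_data(r, 150, [1.0], p_extra=4)
            lam = select_lambda(t, e, X, k=5, random_state=seed)
            fit, _ = _fit_arrays(t, e, X, lam, [f"x{j}" for j in range(5)])
            hits += fit.coefficients["x0"] != 0.0
        assert hits >= 9

    def test_pure_noise_prefers_heavy_penalty(self, rng):
        near_max = 0
        for seed in range(10):
            r = np.random.default_rng(100 + seed)
            t, e, X = make_survival_data(r, 120, [0.0], p_extra=4)
            grid = lambda_grid(t, e, X)
            lam = select_lambda(t, e, X, k=5, grid=grid, random_state=seed)
            near_max += lam >= grid[len(grid) // 2]  # upper half of the grid
        assert near_max >= 9

    def test_k_below_two_rejected(self, rng):
        t, e, X = make_survival_data(rng, 40, [0.5])
        with pytest.raises(ValidationError):
            select_lambda(t, e, X, k=1)


class TestStabilityEnsemble:
    def test_degenerate_single_replicate_equals_single_fit(self, rng):
        t, e, X = make_survival_data(rng, 80, [0.9, -0.8, 0.0])
        recs = to_records(t, e)
        cov = pd.DataFrame(X, columns=["a", "b", "c"], index=[r.patient_id for r in recs])
        ens = stability_ensemble(recs, cov, n_reps=1, frac=0.9, threshold=1, seed=5, cv_folds=3)
        assert set(ens.final_genes) == {g for g, c in ens.avg_coef.items() if c != 0.0}

    def test_deterministic_given_seed(self, rng):
        t, e, X = make_survival_data(rng, 70, [0.9, 0.0])
        recs = to_records(t, e)
        cov = pd.DataFrame(X, columns=["a", "b"], index=[r.patient_id for r in recs])
        a = stability_ensemble(recs, cov, n_reps=5, threshold=4, seed=9, cv_folds=3)
        b = stability_ensemble(recs, cov, n_reps=5, threshold=4, seed=9, cv_folds=3)
        assert a.avg_coef == b.avg_coef and a.retention == b.retention

    def test_retention_bounded_by_reps(self, rng):
        t, e, X = make_survival_data(rng, 70, [0.9, 0.0])
        recs = to_records(t, e)
        cov = pd.DataFrame(X, columns=["a", "b"], index=[r.patient_id for r in recs])
        ens = stability_ensemble(recs, cov, n_reps=6, threshold=5, seed=2, cv_folds=3)
        assert all(0 <= v <= 6 for v in ens.retention.values())

    def test_estimator_interface(self, rng):
        t, e, X = make_survival_data(rng, 90, [1.0, -0.9, 0.0, 0.0])
        est = StabilityCoxLasso(n_reps=8, retention_threshold=6, cv_folds=3, random_state=0)
        est.fit(pd.DataFrame(X, columns=list("abcd")), np.c_[t, e])
        assert est.coef_.shape == (4,)
        assert est.support_.dtype == bool
        scores = est.predict(X)
        assert scores.shape == (90,)
        if est.support_.any():
            model = est.to_model()
            # gene symbols are canonicalized to uppercase inside the model
            assert set(model.coefficients) <= {"A", "B", "C", "D"}


class TestLRScore:
    def test_published_model_unit_itgb4(self):
        model = published_model()
        expr = {g: 0.0 for g in model.coefficients}
        expr["ITGB4"] = 1.0
        assert lr_score(model, expr) == pytest.approx(-0.263)

    def test_published_model_all_ones_sum(self):
        # independent hand summation of the 11 printed coefficients
        model = published_model()
        assert lr_score(model, {g: 1.0 for g in model.coefficients}) == pytest.approx(-0.37542)

    def test_zero_expression_zero_score(self):
        model = published_model()
        assert lr_score(model, {g: 0.0 for g in model.coefficients}) == 0.0

    def test_missing_genes_contribute_zero_with_warning(self, caplog):
        model = LRScoreModel({"A": 1.0, "B": 2.0})
        with caplog.at_level("WARNING"):
            val = lr_score(model, {"A": 3.0})
        assert val == 3.0
        assert "absent" in caplog.text

    @given(st.integers(min_value=0, max_value=10_000))
    def test_linearity(self, seed):
        rng = np.random.default_rng(seed)
        model = published_model()
        genes = list(model.coefficients)
        x = dict(zip(genes, rng.normal(size=len(genes))))
        y = dict(zip(genes, rng.normal(size=len(genes))))
        a, b = rng.normal(size=2)
        combo = {g: a * x[g] + b * y[g] for g in genes}
        assert lr_score(model, combo) == pytest.approx(
            a * lr_score(model, x) + b * lr_score(model, y), rel=1e-12, abs=1e-12
        )

    def test_empty_model_rejected(self):
        with pytest.raises(ValidationError):
            LRScoreModel({})


class TestPartitionCut:
    def test_two_distinct_scores_cut_at_midpoint(self, rng):
        scores = np.repeat([0.0, 1.0], 20)
        T = rng.exponential(1 / (0.1 * np.exp(1.5 * scores)))
        recs = to_records(T + np.arange(40) * 1e-9, np.ones(40, dtype=int))
        res = partition_cut(scores, recs, min_frac=0.1)
        assert res.significant and res.cutpoint == pytest.approx(0.5)

    def test_internal_consistency_with_logrank(self, rng):
        from lrcrosstalk.survival import logrank_test

        scores = rng.normal(size=120)
        T = rng.exponential(1 / (0.1 * np.exp(1.0 * (scores > 0))))
        recs = to_records(T + np.arange(120) * 1e-9, np.ones(120, dtype=int))
        res = partition_cut(scores, recs)
        assert res.significant
        chi2, _ = logrank_test(recs, res.labels)
        assert res.chi2 == pytest.approx(chi2, rel=1e-9)

    def test_min_frac_respected(self, rng):
        scores = rng.normal(size=100)
        T = rng.exponential(1 / (0.1 * np.exp(0.8 * (scores > 0))))
        recs = to_records(T, np.ones(100, dtype=int))
        res = partition_cut(scores, recs, min_frac=0.25)
        if res.significant:
            assert min(res.n_low, res.n_high) >= 25

    def test_single_value_rejected(self):
        recs = to_records([1.0, 2.0], [1, 1])
        with pytest.raises(ValidationError):
            partition_cut([1.0, 1.0], recs)

    def test_no_admissible_cutpoint_rejected(self):
        recs = to_records(np.arange(1, 11.0), np.ones(10, dtype=int))
        scores = np.array([0.0] + [1.0] * 9)  # any cut leaves a group of 1
        with pytest.raises(ValidationError):
            partition_cut(scores, recs, min_frac=0.3)

    def test_estimator_interface(self, rng):
        scores = rng.normal(size=150)
        T = rng.exponential(1 / (0.1 * np.exp(1.2 * (scores > 0))))
        est = SurvivalTreeCut().fit(scores, np.c_[T, np.ones(150)])
        labels = est.predict(scores)
        assert set(labels) == {"low", "high"}
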