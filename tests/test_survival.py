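"""KM / log-rank / Cox wrappers: hand-computed fixtures and analytic scaling."""

import numpy as np
import pandas as pd
import pytest

from lrcrosstalk.exceptions import ValidationError
from lrcrosstalk.io import ExpressionMatrix, SurvivalRecord
from lrcrosstalk.survival import cox_fit, km_estimate, logrank_test, split_by_mean


def records(times, events):
    return [SurvivalRecord(f"P{i}", t, e) for i, (t, e) in enumerate(zip(times, events))]


class TestKM:
    def test_hand_product_limit(self):
        # times [1,2,3], events [1,1,0]: S(1)=2/3, S(2)=1/3, flat afterwards
        curve = km_estimate(records([1, 2, 3], [1, 1, 0]))
        assert curve.at(1) == pytest.approx(2 / 3)
        assert curve.at(2) == pytest.approx(1 / 3)
        assert curve.at(3) == pytest.approx(1 / 3)

    def test_no_censoring_matches_one_minus_ecdf(self):
        times = [1.0, 2.0, 3.0, 4.0]
        curve = km_estimate(records(times, [1, 1, 1, 1]))
        for t, expected in zip(times, [0.75, 0.5, 0.25, 0.0]):
            assert curve.at(t) == pytest.approx(expected)

    def test_all_censored_flat_one(self):
        curve = km_estimate(records([1, 2, 3], [0, 0, 0]))
        assert (curve.survival == 1.0).all()

    def test_order_invariance(self, rng):
        t = rng.exponential(5, 40)
        e = rng.integers(0, 2, 40)
        perm = rng.permutation(40)
        a = km_estimate(records(t, e))
        b = km_estimate(records(t[perm], e[perm]))
        np.testing.assert_allclose(a.survival, b.survival)
        np.testing.assert_allclose(a.times, b.times)


def hand_logrank(times, events, groups):
    """Independent O-E / hypergeometric-variance computation."""
    times, events, groups = map(np.asarray, (times, events, groups))
    U = V = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == 1)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == 1)).sum()
        U += d1 - d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return U * U / V


class TestLogrank:
    # printed-in-repo 6-subject fixture
    times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
    events = [1, 1, 1, 0, 1, 1]
    groups = [1, 0, 1, 0, 1, 0]

    def test_matches_hand_computation(self):
        chi2, p = logrank_test(records(self.times, self.events), self.groups)
        assert chi2 == pytest.approx(hand_logrank(self.times, self.events, self.groups), rel=1e-10)

    def test_identical_groups_chi2_zero(self):
        t = [1, 2, 3, 1, 2, 3]
        e = [1, 0, 1, 1, 0, 1]
        g = [0, 0, 0, 1, 1, 1]
        chi2, p = logrank_test(records(t, e), g)
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_separated_groups_power(self, rng):
        hits = 0
        for _ in range(20):
            n = 100
            g = np.repeat([0, 1], n)
            T = rng.exponential(1 / (0.1 * np.exp(np.log(3) * g)))
            t = np.minimum(T, 30)
            e = (T <= 30).astype(int)
            chi2, p = logrank_test(records(t, e), g)
            hits += p < 0.001
        assert hits >= 19

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            logrank_test(records([1, 2], [1, 1]), [0, 0])

    def test_equals_cox_score_statistic_without_ties(self, rng):
        # the log-rank chi2 is the squared score statistic of a binary-covariate
        # Cox model at beta = 0 (computed here from first principles)
        n = 30
        t = rng.exponential(5, n) + np.arange(n) * 1e-6
        e = rng.integers(0, 2, n)
        e[0] = 1
        g = rng.integers(0, 2, n).astype(float)
        if len(set(g)) < 2:
            g[0] = 1 - g[0]
        order = np.argsort(t)
        ts, es, gs = t[order], e[order], g[order]
        U = I = 0.0
        for i in range(n):
            if es[i] != 1:
                continue
            risk = np.arange(n) >= i
            xbar = gs[risk].mean()
            U += gs[i] - xbar
            I += (gs[risk] ** 2).mean() - xbar**2
        chi2, _ = logrank_test(records(t, e), g)
        assert chi2 == pytest.approx(U * U / I, rel=1e-9)


class TestCoxFit:
    def test_duplicated_data_same_coef_smaller_se(self, rng):
        n = 120
        x = rng.standard_normal(n)
        T = rng.exponential(1 / (0.1 * np.exp(0.7 * x)))
        t = np.minimum(T, 25) + np.arange(n) * 1e-9
        e = (T <= 25).astype(int)
        recs = records(t, e)
        cov = pd.DataFrame({"x": x}, index=[r.patient_id for r in recs])
        fit1 = cox_fit(recs, cov)

        recs2 = recs + [SurvivalRecord(f"Q{i}", r.os_time + 1e-7, r.os_event)
                        for i, r in enumerate(recs)]
        cov2 = pd.DataFrame({"x": np.concatenate([x, x])},
                            index=[r.patient_id for r in recs2])
        fit2 = cox_fit(recs2, cov2)
        assert fit2.coefficients["x"] == pytest.approx(fit1.coefficients["x"], abs=0.01)
        se1 = (np.log(fit1.ci_upper["x"]) - np.log(fit1.ci_lower["x"])) / (2 * 1.96)
        se2 = (np.log(fit2.ci_upper["x"]) - np.log(fit2.ci_lower["x"])) / (2 * 1.96)
        assert se2 / se1 == pytest.approx(1 / np.sqrt(2), rel=0.02)

    def test_ci_brackets_hr(self, rng):
        n = 150
        x = rng.standard_normal(n)
        T = rng.exponential(1 / (0.1 * np.exp(0.5 * x)))
        t = np.minimum(T, 30)
        e = (T <= 30).astype(int)
        recs = records(t, e)
        fit = cox_fit(recs, pd.DataFrame({"x": x}, index=[r.patient_id for r in recs]))
        assert fit.ci_lower["x"] <= fit.hr["x"] <= fit.ci_upper["x"]
        assert fit.converged

    def test_no_events_rejected(self):
        recs = records([1, 2, 3], [0, 0, 0])
        with pytest.raises(ValidationError):
            cox_fit(recs, pd.DataFrame({"x": [1.0, 2.0, 3.0]},
                                       index=[r.patient_id for r in recs]))

    def test_categorical_covariates_one_hot(self, rng):
        n = 80
        t = rng.exponential(5, n)
        e = rng.integers(0, 2, n)
        e[:5] = 1
        recs = records(t, e)
        cov = pd.DataFrame(
            {"gender": rng.choice(["male", "female"], n), "x": rng.standard_normal(n)},
            index=[r.patient_id for r in recs],
        )
        fit = cox_fit(recs, cov)
        assert any(k.startswith("gender_") for k in fit.coefficients)


class TestSplitByMean:
    def test_mean_boundary_goes_high(self):
        bulk = ExpressionMatrix([[1.0, 2.0, 3.0, 4.0]], ["G"], ["P0", "P1", "P2", "P3"], "bulk")
        recs = records([5, 4, 3, 1], [1, 1, 1, 1])
        labels, (chi2, p), (km_high, km_low) = split_by_mean(bulk, "G", recs)
        assert list(labels) == ["low", "low", "high", "high"]  # mean 2.5

        bulk2 = ExpressionMatrix([[1.0, 2.0, 3.0, 2.0]], ["G"], ["P0", "P1", "P2", "P3"], "bulk")
        labels2, _, _ = split_by_mean(bulk2, "G", recs)
        assert labels2[1] == "high"  # exactly at the mean -> high

    def test_constant_expression_rejected(self):
        bulk = ExpressionMatrix([[2.0, 2.0, 2.0, 2.0]], ["G"], ["P0", "P1", "P2", "P3"], "bulk")
        with pytest.raises(ValidationError):
            split_by_mean(bulk, "G", records([1, 2, 3, 4], [1, 1, 1, 1]))

    def test_planted_hazard_gene_shows_worse_survival_in_high_group(self):
        from lrcrosstalk.simulate import SimConfig, generate_bulk, generate_survival

        cfg = SimConfig(n_genes=300, cell_types={"B": 5}, n_tumor_samples=1,
                        n_normal_samples=1, n_bulk_samples=300,
                        surv_beta={"RISKGENE": 0.9}, seed=17)
        bulk = generate_bulk(cfg)
        recs = generate_survival(cfg, bulk)
        labels, (chi2, p), _ = split_by_mean(bulk, "RISKGENE", recs)
        assert p < 0.01
        cov = pd.DataFrame({"high": (labels == "high").astype(float)},
                           index=[r.patient_id for r in recs])
        fit = cox_fit(recs, cov)
        assert fit.hr["high"] > 1.0
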