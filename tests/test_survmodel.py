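"""Log-rank, lasso-Cox, LOOCV risk indices, and Cox summaries."""

import numpy as np
import pandas as pd
import pytest

from histomorph.patientfeat import feature_names
from histomorph.survmodel import (
    FoldModel,
    breslow_loglik,
    cox_regression,
    fit_fold,
    fit_lasso_cox,
    km_curve,
    logrank_filter,
    logrank_statistics,
    logrank_test,
    loocv_risk_indices,
    summarize_selection,
)
from histomorph.synthdata import CohortSpec, generate_cohort


class TestLogrank:
    def test_hand_computed_example(self):
        # group A events at 1, 2; group B events at 3, 4:
        # O_A = 2, E_A = 5/6, V = 17/36 -> chi2 = 49/17
        chi2, p = logrank_test([1, 1, 0, 0], [1, 2, 3, 4], [1, 1, 1, 1])
        assert chi2 == pytest.approx(49 / 17, abs=1e-9)

    def test_identical_groups_null(self):
        t = [2, 2, 5, 5, 9, 9]
        e = [1, 1, 0, 0, 1, 1]
        chi2, p = logrank_test([1, 0, 1, 0, 1, 0], t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1, 1, 1], [1, 2, 3], [1, 1, 1])

    def test_matches_lifelines_on_random_data(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(10, 60))
            t = rng.exponential(10, n).round(1)  # rounding forces ties
            e = (rng.random(n) < 0.7).astype(int)
            g = (rng.random(n) < 0.5).astype(int)
            if g.sum() in (0, n):
                continue
            chi2, p = logrank_test(g, t, e)
            ref = ll_logrank(t[g == 1], t[g == 0], e[g == 1], e[g == 0])
            assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
            assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(1)
        n, k = 80, 25
        t = rng.exponential(10, n).round(1)
        e = (rng.random(n) < 0.6).astype(int)
        G = (rng.random((n, k)) < 0.5).astype(float)
        chi2_v, p_v = logrank_statistics(G, t, e)
        for j in range(k):
            if G[:, j].sum() in (0, n):
                continue
            chi2_s, p_s = logrank_test(G[:, j].astype(int), t, e)
            assert chi2_v[j] == pytest.approx(chi2_s, abs=1e-10)

    def test_null_permutation_p_uniform(self):
        """Log-rank p-values are U(0,1) under random group labels."""
        from scipy import stats as sps

        rng = np.random.default_rng(2)
        n, reps = 60, 1000
        t = rng.exponential(10, n)
        e = (rng.random(n) < 0.7).astype(int)
        G = (rng.random((n, reps)) < 0.5).astype(float)
        _, pvals = logrank_statistics(G, t, e)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


class TestLogrankFilter:
    def test_constant_feature_never_retained(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"const": np.ones(50), "noise": rng.normal(size=50)})
        t = rng.exponential(10, 50)
        e = np.ones(50, int)
        assert "const" not in logrank_filter(X, t, e)

    def test_strong_driver_retained(self, names):
        spec = CohortSpec(n_patients=200, cox_betas={names[0]: 1.0}, seed=4)
        cohort, _ = generate_cohort(spec)
        retained = logrank_filter(cohort[names], cohort["time_months"], cohort["event"])
        assert names[0] in retained


class TestFitLassoCox:
    def test_full_shrinkage_at_huge_alpha(self, planted_cohort, names):
        cohort, _ = planted_cohort
        from sksurv.linear_model import CoxnetSurvivalAnalysis
        from sksurv.util import Surv

        X = cohort[names[:20]]
        Z = (X - X.mean()) / X.std(ddof=0)
        y = Surv.from_arrays(cohort["event"].astype(bool), cohort["time_months"])
        m = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=[1e6]).fit(Z, y)
        assert np.all(np.asarray(m.coef_) == 0)

    def test_planted_signs_recovered(self, planted_cohort, names):
        cohort, betas = planted_cohort
        model = fit_lasso_cox(
            cohort[names], cohort["time_months"], cohort["event"], seed=1
        )
        for f, b in betas.items():
            assert np.sign(model.coefficients.get(f, 0.0)) == np.sign(b)

    def test_duplicated_column_mass_conserved(self, planted_cohort, names):
        cohort, betas = planted_cohort
        feats = [f for f in betas] + [names[7], names[8]]
        X = cohort[feats].copy()
        base = fit_lasso_cox(X, cohort["time_months"], cohort["event"], seed=1)
        f0 = list(betas)[0]
        Xd = X.copy()
        Xd["dup"] = X[f0]
        dup = fit_lasso_cox(Xd, cohort["time_months"], cohort["event"], seed=1)
        mass = dup.coefficients.get(f0, 0.0) + dup.coefficients.get("dup", 0.0)
        assert mass == pytest.approx(base.coefficients[f0], rel=0.2)

    def test_empty_feature_set_gives_empty_model(self):
        model = fit_lasso_cox(pd.DataFrame(index=range(10)), np.arange(1, 11), np.ones(10))
        assert model.is_empty


class TestLOOCV:
    def test_median_split_sizes(self):
        risk = pd.Series([0.1, 0.2, 0.3, 0.4])
        cutoff = risk.median()
        groups = np.where(risk > cutoff, "high", "low")
        assert (groups == "high").sum() == 2

    def test_loocv_on_planted_cohort(self, demo_cohort30, names):
        result, folds = loocv_risk_indices(
            demo_cohort30[names],
            demo_cohort30["time_months"],
            demo_cohort30["event"],
            seed=1,
        )
        assert len(result.risk) == 30
        assert len(folds) == 30
        sizes = result.group.value_counts()
        assert abs(sizes.get("low-risk", 0) - sizes.get("high-risk", 0)) <= 1

    def test_leakage_guard_fold_identical_without_heldout_row(self, demo_cohort30, names):
        """A fold model must be bit-identical whether the held-out row is
        deleted beforehand or simply excluded by the LOOCV loop."""
        X = demo_cohort30[names]
        t, e = demo_cohort30["time_months"], demo_cohort30["event"]
        _, folds = loocv_risk_indices(X, t, e, seed=1)
        pid = folds[0].heldout_id
        rebuilt = fit_fold(
            X.drop(index=pid), t.drop(index=pid), e.drop(index=pid), seed=1, heldout_id=pid
        )
        assert rebuilt.coefficients == folds[0].coefficients
        assert rebuilt.filtered_features == folds[0].filtered_features
        assert rebuilt.alpha == folds[0].alpha
        assert rebuilt.center == folds[0].center

    def test_degenerate_risk_distribution_raises(self, names):
        # no survival signal and tiny n: every fold retains nothing
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(25, 3)), columns=names[:3])
        X.index = [f"P{i}" for i in range(25)]
        t = pd.Series(rng.exponential(10, 25), index=X.index)
        e = pd.Series(np.zeros(25, int), index=X.index)  # zero events
        with pytest.raises(ValueError, match="degenerate risk distribution"):
            loocv_risk_indices(X, t, e, seed=0)


class TestSummarizeSelection:
    def test_counts_and_mean_coefficients(self):
        folds = [
            FoldModel(None, [], {"a": 0.2, "b": 0.5}, 0.1),
            FoldModel(None, [], {"a": 0.3}, 0.1),
        ]
        table = summarize_selection(folds)
        a = table[table.feature == "a"].iloc[0]
        assert a["count"] == 2 and a["mean_coefficient"] == pytest.approx(0.25)
        assert a["frequency"] == 1.0
        b = table[table.feature == "b"].iloc[0]
        assert b["count"] == 1
        assert "c" not in set(table.feature)

    def test_sorted_by_count(self):
        folds = [FoldModel(None, [], {"x": 1.0}, 0.1), FoldModel(None, [], {"x": 1.0, "y": 2.0}, 0.1)]
        assert list(summarize_selection(folds).feature) == ["x", "y"]


class TestCoxRegression:
    def test_identical_groups_null_hr(self):
        t = np.tile([1, 2, 3, 4, 5, 6, 7, 8], 2).astype(float)
        e = np.tile([1, 1, 0, 1, 1, 0, 1, 1], 2)
        g = np.repeat([0, 1], 8)
        terms = pd.DataFrame({"g": g})
        out = cox_regression(t, e, terms, mode="univariable")
        assert out["HR"].iloc[0] == pytest.approx(1.0, abs=0.05)
        assert out["ci_low"].iloc[0] < 1.0 < out["ci_high"].iloc[0]

    def test_hr2_recovered(self):
        rng = np.random.default_rng(5)
        n = 300
        g = np.repeat([0, 1], n // 2)
        t = rng.exponential(1.0 / (0.05 * 2.0**g))
        e = np.ones(n, int)
        out = cox_regression(t, e, pd.DataFrame({"g": g}), mode="univariable")
        assert out["ci_low"].iloc[0] < 2.0 < out["ci_high"].iloc[0]

    def test_null_covariate_leaves_signal_stable(self):
        rng = np.random.default_rng(6)
        n = 300
        g = np.repeat([0, 1], n // 2)
        noise = (rng.random(n) < 0.5).astype(int)
        t = rng.exponential(1.0 / (0.05 * 2.0**g))
        e = np.ones(n, int)
        uni = cox_regression(t, e, pd.DataFrame({"g": g}), mode="univariable")
        multi = cox_regression(t, e, pd.DataFrame({"g": g, "z": noise}), mode="multivariable")
        hr_uni = uni["HR"].iloc[0]
        hr_multi = multi.loc[multi.term == "g", "HR"].iloc[0]
        assert abs(hr_multi - hr_uni) / hr_uni < 0.10

    def test_non_binary_term_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            cox_regression([1, 2, 3], [1, 1, 1], pd.DataFrame({"g": [0.0, 0.5, 1.0]}))


class TestKaplanMeier:
    def test_matches_hand_computed_product_limit(self):
        # times 1,2,3,4,5,6 with events 1,1,0,1,0,1:
        # S(1)=5/6, S(2)=5/6*4/5=2/3, S(4)=2/3*2/3=4/9, S(6)=0
        km = km_curve([1, 2, 3, 4, 5, 6], [1, 1, 0, 1, 0, 1])
        s = dict(zip(km["time"], km["survival"]))
        assert s[1.0] == pytest.approx(5 / 6)
        assert s[2.0] == pytest.approx(2 / 3)
        assert s[4.0] == pytest.approx(4 / 9)
        assert s[6.0] == pytest.approx(0.0)
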