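"""Kaplan-Meier, time-dependent ROC/AUC, multivariable Cox independence."""

import numpy as np
import pandas as pd
import pytest

import reopair as rp
from reopair.evaluation import _km_at
from tests.conftest import make_survival, random_survival


class TestKaplanMeier:
    def test_textbook_product_limit_example(self):
        # subjects at 1, 2+, 3, 4, 5+, 6 with events at 1, 3, 4, 6
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        event = np.array([1, 0, 1, 1, 0, 1])
        assert _km_at(time, event, 1) == pytest.approx(5 / 6)
        assert _km_at(time, event, 3) == pytest.approx(5 / 6 * 3 / 4)
        assert _km_at(time, event, 4) == pytest.approx(5 / 6 * 3 / 4 * 2 / 3)
        assert _km_at(time, event, 6) == pytest.approx(0.0)

    def test_no_deaths_curve_is_one(self):
        time = np.array([100.0, 300.0, 800.0])
        assert _km_at(time, np.zeros(3), 900) == 1.0

    def test_identical_groups_logrank_p_one(self):
        time = np.r_[np.array([50.0, 120, 300, 400, 800]),
                     np.array([50.0, 120, 300, 400, 800])]
        event = np.r_[np.array([1, 0, 1, 1, 0]), np.array([1, 0, 1, 1, 0])]
        groups = pd.Series(["high"] * 5 + ["low"] * 5,
                           index=[f"P{i}" for i in range(10)])
        res = rp.km_logrank(groups, make_survival(time, event))
        assert res["statistic"] == pytest.approx(0.0, abs=1e-10)
        assert res["p"] == pytest.approx(1.0)

    def test_curves_are_nonincreasing_in_unit_interval(self, small_cohort):
        surv = rp.filter_samples(small_cohort.survival)
        rng = np.random.default_rng(0)
        groups = pd.Series(rng.choice(["high", "low"], len(surv.data)),
                           index=surv.data.index)
        res = rp.km_logrank(groups, surv)
        for curve in res["curves"].values():
            s = curve["survival"].to_numpy()
            assert ((s >= -1e-12) & (s <= 1 + 1e-12)).all()
            assert (np.diff(s) <= 1e-12).all()

    def test_single_group_raises(self):
        groups = pd.Series(["high"] * 4, index=[f"P{i}" for i in range(4)])
        with pytest.raises(rp.ReopairError):
            rp.km_logrank(groups, make_survival([1, 2, 3, 4], [1, 1, 1, 1]))


def mann_whitney_auc(scores, case):
    """Brute-force pairwise P(case score > control score), ties count half."""
    cases, controls = scores[case], scores[~case]
    wins = sum((c > d) + 0.5 * (c == d) for c in cases for d in controls)
    return wins / (len(cases) * len(controls))


class TestTimedROC:
    def test_no_censoring_auc_equals_mann_whitney(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            n = 50
            time = rng.uniform(50, 3000, n)
            scores = pd.Series(np.round(rng.normal(size=n), 1),  # force ties
                               index=[f"P{i}" for i in range(n)])
            surv = make_survival(time, np.ones(n))
            roc = rp.time_dependent_roc(scores, surv, 3)
            case = time <= 3 * rp.DAYS_PER_YEAR
            assert roc.auc == pytest.approx(mann_whitney_auc(scores.to_numpy(), case),
                                            abs=1e-10)

    def test_auc_invariant_under_increasing_transform(self):
        rng = np.random.default_rng(2)
        n = 120
        time, event = random_survival(rng, n, hazard=0.002, censor_scale=600.0)
        scores = pd.Series(rng.normal(size=n), index=[f"P{i}" for i in range(n)])
        surv = make_survival(time, event)
        a1 = rp.time_dependent_roc(scores, surv, 2).auc
        a2 = rp.time_dependent_roc(np.exp(scores * 3) + 7, surv, 2).auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_exact_case_indicator_gives_auc_one(self):
        time = np.r_[np.full(15, 100.0), np.full(15, 4000.0)]
        scores = pd.Series(np.r_[np.ones(15), np.zeros(15)],
                           index=[f"P{i}" for i in range(30)])
        roc = rp.time_dependent_roc(scores, make_survival(time, np.r_[np.ones(15), np.zeros(15)]), 5)
        assert roc.auc == pytest.approx(1.0)

    def test_null_scores_auc_near_half(self):
        rng = np.random.default_rng(3)
        aucs = []
        for _ in range(15):
            n = 300
            time, event = random_survival(rng, n, hazard=0.002, censor_scale=600.0)
            scores = pd.Series(rng.normal(size=n), index=[f"P{i}" for i in range(n)])
            aucs.append(rp.time_dependent_roc(scores, make_survival(time, event), 2).auc)
        assert np.mean(np.abs(np.array(aucs) - 0.5) < 0.1) >= 0.9

    def test_reported_curves_are_monotone(self):
        rng = np.random.default_rng(4)
        n = 150
        time, event = random_survival(rng, n, hazard=0.002, censor_scale=600.0)
        scores = pd.Series(rng.normal(size=n), index=[f"P{i}" for i in range(n)])
        roc = rp.time_dependent_roc(scores, make_survival(time, event), 2)
        assert (np.diff(roc.sensitivity) <= 1e-12).all()
        assert (np.diff(roc.specificity) >= -1e-12).all()

    def test_nne_estimator_close_to_km_on_strong_marker(self):
        rng = np.random.default_rng(5)
        n = 200
        lp = rng.normal(size=n)
        time, event = random_survival(rng, n, hazard=0.002, censor_scale=600.0, lp=1.5 * lp)
        scores = pd.Series(lp, index=[f"P{i}" for i in range(n)])
        surv = make_survival(time, event)
        km = rp.time_dependent_roc(scores, surv, 2, estimator="KM")
        nne = rp.time_dependent_roc(scores, surv, 2, estimator="NNE")
        assert km.auc > 0.7 and nne.auc > 0.7
        assert abs(km.auc - nne.auc) < 0.1

    def test_degenerate_horizons_raise(self):
        surv = make_survival([100.0, 200.0], [1, 1])
        with pytest.raises(rp.ReopairError):
            rp.time_dependent_roc(pd.Series([1.0, 2.0], index=["P0", "P1"]), surv, 5)


class TestMultivariateCox:
    def test_single_binary_covariate_matches_pair_screen(self):
        rng = np.random.default_rng(6)
        n = 150
        z = rng.integers(0, 2, n)
        time, event = random_survival(rng, n, censor_scale=150.0, lp=0.8 * z)
        surv = make_survival(time, event)   # no clinical columns
        risk = pd.Series(z.astype(float), index=surv.data.index)
        rep = rp.multivariate_cox(risk, surv)
        reo = rp.REOMatrix([rp.LncPair("a", "b")], z[None, :], list(surv.data.index))
        screen = rp.univariate_cox_screen(reo, surv, low=0, high=1)
        assert rep.loc["risk_score", "beta"] == pytest.approx(screen.beta[0], abs=1e-8)
        assert rep.loc["risk_score", "p"] == pytest.approx(screen.p[0], abs=1e-10)

    def test_duplicated_covariate_dropped_with_warning(self):
        rng = np.random.default_rng(7)
        n = 100
        time, event = random_survival(rng, n, censor_scale=150.0)
        surv = make_survival(time, event, age=rng.normal(60, 8, n),
                             gender=np.where(rng.random(n) < 0.5, "male", "male"))
        risk = pd.Series(rng.normal(size=n), index=surv.data.index)
        with pytest.warns(UserWarning, match="constant"):
            rep = rp.multivariate_cox(risk, surv)
        assert "gender_male" not in rep.index

    def test_risk_only_signal_leaves_covariates_null(self, recovery_cohort):
        """Hazard depends only on the planted pairs; clinical p's behave as null."""
        co = recovery_cohort
        surv = rp.filter_samples(co.survival)
        lp = pd.Series(co.truth["linear_predictor"], index=co.survival.data.index)
        rep = rp.multivariate_cox(lp.loc[surv.data.index], surv)
        assert rep.loc["risk_score", "p"] < 1e-6
        others = rep.drop(index="risk_score")["p"]
        assert (others > 0.01).mean() >= 0.75
        assert ((rep["hr_ci_low"] <= rep["hr"]) & (rep["hr"] <= rep["hr_ci_high"])).all()
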