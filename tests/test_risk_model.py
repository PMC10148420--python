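"""Signature selection, risk scoring, Youden thresholding, published model."""

import itertools
import json

import numpy as np
import pandas as pd
import pytest

import reopair as rp
from reopair.coxph import cox_fit
from tests.conftest import make_survival, random_survival


def _expr_with_orientations(model, states):
    """Expression realising given ordering states for every model pair."""
    rows, ids = [], []
    for (a, b, _), x in zip(model.terms, states):
        lo, hi = (1.0, 2.0) if x else (2.0, 1.0)
        ids += [a, b]
        rows += [lo, hi]
    df = pd.DataFrame({"P0": rows}, index=ids)
    return rp.ExpressionMatrix(df, pd.Series("lncRNA", index=df.index), "log2p1")


class TestPublishedModel:
    def test_eleven_pairs_over_22_lncrnas(self, published):
        assert len(published.terms) == 11
        assert len(published.lncrna_ids) == 22
        assert published.threshold == 0.025
        assert published.provenance == "published"

    def test_all_ones_scores_sum_of_coefficients(self, published):
        expr = _expr_with_orientations(published, [1] * 11)
        score = rp.compute_risk_scores(published, expr)["P0"]
        assert score == pytest.approx(2.1542, abs=1e-10)

    def test_all_zero_scores_zero(self, published):
        expr = _expr_with_orientations(published, [0] * 11)
        assert rp.compute_risk_scores(published, expr)["P0"] == 0.0

    def test_threshold_rule_boundary(self, published):
        scores = pd.Series([0.025, 0.0249, -1.0], index=["x", "y", "z"])
        out = rp.classify(scores, published.threshold)
        assert list(out["group"]) == ["high", "low", "low"]

    def test_json_round_trip(self, tmp_path, published):
        path = tmp_path / "m.json"
        published.to_json(path)
        again = rp.RiskModel.from_json(path)
        assert again.terms == published.terms
        assert again.threshold == published.threshold


def _planted_reo(rng, n=400, n_planted=5, n_null=45, betas=(1.0, -1.0, 1.0, -1.0, 1.0)):
    """Planted binary pair states plus independent null states, with survival."""
    Z = rng.integers(0, 2, (n_planted + n_null, n))
    lp = np.asarray(betas) @ Z[:n_planted]
    time, event = random_survival(rng, n, censor_scale=180.0, lp=lp)
    pairs = [rp.LncPair(f"a{i:02d}", f"b{i:02d}") for i in range(n_planted + n_null)]
    reo = rp.REOMatrix(pairs, Z, [f"P{i}" for i in range(n)])
    return reo, make_survival(time, event), pairs[:n_planted]


class TestLasso:
    def test_retains_planted_pairs(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            reo, surv, planted = _planted_reo(rng)
            path = rp.lasso_cox_select(reo, surv, seed=seed)
            hits += set(planted) <= set(path.selected_pairs)
        assert hits >= 8

    def test_penalty_top_of_grid_has_empty_active_set(self):
        rng = np.random.default_rng(0)
        reo, surv, _ = _planted_reo(rng)
        path = rp.lasso_cox_select(reo, surv, seed=0)
        assert path.n_active[0] == 0
        assert path.selected_alpha == path.alphas[np.argmin(path.cv_deviance_mean)]

    def test_duplicate_covariates_leave_risk_scores_unchanged(self):
        rng = np.random.default_rng(1)
        reo, surv, _ = _planted_reo(rng, n_null=20)
        path = rp.lasso_cox_select(reo, surv, seed=3)
        dup = rp.REOMatrix(reo.pairs + [rp.LncPair("zz0", "zz1")],
                           np.vstack([reo.X, reo.X[0]]), reo.sample_ids)
        path2 = rp.lasso_cox_select(dup, surv, seed=3)

        def predict(r, p):
            pos = {q: i for i, q in enumerate(r.pairs)}
            return sum(coef * r.X[pos[rp.LncPair(*str(name).split("|"))]]
                       for name, coef in p.coefficients.items())
        np.testing.assert_allclose(predict(reo, path), predict(dup, path2), atol=1e-3)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        reo, surv, _ = _planted_reo(rng, n_null=15)
        p1 = rp.lasso_cox_select(reo, surv, seed=9)
        p2 = rp.lasso_cox_select(reo, surv, seed=9)
        assert p1.selected_pairs == p2.selected_pairs
        np.testing.assert_array_equal(p1.cv_deviance_mean, p2.cv_deviance_mean)


class TestStepwise:
    def test_drops_pure_noise_pair(self):
        # AIC drops a term iff its likelihood-ratio statistic is < 2, so a
        # noise covariate is retained with probability P(chi2_1 > 2) ~ 0.16
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            reo, surv, planted = _planted_reo(rng, n_planted=1, n_null=1, betas=(1.2,))
            model = rp.stepwise_aic_cox(reo, surv, reo.pairs)
            kept = {rp.LncPair.make(a, b) for a, b, _ in model.terms}
            hits += kept == {planted[0]}
        assert hits >= 14

    def test_single_prognostic_candidate_retained(self):
        rng = np.random.default_rng(3)
        reo, surv, planted = _planted_reo(rng, n_planted=1, n_null=0, betas=(1.5,))
        model = rp.stepwise_aic_cox(reo, surv, planted)
        assert len(model.terms) == 1

    def test_never_worse_than_exhaustive_oracle_and_often_equal(self):
        """AIC of the stepwise model vs brute-force search over all subsets."""
        equal = 0
        n_instances = 8
        for seed in range(n_instances):
            rng = np.random.default_rng(100 + seed)
            m = 6
            reo, surv, _ = _planted_reo(rng, n=150, n_planted=2, n_null=m - 2,
                                        betas=(1.0, -1.0))
            time, event = surv.times_events(reo.sample_ids)

            def aic(idx):
                return cox_fit(reo.X[list(idx)].T.astype(float), time, event).aic

            best = min(aic(sub) for r in range(1, m + 1)
                       for sub in itertools.combinations(range(m), r))
            model = rp.stepwise_aic_cox(reo, surv, reo.pairs)
            pos = {q: i for i, q in enumerate(reo.pairs)}
            got = aic([pos[rp.LncPair.make(a, b)] for a, b, _ in model.terms])
            assert got >= best - 1e-8
            full = aic(range(m))
            assert got <= full + 1e-8          # never worse than the start
            equal += got == pytest.approx(best, abs=1e-8)
        assert equal / n_instances >= 0.7


class TestScores:
    def test_orientation_respected_against_canonical_matrix(self, published):
        # build a REO matrix in canonical orientation and check flips
        states = [1, 0] * 5 + [1]
        expr = _expr_with_orientations(published, states)
        pairs = [rp.LncPair.make(a, b) for a, b, _ in published.terms]
        reo = rp.build_reo_matrix(expr, sorted(pairs))
        s_expr = rp.compute_risk_scores(published, expr)
        s_reo = rp.compute_risk_scores(published, reo)
        assert s_expr["P0"] == pytest.approx(s_reo["P0"], abs=1e-12)

    def test_negating_coefficients_negates_scores(self, published):
        states = [1, 1, 0, 1, 0, 0, 1, 0, 1, 1, 0]
        expr = _expr_with_orientations(published, states)
        neg = rp.RiskModel([(a, b, -c) for a, b, c in published.terms])
        assert rp.compute_risk_scores(neg, expr)["P0"] == pytest.approx(
            -rp.compute_risk_scores(published, expr)["P0"], abs=1e-12)

    def test_monotone_expression_transform_leaves_scores_unchanged(self, small_cohort):
        model = rp.RiskModel([(p[0], p[1], b) for p, b in
                              [(t["pair"], t["beta"]) for t in
                               small_cohort.truth["planted_pairs"]]])
        lnc = small_cohort.expression.by_biotype("lncRNA")
        s1 = rp.compute_risk_scores(model, lnc)
        squashed = rp.ExpressionMatrix(np.sqrt(lnc.values * 8 + 2), lnc.biotype, "log2p1")
        s2 = rp.compute_risk_scores(model, squashed)
        pd.testing.assert_series_equal(s1, s2)

    def test_missing_lncrna_listed(self, published):
        df = pd.DataFrame({"P0": [1.0]}, index=["VIM-AS1"])
        expr = rp.ExpressionMatrix(df, pd.Series("lncRNA", index=df.index), "log2p1")
        with pytest.raises(rp.ReopairError):
            rp.compute_risk_scores(published, expr)


class TestYouden:
    def test_matches_exhaustive_cutoff_scan(self):
        """Uncensored small instance: J maximiser equals brute force."""
        rng = np.random.default_rng(4)
        n = 20
        scores = pd.Series(rng.normal(size=n), index=[f"P{i}" for i in range(n)])
        time = rng.uniform(100, 2000, n)
        surv = make_survival(time, np.ones(n))
        t = 3 * rp.DAYS_PER_YEAR
        case = time <= t

        best_j, best_c = -np.inf, None
        for c in np.sort(np.unique(scores)):
            sens = ((scores >= c) & case).sum() / case.sum()
            spec = ((scores < c) & ~case).sum() / (~case).sum()
            j = sens + spec - 1
            if j > best_j + 1e-12:
                best_j, best_c = j, c
        got = rp.youden_threshold(scores, surv, horizon_years=3)
        roc = rp.time_dependent_roc(scores, surv, 3)
        assert max(roc.youden()["J"]) == pytest.approx(best_j, abs=1e-10)
        # ties broken toward the smaller (more sensitive) cutoff
        assert got <= best_c + 1e-12

    def test_perfect_marker_reaches_j_of_one(self):
        time = np.r_[np.full(10, 200.0), np.full(10, 3000.0)]
        scores = pd.Series(np.r_[np.ones(10), np.zeros(10)],
                           index=[f"P{i}" for i in range(20)])
        surv = make_survival(time, np.r_[np.ones(10), np.zeros(10)])
        roc = rp.time_dependent_roc(scores, surv, 3)
        assert max(roc.youden()["J"]) == pytest.approx(1.0)
        thr = rp.youden_threshold(scores, surv, 3)
        assert 0 < thr <= 1

    def test_null_scores_give_small_j(self):
        rng = np.random.default_rng(5)
        small = 0
        n_seeds = 20
        for _ in range(n_seeds):
            n = 300
            time, event = random_survival(rng, n, hazard=0.002, censor_scale=500.0)
            scores = pd.Series(rng.normal(size=n), index=[f"P{i}" for i in range(n)])
            j = max(rp.time_dependent_roc(scores, make_survival(time, event), 1)
                    .youden()["J"])
            small += j < 0.3
        assert small / n_seeds >= 0.9

    def test_degenerate_roc_raises(self):
        scores = pd.Series([1.0, 2.0], index=["P0", "P1"])
        surv = make_survival([10_000, 20_000], [1, 1])
        with pytest.raises(rp.ReopairError):
            rp.youden_threshold(scores, surv, 5)


def test_classify_extremes():
    scores = pd.Series([0.1, -0.2], index=["a", "b"])
    assert (rp.classify(scores, -np.inf)["group"] == "high").all()
    assert (rp.classify(scores, np.inf)["group"] == "low").all()
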