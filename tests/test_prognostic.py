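"""Combination enumeration, DEG screening, fitting, leaderboard, selection."""

import numpy as np
import pandas as pd
import pytest

import ecotme as e
from ecotme.prognostic import (
    AlgorithmSpec,
    CombinationTemplate,
    FittedCombination,
    _zscore_genes,
)


@pytest.fixture(scope="module")
def prognostic_cohort():
    """Training cohort with planted prognostic genes, pre-screened genes."""
    cfg = e.SyntheticConfig(seed=17, n_genes=150, n_bulk_samples=500,
                            n_prognostic_genes=5)
    expr, surv, truth = e.generate_bulk_survival(cfg)
    deg = e.screen_degs(expr, surv["ecosystem"], surv, truth.high_risk_ecosystem)
    return expr.loc[list(deg.index)], surv, truth


class TestEnumeration:
    def test_full_registry_gives_126(self):
        templates = e.enumerate_combinations(e.default_registry())
        assert len(templates) == 126
        standalone = [t for t in templates if t.selector is None]
        assert len(standalone) == 21
        selectors = {t.selector for t in templates if t.selector}
        assert selectors == {"LASSO", "KangScore", "RSF", "StepCox", "CoxBoost"}

    def test_single_nonscreening_algorithm(self):
        templates = e.enumerate_combinations([AlgorithmSpec("ridge", "model")])
        assert len(templates) == 1

    def test_two_screeners_three_plain_modelers(self):
        registry = [AlgorithmSpec("LASSO", "both"), AlgorithmSpec("RSF", "both"),
                    AlgorithmSpec("ridge", "model")]
        assert len(e.enumerate_combinations(registry)) == 9  # 2*3 + 3

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            e.enumerate_combinations([AlgorithmSpec("ridge", "model")] * 2)

    def test_names_are_unique(self):
        templates = e.enumerate_combinations(e.default_registry())
        names = [t.name for t in templates]
        assert len(names) == len(set(names))


class TestScreenDegs:
    def test_fold_change_boundary_and_direction(self):
        rng = np.random.default_rng(0)
        n = 200
        high = np.arange(n) < n // 2
        groups = pd.Series(np.where(high, "HR", "rest"),
                           index=[f"s{i}" for i in range(n)])
        base = rng.normal(0, 0.3, size=(3, n))
        base[0, high] += np.log2(1.4)   # FC 1.4: below threshold
        base[1, high] += np.log2(4.0)   # FC 4, HR-consistent (drives hazard)
        base[2, high] += np.log2(4.0)   # FC 4 but protective: direction clash
        expr = pd.DataFrame(base, index=["fc14", "risky", "clash"],
                            columns=groups.index)
        lp = 1.0 * base[1] - 1.0 * base[2]
        t = rng.exponential(1.0 / (0.1 * np.exp(lp)))
        surv = pd.DataFrame({"time": t, "event": 1}, index=groups.index)
        table = e.screen_degs(expr, groups, surv, "HR")
        assert "fc14" not in table.index
        assert "risky" in table.index
        assert "clash" not in table.index

    def test_planted_genes_retained_low_false_positives(self):
        cfg = e.SyntheticConfig(seed=23, n_genes=250, n_bulk_samples=600)
        expr, surv, truth = e.generate_bulk_survival(cfg)
        table = e.screen_degs(expr, surv["ecosystem"], surv,
                              truth.high_risk_ecosystem)
        planted = {g for g, _ in truth.prognostic_genes}
        assert len(planted & set(table.index)) >= 0.8 * len(planted)
        # genes with neither an ecosystem shift nor a planted hazard effect
        eco_genes = {g for gs in truth.ecosystem_genes.values() for g in gs}
        null_genes = set(expr.index) - eco_genes - planted
        fp = len(set(table.index) & null_genes) / len(null_genes)
        assert fp < 0.01

    def test_no_survivors_raises_with_attrition(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.normal(0, 0.01, size=(5, 100)),
                            index=[f"g{i}" for i in range(5)],
                            columns=[f"s{i}" for i in range(100)])
        groups = pd.Series(["HR"] * 50 + ["rest"] * 50, index=expr.columns)
        surv = pd.DataFrame({"time": rng.exponential(5, 100), "event": 1},
                            index=expr.columns)
        with pytest.raises(ValueError, match="FC pass"):
            e.screen_degs(expr, groups, surv, "HR")


class TestSplit:
    def test_seventy_thirty_and_determinism(self):
        rng = np.random.default_rng(2)
        surv = pd.DataFrame({"time": rng.exponential(5, 100),
                             "event": rng.integers(0, 2, 100)},
                            index=[f"s{i}" for i in range(100)])
        tr1, va1 = e.split_train_validation(surv, seed=3)
        tr2, va2 = e.split_train_validation(surv, seed=3)
        assert len(tr1) == 70 and len(va1) == 30
        assert set(tr1) == set(tr2) and set(va1) == set(va2)
        assert set(tr1).isdisjoint(va1)

    def test_event_stratification(self):
        rng = np.random.default_rng(4)
        surv = pd.DataFrame({"time": rng.exponential(5, 300),
                             "event": (rng.random(300) < 0.4).astype(int)},
                            index=[f"s{i}" for i in range(300)])
        tr, va = e.split_train_validation(surv, seed=5)
        overall = surv["event"].mean()
        assert abs(surv.loc[tr, "event"].mean() - overall) < 0.1
        assert abs(surv.loc[va, "event"].mean() - overall) < 0.1


class TestFitCombination:
    def test_ridge_keeps_all_genes(self, prognostic_cohort):
        expr, surv, _ = prognostic_cohort
        sub = expr.iloc[:10]
        fit = e.fit_combination(CombinationTemplate(None, "ridge"), sub, surv,
                                seed=0)
        assert fit.status == "ok"
        assert fit.model_size == 10

    def test_lasso_selects_planted_genes(self):
        found = 0
        for seed in range(5):
            cfg = e.SyntheticConfig(seed=100 + seed, n_genes=150,
                                    n_bulk_samples=500)
            expr, surv, truth = e.generate_bulk_survival(cfg)
            planted = [g for g, _ in truth.prognostic_genes]
            noise = [g for g in expr.index if g not in planted][:20]
            fit = e.fit_combination(CombinationTemplate(None, "LASSO"),
                                    expr.loc[planted + noise], surv, seed=seed)
            found += sum(g in fit.genes for g in planted) >= 4
        assert found >= 4  # >= 80% of seeds

    def test_stepcox_backward_keeps_planted_gene(self):
        kept = 0
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            n = 500
            X = pd.DataFrame(rng.normal(size=(n, 4)),
                             columns=["planted", "n1", "n2", "n3"])
            t = rng.exponential(1.0 / (0.1 * np.exp(0.7 * X["planted"])))
            surv = pd.DataFrame({"time": t, "event": 1},
                                index=[f"s{i}" for i in range(n)])
            expr = X.T
            expr.columns = surv.index
            fit = e.fit_combination(
                CombinationTemplate(None, "StepCox", (("direction", "backward"),)),
                expr, surv, seed=seed)
            kept += "planted" in fit.genes
        assert kept >= 8

    def test_selector_cache_reused(self, prognostic_cohort):
        expr, surv, _ = prognostic_cohort
        cache = {}
        t1 = CombinationTemplate("LASSO", "ridge")
        t2 = CombinationTemplate("LASSO", "plsRcox")
        f1 = e.fit_combination(t1, expr, surv, seed=0, selector_cache=cache)
        f2 = e.fit_combination(t2, expr, surv, seed=0, selector_cache=cache)
        assert "LASSO" in cache
        assert set(f1.coefficients.index) == set(cache["LASSO"])
        assert set(f2.coefficients.index) <= set(cache["LASSO"])

    def test_enet_support_shrinks_with_l1_weight(self, prognostic_cohort):
        expr, surv, _ = prognostic_cohort
        from ecotme.prognostic import _fit_coxnet
        X = _zscore_genes(expr).T.loc[surv.index]
        sizes = {}
        for l1 in (0.1, 1.0):
            path_sizes = []
            from sksurv.linear_model import CoxnetSurvivalAnalysis
            from sksurv.util import Surv
            y = Surv.from_arrays(surv["event"].astype(bool), surv["time"])
            m = CoxnetSurvivalAnalysis(l1_ratio=l1, alphas=[0.1], max_iter=20000)
            m.fit(X.to_numpy(), y)
            sizes[l1] = int((m.coef_ != 0).sum())
        assert sizes[1.0] <= sizes[0.1]


class TestLeaderboardAndSelection:
    def test_risk_equals_negative_time_gives_c_one(self):
        rng = np.random.default_rng(6)
        surv = pd.DataFrame({"time": rng.exponential(5, 80), "event": 1},
                            index=[f"s{i}" for i in range(80)])
        expr = pd.DataFrame({s: [-surv.loc[s, "time"]] for s in surv.index},
                            index=["oracle"])
        coef = pd.Series({"oracle": 1.0})
        model = FittedCombination(CombinationTemplate(None, "ridge"),
                                  ["oracle"], coef, None, 1)
        from ecotme.prognostic import _linear_predictor
        model.predict = _linear_predictor(coef)
        board = e.build_leaderboard([model], [("v", expr, surv)])
        # risk is a monotone transform of -time (z-scored), so C = 1
        assert board["C_v"].iloc[0] == pytest.approx(1.0)
        assert board["mean_C"].iloc[0] == board["C_v"].iloc[0]

    def test_permuted_labels_give_half_c(self, prognostic_cohort):
        expr, surv, _ = prognostic_cohort
        rng = np.random.default_rng(7)
        perm_surv = surv.copy()
        perm_surv[["time", "event"]] = surv[["time", "event"]].sample(
            frac=1.0, random_state=8).to_numpy()
        fit = e.fit_combination(CombinationTemplate(None, "ridge"), expr, surv,
                                seed=0)
        risk = e.compute_risk_score(fit, expr)
        assert e.harrell_c(perm_surv, risk) == pytest.approx(0.5, abs=0.05)

    def test_mean_is_average_over_cohorts(self, prognostic_cohort):
        expr, surv, truth = prognostic_cohort
        fit = e.fit_combination(CombinationTemplate(None, "plsRcox"), expr,
                                surv, seed=0)
        cohorts = [("a", expr, surv), ("b", expr.iloc[:, :250], surv.iloc[:250])]
        board = e.build_leaderboard([fit], cohorts)
        row = board.iloc[0]
        assert row["mean_C"] == pytest.approx((row["C_a"] + row["C_b"]) / 2)

    def _board(self, rows):
        return pd.DataFrame(rows).set_index("combination").assign(status="ok")

    def test_size_bound_excludes_best(self):
        board = self._board([
            {"combination": "big", "mean_C": 0.80, "model_size": 20},
            {"combination": "small", "mean_C": 0.75, "model_size": 12},
        ])
        name, ok = e.select_optimal(board)
        assert name == "small" and ok

    def test_single_small_model(self):
        board = self._board([{"combination": "only", "mean_C": 0.6,
                              "model_size": 3}])
        assert e.select_optimal(board) == ("only", True)

    def test_tie_prefers_smaller_model(self):
        board = self._board([
            {"combination": "m14", "mean_C": 0.7, "model_size": 14},
            {"combination": "m10", "mean_C": 0.7, "model_size": 10},
        ])
        assert e.select_optimal(board)[0] == "m10"

    def test_no_model_within_bound_flagged(self):
        board = self._board([
            {"combination": "a", "mean_C": 0.7, "model_size": 20},
            {"combination": "b", "mean_C": 0.6, "model_size": 25},
        ])
        name, ok = e.select_optimal(board)
        assert name == "a" and not ok


class TestRiskScore:
    def test_linear_score_and_monotonicity(self):
        coef = pd.Series({"g1": 1.0})
        from ecotme.prognostic import _linear_predictor
        model = FittedCombination(CombinationTemplate(None, "ridge"), ["g1"],
                                  coef, _linear_predictor(coef), 1)
        rng = np.random.default_rng(9)
        expr = pd.DataFrame(rng.normal(size=(1, 30)), index=["g1"])
        risk = e.compute_risk_score(model, expr)
        z = (expr.loc["g1"] - expr.loc["g1"].mean()) / expr.loc["g1"].std(ddof=0)
        np.testing.assert_allclose(risk, z, atol=1e-12)
        # doubling a positive-coefficient gene increases the raw linear score
        X = pd.DataFrame({"g1": [1.0, 2.0]})
        assert model.predict(X)[1] > model.predict(X)[0]

    def test_all_zero_coefficients(self):
        coef = pd.Series({"g1": 0.0})
        from ecotme.prognostic import _linear_predictor
        model = FittedCombination(CombinationTemplate(None, "ridge"), ["g1"],
                                  coef, _linear_predictor(coef), 0)
        expr = pd.DataFrame(np.ones((1, 5)) * [[1, 2, 3, 4, 5]], index=["g1"])
        assert (e.compute_risk_score(model, expr) == 0).all()


class TestCrossValidate:
    def test_fold_sizes_determinism_and_signal(self):
        cfg = e.SyntheticConfig(seed=31, n_genes=210, n_bulk_samples=600,
                                n_prognostic_genes=5, effect_size=1.0)
        expr, surv, truth = e.generate_bulk_survival(cfg)
        genes = [g for g, _ in truth.prognostic_genes]
        noise = [g for g in expr.index if g not in genes][:10]
        template = CombinationTemplate(None, "plsRcox")
        res1 = e.cross_validate(template, expr.loc[genes + noise], surv,
                                folds=10, seed=1)
        res2 = e.cross_validate(template, expr.loc[genes + noise], surv,
                                folds=10, seed=1)
        pd.testing.assert_frame_equal(res1, res2)
        assert len(res1) == 10
        assert res1["C"].mean() > 0.7
        assert res1["R2"].mean() > 0.5
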