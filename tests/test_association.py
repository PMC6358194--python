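"""Logistic/multinomial fits: closed forms, cross-checks, invariances."""

import math

import numpy as np
import pandas as pd
import pytest

from wgrs import (
    CollinearityError,
    ConfigError,
    SeparationError,
    default_config,
    diathesis_count_analysis,
    fit_logistic,
    fit_multinomial,
    per_unit_association,
    recurrence_by_category,
    simulate_cohort,
)
from wgrs.association import Z_95

from conftest import logit_2x2_or


def two_by_two(a, b, c, d):
    """Design/outcome for an exposed/unexposed 2x2 layout (events a, c)."""
    x = np.repeat([1.0, 1.0, 0.0, 0.0], [a, b, c, d])
    y = np.repeat([1.0, 0.0, 1.0, 0.0], [a, b, c, d])
    X = pd.DataFrame({"intercept": np.ones_like(x), "exposed": x})
    return X, y


class TestFitLogistic:
    def test_2x2_closed_form(self):
        # exposed: 20 events / 10 non-events; unexposed: 10 events / 20 non-events
        X, y = two_by_two(20, 10, 10, 20)
        fit = fit_logistic(X, y)
        log_or, woolf_se = logit_2x2_or(20, 10, 10, 20)
        assert log_or == pytest.approx(math.log(4), abs=1e-12)
        cell = fit["exposed"]
        assert cell["estimate"] == pytest.approx(log_or, abs=1e-6)
        assert cell["se"] == pytest.approx(woolf_se, abs=1e-6)
        assert cell["ci_low"] == pytest.approx(math.exp(log_or - Z_95 * woolf_se), rel=1e-5)

    def test_balanced_null_slope_zero(self):
        X, y = two_by_two(15, 15, 15, 15)
        fit = fit_logistic(X, y)
        assert fit["exposed"]["estimate"] == pytest.approx(0.0, abs=1e-8)

    def test_agrees_with_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(42)
        n = 500
        X = pd.DataFrame(
            {"intercept": 1.0, "x1": rng.normal(size=n), "x2": rng.binomial(1, 0.4, n)}
        )
        eta = -0.5 + 0.8 * X["x1"] - 0.3 * X["x2"]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        ours = fit_logistic(X, y)
        ref = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(ours.coef, ref.params.to_numpy(), atol=1e-6)
        np.testing.assert_allclose(ours.se, ref.bse.to_numpy(), atol=1e-6)
        assert ours.log_likelihood == pytest.approx(ref.llf, abs=1e-6)

    def test_parameter_recovery_large_n(self):
        rng = np.random.default_rng(1)
        n = 50_000
        x = rng.binomial(1, 0.5, n).astype(float)
        p = 1 / (1 + np.exp(-(-0.5 + math.log(2.0) * x)))
        y = (rng.random(n) < p).astype(float)
        fit = fit_logistic(pd.DataFrame({"intercept": np.ones(n), "x": x}), y)
        cell = fit["x"]
        assert abs(cell["estimate"] - math.log(2.0)) < 3 * cell["se"]

    def test_separation_raises(self):
        X = pd.DataFrame({"intercept": np.ones(20), "x": np.repeat([0.0, 1.0], 10)})
        y = np.repeat([0.0, 1.0], 10)
        with pytest.raises(SeparationError):
            fit_logistic(X, y)

    def test_collinear_design_raises(self):
        X = pd.DataFrame({"intercept": np.ones(30), "a": np.arange(30.0), "b": 2 * np.arange(30.0)})
        y = (np.arange(30) % 2).astype(float)
        with pytest.raises(CollinearityError):
            fit_logistic(X, y)

    def test_shift_invariance_only_moves_intercept(self):
        rng = np.random.default_rng(6)
        n = 400
        x = rng.normal(6, 1, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(-1.2 + 0.2 * x)))).astype(float)
        f1 = fit_logistic(pd.DataFrame({"intercept": np.ones(n), "wgrs": x}), y)
        f2 = fit_logistic(pd.DataFrame({"intercept": np.ones(n), "wgrs": x + 10}), y)
        assert f2["wgrs"]["estimate"] == pytest.approx(f1["wgrs"]["estimate"], abs=1e-6)
        assert f2.coef[0] == pytest.approx(f1.coef[0] - 10 * f1.coef[1], abs=1e-5)

    def test_rescaling_predictor_rescales_slope(self):
        rng = np.random.default_rng(8)
        n = 400
        x = rng.normal(6, 1, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(-1.2 + 0.2 * x)))).astype(float)
        f1 = fit_logistic(pd.DataFrame({"intercept": np.ones(n), "wgrs": x}), y)
        f3 = fit_logistic(pd.DataFrame({"intercept": np.ones(n), "wgrs": 3 * x}), y)
        assert f3["wgrs"]["estimate"] == pytest.approx(f1["wgrs"]["estimate"] / 3, abs=1e-7)


class TestFitMultinomial:
    def test_k2_equals_binary_logistic(self):
        rng = np.random.default_rng(5)
        n = 300
        X = pd.DataFrame({"intercept": np.ones(n), "x": rng.normal(size=n)})
        y = (rng.random(n) < 0.4).astype(int)
        binary = fit_logistic(X, y.astype(float))
        multi = fit_multinomial(X, y, reference=0)
        np.testing.assert_allclose(multi[1].coef, binary.coef, atol=1e-8)
        np.testing.assert_allclose(multi[1].cov, binary.cov, atol=1e-8)

    def test_saturated_2x3_table_matches_cell_ratio_ors(self):
        # exposure x in {0,1}; outcome category in {0,1,2}; counts below
        counts = {(0, 0): 40, (0, 1): 20, (0, 2): 10, (1, 0): 30, (1, 1): 30, (1, 2): 25}
        rows = []
        for (x, k), m in counts.items():
            rows += [(float(x), k)] * m
        x = np.array([r[0] for r in rows])
        y = np.array([r[1] for r in rows])
        X = pd.DataFrame({"intercept": np.ones_like(x), "x": x})
        fits = fit_multinomial(X, y, reference=0)
        for k in (1, 2):
            cell_or = (counts[(1, k)] / counts[(1, 0)]) / (counts[(0, k)] / counts[(0, 0)])
            assert fits[k]["x"]["or"] == pytest.approx(cell_or, rel=1e-6)

    def test_agrees_with_statsmodels_mnlogit(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(21)
        n = 600
        X = pd.DataFrame({"intercept": np.ones(n), "x": rng.normal(size=n)})
        lin1, lin2 = -0.3 + 0.5 * X["x"], 0.1 - 0.4 * X["x"]
        den = 1 + np.exp(lin1) + np.exp(lin2)
        u = rng.random(n)
        y = np.where(u < 1 / den, 0, np.where(u < (1 + np.exp(lin1)) / den, 1, 2))
        ours = fit_multinomial(X, y, reference=0)
        ref = sm.MNLogit(y, X).fit(disp=0)
        np.testing.assert_allclose(ours[1].coef, ref.params.to_numpy()[:, 0], atol=1e-5)
        np.testing.assert_allclose(ours[2].coef, ref.params.to_numpy()[:, 1], atol=1e-5)

    def test_single_category_rejected(self):
        X = pd.DataFrame({"intercept": np.ones(10)})
        with pytest.raises(ConfigError):
            fit_multinomial(X, np.zeros(10, dtype=int))


def _case_table(n_cases, seed, beta_or=1.2, n_controls=0):
    cfg = default_config(
        n_cases=n_cases, n_controls=n_controls, seed=seed,
        per_unit_recurrence_or=beta_or,
        genotype_missing_rate=0.0, phenotype_missing_rate=0.0,
    )
    cohort = simulate_cohort(cfg)
    d = cohort.phenotypes.data
    cases = d[d["is_case"] == 1].copy()
    cases["wgrs"] = cohort.true_wgrs[cases.index]
    return cases, cfg


class TestTableAnalyses:
    def test_per_unit_recovers_generating_slope(self):
        cases, cfg = _case_table(20_000, seed=303)
        res = per_unit_association(
            cases, adjust=("family_history", "early_onset", "bilateral", "ectopic")
        ).iloc[0]
        assert abs(res["estimate"] - cfg.recurrence_model.beta) < 3 * res["se"]

    def test_permuted_outcome_covers_zero(self):
        cases, _ = _case_table(2_000, seed=17)
        rng = np.random.default_rng(99)
        hits = 0
        reps = 60
        for _ in range(reps):
            shuffled = cases.copy()
            shuffled["recurrence"] = rng.permutation(shuffled["recurrence"].to_numpy())
            res = per_unit_association(shuffled).iloc[0]
            if res["ci_low"] <= 1.0 <= res["ci_high"]:
                hits += 1
        assert hits / reps >= 0.90

    def test_category_ors_monotone_under_monotone_model(self):
        from wgrs import categorize_scores

        cases, _ = _case_table(20_000, seed=71)
        cats = categorize_scores(cases["wgrs"], cases["wgrs"].to_numpy())
        cases = cases.assign(wgrs_category=[c.category for c in cats])
        table = recurrence_by_category(cases)
        unadj = table[table["model"] == "unadjusted"].set_index("category")
        assert unadj.loc[4, "or"] > unadj.loc[2, "or"]

    def test_adjustment_without_confounding_changes_little(self):
        # recurrence depends on the score only: adjusted ~ unadjusted
        cfg = default_config(
            n_cases=8_000, n_controls=0, seed=55,
            per_unit_recurrence_or=1.3,
            recurrence_feature_ors={
                "family_history": 1.0, "early_onset": 1.0, "bilateral": 1.0, "ectopic": 1.0
            },
            genotype_missing_rate=0.0, phenotype_missing_rate=0.0,
        )
        cohort = simulate_cohort(cfg)
        d = cohort.phenotypes.data
        cases = d[d["is_case"] == 1].copy()
        cases["wgrs"] = cohort.true_wgrs[cases.index]
        unadj = per_unit_association(cases).iloc[0]
        adj = per_unit_association(
            cases, adjust=("family_history", "early_onset", "bilateral", "ectopic")
        ).iloc[0]
        assert adj["estimate"] == pytest.approx(unadj["estimate"], abs=0.04)

    def test_diathesis_by_category_increases_with_category(self):
        """Positive feature-score slopes show up as rising per-category ORs."""
        from wgrs import categorize_scores, diathesis_by_category

        cases, _ = _case_table(20_000, seed=83)
        cats = categorize_scores(cases["wgrs"], cases["wgrs"].to_numpy())
        cases = cases.assign(wgrs_category=[c.category for c in cats])
        table = diathesis_by_category(cases)
        bilateral = table[table["feature"] == "bilateral"].set_index("category")
        assert bilateral.loc[4, "or"] > bilateral.loc[2, "or"]
        assert set(table["feature"]) == {"family_history", "early_onset", "bilateral", "ectopic"}
        assert len(table) == 12

    def test_diathesis_count_table(self):
        cases, _ = _case_table(20_000, seed=29)
        table = diathesis_count_analysis(cases)
        avail = table[table["available"]]
        assert list(avail["count"]) == [1, 2, 3, 4]
        # equal positive feature effects: ORs increase with the count
        ors = avail.set_index("count")["or"]
        assert ors.loc[4] > ors.loc[1]

    def test_diathesis_count_arithmetic(self):
        df = pd.DataFrame(
            {
                "family_history": [1.0], "early_onset": [0.0],
                "bilateral": [1.0], "ectopic": [0.0],
            }
        )
        counts = df.sum(axis=1)
        assert counts.iloc[0] == 2

    def test_ci_coverage_at_true_or(self):
        # 200 scaled-down replicates; nominal 95% Wald CIs for OR 1.5
        rng = np.random.default_rng(2_718)
        hits, reps = 0, 200
        beta = math.log(1.5)
        for _ in range(reps):
            n = 2_000
            x = rng.normal(0, 1, n)
            p = 1 / (1 + np.exp(-(-0.4 + beta * x)))
            y = (rng.random(n) < p).astype(float)
            fit = fit_logistic(pd.DataFrame({"intercept": np.ones(n), "x": x}), y)
            cell = fit["x"]
            if cell["ci_low"] <= 1.5 <= cell["ci_high"]:
                hits += 1
        assert 0.92 <= hits / reps <= 0.98
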