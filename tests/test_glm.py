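"""Logistic diapause model: IRLS correctness, AIC selection, prediction."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from aedes_diapause.core import EggStatus
from aedes_diapause.glm import (
    build_design,
    fit_logistic,
    predict_diapause,
    select_by_aic,
)

from conftest import make_record


def random_design(rng, n, beta=(-60.0, 1.0, 0.15, 0.0), years=("2019",)):
    """Bernoulli draws from a known logistic law over field-like ranges."""
    x1 = rng.uniform(26, 43, n)
    x2 = rng.normal(176, 7, n)
    year = rng.choice(years, n)
    eta = beta[0] + beta[1] * x1 + beta[2] * x2 + beta[3] * x1 * x2
    p = 1 / (1 + np.exp(-eta))
    y = (rng.random(n) < p).astype(int)
    return pd.DataFrame({"y": y, "x1": x1, "x2": x2, "year": year})


class TestBuildDesign:
    def test_viable_with_morphometry_only(self):
        reps = ((600, 616, 632), (171, 177, 183))
        recs = (
            [make_record(f"h{i}", reps=reps) for i in range(4)]
            + [make_record("h4")]  # viable, no morphometry
            + [make_record("e0", status=EggStatus.EMBRYONATED_UNHATCHED, reps=reps)]
            + [make_record("e1", status=EggStatus.EMBRYONATED_UNHATCHED)]
            + [make_record("p0", status=EggStatus.PARTIAL_EMBRYO, reps=reps)]
            + [make_record("u0", status=EggStatus.UNFERTILISED)]
            + [make_record("x0", status=EggStatus.EXCLUDED, reps=reps)]
        )
        d = build_design(recs)
        assert len(d) == 5
        assert d["y"].sum() == 1

    def test_no_viable_eggs_rejected(self):
        recs = [make_record("p", status=EggStatus.PARTIAL_EMBRYO)]
        with pytest.raises(ValueError, match="viable"):
            build_design(recs)

    def test_row_count_matches_generator_bookkeeping(self, small_season):
        records, _, truth = small_season
        d = build_design(records)
        expected = sum(
            min(r["n_with_morphometry"], r["n_viable"]) for r in truth["realized"]
        )
        # morphometry and viability are drawn independently, so the exact
        # overlap is only known per egg; check via direct recount instead
        direct = sum(1 for r in records if r.is_viable and r.has_morphometry)
        assert len(d) == direct
        assert direct <= expected


class TestFitLogistic:
    def test_intercept_only_even_split(self):
        d = pd.DataFrame({"y": [0, 1] * 25, "x1": 0.0, "x2": 0.0, "year": "2019"})
        f = fit_logistic(d, terms=())
        assert f.coefficients[0] == pytest.approx(0.0, abs=1e-9)

    def test_intercept_only_quarter_positives(self):
        d = pd.DataFrame({"y": [1, 0, 0, 0] * 25, "x1": 0.0, "x2": 0.0, "year": "2019"})
        f = fit_logistic(d, terms=())
        assert f.coefficients[0] == pytest.approx(math.log(1 / 3), abs=1e-9)

    def test_score_equations_hold(self):
        rng = np.random.default_rng(12)
        d = random_design(rng, 400)
        f = fit_logistic(d, terms=("x1", "x2", "x1:x2"))
        X = np.column_stack(
            [np.ones(len(d)), d["x1"], d["x2"], d["x1"] * d["x2"]]
        )
        eta = X @ np.array(f.coefficients)
        p = 1 / (1 + np.exp(-eta))
        score = X.T @ (d["y"].to_numpy() - p)
        assert np.max(np.abs(score)) < 1e-6

    def test_aic_identity_exact(self):
        rng = np.random.default_rng(13)
        f = fit_logistic(random_design(rng, 300), terms=("x1", "x2"))
        assert f.aic == 2 * f.k - 2 * f.log_likelihood

    def test_matches_statsmodels_oracle(self):
        rng = np.random.default_rng(14)
        d = random_design(rng, 500, years=("2019", "2020"))
        f = fit_logistic(d, terms=("x1", "x2", "year", "x1:x2"))
        X = np.column_stack(
            [
                np.ones(len(d)), d["x1"], d["x2"],
                (d["year"] == "2020").astype(float), d["x1"] * d["x2"],
            ]
        )
        ref = sm.GLM(d["y"], X, family=sm.families.Binomial()).fit()
        assert np.allclose(f.coefficients, ref.params, atol=1e-6)
        assert np.allclose(f.standard_errors, ref.bse, atol=1e-5)
        assert f.log_likelihood == pytest.approx(ref.llf, abs=1e-6)

    def test_parameter_recovery_within_two_se(self):
        rng = np.random.default_rng(15)
        beta = (-60.0, 1.2, 0.2, 0.0)
        d = random_design(rng, 5000, beta=beta)
        f = fit_logistic(d, terms=("x1", "x2"))
        for est, se, true in zip(f.coefficients, f.standard_errors, beta[:3]):
            assert abs(est - true) <= 2 * se

    def test_grouped_binomial_equals_bernoulli(self):
        rng = np.random.default_rng(16)
        d = random_design(rng, 600)
        d["x1"] = d["x1"].round()
        d["x2"] = d["x2"].round(-1)  # coarse bins so rows repeat
        per_row = fit_logistic(d, terms=("x1", "x2"))
        g = d.groupby(["y", "x1", "x2"], as_index=False).size()
        g["year"] = "2019"
        grouped = fit_logistic(g, terms=("x1", "x2"), weights=g["size"].to_numpy())
        assert np.allclose(per_row.coefficients, grouped.coefficients, atol=1e-8)
        assert per_row.log_likelihood == pytest.approx(
            grouped.log_likelihood, abs=1e-6
        )

    def test_separation_flagged_not_silent(self):
        d = pd.DataFrame(
            {"y": [0] * 20 + [1] * 20,
             "x1": list(range(20)) + list(range(30, 50)),
             "x2": 0.0, "year": "2019"}
        )
        f = fit_logistic(d, terms=("x1",))
        assert f.separation

    def test_singular_design_names_columns(self):
        d = pd.DataFrame({"y": [0, 1] * 20, "x1": 1.0, "x2": 5.0, "year": "2019"})
        with pytest.raises(ValueError, match="collinear"):
            fit_logistic(d, terms=("x1", "x2"))

    def test_interaction_requires_main_effects(self):
        d = pd.DataFrame({"y": [0, 1], "x1": [1.0, 2.0], "x2": [1.0, 2.0],
                          "year": "2019"})
        with pytest.raises(ValueError, match="main effects"):
            fit_logistic(d, terms=("x1", "x1:x2"))


class TestSelection:
    def test_only_active_predictor_wins_most_runs(self):
        rng = np.random.default_rng(17)
        kept_x1 = 0
        dropped_x2 = 0
        runs = 60
        for _ in range(runs):
            d = random_design(rng, 400, beta=(-18.0, 0.5, 0.0, 0.0))
            best, _ = select_by_aic(d, ("x1", "x2", "x1:x2"))
            kept_x1 += "x1" in best.terms
            dropped_x2 += "x2" not in best.terms
        assert kept_x1 == runs
        # a superfluous parameter sneaks in with P(chi2_1 > 2) ~ 16%, so
        # expect x2 excluded in roughly 3 runs out of 4
        assert dropped_x2 >= 0.65 * runs

    def test_ranking_table_sorted_with_daic(self):
        rng = np.random.default_rng(18)
        d = random_design(rng, 300)
        best, table = select_by_aic(d)
        assert table["AIC"].is_monotonic_increasing
        assert table["dAIC"].iloc[0] == 0.0
        assert best.aic == table["AIC"].min()
        assert (table["AIC"] == 2 * table["k"] - 2 * table["logLik"]).all()

    def test_duplicate_candidates_deduplicated(self):
        rng = np.random.default_rng(19)
        d = random_design(rng, 200)
        _, table = select_by_aic(d, ("x1", "x1", "x2"))
        assert table["formula"].is_unique

    def test_single_candidate_rejected(self):
        rng = np.random.default_rng(20)
        d = random_design(rng, 100)
        with pytest.raises(ValueError, match="two candidate"):
            select_by_aic(d, ())


class TestPredict:
    def fit(self, rng=None):
        rng = rng or np.random.default_rng(21)
        return fit_logistic(random_design(rng, 800), terms=("x1", "x2"))

    def test_zero_linear_predictor_is_half(self):
        f = self.fit()
        b0, b1, b2 = f.coefficients
        # pick (week, width) on the null line of the fitted predictor
        week = 35.0
        width = -(b0 + b1 * week) / b2
        assert predict_diapause(f, week, width) == pytest.approx(0.5, abs=1e-9)

    def test_monotone_in_week_when_slope_positive(self):
        f = self.fit()
        assert f.coef("x1") > 0
        ps = [predict_diapause(f, w, 176.0) for w in range(26, 44)]
        assert all(a < b for a, b in zip(ps, ps[1:]))

    def test_predictions_strictly_inside_unit_interval(self):
        f = self.fit()
        ps = [predict_diapause(f, w, wd)
              for w in (26, 35, 43) for wd in np.linspace(162, 197, 20)]
        assert all(0.0 < p < 1.0 for p in ps)
        assert max(ps) < 1.0 and min(ps) > 0.0

    def test_unseen_year_level_rejected(self):
        rng = np.random.default_rng(22)
        d = random_design(rng, 400, years=("2019", "2020"))
        f = fit_logistic(d, terms=("x1", "x2", "year"))
        assert 0 < predict_diapause(f, 30, 176, year=2020) < 1
        with pytest.raises(ValueError, match="unseen"):
            predict_diapause(f, 30, 176, year=2021)
        with pytest.raises(ValueError, match="year"):
            predict_diapause(f, 30, 176)
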