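"""Spearman matrices and the logistic model suite."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mealtrace.associations import (
    ModelError,
    fit_logistic_suite,
    protein_e_pct,
    spearman_matrix,
)
from mealtrace.config import ModelOptions
from mealtrace.synthetic import generate_logistic_fixture


def _rank_then_pearson(x, y):
    """Independent Spearman oracle: average ranks, then Pearson."""
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    return np.corrcoef(rx, ry)[0, 1]


class TestSpearman:
    def test_self_correlation_is_one(self, rng):
        frame = pd.DataFrame({"a": rng.normal(size=30), "b": rng.normal(size=30)})
        corr, _ = spearman_matrix(frame, ["a", "b"])
        assert corr.loc["a", "a"] == 1.0

    def test_perfect_inverse_monotone(self):
        frame = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [6.0, 5.0, 4.0]})
        corr, _ = spearman_matrix(frame, ["x", "y"])
        assert corr.loc["x", "y"] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle_with_ties(self, rng):
        for _ in range(100):
            n = rng.integers(5, 20)
            x = rng.integers(0, 5, size=n).astype(float)  # heavy ties
            y = rng.normal(size=n).round(1)
            frame = pd.DataFrame({"x": x, "y": y})
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            corr, _ = spearman_matrix(frame, ["x", "y"])
            assert corr.loc["x", "y"] == pytest.approx(
                _rank_then_pearson(x, y), abs=1e-12
            )

    def test_symmetric_unit_diagonal_bounded(self, rng):
        frame = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd"))
        corr, _ = spearman_matrix(frame, list("abcd"))
        m = corr.to_numpy()
        np.testing.assert_allclose(m, m.T, atol=1e-14)
        np.testing.assert_allclose(np.diag(m), 1.0)
        assert (np.abs(m) <= 1 + 1e-12).all()

    def test_constant_variable_flagged_nan(self):
        frame = pd.DataFrame({"x": [1.0, 1.0, 1.0, 1.0], "y": [1.0, 2.0, 3.0, 4.0]})
        corr, _ = spearman_matrix(frame, ["x", "y"])
        assert np.isnan(corr.loc["x", "y"])

    def test_pairwise_complete(self):
        frame = pd.DataFrame(
            {
                "x": [1.0, 2.0, 3.0, 4.0, np.nan],
                "y": [2.0, 4.0, 6.0, 8.0, 1.0],
            }
        )
        corr, _ = spearman_matrix(frame, ["x", "y"])
        assert corr.loc["x", "y"] == pytest.approx(1.0)


def _frame_from_fixture(n, beta, seed, intercept=0.0):
    """Analysis frame whose adequacy outcome follows a known logistic model.

    beta maps to (protein per 5 g, energy per MJ, total EDO) on the model's
    reporting scales; age and education carry zero true effect.
    """
    X, y, truth = generate_logistic_fixture(n, beta, seed=seed, intercept=intercept)
    rng = np.random.default_rng(seed + 1)
    frame = pd.DataFrame(
        {
            "protein_g_day": 5.0 * X["x1"] + 80.0,
            "energy_kj_day": 1000.0 * X["x2"] + 8000.0,
            "total_edo": X["x3"] + 5.0,
            "age_yr": rng.normal(68, 5, n),
            "education": rng.choice(["primary", "secondary", "university"], n),
            "meets_cutoff": y.astype(bool),
            "protein_breakfast": rng.gamma(4, 4, n),
            "protein_lunch": rng.gamma(4, 5, n),
            "protein_dinner": rng.gamma(4, 8, n),
            "protein_other": rng.gamma(2, 5, n),
        }
    )
    return frame, truth


class TestLogisticSuite:
    def test_planted_or_recovered(self):
        frame, _ = _frame_from_fixture(5000, [np.log(2.5), 0.2, 0.1], seed=7)
        results = fit_logistic_suite(frame)
        row = results[(results.model == "daily_mutual") & (results.term == "protein_5g")]
        assert 2.2 < row["or"].iloc[0] < 2.8
        assert row["ci_low"].iloc[0] < row["or"].iloc[0] < row["ci_high"].iloc[0]

    def test_null_coverage_about_95_pct(self):
        covered = 0
        reps = 200
        for rep in range(reps):
            frame, _ = _frame_from_fixture(400, [0.0, 0.3, 0.1], seed=50_000 + rep)
            results = fit_logistic_suite(frame)
            row = results[
                (results.model == "daily_mutual") & (results.term == "protein_5g")
            ].iloc[0]
            covered += row["ci_low"] <= 1.0 <= row["ci_high"]
        assert 0.91 <= covered / reps <= 0.99

    def test_constant_outcome_raises(self):
        frame, _ = _frame_from_fixture(200, [0.5, 0.0, 0.0], seed=3)
        frame["meets_cutoff"] = True
        with pytest.raises(ModelError, match="constant"):
            fit_logistic_suite(frame)

    def test_rescaling_equivariance(self):
        frame, _ = _frame_from_fixture(1500, [np.log(2.0), 0.1, 0.1], seed=11)
        per5 = fit_logistic_suite(frame, ModelOptions(protein_unit_g=5.0))
        frame2 = frame.copy()
        frame2["protein_g_day"] = frame["protein_g_day"] * 2.0
        per10 = fit_logistic_suite(frame2, ModelOptions(protein_unit_g=10.0))
        a = per5[(per5.model == "daily_mutual") & (per5.term == "protein_5g")]["or"].iloc[0]
        b = per10[(per10.model == "daily_mutual") & (per10.term == "protein_5g")]["or"].iloc[0]
        assert a == pytest.approx(b, abs=1e-8)

    def test_adjustment_sets_follow_design(self):
        frame, _ = _frame_from_fixture(800, [0.3, 0.2, 0.1], seed=5)
        results = fit_logistic_suite(frame)
        daily = results[results.model == "daily_protein_individual"].iloc[0]
        assert daily["adjustment"] == "age+education"
        meal = results[results.model == "meal_lunch_individual"].iloc[0]
        assert "energy_mj" in meal["adjustment"] and "total_edo" in meal["adjustment"]
        additive = results[results.model == "meal_additive"]
        assert len(additive) == 4  # all four meals in one model

    def test_bias_shrinks_with_n(self):
        # consistency of the planted-coefficient recovery
        errs = []
        for n in (500, 5000):
            frame, _ = _frame_from_fixture(n, [np.log(2.5), 0.2, 0.1], seed=99)
            results = fit_logistic_suite(frame)
            r = results[
                (results.model == "daily_mutual") & (results.term == "protein_5g")
            ]["or"].iloc[0]
            errs.append(abs(np.log(r) - np.log(2.5)))
        assert errs[1] < errs[0]


class TestFixture:
    def test_zero_beta_gives_half_prevalence(self):
        _, y, _ = generate_logistic_fixture(10_000, [0.0, 0.0], seed=2)
        assert abs(y.mean() - 0.5) < 0.02

    def test_seeded_determinism(self):
        a = generate_logistic_fixture(100, [0.5], seed=4)
        b = generate_logistic_fixture(100, [0.5], seed=4)
        assert (a[1] == b[1]).all()
        pd.testing.assert_frame_equal(a[0], b[0])


def test_protein_e_pct_identity():
    assert protein_e_pct(80.0, 8000.0) == pytest.approx(80.0 * 17.0 / 8000.0 * 100.0)
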