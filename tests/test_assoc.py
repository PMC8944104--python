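"""Design construction, weighted regressions and score correlations."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from actirhythm.assoc import (
    assign_quintiles,
    build_design,
    score_correlations,
    weighted_linear,
    weighted_logistic,
)
from actirhythm.errors import IntegrityError, NumericalError
from actirhythm.simulate import GeneratorConfig, simulate_participants


def reference_row(pid=1):
    return {
        "participant_id": pid,
        "age_group": "25-29",
        "gender": "male",
        "race_ethnicity": "NH White",
        "education": "college grad+",
        "income": ">=$75k",
        "work_status": "40+ h",
    }


def test_design_has_twenty_deterministic_columns():
    cov = simulate_participants(
        GeneratorConfig(n_participants=50, seed=1), expand_minutes=False
    ).covariates
    X = build_design(cov)
    # 1 + 5 + 1 + 5 + 3 + 3 + 2 dummies
    assert X.shape[1] == 20
    X2 = build_design(cov)
    assert list(X.columns) == list(X2.columns)
    assert X.columns[0] == "intercept"


def test_all_reference_participant_is_intercept_only():
    X = build_design(pd.DataFrame([reference_row()]))
    row = X.iloc[0]
    assert row["intercept"] == 1.0
    assert row.drop("intercept").abs().sum() == 0.0


def test_unseen_level_is_rejected():
    bad = pd.DataFrame([{**reference_row(), "age_group": "<25"}])
    with pytest.raises(IntegrityError):
        build_design(bad)


def test_wls_matches_hand_computed_normal_equations():
    """x=(0,1,2), y=(0,1,4), w=(1,1,2): solve (X'WX) b = X'Wy by hand.

    X'WX = [[sum w, sum wx], [sum wx, sum wx^2]] = [[4, 5], [5, 9]];
    X'Wy = [sum wy, sum wxy] = [9, 17] -> b = (X'WX)^-1 [9,17].
    """
    X = pd.DataFrame({"intercept": [1.0, 1.0, 1.0], "x": [0.0, 1.0, 2.0]})
    y = np.array([0.0, 1.0, 4.0])
    w = np.array([1.0, 1.0, 2.0])
    expected = np.linalg.solve(np.array([[4.0, 5.0], [5.0, 9.0]]),
                               np.array([9.0, 17.0]))
    fit = weighted_linear(y, X, w)
    assert np.abs(fit.params.to_numpy() - expected).max() < 1e-12


def test_equal_weights_reduce_to_ols():
    rng = np.random.default_rng(2)
    X = pd.DataFrame({"intercept": np.ones(40), "x": rng.normal(size=40)})
    y = rng.normal(size=40)
    ours = weighted_linear(y, X, np.full(40, 2.5))
    ref = sm.OLS(y, X).fit(cov_type="HC0")
    assert np.allclose(ours.params, ref.params, atol=1e-12)
    assert np.allclose(ours.fit.bse, ref.bse, atol=1e-10)


def test_weight_rescaling_changes_nothing():
    rng = np.random.default_rng(3)
    X = pd.DataFrame({"intercept": np.ones(60), "x": rng.normal(size=60)})
    y = rng.normal(size=60) + X["x"].to_numpy()
    w = rng.lognormal(size=60)
    a = weighted_linear(y, X, w)
    b = weighted_linear(y, X, 37.0 * w)
    assert np.allclose(a.params, b.params, atol=1e-12)
    assert np.allclose(a.fit.bse, b.fit.bse, atol=1e-10)


def test_exactly_linear_outcome_recovers_coefficients():
    X = pd.DataFrame({"intercept": np.ones(10), "x": np.arange(10.0)})
    y = 2.0 + 3.0 * X["x"].to_numpy()
    fit = weighted_linear(y, X, np.ones(10))
    assert np.allclose(fit.params, [2.0, 3.0], atol=1e-10)
    assert abs(fit.fit.resid).max() < 1e-10


def test_collinear_design_is_a_named_error():
    X = pd.DataFrame({"intercept": np.ones(10), "a": np.arange(10.0),
                      "b": 2 * np.arange(10.0)})
    with pytest.raises(NumericalError, match="rank deficient"):
        weighted_linear(np.zeros(10), X, np.ones(10))


def test_quintile_assignment_examples():
    s = pd.Series(np.arange(1, 11, dtype=float), index=range(1, 11))
    q = assign_quintiles(s)
    assert list(q[s <= 2]) == ["Q1", "Q1"]
    assert list(q[s >= 9]) == ["Q5", "Q5"]
    s100 = pd.Series(np.random.default_rng(4).permutation(100).astype(float))
    counts = assign_quintiles(s100).value_counts()
    assert (counts == 20).all()


def test_tied_scores_split_stably_by_participant_id():
    s = pd.Series([0.0] * 7 + [1.0, 2.0, 3.0], index=range(10))
    q1 = assign_quintiles(s)
    q2 = assign_quintiles(s.sample(frac=1.0, random_state=0))
    pd.testing.assert_series_equal(q1, q2.sort_index(), check_names=False)
    # ties fill the lowest quintiles in id order
    assert list(q1[:2]) == ["Q1", "Q1"]


def test_saturated_weighted_logistic_reproduces_two_by_two_odds_ratio():
    """Low-vs-high split with weighted counts a, b, c, d: OR = ad / bc."""
    y = np.array([1.0, 0.0, 1.0, 0.0])
    group_low = np.array([1.0, 1.0, 0.0, 0.0])
    w = np.array([3.0, 5.0, 2.0, 7.0])     # a=3, b=5, c=2, d=7
    X = pd.DataFrame({"intercept": np.ones(4), "low": group_low})
    fit = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=w).fit()
    assert np.exp(fit.params["low"]) == pytest.approx((3 * 7) / (5 * 2), rel=1e-8)


def test_weighted_logistic_quintile_table_and_reference():
    rng = np.random.default_rng(5)
    n = 500
    scores = pd.Series(rng.normal(size=n), index=range(n))
    q = assign_quintiles(scores)
    lin = -0.8 * (q.str[1].astype(float) - 3) / 1.4
    y = (rng.uniform(size=n) < 1 / (1 + np.exp(-lin))).astype(float)
    w = rng.lognormal(sigma=0.4, size=n)
    res = weighted_logistic(y, q, None, w)
    t = res.table.set_index("quintile")
    assert t.loc["Q5", "odds_ratio"] == 1.0 and bool(t.loc["Q5", "reference"])
    assert (t.loc[["Q1", "Q2", "Q3", "Q4"], "odds_ratio"] > 0).all()
    assert t["n_cases"].sum() == int(y.sum())
    assert res.p_trend < 0.01                  # strong built-in trend
    # a decreasing true trend yields Q1 > Q4 odds ratios
    assert t.loc["Q1", "odds_ratio"] > t.loc["Q4", "odds_ratio"]


def test_logistic_weight_rescaling_invariance():
    rng = np.random.default_rng(6)
    n = 300
    scores = pd.Series(rng.normal(size=n), index=range(n))
    q = assign_quintiles(scores)
    y = (rng.uniform(size=n) < 0.3).astype(float)
    w = rng.lognormal(sigma=0.3, size=n)
    a = weighted_logistic(y, q, None, w)
    b = weighted_logistic(y, q, None, 11.0 * w)
    pd.testing.assert_frame_equal(a.table, b.table, atol=1e-8, rtol=1e-8)
    assert a.p_trend == pytest.approx(b.p_trend, abs=1e-8)


def test_separated_quintile_is_diagnosed():
    scores = pd.Series(np.arange(50, dtype=float), index=range(50))
    q = assign_quintiles(scores)
    y = np.where(q == "Q1", 1.0, np.random.default_rng(7).integers(0, 2, 50).astype(float))
    y[(q == "Q1").to_numpy()] = 1.0
    with pytest.raises(NumericalError, match="Q1"):
        weighted_logistic(y, q, None, np.ones(50))


def test_score_correlations_identity_and_negation():
    rng = np.random.default_rng(8)
    a = pd.DataFrame(
        {"score_1": rng.normal(size=30), "score_2": rng.normal(size=30)},
        index=pd.Index(range(30), name="participant_id"),
    )
    r_same = score_correlations(a, a)
    assert np.allclose(r_same, 1.0)
    r_neg = score_correlations(a, -a)
    assert np.allclose(r_neg, -1.0)
    with pytest.raises(ValueError):
        score_correlations(a.iloc[:2], a.iloc[:2])


def test_informative_weights_separate_weighted_and_unweighted_estimands():
    """With weights tied to age and an age-dependent score shift, the
    weighted regression tracks the superpopulation effect while the
    unweighted one is pulled toward the sampled mix."""
    cfg = GeneratorConfig(
        n_participants=3000, seed=9, informative_weights=True,
        covariate_effects={"age_group=70+": (1.0, 0.0, 0.0, 0.0),
                           "gender=female": (0.4, 0.0, 0.0, 0.0)},
    )
    cohort = simulate_participants(cfg, expand_minutes=False)
    cov = cohort.covariates
    y = cohort.truth.true_scores["weekday"][:, 0]
    X = build_design(cov)
    w = cov["exam_weight"].to_numpy()
    res_w = weighted_linear(y, X, w)
    res_u = weighted_linear(y, X, np.ones(len(y)))
    bw = res_w.params["age_group[70+]"]
    bu = res_u.params["age_group[70+]"]
    # both consistent here (correct specification), but the weighted fit must
    # sit within its own CI of the generating effect
    se = res_w.fit.bse["age_group[70+]"]
    assert abs(bw - 1.0) < 1.96 * se * 1.5
    assert abs(bu - 1.0) < 0.3
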