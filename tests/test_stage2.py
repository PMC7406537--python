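"""Stage-2 design grammar, per-imputation fits and Rubin pooling."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from mixls import (Stage2Spec, build_stage2_design, fit_linear,
                   fit_logistic_ordinal, fit_stage2, pool_rubin)
from mixls.errors import RankError, SpecificationError
from mixls.plausible import PlausibleDraws
from mixls.stage2 import ImputationFit


def _subjects(n=40, seed=0):
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame({"id": np.arange(1, n + 1),
                          "age": rng.normal(30, 5, n),
                          "sex": rng.binomial(1, 0.5, n).astype(float)})
    effects = rng.normal(size=(n, 2))
    return frame, effects, ["Locat_1", "Scale"]


def test_design_full_grammar_labels():
    frame, effects, names = _subjects()
    spec = Stage2Spec(outcome="o", regressors=["age", "sex"],
                      interactions={"age": {"location", "scale",
                                            "three_way"}})
    X, labels = build_stage2_design(frame, effects, names, spec)
    assert labels == ["Intercept", "age", "sex", "Locat_1", "Locat_1*age",
                      "Scale", "Scale*age", "Locat_1*Scale", "L*S*age"]
    np.testing.assert_allclose(X[:, labels.index("Locat_1*age")],
                               effects[:, 0] * frame["age"])
    np.testing.assert_allclose(
        X[:, labels.index("L*S*age")],
        effects[:, 0] * effects[:, 1] * frame["age"])


def test_design_slope_interaction_and_suppression():
    frame, _, _ = _subjects()
    rng = np.random.default_rng(1)
    effects = rng.normal(size=(len(frame), 3))
    names = ["Locat_1", "Locat_2", "Scale"]
    spec = Stage2Spec(outcome="o", regressors=["sex"],
                      interactions={"sex": {"slope"}})
    X, labels = build_stage2_design(frame, effects, names, spec)
    assert "Locat_2*sex" in labels and "Locat_1*sex" not in labels
    supp = Stage2Spec(outcome="o", regressors=["sex"],
                      interactions={"sex": {"slope", "scale"}},
                      suppress_all_interactions=True)
    X2, labels2 = build_stage2_design(frame, effects, names, supp)
    assert labels2 == ["Intercept", "sex", "Locat_1", "Locat_2", "Scale"]


def test_design_errors_and_warnings():
    frame, effects, names = _subjects()
    with pytest.raises(SpecificationError):
        Stage2Spec(outcome="o", outcome_type="count")
    with pytest.raises(SpecificationError):
        Stage2Spec(outcome="o", regressors=["age"],
                   interactions={"bmi": {"location"}})
    with pytest.raises(SpecificationError):
        Stage2Spec(outcome="o", regressors=["age"],
                   interactions={"age": {"quadratic"}})
    spec = Stage2Spec(outcome="o", regressors=["ghost"])
    with pytest.raises(SpecificationError, match="unknown stage-2"):
        build_stage2_design(frame, effects, names, spec)
    # scale interaction without a random scale effect in stage 1
    spec = Stage2Spec(outcome="o", regressors=["age"],
                      interactions={"age": {"scale"}})
    with pytest.raises(SpecificationError, match="no random scale"):
        build_stage2_design(frame, effects[:, :1], ["Locat_1"], spec)
    # misaligned effects
    with pytest.raises(SpecificationError, match="aligned"):
        build_stage2_design(frame, effects[:-1], names,
                            Stage2Spec(outcome="o"))
    # constant regressor warns
    frame2 = frame.copy()
    frame2["age"] = 1.0
    with pytest.warns(UserWarning, match="constant"):
        build_stage2_design(frame2, effects, names,
                            Stage2Spec(outcome="o", regressors=["age"]))


def test_fit_linear_matches_normal_equations():
    rng = np.random.default_rng(3)
    n = 60
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = 2.0 + 0.5 * X[:, 1] + rng.normal(size=n)
    fit = fit_linear(X, y, ["Intercept", "x"])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    np.testing.assert_allclose(fit.params[:2], beta, rtol=1e-10)
    resid = y - X @ beta
    sigma2 = resid @ resid / n                 # ML, not OLS, divisor
    assert fit.labels[-1] == "Residual_Variance"
    assert fit.params[-1] == pytest.approx(sigma2)
    np.testing.assert_allclose(np.diag(fit.cov)[:2],
                               sigma2 * np.diag(np.linalg.inv(X.T @ X)))
    ll = sm.OLS(y, X).loglike(beta)            # ML loglik at the optimum
    # statsmodels loglike uses the ML sigma2 internally at the MLE
    assert fit.loglik == pytest.approx(ll, abs=1e-6)
    with pytest.raises(SpecificationError):
        fit_linear(X[:2], y[:2])               # n <= k


def test_fit_logistic_closed_form_two_by_two():
    # binary x: logistic MLE equals the empirical log-odds / log odds ratio
    x = np.repeat([0.0, 1.0], [50, 50])
    y = np.concatenate([np.repeat([0, 1], [30, 20]),
                        np.repeat([0, 1], [15, 35])])
    X = np.column_stack([np.ones(100), x])
    fit = fit_logistic_ordinal(X, y, ["Intercept", "x"])
    b0 = np.log(20 / 30)
    b1 = np.log(35 / 15) - b0
    np.testing.assert_allclose(fit.params, [b0, b1], atol=1e-6)
    # categories are auto-recoded: {3, 7} behaves like {0, 1}
    fit2 = fit_logistic_ordinal(X, np.where(y == 1, 7.0, 3.0),
                                ["Intercept", "x"])
    np.testing.assert_allclose(fit2.params, fit.params, atol=1e-8)


def test_fit_ordinal_thresholds():
    rng = np.random.default_rng(5)
    n = 400
    x = rng.normal(size=n)
    eta = 0.8 * x
    cuts = np.array([-1.0, 0.5])
    u = rng.random(n)
    cdf = 1 / (1 + np.exp(-(cuts[None, :] - eta[:, None])))
    y = (u[:, None] > cdf).sum(axis=1)
    X = np.column_stack([np.ones(n), x])
    fit = fit_logistic_ordinal(X, y, ["Intercept", "x"])
    assert fit.labels == ["Threshold_1", "Threshold_2", "x"]
    assert fit.params[0] < fit.params[1]       # strictly increasing
    np.testing.assert_allclose(fit.params[:2], cuts, atol=0.35)
    assert fit.params[2] == pytest.approx(0.8, abs=0.3)
    assert np.diag(fit.cov).min() > 0


def test_logistic_validation():
    X = np.column_stack([np.ones(10), np.arange(10.0)])
    with pytest.raises(SpecificationError, match="integer-coded"):
        fit_logistic_ordinal(X, np.linspace(0, 1, 10))
    with pytest.raises(SpecificationError, match="single observed"):
        fit_logistic_ordinal(X, np.ones(10))


def test_rank_deficient_design_names_columns():
    n = 30
    x = np.linspace(0, 1, n)
    X = np.column_stack([np.ones(n), x, 2 * x])
    with pytest.raises(RankError, match="rank deficient"):
        fit_linear(X, np.random.default_rng(0).normal(size=n),
                   ["Intercept", "a", "b"])


def test_rubin_pooling_hand_example():
    # two imputations, one parameter: estimates 0 and 2, within-variance 1
    # => pooled estimate 1, T = 1 + (1 + 1/2) * var([0, 2]) = 1 + 1.5*2 = 4
    fits = [ImputationFit(["b"], np.array([0.0]), np.array([[1.0]]), -10.0),
            ImputationFit(["b"], np.array([2.0]), np.array([[1.0]]), -12.0)]
    table, avg_ll, ll_sd = pool_rubin(fits)
    assert table.loc[0, "estimate"] == pytest.approx(1.0)
    assert table.loc[0, "se"] == pytest.approx(2.0)       # sqrt(4), exact
    assert avg_ll == pytest.approx(-11.0)
    assert ll_sd == pytest.approx(np.sqrt(2.0))
    with pytest.raises(SpecificationError):
        pool_rubin(fits[:1])
    bad = ImputationFit(["c"], np.array([1.0]), np.array([[1.0]]), -1.0)
    with pytest.raises(SpecificationError, match="mismatched"):
        pool_rubin([fits[0], bad])


def test_fit_stage2_alignment_check():
    frame, effects, names = _subjects(n=10)
    frame["o"] = np.arange(10.0)
    draws = PlausibleDraws(
        draws=np.stack([effects, effects]),
        ids=np.arange(2, 12),          # shifted IDs: misaligned
        names=names, seed=1)
    with pytest.raises(SpecificationError, match="aligned"):
        fit_stage2(frame, draws, Stage2Spec(outcome="o"))
    draws.ids = np.arange(1, 11)
    with pytest.raises(SpecificationError, match="not in subject table"):
        fit_stage2(frame, draws, Stage2Spec(outcome="missing"))
    res = fit_stage2(frame, draws, Stage2Spec(outcome="o"))
    assert res.n_imputations == 2
    assert set(res.table["name"]) == {"Intercept", "Locat_1", "Scale",
                                      "Locat_1*Scale", "Residual_Variance"}
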