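"""Random-intercept location-scale model: likelihood, score, fit, EB."""

import numpy as np
import pandas as pd
import pytest

from mixls import MELS, LongitudinalData, default_mels_config, \
    simulate_stage1, true_param_vector
from mixls.errors import RankError, SpecificationError


def _tiny():
    cfg = default_mels_config(n_subjects=12, occasions=6, seed=21)
    data, _ = simulate_stage1(cfg)
    return cfg, data


def test_score_matches_finite_differences():
    cfg, data = _tiny()
    model = MELS(data, "y", mean=["dow", "sex"], bs_var=["sex"],
                 ws_var=["sex"], ncov=2, quad_points=7)
    p = true_param_vector(model, cfg)
    p[model.param_names().index("tau_q")] = 0.1   # exercise every block
    # frozen-grid objective: analytic score should match FD exactly
    g = model.score(p, adaptive=False)
    h = 1e-6
    fd = np.empty_like(g)
    for k in range(len(p)):
        e = np.zeros(len(p))
        e[k] = h
        fd[k] = (model.loglike(p + e, adaptive=False)
                 - model.loglike(p - e, adaptive=False)) / (2 * h)
    np.testing.assert_allclose(g, fd, rtol=2e-5, atol=2e-5)


def test_adaptive_matches_nonadaptive_at_high_order():
    # unit-scale toy: a dense prior grid is itself accurate here, so it
    # serves as an oracle for the adaptive scheme
    cfg = default_mels_config(
        n_subjects=12, occasions=6, seed=21,
        beta={"Intercept": 0.5, "dow": 0.1, "sex": -0.2},
        alpha={"Intercept": np.log(0.6), "sex": 0.1},
        tau={"Intercept": np.log(0.5), "sex": -0.1},
        tau_l=-0.1, sigma_omega=0.3)
    data, _ = simulate_stage1(cfg)
    model = MELS(data, "y", mean=["dow", "sex"], bs_var=["sex"],
                 ws_var=["sex"], ncov=1)
    p = true_param_vector(model, cfg)
    ll_ad = model.loglike(p, quad_points=9, adaptive=True)
    ll_dense = model.loglike(p, quad_points=81, adaptive=False)
    assert np.isclose(ll_ad, ll_dense, atol=1e-7)


def test_fit_results_structure(mels_fit):
    model, res = mels_fit
    assert res.converged
    assert np.isfinite(res.loglik)
    assert len(res.params) == len(model.param_names())
    assert len(res.submodel_chain) == 3
    # nested submodels cannot lose likelihood (each adds parameters and is
    # warm-started from the previous optimum)
    lls = [s.loglik for s in res.submodel_chain]
    assert lls[0] <= lls[1] + 1e-3 and lls[1] <= lls[2] + 1e-3
    # information criteria on the LL - p convention
    p = len(res.params)
    assert np.isclose(res.aic, res.loglik - p)
    assert np.isclose(res.bic, res.loglik - 0.5 * p * np.log(res.n_subjects))
    # reported table: every section present, positive standard errors
    secs = set(res.table["section"])
    assert any("BETA" in s for s in secs)
    assert any("ALPHA" in s for s in secs)
    assert any("TAU" in s for s in secs)
    assert float(res.estimate("Std Dev")["estimate"]) > 0
    assert (res.se > 0).all()
    assert res.loglik == pytest.approx(
        model.loglike(res.params, quad_points=7), abs=1e-6)


def test_fit_recovers_truth_loosely(mels_sim, mels_fit):
    cfg, _, _ = mels_sim
    model, res = mels_fit
    truth = true_param_vector(model, cfg)
    se = np.sqrt(np.diag(res.asymp_cov))
    # small sample: every estimate within 4 SEs of the generative truth
    assert np.all(np.abs(res.params - truth) < 4.0 * se + 0.05)


def test_empirical_bayes(mels_fit):
    model, res = mels_fit
    eb = res.empirical_bayes()
    n = model.data.n_subjects
    assert eb.means.shape == (n, 2)
    assert eb.covs.shape == (n, 2, 2)
    assert eb.names == ["Locat_1", "Scale"]
    # posterior variances are positive and below the prior variance 1
    assert (eb.covs[:, 0, 0] > 0).all() and (eb.covs[:, 0, 0] < 1.0).all()
    assert abs(eb.means[:, 0].mean()) < 0.3
    f = eb.to_frame()
    assert list(f.columns) == ["id", "eb_Locat_1", "eb_Scale",
                               "pv_Locat_1_Locat_1", "pv_Scale_Locat_1",
                               "pv_Scale_Scale", "n_obs"]


def test_eb_tracks_latent_truth(mels_sim, mels_fit):
    _, _, truth = mels_sim
    _, res = mels_fit
    eb = res.empirical_bayes()
    corr = np.corrcoef(eb.means[:, 0], truth["Locat_1"])[0, 1]
    assert corr > 0.8        # location effects are well identified


def test_specification_errors():
    _, data = _tiny()
    with pytest.raises(SpecificationError):
        MELS(data, "y", ncov=3)
    with pytest.raises(SpecificationError):
        MELS(data, "sex")            # time-invariant outcome
    frame = data.frame.copy()
    frame["one"] = 1.0
    d2 = LongitudinalData(frame, "id")
    with pytest.raises(RankError):
        MELS(d2, "y", mean=["one"])  # constant regressor
    model = MELS(data, "y")
    with pytest.raises(SpecificationError):
        model.loglike(np.zeros(2))   # wrong length
    with pytest.raises(SpecificationError):
        model.loglike(np.array([np.nan, 0, 0, 0]))


def test_no_random_scale_fits_two_submodels():
    _, data = _tiny()
    model = MELS(data, "y", mean=["dow"], ncov=0, random_scale=False,
                 quad_points=7)
    res = model.fit()
    assert len(res.submodel_chain) == 2
    assert "sigma_omega" not in model.param_names()
    eb = res.empirical_bayes()
    assert eb.names == ["Locat_1"]
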