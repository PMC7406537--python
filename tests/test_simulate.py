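"""Synthetic data generator and the recovery harness."""

import numpy as np
import pytest

from mixls import (Covariate, SimulationConfig, Stage2Truth,
                   default_mels_config, default_memls_config,
                   make_stage1_model, recovery_experiment, simulate_stage1,
                   simulate_two_stage, true_param_vector)
from mixls.errors import SpecificationError


def test_determinism():
    cfg = default_mels_config(n_subjects=20, occasions=5, seed=17)
    d1, t1 = simulate_stage1(cfg)
    d2, t2 = simulate_stage1(cfg)
    assert d1.frame.equals(d2.frame) and t1.equals(t2)
    d3, _ = simulate_stage1(cfg, seed=18)
    assert not d1.frame.equals(d3.frame)


def test_variance_structure_of_generated_data():
    # no covariates, no association, no random scale: y_ij = b0 + u_i + e,
    # u ~ N(0, e^a0), e ~ N(0, e^t0) — check both variance components
    cfg = SimulationConfig(
        n_subjects=2000, occasions=8, covariates={},
        beta={"Intercept": 5.0}, alpha={"Intercept": np.log(4.0)},
        tau={"Intercept": np.log(2.25)}, tau_l=0.0, sigma_omega=0.0, seed=2)
    data, truth = simulate_stage1(cfg)
    y = data.column("y")
    dev = y - np.repeat(data.subject_means("y"),
                        data.occasions_per_subject)
    vw = dev @ dev / (data.n_obs - data.n_subjects)
    assert vw == pytest.approx(2.25, rel=0.05)
    vb = np.var(data.subject_means("y"), ddof=1) - vw / 8
    assert vb == pytest.approx(4.0, rel=0.15)
    assert y.mean() == pytest.approx(5.0, abs=0.1)
    # latent truth table carries the standardized effects
    assert truth["Locat_1"].std() == pytest.approx(1.0, rel=0.1)


def test_occasion_counts_and_missingness():
    cfg = default_mels_config(n_subjects=30, occasions=("poisson", 6),
                              seed=3, missing_rate=0.2)
    data, _ = simulate_stage1(cfg)
    assert data.occasions_per_subject.min() >= 1
    assert data.n_obs < 30 * 12
    with pytest.raises(SpecificationError):
        simulate_stage1(default_mels_config(occasions=("uniform", 5)))


def test_overflow_guard():
    cfg = default_mels_config(n_subjects=10, occasions=4,
                              tau={"Intercept": 60.0}, seed=1)
    with pytest.raises(SpecificationError, match="overflow"):
        simulate_stage1(cfg)


def test_unknown_covariate_kind():
    cfg = default_mels_config(
        n_subjects=10, occasions=4,
        covariates={"z": Covariate("beta", "subject", (1.0,))})
    with pytest.raises(SpecificationError):
        simulate_stage1(cfg)


def test_true_param_vector_matches_config():
    cfg = default_mels_config(n_subjects=15, occasions=5, seed=4)
    data, _ = simulate_stage1(cfg)
    model = make_stage1_model(data, cfg, quad_points=7)
    p = dict(zip(model.param_names(), true_param_vector(model, cfg)))
    assert p["beta.Intercept"] == 40.0
    assert p["beta.dow"] == 0.4
    assert p["alpha.sex"] == -0.15
    assert p["tau_l"] == -0.15
    assert p["sigma_omega"] == 0.4

    cfgm = default_memls_config(n_subjects=15, occasions=6, seed=4)
    datam, _ = simulate_stage1(cfgm)
    mm = make_stage1_model(datam, cfgm, quad_points=7)
    pm = dict(zip(mm.param_names(), true_param_vector(mm, cfgm)))
    S = np.linalg.cholesky(cfgm.sigma_upsilon)
    assert pm["chol.11"] == pytest.approx(np.log(S[0, 0]))
    assert pm["chol.21"] == pytest.approx(S[1, 0])
    assert pm["chol.22"] == pytest.approx(np.log(S[1, 1]))
    assert pm["tau_ups.weekend"] == pytest.approx(-0.04)


def test_stage2_outcome_types():
    base = dict(regressors=["sex"],
                coefficients={"Intercept": 0.2, "sex": 0.5, "Locat_1": 0.6,
                              "Scale": 0.4})
    for kind, check in [
        ("continuous", lambda y: np.std(y) > 0),
        ("dichotomous", lambda y: set(np.unique(y)) <= {0.0, 1.0}),
        ("ordinal", lambda y: set(np.unique(y)) <= {0.0, 1.0, 2.0}),
    ]:
        cfg = default_mels_config(
            n_subjects=50, occasions=4, seed=6,
            stage2=Stage2Truth(outcome_type=kind, thresholds=(-0.5, 0.8),
                               **base))
        data, subject, truth = simulate_two_stage(cfg)
        y = np.asarray(subject["s2y"])
        assert len(y) == 50 and check(y)
    cfg = default_mels_config(n_subjects=10, occasions=4, seed=6)
    with pytest.raises(SpecificationError, match="no stage-2"):
        from mixls import simulate_stage2_outcome
        _, truth = simulate_stage1(cfg)
        simulate_stage2_outcome(truth, cfg)


def test_recovery_experiment_smoke():
    cfg = default_mels_config(n_subjects=40, occasions=6, seed=8)
    rep = recovery_experiment(cfg, replicates=2, quad_points=7, seed=2)
    assert list(rep.columns) == ["parameter", "truth", "mean_estimate",
                                 "bias", "mc_se", "rmse", "coverage95"]
    assert rep.attrs["n_replicates"] == 2
    assert rep.attrs["estimates"].shape == (2, len(rep))
    assert np.isfinite(rep["bias"]).all()
    with pytest.raises(SpecificationError):
        recovery_experiment(cfg, replicates=0)
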