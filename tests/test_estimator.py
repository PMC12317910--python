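import numpy as np
import pytest

from aftfuse.data import SurvivalDataset
from aftfuse.estimator import (
    FitOptions,
    build_design,
    fit_integrative,
    fit_naive,
    fit_oracle,
    fit_rct_only,
    predict_hte,
)
from aftfuse.nuisance import LearnerSpec, NuisanceFit, cross_fit
from aftfuse.penalties import PenaltySpec
from aftfuse.simulate import SimulationConfig, generate, true_nuisances


def _true_nuisance_fit(cfg, ds):
    e, mu, mu0, mu1 = true_nuisances(cfg, ds)
    return NuisanceFit(e_hat=np.clip(e, 0.01, 0.99), mu_hat=mu, mu0_hat=mu0, mu1_hat=mu1,
                       fold_id=np.zeros(ds.n, int))


def test_design_zero_block_for_rct_rows(sim_small):
    cfg, dataset, _ = sim_small
    nu = _true_nuisance_fit(cfg, dataset)
    bundle = build_design(dataset, nu)
    p = dataset.p
    rct_rows = dataset.source[bundle.weights.order] == 1
    beta_cols = bundle.design[:, p + 1 :]
    assert np.all(beta_cols[rct_rows] == 0.0)
    assert bundle.design.shape == (dataset.n, 2 * p + 2)


def test_design_arithmetic_half_propensity():
    ds = SurvivalDataset(time=[1.0], event=[1], treatment=[1], source=[1],
                         covariates=np.array([[2.0, -1.0]]))
    nu = NuisanceFit(e_hat=np.array([0.5]), mu_hat=np.array([0.0]),
                     mu0_hat=None, mu1_hat=None, fold_id=np.zeros(1, int))
    bundle = build_design(ds, nu)
    np.testing.assert_allclose(bundle.design[0, :3], [0.5, 1.0, -0.5])


def test_design_rejects_unclipped_propensity(sim_small):
    cfg, dataset, _ = sim_small
    nu = _true_nuisance_fit(cfg, dataset)
    nu.e_hat[0] = 1.0
    with pytest.raises(ValueError, match="strictly inside"):
        build_design(dataset, nu)


def test_full_shrinkage_leaves_only_intercepts(sim_small):
    cfg, dataset, _ = sim_small
    nu = _true_nuisance_fit(cfg, dataset)
    opts = FitOptions(tuning="fixed", penalty=PenaltySpec(lambda1=1e6, lambda2=1e6))
    est = fit_integrative(dataset, opts, nu)
    assert est.support_alpha.size == 0 and est.support_beta.size == 0
    assert not est.confounding_detected


def test_integrative_recovers_truth_with_true_nuisances():
    cfg = SimulationConfig(n=2000, p=10, confounded=True, censor_rate=0.2, seed=17)
    ds, truth = generate(cfg)
    nu = _true_nuisance_fit(cfg, ds)
    est = fit_integrative(ds, FitOptions(seed=17), nu)
    assert set(np.flatnonzero(truth.alpha_star != 0)) <= set(est.support_alpha)
    assert est.confounding_detected
    err = est.alpha[1:] - truth.alpha_star
    assert np.sqrt(np.mean(err**2)) < 0.25


def test_integrative_requires_both_sources(sim_small):
    cfg, dataset, _ = sim_small
    rct = dataset.subset(dataset.source == 1)
    with pytest.raises(ValueError, match="both S=1"):
        fit_integrative(rct, FitOptions())


def test_rct_only_and_naive_variants(sim_small):
    cfg, dataset, truth = sim_small
    est_rct = fit_rct_only(dataset, FitOptions(seed=1))
    assert est_rct.beta is None and not est_rct.confounding_detected
    est_nai = fit_naive(dataset, FitOptions(seed=1))
    assert est_nai.beta is None
    rwd_only = dataset.subset(dataset.source == 0)
    with pytest.raises(ValueError, match="no RCT"):
        fit_rct_only(rwd_only, FitOptions())


def test_rct_only_equals_naive_on_pure_trial_data(sim_small):
    """With S identically 1 the pooled no-confounding fit and the trial-only fit coincide."""
    cfg, dataset, _ = sim_small
    rct = dataset.subset(dataset.source == 1)
    nu = cross_fit(rct, LearnerSpec(), K=2, seed=3)
    a = fit_rct_only(rct, FitOptions(seed=3), nu)
    b = fit_naive(rct, FitOptions(seed=3), nu)
    np.testing.assert_allclose(a.alpha, b.alpha, atol=1e-10)


def test_oracle_restricted_wls(sim_small):
    cfg, dataset, truth = sim_small
    nu = _true_nuisance_fit(cfg, dataset)
    sa = np.flatnonzero(truth.alpha_star != 0)
    sb = np.flatnonzero(truth.beta_star != 0)
    est = fit_oracle(dataset, sa, sb, FitOptions(), nu)
    assert set(est.support_alpha) <= set(sa)
    assert np.all(est.alpha[1 + np.setdiff1d(np.arange(dataset.p), sa)] == 0)
    # empty support -> intercept-only fit
    est0 = fit_oracle(dataset, [], [], FitOptions(), nu)
    assert est0.support_alpha.size == 0 and est0.support_beta.size == 0
    # full support with no censoring equals plain weighted OLS
    cfg_nc = SimulationConfig(n=300, p=8, censor_rate=0.0, seed=23)
    ds_nc, _ = generate(cfg_nc)
    nu_nc = _true_nuisance_fit(cfg_nc, ds_nc)
    full = np.arange(ds_nc.p)
    est_full = fit_oracle(ds_nc, full, full, FitOptions(), nu_nc)
    bundle = build_design(ds_nc, nu_nc)
    coef_ls, *_ = np.linalg.lstsq(
        bundle.design * np.sqrt(bundle.weights.weights)[:, None],
        bundle.pseudo_response * np.sqrt(bundle.weights.weights), rcond=None)
    np.testing.assert_allclose(est_full.theta, coef_ls, atol=1e-8)


def test_predict_hte():
    from aftfuse.estimator import ThetaEstimate

    est = ThetaEstimate(alpha=np.array([0.5, 1.0, -2.0]), beta=None,
                        support_alpha=np.array([0, 1]), support_beta=np.array([], dtype=int),
                        confounding_detected=False, lambda1=None, lambda2=None,
                        tuning_rule="fixed", penalty_family="mcp")
    np.testing.assert_allclose(predict_hte(est, np.zeros((1, 2))), [0.5])
    np.testing.assert_allclose(predict_hte(est, np.array([[1.0, 1.0]])), [-0.5])
    with pytest.raises(ValueError, match="columns"):
        predict_hte(est, np.zeros((1, 3)))
    est_int = ThetaEstimate(alpha=np.array([0.7]), beta=None,
                            support_alpha=np.array([], dtype=int),
                            support_beta=np.array([], dtype=int),
                            confounding_detected=False, lambda1=None, lambda2=None,
                            tuning_rule="fixed", penalty_family="mcp")
    np.testing.assert_allclose(predict_hte(est_int, np.zeros((3, 0))), [0.7, 0.7, 0.7])
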