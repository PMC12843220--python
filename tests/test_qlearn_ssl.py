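"""SSL projection: degeneracy to the supervised solution, brute-force
agreement, variance properties, and robustness to a useless base learner."""

import numpy as np
import pytest

from ssdtr import (SimConfig, backward_fit_ssl, backward_fit_sup,
                   build_designs, fit_stage1_ssl, fit_stage2_ssl,
                   impute_for_qlearning, make_learner, pseudo_outcome_ssl,
                   relative_efficiency, simulate, variance_ssl)
from ssdtr.impute import ImputationSet


def _oracle_imps(designs):
    """Imputations equal to the observed outcomes/products (labelled rows)."""
    mu = {("y", 2): designs.Y[2], ("y", 3): designs.Y[3],
          ("yy", 2, 2): designs.Y[2] ** 2,
          ("yy", 2, 3): designs.Y[2] * designs.Y[3]}
    n = int(designs.labeled.sum())
    return ImputationSet(mu=mu, eta={}, folds=np.zeros(n, dtype=int), K=2,
                         preds={}, refit_design={})


def test_degeneracy_identity(cont_small):
    """Projection onto the labelled set with oracle imputations reproduces
    the supervised estimator exactly, at both stages."""
    _, traj = cont_small
    lab_traj = traj.subset(np.flatnonzero(traj.labeled))
    d = build_designs(lab_traj)
    imps = _oracle_imps(d)
    ssl = backward_fit_ssl(d, imps)
    sup = backward_fit_sup(d)
    for t in (1, 2):
        np.testing.assert_allclose(ssl.theta[t], sup.theta[t], atol=1e-9)


def test_stage2_matches_brute_force_stack(cont_designs, cont_imps):
    """Explicit assembly of the stacked (1+p)-dimensional moment system."""
    d, imps = cont_designs, cont_imps
    th2 = fit_stage2_ssl(d, imps)
    mu2 = imps.mu[("y", 2)]
    mu3 = imps.mu[("y", 3)]
    mu22 = imps.mu[("yy", 2, 2)]
    mu23 = imps.mu[("yy", 2, 3)]
    X2 = d.X[2]
    n = d.n
    M = np.zeros((9, 9))
    M[0, 0] = mu22.mean()
    M[0, 1:] = (X2 * mu2[:, None]).mean(axis=0)
    M[1:, 0] = M[0, 1:]
    M[1:, 1:] = X2.T @ X2 / n
    v = np.concatenate([[mu23.mean()], X2.T @ mu3 / n])
    np.testing.assert_allclose(th2, np.linalg.solve(M, v), atol=1e-8)


def test_pseudo_outcome_ssl_reductions(cont_designs, cont_imps):
    d, imps = cont_designs, cont_imps
    th = np.zeros(9)
    np.testing.assert_allclose(pseudo_outcome_ssl(d, imps, th),
                               imps.mu[("y", 2)])
    # hand row: b21=0.5, b22 = e_1, g2 chosen negative everywhere
    th = np.zeros(9)
    th[0] = 0.5
    th[1] = 2.0
    th[6] = -50.0
    np.testing.assert_allclose(pseudo_outcome_ssl(d, imps, th),
                               1.5 * imps.mu[("y", 2)] + 2.0, atol=1e-8)


def test_stage1_ssl_exact_linear(cont_designs):
    d = cont_designs
    beta = np.array([1.0, -2.0, 0.5, 0.25])
    ytilde = d.X[1] @ beta
    np.testing.assert_allclose(fit_stage1_ssl(d, ytilde), beta, atol=1e-9)


def test_variance_psd_and_influence_centred(cont_designs, ssl_fit):
    for t in (1, 2):
        w = np.linalg.eigvalsh(ssl_fit.cov[t])
        assert w.min() > -1e-12
        # influence-function sample mean is O(n^{-1/2})
        n = ssl_fit.influence[t].shape[0]
        scale = np.sqrt(np.diag(ssl_fit.cov[t])) * n
        assert np.abs(ssl_fit.influence[t].mean(axis=0) / scale).max() < 0.5


def test_relative_efficiency_identities():
    e = np.array([0.4, 0.2])
    np.testing.assert_allclose(relative_efficiency(e, e), [1.0, 1.0])
    np.testing.assert_allclose(relative_efficiency(np.array([0.3]),
                                                   np.array([0.2])), [1.5])
    with pytest.raises(ZeroDivisionError):
        relative_efficiency(e, np.zeros(2))


def test_constant_learner_still_consistent():
    """A useless base learner (constant prediction) leaves the SSL estimator
    consistent: the refitting step repairs the imputation bias."""
    cfg = SimConfig(n_labeled=2000, N_unlabeled=40_000, seed=77)
    d = build_designs(simulate(cfg))

    class Const:
        def fit(self, X, y):
            return self

        def predict(self, X):
            return np.zeros((X.shape[0], 4))

    imps = impute_for_qlearning(d, Const, K=5, seed=1)
    ssl = backward_fit_ssl(d, imps)
    truth2 = np.array([0.1, 3.0, 0.0, 0.1, -0.5, -0.5, 1.0, 0.25, 0.5])
    assert np.abs(ssl.theta[2] - truth2).max() < 0.15
    # stage-1 solution close to the supervised mega-sample target
    assert ssl.gamma(1) == pytest.approx([1.46, -2.71], abs=0.25)


def test_T2_backward_equals_explicit_pipeline(cont_designs, cont_imps):
    fit = backward_fit_ssl(cont_designs, cont_imps)
    th2 = fit_stage2_ssl(cont_designs, cont_imps)
    np.testing.assert_allclose(fit.theta[2], th2, atol=1e-9)
    th1 = fit_stage1_ssl(cont_designs,
                         pseudo_outcome_ssl(cont_designs, cont_imps, th2))
    np.testing.assert_allclose(fit.theta[1], th1, atol=1e-9)


def test_generalT_ssl_runs_and_t3_orthogonality():
    cfg = SimConfig(setting="generalT", T=3, n_labeled=300, N_unlabeled=2000,
                    seed=5)
    d = build_designs(simulate(cfg))
    lrn = make_learner("spline")
    imps = impute_for_qlearning(d, lrn, K=5, seed=5)
    fit = backward_fit_ssl(d, imps)
    # stage-wise imputed estimating equations vanish at the solution
    from ssdtr.qlearn_ssl import _fit_stage_ssl, _projection_rows
    from ssdtr.qlearn_sup import _pseudo_coefs
    rows = np.ones(d.n, dtype=bool)
    for t in (3, 2, 1):
        c, g = _pseudo_coefs(fit, d, t)
        q = d.n_y(t)
        G = d.X[t]
        resid_atoms = g.copy()
        for s in range(2, d.T + 2):
            if c[s]:
                resid_atoms = resid_atoms + c[s] * imps.mu[("y", s)]
        bY, beta, gamma = fit.split(t)
        pred_obs = G @ np.concatenate([beta, gamma])
        # observable block of the estimating equation
        lhs = G.T @ (resid_atoms - pred_obs)
        for j, s in enumerate(range(2, t + 1)):
            lhs -= bY[j] * (G * imps.mu[("y", s)][:, None]).sum(axis=0)
        assert np.abs(lhs).max() / d.n < 1e-7
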