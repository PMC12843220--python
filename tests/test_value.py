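"""Value estimators: weight algebra, exact identities, degeneracies, and
smoothing limits."""

import numpy as np
import pytest

from ssdtr import (SimConfig, build_designs, backward_fit_sup, cv_value,
                   fit_all_propensities, fit_value_imputations, ipw_weights,
                   make_learner, simulate, value_dr_T, value_q_plugin,
                   value_ssl_dr, value_sup_dr)
from ssdtr.impute import ImputationSet
from ssdtr.propensity import PropensityFit
from ssdtr.value import _q_pieces


def test_ipw_hand_cases(cont_designs, sup_fit):
    """Four hand-checkable weight configurations."""
    d = cont_designs
    pi = PropensityFit(xi={1: np.zeros(2), 2: np.zeros(6)})  # pi = 0.5
    w = ipw_weights(d, sup_fit, pi)
    d1 = (d.H1[1] @ sup_fit.gamma(1) > 0).astype(float)
    d2 = (d.H1[2] @ sup_fit.gamma(2) > 0).astype(float)
    A1, A2 = d.A[1], d.A[2]
    # d=A=1 with pi=0.5 -> weight 2; mismatch -> 0
    expect1 = np.where(d1 == A1, 2.0, 0.0)
    np.testing.assert_allclose(w[1], expect1)
    lab = d.labeled   # w2 needs Y2 in the stage-2 propensity design
    np.testing.assert_allclose(
        w[2][lab], (expect1 * np.where(d2 == A2, 2.0, 0.0))[lab])
    assert np.isnan(w[2][~lab]).all()


def test_eq5_equals_rewriting_per_subject(cont_designs, sup_fit, pi_fit):
    """The augmented estimator and its stage-2-decomposed rewriting agree on
    every labelled subject at machine precision."""
    d = cont_designs
    w = ipw_weights(d, sup_fit, pi_fit)
    _, q1 = _q_pieces(d, sup_fit, 1)
    bY2, q2m = _q_pieces(d, sup_fit, 2)
    b21 = float(bY2.sum())
    Y2, Y3 = d.Y[2], d.Y[3]
    q2 = b21 * Y2 + q2m
    lhs = q1 + w[1] * (Y2 - q1 + q2) + w[2] * (Y3 - q2)
    rhs = (q1 + w[1] * ((1 + b21) * Y2 - q1 + q2m)
           + w[2] * (Y3 - b21 * Y2 - q2m))
    lab = d.labeled
    np.testing.assert_allclose(lhs[lab], rhs[lab], atol=1e-10)


def test_plugin_reductions(cont_designs, sup_fit):
    d = cont_designs
    import copy
    qf = copy.deepcopy(sup_fit)
    qf.theta[1] = qf.theta[1].copy()
    qf.theta[1][2:] = 0.0                       # gamma1 = 0
    v = value_q_plugin(d, qf)
    assert v.estimate == pytest.approx(float(np.mean(d.H0[1] @ qf.theta[1][:2])))
    # explicit row-wise max agreement
    v2 = value_q_plugin(d, sup_fit)
    beta1, gamma1 = sup_fit.theta[1][:2], sup_fit.gamma(1)
    rowmax = np.maximum(d.H0[1] @ beta1, d.H0[1] @ beta1 + d.H1[1] @ gamma1)
    assert v2.estimate == pytest.approx(float(rowmax.mean()))


def test_never_matching_policy_reduces_to_plugin(cont_designs, sup_fit, pi_fit):
    """If the weights are identically zero the DR estimate is the plug-in
    (evaluated over labelled subjects)."""
    from ssdtr.qlearn_sup import QFit
    # all-treated sample under a never-treat rule: every weight is zero
    traj = simulate(SimConfig(n_labeled=80, N_unlabeled=0, seed=9))
    traj.A[1][:] = 1.0
    traj.A[2][:] = 1.0
    dd = build_designs(traj)
    qf2 = QFit(theta={1: np.array([1.0, 0.5, -100.0, 0.0]),
                      2: np.array([0.2, 1.0, 0.1, 0.0, 0.0, -0.3,
                                   -100.0, 0.0, 0.0])},
               n_y={1: 0, 2: 1}, p0={1: 2, 2: 5}, p1={1: 2, 2: 3})
    pi = PropensityFit(xi={1: np.zeros(2), 2: np.zeros(6)})
    v_dr = value_sup_dr(dd, qf2, pi)
    v_plug = value_q_plugin(dd, qf2, projection="labeled")
    assert v_dr.estimate == pytest.approx(v_plug.estimate, abs=1e-10)


def test_ssl_oracle_imputations_equal_sup_dr(cont_small, pi_fit):
    """Projection onto the labelled set with oracle value imputations gives
    exactly the supervised DR estimate (algebraic identity)."""
    _, traj = cont_small
    lab_traj = traj.subset(np.flatnonzero(traj.labeled))
    d = build_designs(lab_traj)
    qf = backward_fit_sup(d)
    pf = fit_all_propensities(d)
    w = ipw_weights(d, qf, pf)
    mu = {"y2v": d.Y[2], "w2": w[2], "y2w2": d.Y[2] * w[2],
          "y3w2": d.Y[3] * w[2]}
    imps = ImputationSet(mu=mu, eta={k: 0.0 for k in mu},
                         folds=np.zeros(d.n, dtype=int), K=2,
                         preds={k: np.tile(v, (2, 1)) for k, v in mu.items()},
                         refit_design={k: None for k in mu})
    v_ssl = value_ssl_dr(d, qf, pf, imps)
    v_sup = value_sup_dr(d, qf, pf)
    assert v_ssl.estimate == pytest.approx(v_sup.estimate, abs=1e-10)


def test_refit_orthogonality_value(cont_designs, ssl_fit, pi_fit, cont_folds):
    """Post-refit: sum w1 (Y2 - mu) = 0 and sum Q2-minus (w2 - mu) = 0."""
    d = cont_designs
    lrn = make_learner("forest", seed=42, n_trees=50)
    impv = fit_value_imputations(d, ssl_fit, pi_fit, lrn, K=5, seed=42,
                                 folds=cont_folds)
    lab_idx = np.flatnonzero(d.labeled)
    w = ipw_weights(d, ssl_fit, pi_fit)
    _, q2m = _q_pieces(d, ssl_fit, 2)
    oof = {name: impv.crossfit_mu(name, lab_idx) for name in impv.mu}
    assert abs(np.sum(w[1][lab_idx] * (d.Y[2][lab_idx] - oof["y2v"]))) < 1e-7
    assert abs(np.sum(q2m[lab_idx] * (w[2][lab_idx] - oof["w2"]))) < 1e-7
    assert abs(np.mean((d.Y[3] * w[2])[lab_idx] - oof["y3w2"])) < 1e-9


def test_smoothed_weights_limit(cont_designs, sup_fit, pi_fit):
    d = cont_designs
    w_raw = ipw_weights(d, sup_fit, pi_fit)
    w_h = ipw_weights(d, sup_fit, pi_fit, h=1e-6)
    lab = d.labeled
    off_boundary = np.abs(d.H1[2][lab] @ sup_fit.gamma(2)) > 1e-3
    np.testing.assert_allclose(w_h[2][lab][off_boundary],
                               w_raw[2][lab][off_boundary], atol=1e-6)


def test_sup_and_ssl_dr_near_truth_large_n():
    """Double robustness sanity at moderate scale: correct models, n=4000."""
    cfg = SimConfig(n_labeled=4000, N_unlabeled=20_000, seed=55)
    d = build_designs(simulate(cfg))
    from ssdtr import variance_sup, backward_fit_ssl, impute_for_qlearning, variance_ssl
    qf = variance_sup(d, backward_fit_sup(d))
    pf = fit_all_propensities(d)
    v = value_sup_dr(d, qf, pf)
    assert v.estimate == pytest.approx(6.40, abs=5 * v.se)
    assert 0 < v.se < 0.15


def test_cv_value_single_fold_is_in_sample(cont_small):
    _, traj = cont_small
    lab_traj = traj.subset(np.flatnonzero(traj.labeled))

    def fit_fn(tr):
        d = build_designs(tr)
        return backward_fit_sup(d), fit_all_propensities(d)

    def value_fn(fitted, tr):
        qf, pf = fitted
        d = build_designs(tr)
        pf2 = fit_all_propensities(d)
        return value_sup_dr(d, qf, pf2)

    v1 = cv_value(lab_traj, fit_fn, value_fn, n_folds=1)
    qf, pf = fit_fn(lab_traj)
    assert v1.estimate == pytest.approx(
        value_sup_dr(build_designs(lab_traj), qf, pf).estimate)
    v2 = cv_value(lab_traj, fit_fn, value_fn, n_folds=2, seed=3)
    assert np.isfinite(v2.estimate) and v2.variant.endswith("_CV")


def test_value_dr_T_reduces_at_T2(cont_designs, sup_fit, pi_fit):
    v2 = value_sup_dr(cont_designs, sup_fit, pi_fit)
    vT = value_dr_T(cont_designs, sup_fit, pi_fit, variant="sup")
    assert vT.estimate == pytest.approx(v2.estimate, abs=1e-10)


def test_value_dr_T3_runs():
    cfg = SimConfig(setting="generalT", T=3, n_labeled=400, N_unlabeled=3000,
                    seed=6)
    d = build_designs(simulate(cfg))
    qf = backward_fit_sup(d)
    pf = fit_all_propensities(d)
    vs = value_dr_T(d, qf, pf, variant="sup")
    vl = value_dr_T(d, qf, pf, learner=make_learner("spline"), K=5, seed=6,
                    variant="ssl")
    assert np.isfinite(vs.estimate) and np.isfinite(vl.estimate)
    assert abs(vs.estimate - vl.estimate) < 1.5
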