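"""Cross-fitting honesty, refitting orthogonality, and learner quality."""

import numpy as np
import pytest

from ssdtr import (CrossFitImputer, SimConfig, SplineBasisRegressor,
                   assign_folds, build_designs, make_learner, simulate)
from ssdtr.impute import qlearning_refit_designs, qlearning_targets


def test_fold_assignment_balanced_and_reproducible():
    f1 = assign_folds(103, 5, 7)
    f2 = assign_folds(103, 5, 7)
    np.testing.assert_array_equal(f1, f2)
    counts = np.bincount(f1)
    assert counts.max() - counts.min() <= 1
    with pytest.raises(ValueError):
        assign_folds(3, 5, 0)
    with pytest.raises(ValueError):
        assign_folds(10, 1, 0)


def test_refit_orthogonality(cont_designs, cont_imps):
    """The four post-refit moment identities hold at machine precision:
    sum_k sum_{i in fold k} D_i (target_i - mu_i) = 0."""
    d = cont_designs
    lab_idx = np.flatnonzero(d.labeled)
    imps = cont_imps
    folds = imps.folds

    def oof_mu(name):
        return imps.preds[name][folds, lab_idx] + imps._correction(name)[lab_idx]

    n = lab_idx.size
    Xarrow = d.Xarrow[lab_idx]
    r2 = d.Y[2][lab_idx] - oof_mu(("y", 2))
    assert np.abs(Xarrow.T @ r2).max() / n < 1e-8
    r3 = d.Y[3][lab_idx] - oof_mu(("y", 3))
    assert np.abs(d.X[2][lab_idx].T @ r3).max() / n < 1e-8
    assert abs(np.mean(d.Y[2][lab_idx] ** 2 - oof_mu(("yy", 2, 2)))) < 1e-8
    assert abs(np.mean((d.Y[2] * d.Y[3])[lab_idx] - oof_mu(("yy", 2, 3)))) < 1e-8


def test_refit_design_t2_matches_canonical(cont_designs):
    designs = qlearning_refit_designs(cont_designs)
    # Y2 over (1, X1, X2); Y3 over X2; products scalar
    assert designs[("y", 2)].shape[1] == 1 + 4 + 8
    assert designs[("y", 3)].shape[1] == 8
    assert designs[("yy", 2, 2)] is None and designs[("yy", 2, 3)] is None


def test_zero_base_learner_reduces_to_ols(cont_designs):
    """With m-hat = 0 the refit coefficient equals the OLS coefficient of the
    raw outcome on the refit design."""
    d = cont_designs
    lab = d.labeled

    class Zero:
        def fit(self, X, y):
            self._m = np.atleast_2d(y).shape[-1] if y.ndim > 1 else 1
            return self

        def predict(self, X):
            return np.zeros((X.shape[0], self._m))

    imp = CrossFitImputer(K=5, learner=Zero, seed=0, standardize=False)
    out = imp.fit(d.U, lab, {("y", 3): d.Y[3][lab]},
                  {("y", 3): d.X[2]})
    X2 = d.X[2][lab]
    ols_coef = np.linalg.lstsq(X2, d.Y[3][lab], rcond=None)[0]
    np.testing.assert_allclose(out.mu[("y", 3)][lab], X2 @ ols_coef,
                               atol=1e-8)
    np.testing.assert_allclose(out.eta[("y", 3)], ols_coef, atol=1e-8)


def test_mu_formula_hand_check():
    """mu = K^{-1} sum_k m^{(-k)} + eta on a tiny n=10, K=2 example."""
    rng = np.random.default_rng(0)
    U = rng.normal(size=(12, 2))
    lab = np.ones(12, dtype=bool)
    lab[10:] = False
    y = rng.normal(size=10)

    class Mean:
        def fit(self, X, yy):
            self._v = np.mean(yy, axis=0)
            return self

        def predict(self, X):
            return np.tile(self._v, (X.shape[0], 1))

    folds = np.array([0, 1] * 5)
    imp = CrossFitImputer(K=2, learner=Mean, seed=0, folds=folds)
    out = imp.fit(U, lab, {"t": y}, {"t": None})
    m0, m1 = y[folds != 0].mean(), y[folds != 1].mean()
    oof = np.where(folds == 0, m0, m1)
    eta = np.mean(y - oof)
    np.testing.assert_allclose(out.mu["t"][:10], (m0 + m1) / 2 + eta,
                               atol=1e-10)
    assert out.eta["t"] == pytest.approx(eta)


def test_cross_fitting_honesty():
    """Fold-k predictions never depend on fold-k outcomes: perturbing fold-0
    outcomes leaves the fold-0 out-of-fold predictions unchanged."""
    rng = np.random.default_rng(1)
    U = rng.normal(size=(60, 3))
    lab = np.ones(60, dtype=bool)
    y = U[:, 0] + rng.normal(size=60) * 0.1
    folds = assign_folds(60, 3, 0)
    lrn = make_learner("forest", seed=0, n_trees=20)
    out1 = CrossFitImputer(K=3, learner=lrn, seed=0, folds=folds).fit(
        U, lab, {"t": y.copy()}, {"t": None})
    y2 = y.copy()
    y2[folds == 0] += 100.0
    out2 = CrossFitImputer(K=3, learner=lrn, seed=0, folds=folds).fit(
        U, lab, {"t": y2}, {"t": None})
    np.testing.assert_allclose(out1.preds["t"][0], out2.preds["t"][0])


def test_spline_recovers_smooth_function():
    """Noise-free smooth target: out-of-fold R^2 > 0.99 at n = 2000."""
    rng = np.random.default_rng(2)
    U = rng.uniform(-2, 2, size=(2000, 2))
    y = np.sin(U[:, 0]) + 0.5 * U[:, 1]
    lab = np.ones(2000, dtype=bool)
    lrn = make_learner("spline")
    out = CrossFitImputer(K=5, learner=lrn, seed=0).fit(
        U, lab, {"t": y}, {"t": None})
    oof = out.preds["t"][out.folds, np.arange(2000)]
    r2 = 1 - np.mean((y - oof) ** 2) / np.var(y)
    assert r2 > 0.99


def test_perfect_surrogate_oracle_limit(cont_small):
    """When a surrogate equals the outcome exactly, a linear-in-basis learner
    drives mu_2 to Y2 on labelled subjects."""
    _, traj = cont_small
    traj2 = traj.subset(np.arange(traj.n_subjects))
    traj2.W = dict(traj.W)
    traj2.W[1] = np.where(np.isnan(traj.Y[2]), 0.0, traj.Y[2])[:, None]
    # unlabeled W must still reflect Y2: regenerate without masking
    full = simulate(SimConfig(n_labeled=traj.n_subjects, N_unlabeled=0,
                              seed=42))
    traj2.W[1] = full.Y[2][:traj.n_subjects, None]
    d = build_designs(traj2)
    out = CrossFitImputer(K=5, learner=make_learner("spline"), seed=0).fit(
        d.U, d.labeled, {("y", 2): d.Y[2][d.labeled]}, {("y", 2): None})
    lab = d.labeled
    corr = np.corrcoef(out.mu[("y", 2)][lab], d.Y[2][lab])[0, 1]
    assert corr > 0.999


def test_constant_target_handled():
    rng = np.random.default_rng(3)
    U = rng.normal(size=(40, 2))
    lab = np.ones(40, dtype=bool)
    out = CrossFitImputer(K=2, learner=make_learner("spline"), seed=0).fit(
        U, lab, {"c": np.full(40, 2.5)}, {"c": None})
    np.testing.assert_allclose(out.mu["c"], 2.5, atol=1e-8)
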