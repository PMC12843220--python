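"""Semi-supervised Q-learning: projection of imputed moments, and its
influence-function sandwich variance.

The supervised normal equations are projected onto the full sample
(labelled plus unlabelled) after replacing every outcome ``Y_s`` by its
refitted imputation ``mu_s(U)`` and every product ``Y_r Y_s`` by
``mu_rs(U)``.  Because each stage's equations are linear in theta_t, the
projection is a single linear solve per stage; the backward recursion then
mirrors the supervised one with the imputed pseudo-outcome.

The variance estimator is the sample-split sandwich: the influence function
of the stage-2 (and, recursively, stage-1) estimator depends on the data
only through imputation residuals such as ``Y2 Y3 - mu_23`` evaluated with
the out-of-fold learners, so imputation precision — driven by how predictive
the surrogates are — translates directly into smaller standard errors.
"""

from __future__ import annotations

import numpy as np

from .features import DesignBundle
from .impute import (CrossFitImputer, ImputationSet, qlearning_refit_designs,
                     qlearning_targets)
from .qlearn_sup import QFit, _pseudo_coefs, _sigma_hat, _stage1_plugins

__all__ = ["impute_for_qlearning", "fit_stage2_ssl", "pseudo_outcome_ssl",
           "fit_stage1_ssl", "backward_fit_ssl", "variance_ssl",
           "relative_efficiency"]


def impute_for_qlearning(designs: DesignBundle, learner, K: int = 5,
                         seed: int = 0, folds=None) -> ImputationSet:
    """Cross-fit and refit all O(T^2) Q-learning imputation targets."""
    imputer = CrossFitImputer(K=K, learner=learner, seed=seed, folds=folds)
    return imputer.fit(designs.U, designs.labeled,
                       qlearning_targets(designs),
                       qlearning_refit_designs(designs))


def _mu_pair(imps, r, s):
    key = ("yy", r, s) if r <= s else ("yy", s, r)
    return imps.mu[key]


def _projection_rows(designs, projection):
    if projection == "all":
        return np.ones(designs.n, dtype=bool)
    if projection == "unlabeled":
        return ~designs.labeled
    raise ValueError("projection must be 'all' or 'unlabeled'")


def _fit_stage_ssl(designs, imps, fit, t, rows):
    """Solve the imputed stage-t normal equations (one linear system)."""
    c, g = _pseudo_coefs(fit, designs, t)
    q = designs.n_y(t)
    G = designs.X[t][rows]
    m = G.shape[0]
    ys = list(range(2, t + 1))            # outcome columns of Xcheck_t
    resp_lin = g[rows].copy()             # sum_s c_s mu_s + g
    for s in range(2, designs.T + 2):
        if c[s]:
            resp_lin += c[s] * imps.mu[("y", s)][rows]
    dim = q + G.shape[1]
    M = np.empty((dim, dim))
    v = np.empty(dim)
    for i, r in enumerate(ys):
        mu_r = imps.mu[("y", r)][rows]
        for j, rp in enumerate(ys):
            M[i, j] = np.mean(_mu_pair(imps, r, rp)[rows])
        M[i, q:] = (G * mu_r[:, None]).mean(axis=0)
        M[q:, i] = M[i, q:]
        v[i] = np.mean(mu_r * g[rows])
        for s in range(2, designs.T + 2):
            if c[s]:
                v[i] += c[s] * np.mean(_mu_pair(imps, r, s)[rows])
    M[q:, q:] = G.T @ G / m
    v[q:] = G.T @ resp_lin / m
    return np.linalg.solve(M, v)


def fit_stage2_ssl(designs: DesignBundle, imps: ImputationSet,
                   projection: str = "all") -> np.ndarray:
    """theta_2 from the stacked imputed-moment system (T = 2)."""
    rows = _projection_rows(designs, projection)
    dummy = QFit(theta={}, n_y={t: designs.n_y(t) for t in (1, 2)},
                 p0={t: designs.H0[t].shape[1] for t in (1, 2)},
                 p1={t: designs.H1[t].shape[1] for t in (1, 2)}, tag="SSL")
    return _fit_stage_ssl(designs, imps, dummy, 2, rows)


def pseudo_outcome_ssl(designs: DesignBundle, imps: ImputationSet,
                       theta2: np.ndarray) -> np.ndarray:
    """Imputed pseudo-outcome: Q2 at the argmax action with mu_2 for Y2."""
    q = designs.n_y(2)
    p0 = designs.H0[2].shape[1]
    b21 = theta2[:q].sum() if q else 0.0
    return (imps.mu[("y", 2)] * (1.0 + b21) + designs.H0[2] @ theta2[q:q + p0]
            + np.maximum(designs.H1[2] @ theta2[q + p0:], 0.0))


def fit_stage1_ssl(designs: DesignBundle, ytilde: np.ndarray,
                   projection: str = "all") -> np.ndarray:
    rows = _projection_rows(designs, projection)
    X1 = designs.X[1][rows]
    return np.linalg.solve(X1.T @ X1, X1.T @ ytilde[rows])


def backward_fit_ssl(designs: DesignBundle, imps: ImputationSet,
                     T: int | None = None, projection: str = "all") -> QFit:
    """SSL backward recursion for stages T..1 (reduces to the explicit
    two-stage pipeline at T = 2)."""
    T = T or designs.T
    rows = _projection_rows(designs, projection)
    fit = QFit(theta={}, n_y={t: designs.n_y(t) for t in range(1, T + 1)},
               p0={t: designs.H0[t].shape[1] for t in range(1, T + 1)},
               p1={t: designs.H1[t].shape[1] for t in range(1, T + 1)},
               tag="SSL", folds=imps.folds)
    for t in range(T, 0, -1):
        fit.theta[t] = _fit_stage_ssl(designs, imps, fit, t, rows)
    return fit


# ---------------------------------------------------------------------------
# sample-split sandwich variance (two-stage)
# ---------------------------------------------------------------------------

def variance_ssl(designs: DesignBundle, fit: QFit, imps: ImputationSet,
                 sigma_design: str = "xcheck") -> QFit:
    """Influence-function covariance of the two-stage SSL estimator.

    psi_2 combines the imputation residuals of (Y2 Y3, Y2^2, Y2, Y3);
    psi_1 adds the plug-in propagation of theta_2-hat through the
    pseudo-outcome.  Residuals on fold-k subjects use the out-of-fold
    learner (sample-split A-hat); ``sigma_design`` selects whether the
    bread uses Xcheck_t (default, matching Sigma_t = E[Xcheck Xcheck'])
    or the outcome-free X_t.
    """
    if designs.T != 2:
        raise NotImplementedError("SSL sandwich variance implemented for T = 2")
    lab = designs.labeled
    lab_idx = np.flatnonzero(lab)
    n = lab_idx.size
    b21 = fit.theta[2][0]
    _, beta22, gamma2 = fit.split(2)

    mu2 = imps.crossfit_mu(("y", 2), lab_idx)
    mu3 = imps.crossfit_mu(("y", 3), lab_idx)
    mu22 = imps.crossfit_mu(("yy", 2, 2), lab_idx)
    mu23 = imps.crossfit_mu(("yy", 2, 3), lab_idx)

    Y2, Y3 = designs.Y[2][lab], designs.Y[3][lab]
    X2 = designs.X[2][lab]
    q2_minus = designs.H0[2][lab] @ beta22 + designs.A[2][lab] * (
        designs.H1[2][lab] @ gamma2)
    r0 = ((Y2 * Y3 - mu23) - b21 * (Y2 ** 2 - mu22)
          - q2_minus * (Y2 - mu2))
    rX = X2 * ((Y3 - mu3) - b21 * (Y2 - mu2))[:, None]
    psi2 = np.column_stack([r0, rX])
    S2 = _sigma_hat(designs, 2, use_xcheck=(sigma_design == "xcheck"))
    phi2 = np.linalg.solve(S2, psi2.T).T

    C_beta, C_gamma, _ = _stage1_plugins(designs, fit)
    p_beta = 1 + designs.H0[2].shape[1]
    phi_beta = phi2[:, :p_beta]
    phi_gamma = phi2[:, p_beta:]
    X1 = designs.X[1][lab]
    psi1 = (X1 * ((1.0 + b21) * (Y2 - mu2))[:, None]
            + phi_beta @ C_beta.T + phi_gamma @ C_gamma.T)
    S1 = _sigma_hat(designs, 1)
    phi1 = np.linalg.solve(S1, psi1.T).T
    fit.cov = {2: phi2.T @ phi2 / n ** 2, 1: phi1.T @ phi1 / n ** 2}
    fit.influence = {1: phi1, 2: phi2}
    return fit


def relative_efficiency(ese_sup: np.ndarray, ese_ssl: np.ndarray) -> np.ndarray:
    """RE = supervised ESE / SSL ESE, elementwise."""
    ese_sup = np.asarray(ese_sup, dtype=float)
    ese_ssl = np.asarray(ese_ssl, dtype=float)
    if np.any(ese_ssl == 0):
        raise ZeroDivisionError("zero SSL empirical standard error")
    return ese_sup / ese_ssl
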