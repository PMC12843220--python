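"""Doubly robust off-policy value estimation, supervised and semi-supervised.

For the two-stage regime d_t = I(H_t1' gamma_t > 0) learned by Q-learning,
the supervised estimator augments the Q-function plug-in with inverse
probability weights:

    V_SUPDR = P_n[ Q1o + w1 {Y2 - Q1o + Q2o} + w2 {Y3 - Q2o} ],

where w1, w2 are the cumulative weights matching the observed treatments to
the policy's decisions.  The estimator is doubly robust: it is consistent if
either the outcome models or the propensity models are correct.

The semi-supervised variant rewrites the summand so that the only
unobservables are Y2, w2 and Y_t w2, imputes those from the surrogate-rich
history with cross-fitted, refitted models, and projects onto the full
sample.  Standard errors come from a sample-split influence-function
expansion in which the policy indicators are replaced by a sigmoid kernel
K_h(x) = sigma(x / h), and the derivative correction terms for the estimated
(theta, xi) are computed analytically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import DesignBundle
from .impute import CrossFitImputer, ImputationSet
from .propensity import PropensityFit
from .qlearn_sup import QFit

__all__ = ["ValueEstimate", "ipw_weights", "value_q_plugin", "value_sup_dr",
           "fit_value_imputations", "value_ssl_dr", "cv_value",
           "default_bandwidth", "value_dr_T"]


@dataclass
class ValueEstimate:
    estimate: float
    se: float
    variant: str
    h: float | None = None
    n: int = 0

    def ci(self, level=0.95):
        from scipy.stats import norm
        z = norm.ppf(0.5 + level / 2)
        return self.estimate - z * self.se, self.estimate + z * self.se


def _sigmoid(x):
    from scipy.special import expit
    return expit(x)


def default_bandwidth(u: np.ndarray, n: int) -> float:
    """Rule-of-thumb smoothing bandwidth 0.9 sd(u) n^{-1/5} (floored)."""
    return max(0.9 * float(np.std(u)) * n ** (-0.2), 1e-3)


def _stage_pieces(designs, qfit, pifit, t, h=None):
    """Per-subject policy signal u_t, (smoothed) decision s_t, propensity."""
    u = designs.H1[t] @ qfit.gamma(t)
    if h is None:
        s = (u > 0).astype(float)
        sd = np.zeros_like(u)
    else:
        s = _sigmoid(u / h)
        sd = s * (1 - s) / h
    pi = pifit.predict(designs, t)
    return u, s, sd, pi


def ipw_weights(designs: DesignBundle, qfit: QFit, pifit: PropensityFit,
                h: float | None = None):
    """Cumulative policy-matching IPW weights (w_1, ..., w_T).

    ``w_t = prod_{s<=t} [ d_s A_s / pi_s + (1-d_s)(1-A_s) / (1-pi_s) ]``;
    with a bandwidth ``h`` the indicators d_s are smoothed to sigma(u/h).
    Weights that need masked outcomes in the propensity design are NaN on
    unlabelled subjects.
    """
    w = {}
    cum = np.ones(designs.n)
    for t in range(1, designs.T + 1):
        _, s, _, pi = _stage_pieces(designs, qfit, pifit, t, h)
        A = designs.A[t]
        cum = cum * (s * A / pi + (1 - s) * (1 - A) / (1 - pi))
        w[t] = cum.copy()
    return w


def _q_pieces(designs, qfit, t, h=None):
    """Q_t at the policy action: (Q_t^o outcome-coef part, observable part).

    Returns (bY, q_obs) with Q_t^o = sum_s bY_s Y_s + q_obs and the
    policy-action hinge smoothed when h is given."""
    bY, beta, gamma = qfit.split(t)
    u = designs.H1[t] @ gamma
    hinge = np.maximum(u, 0.0) if h is None else _sigmoid(u / h) * u
    return bY, designs.H0[t] @ beta + hinge


def value_q_plugin(designs: DesignBundle, qfit: QFit,
                   projection: str = "all") -> ValueEstimate:
    """Plain Q-function plug-in P[Q1(H1, d1(H1))] (no augmentation).

    The reported SE is the naive projection-sampling SE of the summand; it
    ignores the estimation error in theta_1 and is consistent for the true
    value only under a correctly specified outcome model.
    """
    rows = designs.labeled if projection == "labeled" else np.ones(
        designs.n, dtype=bool)
    _, q1 = _q_pieces(designs, qfit, 1)
    v = q1[rows]
    return ValueEstimate(float(v.mean()), float(v.std(ddof=1) / np.sqrt(v.size)),
                         "Q_plugin", n=int(rows.sum()))


def _supdr_terms(designs, qfit, pifit, h=None):
    """Per-labelled-subject V_SUPDR summands (T = 2)."""
    lab = designs.labeled
    w = ipw_weights(designs, qfit, pifit, h)
    _, q1 = _q_pieces(designs, qfit, 1, h)
    bY2, q2_minus = _q_pieces(designs, qfit, 2, h)
    b21 = float(bY2.sum())
    Y2, Y3 = designs.Y[2], designs.Y[3]
    q2 = b21 * Y2 + q2_minus
    V = q1 + w[1] * (Y2 - q1 + q2) + w[2] * (Y3 - q2)
    return V[lab], w, q1, q2_minus, b21


def value_sup_dr(designs: DesignBundle, qfit: QFit, pifit: PropensityFit,
                 h: float | None = None, folds=None) -> ValueEstimate:
    """Supervised doubly robust value estimate with influence-function SE.

    The SE accounts for the estimation of (theta, xi) through analytic
    derivatives of the kernel-smoothed summand; ``h`` defaults to the
    rule-of-thumb bandwidth per stage.
    """
    V, *_ = _supdr_terms(designs, qfit, pifit, None)
    est = float(V.mean())
    n = V.size
    psi = _psi_supdr(designs, qfit, pifit, h)
    se = float(np.sqrt(np.mean(psi ** 2) / n))
    return ValueEstimate(est, se, "SUP_DR", h=h, n=n)


# ---------------------------------------------------------------------------
# analytic gradient of the smoothed summand (T = 2)
# ---------------------------------------------------------------------------

def _smoothed_gradient(designs, qfit, pifit, h1, h2, rows):
    """Mean gradient of the smoothed V_SUPDR summand w.r.t.
    (theta1, theta2, xi1, xi2), evaluated on ``rows``."""
    u1, s1, s1d, pi1 = _stage_pieces(designs, qfit, pifit, 1, h1)
    u2, s2, s2d, pi2 = _stage_pieces(designs, qfit, pifit, 2, h2)
    A1, A2 = designs.A[1], designs.A[2]
    Y2, Y3 = designs.Y[2], designs.Y[3]
    bY2, q2m = _q_pieces(designs, qfit, 2, h2)
    b21 = float(bY2.sum())
    _, q1 = _q_pieces(designs, qfit, 1, h1)
    q2 = b21 * Y2 + q2m
    w1 = s1 * A1 / pi1 + (1 - s1) * (1 - A1) / (1 - pi1)
    r2 = s2 * A2 / pi2 + (1 - s2) * (1 - A2) / (1 - pi2)
    w2 = w1 * r2
    resid1 = Y2 - q1 + q2
    resid2 = Y3 - q2

    H10, H11 = designs.H0[1], designs.H1[1]
    H20, H21 = designs.H0[2], designs.H1[2]
    D1, D2 = designs.prop[1], designs.prop[2]

    dw1_du = (A1 / pi1 - (1 - A1) / (1 - pi1)) * s1d
    g_b1 = H10 * (1 - w1)[:, None]
    g_g1 = (H11 * ((1 - w1) * (s1 + u1 * s1d))[:, None]
            + H11 * (dw1_du * (resid1 + r2 * resid2))[:, None])
    g_b21 = (w1 - w2) * Y2
    g_b22 = H20 * (w1 - w2)[:, None]
    dr2_du = (A2 / pi2 - (1 - A2) / (1 - pi2)) * s2d
    g_g2 = (H21 * ((w1 - w2) * (s2 + u2 * s2d))[:, None]
            + H21 * (w1 * dr2_du * resid2)[:, None])
    dw1_dpi = (-A1 * s1 / pi1 ** 2 + (1 - A1) * (1 - s1) / (1 - pi1) ** 2)
    g_x1 = D1 * (dw1_dpi * pi1 * (1 - pi1) * (resid1 + r2 * resid2))[:, None]
    dr2_dpi = (-A2 * s2 / pi2 ** 2 + (1 - A2) * (1 - s2) / (1 - pi2) ** 2)
    g_x2 = D2 * (w1 * dr2_dpi * pi2 * (1 - pi2) * resid2)[:, None]

    def m(x):
        return x[rows].mean(axis=0)

    return {
        "theta1": np.concatenate([m(g_b1), m(g_g1)]),
        "theta2": np.concatenate([[m(g_b21)], m(g_b22), m(g_g2)]),
        "xi1": m(g_x1),
        "xi2": m(g_x2),
    }


def _theta_xi_correction(designs, qfit, pifit, h1, h2):
    """Sum of influence-function correction terms phi' dV/dTheta, per
    labelled subject.  Requires qfit.influence (set by the variance call)."""
    lab = designs.labeled
    grad = _smoothed_gradient(designs, qfit, pifit, h1, h2, lab)
    corr = np.zeros(int(lab.sum()))
    if getattr(qfit, "influence", None) is not None:
        corr = corr + qfit.influence[1] @ grad["theta1"]
        corr = corr + qfit.influence[2] @ grad["theta2"]
    corr = corr + pifit.influence(designs, 1) @ grad["xi1"]
    corr = corr + pifit.influence(designs, 2) @ grad["xi2"]
    return corr


def _psi_supdr(designs, qfit, pifit, h=None):
    lab = designs.labeled
    n = int(lab.sum())
    h1 = h or default_bandwidth(designs.H1[1][lab] @ qfit.gamma(1), n)
    h2 = h or default_bandwidth(designs.H1[2][lab] @ qfit.gamma(2), n)
    V, *_ = _supdr_terms(designs, qfit, pifit, None)
    nu = V - V.mean()
    return nu + _theta_xi_correction(designs, qfit, pifit, h1, h2)


# ---------------------------------------------------------------------------
# semi-supervised DR estimator
# ---------------------------------------------------------------------------

VALUE_TARGETS = ("y2v", "w2", "y2w2", "y3w2")


def fit_value_imputations(designs: DesignBundle, qfit: QFit,
                          pifit: PropensityFit, learner, K: int = 5,
                          seed: int = 0, folds=None) -> ImputationSet:
    """Cross-fit {Y2, w2, Y2 w2, Y3 w2} on U and solve the refit equations.

    Refit offsets are scalars solving the weighted moment conditions: the Y2
    equation is weighted by w1, the w2 equation by the outcome-free policy
    Q-function Q2^{-o}, and the product equations are plain means — exactly
    the constraints that make the projection step unbiased.
    """
    lab = designs.labeled
    w = ipw_weights(designs, qfit, pifit)
    _, q2m = _q_pieces(designs, qfit, 2)
    Y2, Y3 = designs.Y[2][lab], designs.Y[3][lab]
    targets = {
        "y2v": Y2,
        "w2": w[2][lab],
        "y2w2": (designs.Y[2] * w[2])[lab],
        "y3w2": (designs.Y[3] * w[2])[lab],
    }
    weights = {"y2v": w[1][lab], "w2": q2m[lab]}
    imputer = CrossFitImputer(K=K, learner=learner, seed=seed, folds=folds)
    return imputer.fit(designs.U, lab, targets,
                       {name: None for name in targets}, weights)


def value_ssl_dr(designs: DesignBundle, qfit: QFit, pifit: PropensityFit,
                 impv: ImputationSet, projection: str = "all",
                 h: float | None = None) -> ValueEstimate:
    """Semi-supervised augmented value estimate over the projection set.

    Point estimate per subject:
    Q1o + w1 [(1+b21) mu_y2 - Q1o + Q2^{-o}] + mu_y3w2 - b21 mu_y2w2
        - Q2^{-o} mu_w2.
    The SE uses the sample-split residual expansion plus the same
    (theta, xi) derivative corrections as the supervised estimator.
    """
    rows = (np.ones(designs.n, dtype=bool) if projection == "all"
            else ~designs.labeled)
    lab = designs.labeled
    n = int(lab.sum())
    w = ipw_weights(designs, qfit, pifit)
    _, q1 = _q_pieces(designs, qfit, 1)
    bY2, q2m = _q_pieces(designs, qfit, 2)
    b21 = float(bY2.sum())
    V = (q1 + w[1] * ((1 + b21) * impv.mu["y2v"] - q1 + q2m)
         + impv.mu["y3w2"] - b21 * impv.mu["y2w2"] - q2m * impv.mu["w2"])
    est = float(V[rows].mean())

    # sample-split variance with smoothed weights
    h1 = h or default_bandwidth(designs.H1[1][lab] @ qfit.gamma(1), n)
    h2 = h or default_bandwidth(designs.H1[2][lab] @ qfit.gamma(2), n)
    ws = ipw_weights(designs, qfit, pifit, h=h2)
    lab_idx = np.flatnonzero(lab)
    mu2 = impv.crossfit_mu("y2v", lab_idx)
    muw2 = impv.crossfit_mu("w2", lab_idx)
    mu2w2 = impv.crossfit_mu("y2w2", lab_idx)
    mu3w2 = impv.crossfit_mu("y3w2", lab_idx)
    Y2, Y3 = designs.Y[2][lab], designs.Y[3][lab]
    nu = (ws[1][lab] * (1 + b21) * (Y2 - mu2)
          + (ws[2][lab] * Y3 - mu3w2)
          - b21 * (ws[2][lab] * Y2 - mu2w2)
          - q2m[lab] * (ws[2][lab] - muw2))
    psi = nu + _theta_xi_correction(designs, qfit, pifit, h1, h2)
    se = float(np.sqrt(np.mean(psi ** 2) / n))
    return ValueEstimate(est, se, "SSL_DR", h=h, n=n)


def cv_value(traj, fit_fn, value_fn, n_folds: int, seed: int = 0):
    """Cross-validated value: learn the regime on training folds, estimate
    its value on the held-out fold, average (guards against same-data
    optimism).  ``n_folds=1`` is the in-sample estimate."""
    from .impute import assign_folds
    if n_folds == 1:
        fitted = fit_fn(traj)
        return value_fn(fitted, traj)
    labels = assign_folds(traj.n_subjects, n_folds, seed)
    vals = []
    for k in range(n_folds):
        fitted = fit_fn(traj.subset(labels != k))
        vals.append(value_fn(fitted, traj.subset(labels == k)))
    ests = [v.estimate for v in vals]
    ses = [v.se for v in vals]
    return ValueEstimate(float(np.mean(ests)),
                         float(np.sqrt(np.mean(np.square(ses)) / n_folds)),
                         vals[0].variant + "_CV", n=traj.n_subjects)


# ---------------------------------------------------------------------------
# general time horizon
# ---------------------------------------------------------------------------

def _telescope_pieces(designs, qfit, h=None):
    """c[t][s] coefficients and observable parts g[t] of
    D_t = Y_{t+1} + Q_{t+1}^o - Q_t^o = sum_s c[t][s] Y_s + g[t]."""
    T = designs.T
    bY = {}
    qobs = {}
    for t in range(1, T + 1):
        bY[t], qobs[t] = _q_pieces(designs, qfit, t, h)
    c = {}
    g = {}
    for t in range(1, T + 1):
        cs = np.zeros(T + 2)
        cs[t + 1] += 1.0
        if t < T:
            for j, s in enumerate(range(2, t + 2)):
                cs[s] += bY[t + 1][j]
            gt = qobs[t + 1] - qobs[t]
        else:
            gt = -qobs[t]
        for j, s in enumerate(range(2, t + 1)):
            cs[s] -= bY[t][j]
        c[t] = cs
        g[t] = gt
    return c, g, qobs


def value_dr_T(designs: DesignBundle, qfit: QFit, pifit: PropensityFit,
               learner=None, K: int = 5, seed: int = 0, folds=None,
               variant: str = "sup", projection: str = "all") -> ValueEstimate:
    """Doubly robust value for a general horizon T (reduces to the two-stage
    estimators at T = 2).

    The supervised summand telescopes Q-function corrections with cumulative
    weights; the SSL variant imputes each unobservable atom (w_t and
    Y_s w_t) with a cross-fitted, refitted model and projects onto the full
    sample.  SEs use the residual (nu) part of the influence expansion.
    """
    T = designs.T
    lab = designs.labeled
    n = int(lab.sum())
    w = ipw_weights(designs, qfit, pifit)
    c, g, qobs = _telescope_pieces(designs, qfit)
    q1o = qobs[1]
    if variant == "sup":
        V = q1o.copy()
        for t in range(1, T + 1):
            Dt = g[t].copy()
            for s in range(2, T + 2):
                if c[t][s]:
                    Dt += c[t][s] * designs.Y[s]
            V = V + w[t] * Dt
        V = V[lab]
        return ValueEstimate(float(V.mean()),
                             float(V.std(ddof=1) / np.sqrt(n)),
                             "SUP_DR", n=n)

    # --- SSL: impute w_t and Y_s w_t for t >= 2, Y_2 for the t=1 term
    targets = {("yv", 2): designs.Y[2][lab]}
    weights = {("yv", 2): w[1][lab]}
    for t in range(2, T + 1):
        targets[("w", t)] = w[t][lab]
        weights[("w", t)] = g[t][lab]
        for s in range(2, t + 2):
            targets[("yw", s, t)] = (designs.Y[s] * w[t])[lab]
    imputer = CrossFitImputer(K=K, learner=learner, seed=seed, folds=folds)
    impv = imputer.fit(designs.U, lab, targets,
                       {name: None for name in targets}, weights)
    rows = (np.ones(designs.n, dtype=bool) if projection == "all"
            else ~designs.labeled)
    V = q1o + w[1] * (c[1][2] * impv.mu[("yv", 2)] + g[1])
    for t in range(2, T + 1):
        V = V + g[t] * impv.mu[("w", t)]
        for s in range(2, t + 2):
            if c[t][s]:
                V = V + c[t][s] * impv.mu[("yw", s, t)]
    est = float(V[rows].mean())

    lab_idx = np.flatnonzero(lab)
    nu = w[1][lab] * c[1][2] * (designs.Y[2][lab]
                                - impv.crossfit_mu(("yv", 2), lab_idx))
    for t in range(2, T + 1):
        nu = nu + g[t][lab] * (w[t][lab] - impv.crossfit_mu(("w", t), lab_idx))
        for s in range(2, t + 2):
            if c[t][s]:
                nu = nu + c[t][s] * ((designs.Y[s] * w[t])[lab]
                                     - impv.crossfit_mu(("yw", s, t), lab_idx))
    se = float(np.sqrt(np.mean(nu ** 2) / n))
    return ValueEstimate(est, se, "SSL_DR", n=n)
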