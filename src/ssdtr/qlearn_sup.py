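"""Fully supervised Q-learning with sandwich variance.

Backward induction on the labelled data: the final stage regresses the
terminal outcome on ``Xcheck_T`` by least squares; each earlier stage t
regresses the pseudo-outcome

    Y_t* = Y_{t+1} + max_a Q_{t+1}(Hcheck_{t+1}, a; theta_{t+1})

on ``Xcheck_t``.  With linear working models the maximised next-stage Q is
linear in the observed outcomes plus a hinge term ``[H_{t+1,1}' gamma]_+``.
This is the baseline estimator every semi-supervised result is compared
against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import DesignBundle, Policy

__all__ = ["QFit", "fit_stage2_sup", "pseudo_outcome_sup", "fit_stage1_sup",
           "backward_fit_sup", "variance_sup", "lstsq_checked"]

_COND_MAX = 1e10


def lstsq_checked(X: np.ndarray, y: np.ndarray, weights=None) -> np.ndarray:
    """Least-squares solve with a condition-number guard.

    Raises ``np.linalg.LinAlgError`` (with the condition number in the
    message) if the design is numerically rank deficient beyond repair;
    otherwise returns the minimum-norm solution.
    """
    if X.shape[0] < X.shape[1] + 1:
        raise np.linalg.LinAlgError(
            f"need at least {X.shape[1] + 1} rows, got {X.shape[0]}")
    if weights is not None:
        w = np.sqrt(weights)
        X = X * w[:, None]
        y = y * w
    beta, _, rank, sv = np.linalg.lstsq(X, y, rcond=None)
    cond = sv[0] / sv[-1] if sv[-1] > 0 else np.inf
    if rank < X.shape[1] and cond > _COND_MAX:
        raise np.linalg.LinAlgError(
            f"rank-deficient design (rank {rank} < {X.shape[1]}, "
            f"condition number {cond:.2e})")
    return beta


@dataclass
class QFit:
    """Stage-wise Q-learning coefficients theta_t = (bY_t, beta_t, gamma_t).

    ``theta[t]`` is ordered as Xcheck_t: prior outcomes Y_2..Y_t first, then
    H_t0, then the A_t * H_t1 interaction block.  ``cov`` (when computed)
    maps stage -> covariance matrix of theta_t-hat; ``tag`` records the
    estimator ("SUP" or "SSL").
    """

    theta: dict
    n_y: dict
    p0: dict
    p1: dict
    tag: str = "SUP"
    cov: dict = field(default_factory=dict)
    folds: np.ndarray | None = None

    def split(self, t):
        """Return (bY, beta, gamma) blocks of theta_t."""
        th = self.theta[t]
        q = self.n_y[t]
        return th[:q], th[q:q + self.p0[t]], th[q + self.p0[t]:]

    def gamma(self, t):
        return self.split(t)[2]

    def policy(self) -> Policy:
        return Policy({t: self.gamma(t) for t in self.theta})

    def se(self, t):
        return np.sqrt(np.diag(self.cov[t]))

    def max_q(self, designs: DesignBundle, t: int):
        """max_a Q_t evaluated on every subject, decomposed as
        (c, g): coefficients on (Y_2..Y_t) and the observable remainder."""
        bY, beta, gamma = self.split(t)
        g = designs.H0[t] @ beta + np.maximum(designs.H1[t] @ gamma, 0.0)
        return bY, g


def _pseudo_coefs(fit: QFit, designs: DesignBundle, t: int):
    """Stage-t response Y_t* = sum_s c_s Y_s + g with observable g.

    For t = T the response is just Y_{T+1} (c = e_{T+1}, g = 0); otherwise
    Y_t* = Y_{t+1} + max_a Q_{t+1} which adds theta_{t+1}'s outcome
    coefficients and the hinge term.
    """
    T = designs.T
    c = np.zeros(T + 2)  # index s = outcome Y_s, s in 2..T+1
    if t == T:
        c[T + 1] = 1.0
        g = np.zeros(designs.n)
    else:
        bY, g = fit.max_q(designs, t + 1)
        c[t + 1] += 1.0
        for j, s in enumerate(range(2, t + 2)):
            c[s] += bY[j]
    return c, g


def _response(fit: QFit, designs: DesignBundle, t: int):
    c, g = _pseudo_coefs(fit, designs, t)
    y = g.copy()
    for s in range(2, designs.T + 2):
        if c[s]:
            y = y + c[s] * designs.Y[s]
    return y


def fit_stage2_sup(designs: DesignBundle) -> np.ndarray:
    """Least squares of Y_3 on Xcheck_2 over labelled subjects (T = 2)."""
    lab = designs.labeled
    return lstsq_checked(designs.xcheck(2)[lab], designs.Y[3][lab])


def pseudo_outcome_sup(designs: DesignBundle, theta2: np.ndarray) -> np.ndarray:
    """Y_2* = Y_2 (1 + b21) + H_20' b22 + [H_21' g2]_+ on labelled subjects."""
    q = designs.n_y(2)
    p0 = designs.H0[2].shape[1]
    b21 = theta2[:q].sum() if q else 0.0
    b22 = theta2[q:q + p0]
    g2 = theta2[q + p0:]
    return (designs.Y[2] * (1.0 + b21) + designs.H0[2] @ b22
            + np.maximum(designs.H1[2] @ g2, 0.0))


def fit_stage1_sup(designs: DesignBundle, ystar: np.ndarray) -> np.ndarray:
    lab = designs.labeled
    return lstsq_checked(designs.X[1][lab], ystar[lab])


def backward_fit_sup(designs: DesignBundle, T: int | None = None) -> QFit:
    """Supervised backward recursion for stages T..1.

    For T = 2 this reduces exactly to ``fit_stage2_sup`` followed by
    ``fit_stage1_sup`` on the pseudo-outcome.
    """
    T = T or designs.T
    lab = designs.labeled
    fit = QFit(theta={}, n_y={t: designs.n_y(t) for t in range(1, T + 1)},
               p0={t: designs.H0[t].shape[1] for t in range(1, T + 1)},
               p1={t: designs.H1[t].shape[1] for t in range(1, T + 1)},
               tag="SUP")
    for t in range(T, 0, -1):
        y = _response(fit, designs, t)
        fit.theta[t] = lstsq_checked(designs.xcheck(t)[lab], y[lab])
    return fit


# ---------------------------------------------------------------------------
# sandwich variance (two-stage)
# ---------------------------------------------------------------------------

def _sigma_hat(designs, t, use_xcheck=True):
    lab = designs.labeled
    M = designs.xcheck(t)[lab] if use_xcheck else designs.X[t][lab]
    return M.T @ M / M.shape[0]


def _stage1_plugins(designs, fit):
    """Empirical E[X1 (Y2, H20')] and E[X1 H21' I(H21'g2 > 0)] (labelled)."""
    lab = designs.labeled
    X1 = designs.X[1][lab]
    n = X1.shape[0]
    YH = np.column_stack([designs.Y[2][lab], designs.H0[2][lab]])
    C_beta = X1.T @ YH / n
    ind = (designs.H1[2][lab] @ fit.gamma(2) > 0).astype(float)
    C_gamma = X1.T @ (designs.H1[2][lab] * ind[:, None]) / n
    frac_degenerate = float(np.mean(
        np.abs(designs.H1[2][lab] @ fit.gamma(2)) < 1e-8))
    return C_beta, C_gamma, frac_degenerate


def variance_sup(designs: DesignBundle, fit: QFit) -> QFit:
    """Sandwich covariance of the supervised two-stage estimator.

    Stage 2 is the heteroskedasticity-robust OLS sandwich.  Stage 1 adds the
    plug-in terms that propagate theta_2-hat's sampling variability through
    the pseudo-outcome (outcome block via E[X1 (Y2, H20')], hinge block via
    E[X1 H21' I(H21' gamma_2 > 0)]).
    """
    if designs.T != 2:
        raise NotImplementedError("sandwich variance implemented for T = 2")
    lab = designs.labeled
    n = int(lab.sum())
    Xc2 = designs.xcheck(2)[lab]
    resid2 = designs.Y[3][lab] - Xc2 @ fit.theta[2]
    psi2 = Xc2 * resid2[:, None]
    S2 = _sigma_hat(designs, 2)
    phi2 = np.linalg.solve(S2, psi2.T).T

    C_beta, C_gamma, frac = _stage1_plugins(designs, fit)
    if frac > 0.05:
        import warnings
        warnings.warn(
            f"{frac:.1%} of labelled subjects sit within 1e-8 of the stage-2 "
            "decision boundary; near-degenerate treatment effects make the "
            "stage-1 expansion unreliable")
    q = designs.n_y(2)
    p0 = designs.H0[2].shape[1]
    phi_beta = phi2[:, :q + p0]
    phi_gamma = phi2[:, q + p0:]

    X1 = designs.X[1][lab]
    ystar = pseudo_outcome_sup(designs, fit.theta[2])[lab]
    psi1 = (X1 * (ystar - X1 @ fit.theta[1])[:, None]
            + phi_beta @ C_beta.T + phi_gamma @ C_gamma.T)
    S1 = _sigma_hat(designs, 1)
    phi1 = np.linalg.solve(S1, psi1.T).T
    fit.cov = {2: phi2.T @ phi2 / n ** 2, 1: phi1.T @ phi1 / n ** 2}
    fit.influence = {1: phi1, 2: phi2}
    return fit
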