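"""Stage-wise logistic propensity models fitted on labelled data.

The stage-t working model is pi_t = sigma(Hcheck_t0' xi_t) where the stage-2
(and later) design includes the observed prior outcomes, so those fits can
only use labelled subjects.  Estimation is plain maximum likelihood with a
ridge-penalised fallback under (near-)separation; predicted probabilities
are clamped away from {0, 1} before any weighting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .features import DesignBundle

__all__ = ["PropensityFit", "fit_propensity", "predict_propensity"]

_CLAMP = 1e-6


@dataclass
class PropensityFit:
    """Logistic coefficients per stage, MLE covariance, and bookkeeping."""

    xi: dict = field(default_factory=dict)
    cov: dict = field(default_factory=dict)
    ridge_used: dict = field(default_factory=dict)

    def linear_predictor(self, designs: DesignBundle, t: int) -> np.ndarray:
        return designs.prop[t] @ self.xi[t]

    def predict(self, designs: DesignBundle, t: int) -> np.ndarray:
        """pi_t-hat for every subject (NaN where the design needs outcomes
        that are masked), clamped to (1e-6, 1 - 1e-6)."""
        eta = self.linear_predictor(designs, t)
        p = 1.0 / (1.0 + np.exp(-eta))
        return np.clip(p, _CLAMP, 1.0 - _CLAMP)

    def influence(self, designs: DesignBundle, t: int) -> np.ndarray:
        """Per-labelled-subject MLE influence I^{-1} D (A - pi)."""
        lab = designs.labeled
        D = designs.prop[t][lab]
        p = self.predict(designs, t)[lab]
        info = (D * (p * (1 - p))[:, None]).T @ D / D.shape[0]
        score = D * (designs.A[t][lab] - p)[:, None]
        # pinv: degenerate designs (e.g. a constant treatment column) should
        # not abort the variance computation
        return score @ np.linalg.pinv(info).T


def fit_propensity(designs: DesignBundle, stage: int,
                   penalty: float | None = None) -> tuple[np.ndarray, np.ndarray, bool]:
    """Logistic MLE of A_stage on the stage design over labelled rows.

    Returns (xi_hat, covariance, ridge_used).  Falls back to a small ridge
    penalty when the MLE diverges (complete or quasi-complete separation).
    """
    lab = designs.labeled
    D = designs.prop[stage][lab]
    A = designs.A[stage][lab]
    if A.min() == A.max():
        raise ValueError(f"only one treatment arm present at stage {stage}")
    ridge_used = penalty is not None
    if penalty is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.GLM(A, D, family=sm.families.Binomial()).fit(maxiter=100)
                xi, cov = res.params, res.cov_params()
                if not np.isfinite(xi).all() or np.abs(xi).max() > 30:
                    raise np.linalg.LinAlgError("divergent MLE")
                return xi, np.asarray(cov), False
            except Exception:
                ridge_used = True
                penalty = 1e-3
    # ridge-penalised IRLS
    xi = np.zeros(D.shape[1])
    for _ in range(200):
        p = 1.0 / (1.0 + np.exp(-(D @ xi)))
        W = p * (1 - p)
        H = (D * W[:, None]).T @ D + penalty * np.eye(D.shape[1])
        g = D.T @ (A - p) - penalty * xi
        step = np.linalg.solve(H, g)
        xi = xi + step
        if np.abs(step).max() < 1e-10:
            break
    p = 1.0 / (1.0 + np.exp(-(D @ xi)))
    H = (D * (p * (1 - p))[:, None]).T @ D + penalty * np.eye(D.shape[1])
    return xi, np.linalg.inv(H), ridge_used


def fit_all_propensities(designs: DesignBundle,
                         penalty: float | None = None) -> PropensityFit:
    fit = PropensityFit()
    for t in range(1, designs.T + 1):
        xi, cov, ridge = fit_propensity(designs, t, penalty)
        fit.xi[t] = xi
        fit.cov[t] = cov
        fit.ridge_used[t] = ridge
    return fit


def predict_propensity(fit: PropensityFit, designs: DesignBundle, t: int,
                       trim: tuple[float, float] | None = None):
    """Predicted pi_t plus a keep-mask (True = inside the trim interval).

    Trimming is off by default; with e.g. ``trim=(0.1, 0.9)`` subjects whose
    predicted score falls outside the closed interval are flagged for
    exclusion from downstream weighting.
    """
    p = fit.predict(designs, t)
    if trim is None:
        keep = np.ones_like(p, dtype=bool)
    else:
        lo, hi = trim
        keep = (p >= lo) & (p <= hi)
    return p, keep
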