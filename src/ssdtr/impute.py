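"""Cross-fitted imputation of unobserved outcomes, with refitting.

Step I fits flexible regressions of each imputation target (outcomes,
pairwise outcome products, or weight functionals for the value estimator) on
the full surrogate-augmented history ``U`` over K labelled folds, leaving one
fold out at a time.  Step II ("refitting") adds a linear correction solving
moment equations of the form

    sum_k sum_{i in fold k}  D_i * (target_i - m^{(-k)}(U_i) - eta' D_i) = 0

so that downstream projections remain unbiased even when the flexible
learners are arbitrarily mis-specified.  The final imputation for any subject
is the fold-average prediction plus the linear correction:

    mu_hat(U) = K^{-1} sum_k m^{(-k)}(U) + eta' D.

Two learners are provided: a random forest (default 500 trees) and an
additive piecewise-cubic spline basis with two interior knots at the 33rd
and 67th percentiles of each continuous input (binary inputs enter
linearly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestRegressor

__all__ = ["make_learner", "SplineBasisRegressor", "CrossFitImputer",
           "assign_folds", "qlearning_targets", "ImputationSet"]


class SplineBasisRegressor:
    """Additive natural (restricted) cubic spline regression.

    Each continuous column contributes a natural cubic spline basis with two
    interior knots at the 33rd/67th percentiles of the training data and
    boundary knots at the training range, so the fit is linear beyond the
    observed range (cubic extrapolation onto the large unlabelled sample is
    exactly the failure mode this avoids).  Binary columns enter linearly.
    Fit by ridge-stabilised least squares; supports multi-output targets.
    """

    def __init__(self, ridge: float = 1e-6):
        self.ridge = ridge

    @staticmethod
    def _ns_cols(x, knots):
        # natural cubic spline basis (R ns()-style) for knot sequence
        # (boundary, interior..., boundary)
        kmax = knots[-1]
        kpen = knots[-2]

        def d(k):
            return ((np.maximum(x - k, 0.0) ** 3
                     - np.maximum(x - kmax, 0.0) ** 3) / (kmax - k))

        dpen = d(kpen)
        return [x] + [d(k) - dpen for k in knots[:-2]]

    def _basis(self, X):
        cols = [np.ones(X.shape[0])]
        for j in range(X.shape[1]):
            x = X[:, j]
            if j in self._binary:
                cols.append(x)
            else:
                cols.extend(self._ns_cols(x, self._knots[j]))
        return np.column_stack(cols)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self._binary = {j for j in range(X.shape[1])
                        if np.isin(np.unique(X[:, j]), (0.0, 1.0)).all()}
        self._knots = {}
        for j in range(X.shape[1]):
            if j in self._binary:
                continue
            lo, k1, k2, hi = np.percentile(X[:, j], (0, 33, 67, 100))
            ks = np.unique([lo, k1, k2, hi])
            if ks.size < 3:   # nearly degenerate column: keep it linear
                self._binary.add(j)
            else:
                self._knots[j] = ks
        B = self._basis(X)
        # standardise to keep the ridge penalty scale-free
        self._mu = B.mean(axis=0)
        self._sd = B.std(axis=0)
        self._sd[self._sd == 0] = 1.0
        Bs = (B - self._mu) / self._sd
        A = Bs.T @ Bs + self.ridge * np.eye(B.shape[1])
        self._coef = np.linalg.solve(A, Bs.T @ y)   # multi-RHS when y is 2-d
        self._intercept = np.mean(y, axis=0)
        return self

    def predict(self, X):
        Bs = (self._basis(np.asarray(X, dtype=float)) - self._mu) / self._sd
        return Bs @ self._coef + self._intercept


def make_learner(kind: str, seed: int = 0, n_trees: int = 500):
    """Factory for imputation base learners: 'forest' or 'spline'."""
    if kind in ("forest", "tree_ensemble", "rf"):
        return lambda: RandomForestRegressor(
            n_estimators=n_trees, random_state=seed, n_jobs=1)
    if kind in ("spline", "spline_basis", "be"):
        return lambda: SplineBasisRegressor()
    raise ValueError(f"unknown learner kind {kind!r}")


def assign_folds(n: int, K: int, seed: int) -> np.ndarray:
    """Equal-sized (up to 1) random fold labels 0..K-1 for n subjects."""
    if K < 2:
        raise ValueError("K must be >= 2")
    if K > n:
        raise ValueError(f"K={K} exceeds the {n} labelled subjects")
    rng = np.random.default_rng(seed)
    labels = np.arange(n) % K
    return labels[rng.permutation(n)]


def qlearning_targets(designs, T: int | None = None) -> dict:
    """Imputation targets for the T-stage SSL projection.

    Means of every outcome Y_s (s = 2..T+1) and of every pairwise product
    Y_r Y_s with r <= min(s, T): the products that appear when the stage-t
    normal equations pair the outcome rows of Xcheck_t with the
    pseudo-outcome.  O(T^2) targets, each linear or quadratic in the missing
    outcomes.
    """
    T = T or designs.T
    lab = designs.labeled
    out = {}
    for s in range(2, T + 2):
        out[("y", s)] = designs.Y[s][lab]
    for r in range(2, T + 1):
        for s in range(r, T + 2):
            out[("yy", r, s)] = (designs.Y[r] * designs.Y[s])[lab]
    return out


@dataclass
class ImputationSet:
    """Cross-fitted imputations mu_hat for every subject.

    ``mu[name]`` is the refitted imputation over all N+n subjects;
    ``mu_foldwise[name]`` is the (K, n_all) matrix of per-fold predictions
    plus the correction, used by the sample-split variance (fold-k labelled
    subjects are evaluated with the learner that never saw fold k).
    ``eta[name]`` stores the refit coefficients.
    """

    mu: dict
    eta: dict
    folds: np.ndarray
    K: int
    preds: dict          # name -> (K, n_all) raw fold predictions
    refit_design: dict   # name -> design matrix or None (scalar refit)

    def foldwise(self, name: str) -> np.ndarray:
        """mu^{(-k)} evaluated on all subjects, per fold (K, n_all)."""
        corr = self._correction(name)
        return self.preds[name] + corr[None, :]

    def _correction(self, name):
        D = self.refit_design[name]
        eta = self.eta[name]
        return D @ eta if D is not None else np.full(
            self.preds[name].shape[1], eta)

    def crossfit_mu(self, name: str, labeled_idx: np.ndarray) -> np.ndarray:
        """On labelled subject i of fold k: m^{(-k)}(U_i) + correction."""
        fw = self.foldwise(name)
        return fw[self.folds, labeled_idx]


class CrossFitImputer:
    """Fits base learners per fold and solves the refitting equations.

    Parameters
    ----------
    K : fold count (the operating choice is 5).
    learner : factory returning a fresh fit/predict estimator.
    seed : governs the single fold shuffle, shared by every target so the
        refitting sums stay coherent.
    """

    def __init__(self, K: int = 5, learner=None, seed: int = 0,
                 folds: np.ndarray | None = None, standardize: bool = True):
        self.K = K
        self.learner = learner or make_learner("forest", seed)
        self.seed = seed
        self.folds = folds
        self.standardize = standardize

    def fit(self, U: np.ndarray, labeled: np.ndarray, targets: dict,
            refit_designs: dict, refit_weights: dict | None = None
            ) -> ImputationSet:
        """Cross-fit every target and solve its refitting equation.

        ``targets[name]`` is the labelled-row response; ``refit_designs[name]``
        is the refit design over all subjects (or None for a scalar offset);
        ``refit_weights[name]`` optionally weights a scalar refit equation
        sum_i w_i (resid_i - eta) = 0.
        """
        lab_idx = np.flatnonzero(labeled)
        n = lab_idx.size
        folds = self.folds if self.folds is not None else assign_folds(
            n, self.K, self.seed)
        if folds.shape[0] != n:
            raise ValueError("fold labels must cover the labelled subjects")
        refit_weights = refit_weights or {}

        names = list(targets)
        for name in names:
            if targets[name].shape[0] != n:
                raise ValueError(f"target {name!r} must have {n} labelled rows")
        # all targets are cross-fitted jointly: one (multi-output) learner per
        # fold, targets standardised so no single target dominates the fit;
        # for linear-in-basis learners this is exactly equivalent to separate
        # per-target fits.
        Ymat = np.column_stack([targets[name] for name in names])
        P_all = np.empty((self.K, U.shape[0], len(names)))
        models = {}
        for k in range(self.K):
            tr = lab_idx[folds != k]
            Ytr = Ymat[folds != k]
            # standardisation uses training folds only (cross-fit honesty)
            if self.standardize:
                centre = Ytr.mean(axis=0)
                scale = Ytr.std(axis=0)
                scale[scale == 0] = 1.0
            else:
                centre = np.zeros(Ytr.shape[1])
                scale = np.ones(Ytr.shape[1])
            m = self.learner()
            Ytr_s = (Ytr - centre) / scale
            m.fit(U[tr], Ytr_s[:, 0] if Ytr_s.shape[1] == 1 else Ytr_s)
            pk = np.asarray(m.predict(U))
            if pk.ndim == 1:
                pk = pk[:, None]
            P_all[k] = pk * scale + centre
            models[k] = m

        preds, eta, mu = {}, {}, {}
        for j, name in enumerate(names):
            y = targets[name]
            P = P_all[:, :, j]
            preds[name] = P
            # out-of-fold residuals on labelled subjects
            resid = y - P[folds, lab_idx]
            D = refit_designs.get(name)
            if D is not None:
                # minimum-norm solve: the refit design may carry a redundant
                # intercept (X_t blocks already contain one); mu is invariant
                # to the particular solution.
                eta[name] = np.linalg.lstsq(D[lab_idx], resid, rcond=None)[0]
                corr = D @ eta[name]
            else:
                w = refit_weights.get(name)
                if w is None:
                    eta[name] = float(np.mean(resid))
                else:
                    sw = float(np.sum(w))
                    if abs(sw) < 1e-12:
                        raise ZeroDivisionError(
                            f"zero total weight in refit equation for {name!r}")
                    eta[name] = float(np.sum(w * resid) / sw)
                corr = np.full(U.shape[0], eta[name])
            mu[name] = P.mean(axis=0) + corr

        out = ImputationSet(mu=mu, eta=eta, folds=folds, K=self.K, preds=preds,
                            refit_design={name: refit_designs.get(name)
                                          for name in targets})
        out.models = models
        out.labeled_idx = lab_idx
        return out


def qlearning_refit_designs(designs, T: int | None = None) -> dict:
    """Refit designs for the Q-learning targets.

    Outcome Y_s is refitted over (1, X_{s-1}, X_s, ..., X_T) — every design
    block that multiplies Y_s somewhere in the stage-wise normal equations;
    product targets get scalar offsets.  For T=2 this reproduces the
    canonical choices: Y2 over (1, X1, X2), Y3 over X2, scalars for Y2^2 and
    Y2 Y3.
    """
    T = T or designs.T
    n = designs.n
    out = {}
    for s in range(2, T + 2):
        blocks = [designs.X[t] for t in range(max(s - 1, 1), T + 1)]
        if s == 2:
            blocks = [np.ones((n, 1))] + blocks
        out[("y", s)] = np.column_stack(blocks)
    for r in range(2, T + 1):
        for s in range(r, T + 2):
            out[("yy", r, s)] = None
    return out
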