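"""History features, working-model design matrices, and treatment rules.

The working models regress stage outcomes on ``X_t = (H_t0', A_t * H_t1')'``
where ``H_t0 = phi_t0(history)`` and ``H_t1 = phi_t1(history)`` are
user-declared basis maps.  ``Xcheck_t`` prepends the observed prior outcomes
``Y_2..Y_t`` to ``X_t`` (for t >= 2), matching the convention that stage-t
histories include everything measured so far.  Column order is fixed:
intercept first, covariates in declaration order, then the treatment
interaction block.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .dgp import TrajectorySet

__all__ = ["FeatureSpec", "Policy", "DesignBundle", "build_designs", "apply_policy"]


def _ones(n):
    return np.ones(n)


def _cont_maps(traj):
    n = traj.n_subjects
    O1 = traj.O[1][:, 0]
    A1 = traj.A[1]
    O2 = traj.O[2][:, 0]
    H10 = np.column_stack([_ones(n), O1])
    H20 = np.column_stack([_ones(n), O1, A1, O1 * A1, O2])
    H21 = np.column_stack([_ones(n), A1, O2])
    return {1: (H10, H10.copy()), 2: (H20, H21)}


def _ehr_maps(traj):
    n = traj.n_subjects
    O1 = traj.O[1]
    A1 = traj.A[1]
    Z = traj.O[2][:, 2:4]
    H10 = np.column_stack([_ones(n), O1])
    H11 = np.column_stack([_ones(n), O1[:, 1:]])
    H20 = np.column_stack([_ones(n), O1, A1, Z])
    H21 = np.column_stack([_ones(n), O1[:, :4], A1, Z])
    return {1: (H10, H11), 2: (H20, H21)}


def _generalT_maps(traj):
    n = traj.n_subjects
    out = {}
    O1 = traj.O[1][:, 0]
    H10 = np.column_stack([_ones(n), O1])
    out[1] = (H10, H10.copy())
    for t in range(2, traj.T + 1):
        Op = traj.O[t - 1][:, 0]
        Ap = traj.A[t - 1]
        Ot = traj.O[t][:, 0]
        Ht0 = np.column_stack([_ones(n), Op, Ap, Op * Ap, Ot])
        Ht1 = np.column_stack([_ones(n), Ap, Ot])
        out[t] = (Ht0, Ht1)
    return out


_PRESETS: dict[str, Callable] = {
    "continuous2": _cont_maps,
    "ehr2": _ehr_maps,
    "generalT": _generalT_maps,
}


@dataclass(frozen=True)
class FeatureSpec:
    """Basis maps producing per-stage (H_t0, H_t1) from a trajectory set.

    ``maps`` is a callable ``traj -> {t: (H_t0, H_t1)}``; presets exist for
    every built-in simulation setting.  ``include_prior_outcomes`` controls
    whether Xcheck_t prepends Y_2..Y_t (the standard backward-induction
    design).
    """

    maps: Callable[[TrajectorySet], dict]
    include_prior_outcomes: bool = True

    @classmethod
    def preset(cls, setting: str) -> "FeatureSpec":
        return cls(maps=_PRESETS[setting])


@dataclass(frozen=True)
class Policy:
    """Linear treatment rule d_t(H_t) = I(H_t1' gamma_t > 0) per stage.

    Ties (inner product exactly zero) deterministically map to action 0.
    """

    gammas: dict

    def decide(self, t: int, H1: np.ndarray) -> np.ndarray:
        return apply_policy(self.gammas[t], H1)

    def as_generation_rule(self, setting: str):
        """Adapter used by the simulators to override behavioural treatment."""

        def rule(stage, hist):
            n = None
            if setting == "continuous2":
                if stage == 1:
                    H1 = np.column_stack([_ones(len(hist["O1"])), hist["O1"]])
                else:
                    H1 = np.column_stack(
                        [_ones(len(hist["O1"])), hist["A1"], hist["O2"]])
            elif setting == "ehr2":
                if stage == 1:
                    H1 = np.column_stack(
                        [_ones(hist["O1"].shape[0]), hist["O1"][:, 1:]])
                else:
                    H1 = np.column_stack(
                        [_ones(hist["O1"].shape[0]), hist["O1"][:, :4],
                         hist["A1"], hist["Z"]])
            elif setting == "generalT":
                O, A = hist["O"], hist["A"]
                n = len(O[1])
                if stage == 1:
                    H1 = np.column_stack([_ones(n), O[1]])
                else:
                    H1 = np.column_stack([_ones(n), A[stage - 1], O[stage]])
            else:  # pragma: no cover
                raise ValueError(setting)
            return apply_policy(self.gammas[stage], H1)

        return rule


def apply_policy(gamma: np.ndarray, H1: np.ndarray) -> np.ndarray:
    """Evaluate I(H_t1' gamma > 0) row-wise (strict inequality; ties -> 0)."""
    gamma = np.asarray(gamma, dtype=float)
    if H1.shape[1] != gamma.shape[0]:
        raise ValueError(
            f"dimension mismatch: H1 has {H1.shape[1]} columns, gamma has "
            f"{gamma.shape[0]}")
    return (H1 @ gamma > 0).astype(float)


class DesignBundle:
    """All design matrices derived from one trajectory set.

    Attributes
    ----------
    H0, H1 : dict of per-stage basis matrices.
    X : dict, X_t = [H_t0, A_t * H_t1].
    Y : outcomes (NaN on unlabelled subjects).
    U : imputation features, the full surrogate-augmented history
        (O_1, A_1, W_1, ..., O_T, A_T, W_T).
    Xarrow : (1, X_1, ..., X_T), the refitting design.
    prop : dict of propensity designs Hcheck_t0 = (Y_2..Y_t, H_t0); for t >= 2
        these involve outcomes and are only finite on labelled rows.
    """

    def __init__(self, traj: TrajectorySet, spec: FeatureSpec):
        maps = spec.maps(traj)
        if set(maps) != set(range(1, traj.T + 1)):
            raise ValueError("feature spec must cover stages 1..T")
        self.T = traj.T
        self.n = traj.n_subjects
        self.labeled = traj.labeled
        self.A = dict(traj.A)
        self.Y = dict(traj.Y)
        self.H0 = {}
        self.H1 = {}
        self.X = {}
        self.include_prior_outcomes = spec.include_prior_outcomes
        for t, (h0, h1) in maps.items():
            if not (np.isfinite(h0).all() and np.isfinite(h1).all()):
                raise ValueError(f"non-finite features at stage {t}")
            self.H0[t] = h0
            self.H1[t] = h1
            self.X[t] = np.column_stack([h0, traj.A[t][:, None] * h1])
        self.U = np.column_stack(
            [np.column_stack([traj.O[t], traj.A[t][:, None], traj.W[t]])
             for t in range(1, traj.T + 1)])
        self.Xarrow = np.column_stack(
            [np.ones(self.n)] + [self.X[t] for t in range(1, traj.T + 1)])
        self.prop = {}
        for t in range(1, traj.T + 1):
            if t == 1:
                self.prop[t] = self.H0[1]
            else:
                ys = [traj.Y[s] for s in range(2, t + 1)]
                self.prop[t] = np.column_stack(ys + [self.H0[t]])

    def n_y(self, t: int) -> int:
        """Number of prior-outcome columns in Xcheck_t."""
        return (t - 1) if self.include_prior_outcomes else 0

    def xcheck(self, t: int) -> np.ndarray:
        """(Y_2..Y_t, X_t); rows with unobserved outcomes contain NaN."""
        if t == 1 or not self.include_prior_outcomes:
            return self.X[t]
        ys = [self.Y[s] for s in range(2, t + 1)]
        return np.column_stack(ys + [self.X[t]])

    def xcheck_imputed(self, t: int, mu: dict) -> np.ndarray:
        """Xcheck_t with outcomes replaced by imputed means mu[s]."""
        if t == 1 or not self.include_prior_outcomes:
            return self.X[t]
        return np.column_stack([mu[s] for s in range(2, t + 1)] + [self.X[t]])


def build_designs(traj: TrajectorySet, spec: FeatureSpec | None = None) -> DesignBundle:
    """Construct every working-model design from raw trajectories."""
    if spec is None:
        spec = FeatureSpec.preset(traj.setting)
    return DesignBundle(traj, spec)
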