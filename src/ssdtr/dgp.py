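"""Synthetic data generators for semi-supervised dynamic treatment regimes.

Three sequentially generated observational settings are provided, each with a
small labelled set (outcomes observed) and a large unlabelled set (outcomes
masked, surrogates observed):

``continuous2``
    Two stages, a single binary baseline confounder, Gaussian intermediate and
    final outcomes, scalar integer-valued surrogates ``W_t = trunc(Y_{t+1}+Z)``.

``ehr2``
    Two stages mimicking an EHR cohort: six baseline covariates, binary
    outcomes, latent continuous stage-2 severity scores with binarised
    indicators, and bivariate Gaussian surrogate panels whose mean shifts with
    the (possibly unobserved) outcome.

``generalT``
    A T-stage extension of the continuous setting in which covariates,
    treatments and outcomes depend recursively on the history.

Each setting carries mis-specification dials for the outcome (Q) and the
treatment (propensity) models: at 0 both working models used downstream are
correctly specified; nonzero values add a highly non-linear term that no
linear/logistic working model captures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "TrajectorySet",
    "simulate",
    "split_labeled",
    "true_value_mc",
    "write_csv",
    "read_csv",
    "CONTINUOUS2",
    "EHR2",
    "GENERALT",
]

SETTINGS = ("continuous2", "ehr2", "generalT")


def _sigmoid(x):
    from scipy.special import expit
    return expit(x)


# ---------------------------------------------------------------------------
# generative coefficient sets
# ---------------------------------------------------------------------------

CONTINUOUS2 = {
    "xi1": np.array([0.3, -0.5]),                    # A1 | (1, O1)
    "theta1": np.array([1.0, 1.0, 1.0, -2.0]),       # Y2 mean | (1, O1, A1, A1*O1)
    "delta": np.array([0.0, 0.5, -0.75, 0.25]),      # O2 mean | (1, O1, A1, O1*A1)
    "xi2": np.array([0.0, 0.5, 0.1, -1.0, -0.1]),    # A2 | H20=(1,O1,A1,O1A1,O2)
    "beta2": np.array([0.1, 3.0, 0.0, 0.1, -0.5, -0.5]),  # Y3 | (Y2, H20)
    "gamma2": np.array([1.0, 0.25, 0.5]),            # A2 interaction | H21=(1,A1,O2)
    "var_y2": 1.0,
    "var_o2": 2.0,
    "var_y3": 2.0,
}

EHR2 = {
    "xi1": np.array([-0.1, 1.0, -1.0, 0.1]),         # A1 | (1, O1_1, O1_2, O1_3)
    "beta1": np.array([0.5, 0.2, -1.0, -1.0, 0.1, -0.1, 0.1]),   # H10=(1,O1..O6)
    "gamma1": np.array([1.0, -2.0, -2.0, -0.1, 0.1, -1.5]),      # H11=(1,O2..O6)
    "delta_z": np.array([1.0, 1.0]),                 # Z_l = delta_l * O1_l + eps
    "xi2": np.array([0.0, 0.5, 0.1, -1.0, 1.0, -0.1]),  # A2 | (1, O1_1..O1_5)
    "beta21": 1.0,                                   # Y3 coefficient on Y2
    # beta22 over H20=(1,O1..O6,A1,Z1,Z2) = (beta1, 0.25, -1, -0.5)
    "beta22": np.array([0.5, 0.2, -1.0, -1.0, 0.1, -0.1, 0.1, 0.25, -1.0, -0.5]),
    "gamma2": np.array([1.0, 0.1, -0.1, 0.1, -0.1, 0.25, -1.0, -0.5]),
    "alpha": np.array([1.0, 0.0, 1.0]),              # surrogate mean (1, A_t, Y_{t+1})
    "d_w": 2,
}

GENERALT = {
    "xi1": np.array([0.3, -0.5]),
    "theta1": np.array([0.1, 1.0, 1.0, -0.2]),       # (beta10, gamma10)
    "delta": np.array([0.0, 0.5, -0.75, 0.25, 1.0]),  # O_t | (1,O,A,OA,Y_t)
    "xi": np.array([0.0, 0.5, 0.1, -1.0, -0.1, 1.0]),  # A_t | (1,O,A,OA,O_t,Y_t)
    "beta": np.array([0.1, 0.0, 0.1, -0.5, -0.5, 0.1]),  # Y | (Y_t,1,O,A,OA,O_t)
    "gamma": np.array([1.0, 0.25, 0.5]),             # A_t interaction | (1,A_{t-1},O_t)
    "var_y": 2.0,
    "var_o": 2.0,
}


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulated study.

    Parameters
    ----------
    setting : {"continuous2", "ehr2", "generalT"}
    T : number of treatment stages (2 unless ``setting == "generalT"``).
    n_labeled, N_unlabeled : sizes of the labelled / unlabelled samples.
    misspec_q : outcome-model mis-specification dial (0 = correct).
    misspec_pi : propensity-model mis-specification dial (0 = correct).
    surrogate_noise : sd of the additive surrogate noise Z_t (continuous /
        generalT settings).
    seed : base seed for the generator.
    """

    setting: str = "continuous2"
    T: int = 2
    n_labeled: int = 135
    N_unlabeled: int = 1272
    misspec_q: float = 0.0
    misspec_pi: float = 0.0
    surrogate_noise: float = 1.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        """Load a configuration from a YAML mapping of the field names."""
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        import yaml
        from dataclasses import asdict
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def __post_init__(self):
        if self.setting not in SETTINGS:
            raise ValueError(f"unknown setting {self.setting!r}")
        if self.setting != "generalT" and self.T != 2:
            raise ValueError(f"setting {self.setting!r} requires T=2")
        if self.T < 2:
            raise ValueError("T must be >= 2")
        if self.surrogate_noise <= 0:
            raise ValueError("surrogate_noise must be positive")
        if self.n_labeled + self.N_unlabeled <= 0:
            raise ValueError("need at least one subject")


@dataclass
class TrajectorySet:
    """Per-subject stage-wise records with a labelled/unlabelled split.

    ``O[t]``, ``W[t]`` are (n, d) arrays for stages t = 1..T; ``A[t]`` are
    (n,) arrays in {0,1}; ``Y[t]`` for t = 2..T+1 hold outcomes with NaN on
    unlabelled subjects.  Masking only hides outcomes; covariates, treatments
    and surrogates are always observed.
    """

    setting: str
    T: int
    O: dict
    A: dict
    W: dict
    Y: dict
    labeled: np.ndarray
    clip_rate: float = 0.0

    @property
    def n_subjects(self) -> int:
        return self.labeled.shape[0]

    @property
    def n_labeled(self) -> int:
        return int(self.labeled.sum())

    def subset(self, idx) -> "TrajectorySet":
        return TrajectorySet(
            self.setting,
            self.T,
            {t: v[idx] for t, v in self.O.items()},
            {t: v[idx] for t, v in self.A.items()},
            {t: v[idx] for t, v in self.W.items()},
            {t: v[idx] for t, v in self.Y.items()},
            self.labeled[idx].copy(),
            self.clip_rate,
        )

    def to_frame(self) -> pd.DataFrame:
        cols = {"labeled": self.labeled.astype(int)}
        for t in range(1, self.T + 1):
            for j in range(self.O[t].shape[1]):
                cols[f"O{t}_{j + 1}"] = self.O[t][:, j]
            cols[f"A{t}"] = self.A[t]
            for j in range(self.W[t].shape[1]):
                cols[f"W{t}_{j + 1}"] = self.W[t][:, j]
            cols[f"Y{t + 1}"] = self.Y[t + 1]
        df = pd.DataFrame(cols)
        df.index.name = "subject_id"
        return df


def _frame_block(df, prefix):
    names = sorted(
        (c for c in df.columns if c.startswith(prefix + "_")),
        key=lambda c: int(c.split("_")[-1]),
    )
    return df[names].to_numpy(dtype=float)


def read_csv(path, setting="continuous2") -> TrajectorySet:
    """Read a wide trajectory CSV written by :func:`write_csv`."""
    df = pd.read_csv(path, index_col="subject_id")
    T = max(int(c[1:].split("_")[0]) for c in df.columns if c.startswith("O"))
    O = {t: _frame_block(df, f"O{t}") for t in range(1, T + 1)}
    W = {t: _frame_block(df, f"W{t}") for t in range(1, T + 1)}
    A = {t: df[f"A{t}"].to_numpy(dtype=float) for t in range(1, T + 1)}
    Y = {t + 1: df[f"Y{t + 1}"].to_numpy(dtype=float) for t in range(1, T + 1)}
    labeled = df["labeled"].to_numpy(dtype=bool)
    return TrajectorySet(setting, T, O, A, W, Y, labeled)


def write_csv(traj: TrajectorySet, path) -> None:
    """Write a wide CSV; missing outcomes become empty cells."""
    traj.to_frame().to_csv(path)


# ---------------------------------------------------------------------------
# sequential generation
# ---------------------------------------------------------------------------

def _draw_actions(rng, prob, policy_fn, stage, history):
    if policy_fn is None:
        return rng.binomial(1, prob).astype(float)
    return policy_fn(stage, history).astype(float)


def _gen_continuous2(cfg, n, rng, policy_fn=None):
    p = CONTINUOUS2
    O1 = rng.binomial(1, 0.5, n).astype(float)
    A1 = _draw_actions(rng, _sigmoid(p["xi1"][0] + p["xi1"][1] * O1), policy_fn, 1,
                       {"O1": O1})
    m_y2 = p["theta1"] @ np.array([np.ones(n), O1, A1, A1 * O1])
    Y2 = m_y2 + rng.normal(0, np.sqrt(p["var_y2"]), n)
    D = np.array([np.ones(n), O1, A1, O1 * A1])
    O2 = p["delta"] @ D + rng.normal(0, np.sqrt(p["var_o2"]), n)
    H20 = np.column_stack([np.ones(n), O1, A1, O1 * A1, O2])
    lin_a2 = H20 @ p["xi2"] + cfg.misspec_pi * O2 ** 2
    A2 = _draw_actions(rng, _sigmoid(lin_a2), policy_fn, 2,
                       {"O1": O1, "A1": A1, "O2": O2})
    H21 = np.column_stack([np.ones(n), A1, O2])
    m_y3 = (
        p["beta2"][0] * Y2
        + H20 @ p["beta2"][1:]
        + A2 * (H21 @ p["gamma2"])
        + cfg.misspec_q * O2 ** 2 * Y2 * np.sin(1.0 / (O2 ** 2 * Y2 + 1.0))
    )
    Y3 = m_y3 + rng.normal(0, np.sqrt(p["var_y3"]), n)
    sz = cfg.surrogate_noise
    W1 = np.trunc(Y2 + rng.normal(0, sz, n))[:, None]
    W2 = np.trunc(Y3 + rng.normal(0, sz, n))[:, None]
    return TrajectorySet(
        cfg.setting, 2,
        {1: O1[:, None], 2: O2[:, None]},
        {1: A1, 2: A2},
        {1: W1, 2: W2},
        {2: Y2, 3: Y3},
        np.ones(n, dtype=bool),
    )


def _gen_ehr2(cfg, n, rng, policy_fn=None):
    p = EHR2
    O1 = rng.normal(0, 1, (n, 6))
    H10 = np.column_stack([np.ones(n), O1])
    A1 = _draw_actions(rng, _sigmoid(H10[:, :4] @ p["xi1"]), policy_fn, 1,
                       {"O1": O1})
    H11 = np.column_stack([np.ones(n), O1[:, 1:]])
    pr_y2 = _sigmoid(H10 @ p["beta1"] + A1 * (H11 @ p["gamma1"]))
    Y2 = rng.binomial(1, pr_y2).astype(float)
    Z = O1[:, :2] * p["delta_z"] + rng.normal(0, 1, (n, 2))
    O2bin = (Z > 0).astype(float)
    H20 = np.column_stack([np.ones(n), O1, A1, Z])
    scale = cfg.misspec_pi / np.sqrt(2.0)
    pr_a2 = _sigmoid(H20[:, :6] @ p["xi2"] + scale * O2bin.sum(axis=1))
    A2 = _draw_actions(rng, pr_a2, policy_fn, 2,
                       {"O1": O1, "A1": A1, "Z": Z, "O2bin": O2bin})
    H21 = np.column_stack([np.ones(n), O1[:, :4], A1, Z])
    qscale = cfg.misspec_q / np.sqrt(2.0)
    m_y3 = (
        p["beta21"] * Y2
        + H20 @ p["beta22"]
        + A2 * (H21 @ p["gamma2"])
        + qscale * O2bin.sum(axis=1) * Y2
        * np.sin((O2bin ** 2).sum(axis=1) / (Y2 + 1.0))
    )
    clip_rate = float(np.mean((m_y3 < 0) | (m_y3 > 1)))
    Y3 = rng.binomial(1, np.clip(m_y3, 0.0, 1.0)).astype(float)
    dw = p["d_w"]
    a = p["alpha"]
    W1 = a[0] + a[1] * A1[:, None] + a[2] * Y2[:, None] + rng.normal(0, 1, (n, dw))
    W2 = a[0] + a[1] * A2[:, None] + a[2] * Y3[:, None] + rng.normal(0, 1, (n, dw))
    return TrajectorySet(
        cfg.setting, 2,
        {1: O1, 2: np.column_stack([O2bin, Z])},
        {1: A1, 2: A2},
        {1: W1, 2: W2},
        {2: Y2, 3: Y3},
        np.ones(n, dtype=bool),
        clip_rate,
    )


def _gen_generalT(cfg, n, rng, policy_fn=None):
    p = GENERALT
    T = cfg.T
    O = {}
    A = {}
    Y = {}
    W = {}
    O1 = rng.binomial(1, 0.5, n).astype(float)
    O[1] = O1
    A[1] = _draw_actions(rng, _sigmoid(p["xi1"][0] + p["xi1"][1] * O1), policy_fn, 1,
                         {"O": O, "A": A, "Y": Y})
    m_y2 = p["theta1"] @ np.array([np.ones(n), O1, A[1], A[1] * O1])
    Y[2] = m_y2 + rng.normal(0, 1.0, n)
    sz = cfg.surrogate_noise
    W[1] = np.trunc(Y[2] + rng.normal(0, sz, n))[:, None]
    for t in range(2, T + 1):
        Op, Ap, Yt = O[t - 1], A[t - 1], Y[t]
        ones = np.ones(n)
        O[t] = p["delta"] @ np.array([ones, Op, Ap, Op * Ap, Yt]) \
            + rng.normal(0, np.sqrt(p["var_o"]), n)
        lin_a = p["xi"] @ np.array([ones, Op, Ap, Op * Ap, O[t], Yt]) \
            + cfg.misspec_pi * np.sin(O[t] ** 2)
        A[t] = _draw_actions(rng, _sigmoid(lin_a), policy_fn, t,
                             {"O": O, "A": A, "Y": Y})
        m_y = (
            p["beta"] @ np.array([Yt, ones, Op, Ap, Op * Ap, O[t]])
            + A[t] * (p["gamma"] @ np.array([ones, Ap, O[t]]))
            + cfg.misspec_q * O[t] ** 2 * Yt * np.sin(1.0 / (O[t] ** 2 * Yt + 1.0))
        )
        Y[t + 1] = m_y + rng.normal(0, np.sqrt(p["var_y"]), n)
        W[t] = np.trunc(Y[t + 1] + rng.normal(0, sz, n))[:, None]
    return TrajectorySet(
        cfg.setting, T,
        {t: (O[t][:, None] if O[t].ndim == 1 else O[t]) for t in O},
        A, W, Y,
        np.ones(n, dtype=bool),
    )


_GENERATORS: dict[str, Callable] = {
    "continuous2": _gen_continuous2,
    "ehr2": _gen_ehr2,
    "generalT": _gen_generalT,
}


def simulate(config: SimConfig, policy=None) -> TrajectorySet:
    """Draw ``n_labeled + N_unlabeled`` iid trajectories and mask outcomes.

    Outcomes are generated for every subject and then hidden (set to NaN) on a
    uniformly random unlabelled subset, i.e. labelling is missing completely
    at random by design.  If ``policy`` is given (a :class:`features.Policy`),
    every treatment is overridden by the policy's decision instead of the
    behavioural treatment model.
    """
    rng = np.random.default_rng(config.seed)
    n_tot = config.n_labeled + config.N_unlabeled
    policy_fn = None if policy is None else policy.as_generation_rule(config.setting)
    traj = _GENERATORS[config.setting](config, n_tot, rng, policy_fn)
    return _mask(traj, config.n_labeled, rng)


def _mask(traj: TrajectorySet, n_keep: int, rng) -> TrajectorySet:
    n = traj.n_subjects
    keep = np.zeros(n, dtype=bool)
    keep[rng.permutation(n)[:n_keep]] = True
    traj.labeled = keep
    for t in traj.Y:
        y = traj.Y[t].copy()
        y[~keep] = np.nan
        traj.Y[t] = y
    return traj


def split_labeled(traj: TrajectorySet, n: int, seed: int) -> TrajectorySet:
    """Re-draw the labelled subset: keep outcomes on ``n`` random subjects.

    Requires a fully labelled input (no NaN outcomes); raises if ``n`` is not
    in ``1..n_subjects``.
    """
    if n <= 0 or n > traj.n_subjects:
        raise ValueError(f"n must be in 1..{traj.n_subjects}, got {n}")
    if any(np.isnan(v).any() for v in traj.Y.values()):
        raise ValueError("split_labeled needs fully observed outcomes")
    out = traj.subset(np.arange(traj.n_subjects))
    return _mask(out, n, np.random.default_rng(seed))


def true_value_mc(config: SimConfig, policy, n_mc: int, seed: int) -> float:
    """Monte-Carlo value of ``policy``: mean of Y_2 + ... + Y_{T+1} under the
    regime (treatments forced to the policy's decisions).  With ``policy is
    None`` no override happens and the behavioural value is returned.
    The standard error is O(n_mc^{-1/2})."""
    cfg = replace(config, n_labeled=n_mc, N_unlabeled=0, seed=seed)
    rng = np.random.default_rng(seed)
    policy_fn = None if policy is None else policy.as_generation_rule(config.setting)
    traj = _GENERATORS[config.setting](cfg, n_mc, rng, policy_fn)
    total = sum(traj.Y[t] for t in range(2, config.T + 2))
    return float(np.mean(total))
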