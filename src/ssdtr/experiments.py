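"""Replication harness: bias / ESE / ASE / coverage / relative efficiency.

Runs repeated simulate-fit cycles for a study configuration, fitting the
supervised and semi-supervised estimators on each replication, and
summarises the usual Monte-Carlo operating characteristics against oracle
targets (the population working-model solution theta-bar from a mega-sample
fit, and the true policy value from a Monte-Carlo rollout).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .dgp import SimConfig, simulate, true_value_mc
from .features import build_designs
from .impute import assign_folds, make_learner
from .propensity import fit_all_propensities
from .qlearn_sup import backward_fit_sup, variance_sup
from .qlearn_ssl import backward_fit_ssl, impute_for_qlearning, variance_ssl
from .value import fit_value_imputations, value_dr_T, value_ssl_dr, value_sup_dr

__all__ = ["oracle_theta", "oracle_value", "run_replications", "summarize",
           "report_tables"]


def oracle_theta(config: SimConfig, n_oracle: int = 10 ** 6,
                 seed: int = 12345) -> dict:
    """Population working-model solution theta-bar via one huge supervised
    fit (the mis-specification regime of ``config`` is honoured)."""
    cfg = replace(config, n_labeled=n_oracle, N_unlabeled=0, seed=seed)
    designs = build_designs(simulate(cfg))
    return backward_fit_sup(designs).theta


def oracle_value(config: SimConfig, policy, n_mc: int = 10 ** 6,
                 seed: int = 54321) -> float:
    """True value of ``policy`` by Monte-Carlo rollout."""
    return true_value_mc(config, policy, n_mc, seed)


def _gamma_rows(fit, designs, estimator, rep, with_ase):
    rows = []
    for t in fit.theta:
        gam = fit.gamma(t)
        if with_ase and fit.cov:
            q = fit.n_y[t] + fit.p0[t]
            ses = fit.se(t)[q:]
        else:
            ses = np.full(gam.size, np.nan)
        for j, (g, s) in enumerate(zip(gam, ses), start=1):
            rows.append({"rep": rep, "quantity": f"gamma{t}_{j}",
                         "estimator": estimator, "estimate": g, "ase": s})
    return rows


def run_replications(config: SimConfig, reps: int, seed: int,
                     learner: str = "forest", n_trees: int = 100,
                     K: int = 5, do_value: bool = False,
                     do_variance: bool = True,
                     projection: str = "all") -> pd.DataFrame:
    """Replicated simulate-and-fit runs.

    Returns one tidy frame with per-replication estimates (and estimated
    SEs where available) for every treatment-interaction coefficient and,
    with ``do_value``, the supervised and SSL doubly robust value
    estimates.  Failures in individual replications are recorded and
    skipped; the failure count is attached as ``df.attrs['failures']``.
    """
    rows = []
    failures = 0
    for rep in range(reps):
        rep_seed = seed + rep
        try:
            rows.extend(_one_rep(config, rep, rep_seed, learner, n_trees, K,
                                 do_value, do_variance, projection))
        except Exception:
            failures += 1
    df = pd.DataFrame(rows)
    df.attrs["failures"] = failures
    return df


def _one_rep(config, rep, rep_seed, learner, n_trees, K, do_value,
             do_variance, projection):
    cfg = replace(config, seed=rep_seed)
    traj = simulate(cfg)
    designs = build_designs(traj)
    two_stage = designs.T == 2

    sup = backward_fit_sup(designs)
    if two_stage and do_variance:
        sup = variance_sup(designs, sup)
    folds = assign_folds(designs.labeled.sum(), K, rep_seed)
    lrn = make_learner(learner, seed=rep_seed, n_trees=n_trees)
    imps = impute_for_qlearning(designs, lrn, K=K, seed=rep_seed, folds=folds)
    ssl = backward_fit_ssl(designs, imps, projection=projection)
    if two_stage and do_variance:
        ssl = variance_ssl(designs, ssl, imps)

    with_ase = two_stage and do_variance
    rows = _gamma_rows(sup, designs, "sup", rep, with_ase)
    rows += _gamma_rows(ssl, designs, "ssl", rep, with_ase)

    if do_value:
        pifit = fit_all_propensities(designs)
        if two_stage:
            v_sup = value_sup_dr(designs, sup, pifit)
            impv = fit_value_imputations(designs, ssl, pifit, lrn, K=K,
                                         seed=rep_seed, folds=folds)
            v_ssl = value_ssl_dr(designs, ssl, pifit, impv,
                                 projection=projection)
        else:
            v_sup = value_dr_T(designs, sup, pifit, variant="sup")
            v_ssl = value_dr_T(designs, ssl, pifit, learner=lrn, K=K,
                               seed=rep_seed, folds=folds, variant="ssl",
                               projection=projection)
        rows.append({"rep": rep, "quantity": "value", "estimator": "sup",
                     "estimate": v_sup.estimate, "ase": v_sup.se})
        rows.append({"rep": rep, "quantity": "value", "estimator": "ssl",
                     "estimate": v_ssl.estimate, "ase": v_ssl.se})
    return rows


def summarize(df: pd.DataFrame, targets: dict) -> pd.DataFrame:
    """Per-quantity operating characteristics.

    bias = mean estimate - target; ESE = SD across replications; ASE = mean
    estimated SE; CovP = fraction of 95% Wald intervals covering the target;
    RE = supervised ESE / SSL ESE.
    """
    recs = []
    for (quantity, estimator), grp in df.groupby(["quantity", "estimator"]):
        tgt = targets.get(quantity, np.nan)
        est = grp["estimate"].to_numpy()
        ase = grp["ase"].to_numpy()
        cov = np.nan
        if np.isfinite(ase).all() and np.isfinite(tgt):
            cov = float(np.mean((est - 1.96 * ase <= tgt)
                                & (tgt <= est + 1.96 * ase)))
        recs.append({
            "quantity": quantity, "estimator": estimator, "target": tgt,
            "bias": float(np.mean(est) - tgt) if np.isfinite(tgt) else np.nan,
            "ese": float(np.std(est, ddof=1)),
            "ase": (float(np.nanmean(ase))
                    if np.isfinite(ase).any() else np.nan),
            "covp": cov, "reps": len(grp),
        })
    out = pd.DataFrame(recs)
    wide = out.pivot(index="quantity", columns="estimator", values="ese")
    if {"sup", "ssl"} <= set(wide.columns):
        re = (wide["sup"] / wide["ssl"]).rename("re")
        out = out.merge(re, on="quantity", how="left")
        out.loc[out["estimator"] == "sup", "re"] = np.nan
    return out.sort_values(["quantity", "estimator"]).reset_index(drop=True)


def report_tables(summary: pd.DataFrame) -> str:
    """Deterministic text rendering of a summary frame."""
    cols = ["quantity", "estimator", "target", "bias", "ese", "ase", "covp",
            "re"]
    present = [c for c in cols if c in summary.columns]
    return summary[present].to_string(index=False, float_format="%.3f")
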