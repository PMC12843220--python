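import numpy as np
import pytest

from ssdtr import (SimConfig, assign_folds, backward_fit_ssl, backward_fit_sup,
                   build_designs, fit_all_propensities, impute_for_qlearning,
                   make_learner, simulate, variance_ssl, variance_sup)


@pytest.fixture(scope="session")
def cont_small():
    """One small continuous-setting study: 135 labelled, 1272 unlabelled."""
    cfg = SimConfig(setting="continuous2", n_labeled=135, N_unlabeled=1272,
                    seed=42)
    traj = simulate(cfg)
    return cfg, traj


@pytest.fixture(scope="session")
def cont_designs(cont_small):
    _, traj = cont_small
    return build_designs(traj)


@pytest.fixture(scope="session")
def sup_fit(cont_designs):
    return variance_sup(cont_designs, backward_fit_sup(cont_designs))


@pytest.fixture(scope="session")
def cont_folds(cont_designs):
    return assign_folds(int(cont_designs.labeled.sum()), 5, 42)


@pytest.fixture(scope="session")
def cont_imps(cont_designs, cont_folds):
    lrn = make_learner("forest", seed=42, n_trees=100)
    return impute_for_qlearning(cont_designs, lrn, K=5, seed=42,
                                folds=cont_folds)


@pytest.fixture(scope="session")
def ssl_fit(cont_designs, cont_imps):
    return variance_ssl(cont_designs,
                        backward_fit_ssl(cont_designs, cont_imps), cont_imps)


@pytest.fixture(scope="session")
def pi_fit(cont_designs):
    return fit_all_propensities(cont_designs)


@pytest.fixture(scope="session")
def cont_oracle():
    """Population working-model solution for the correctly specified
    continuous setting, from one mega-sample supervised fit (frozen seed)."""
    from ssdtr import oracle_theta
    cfg = SimConfig(setting="continuous2", n_labeled=135, N_unlabeled=1272)
    return oracle_theta(cfg, n_oracle=10 ** 6, seed=99)


def rng(seed=0):
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# replication batches shared by the Monte-Carlo oracle and acceptance tests
# (scaled to desk size: rep counts below keep the whole suite within a
# practical run time; the methods note states the sizes used)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def batch_small_rf():
    """(n, N) = (135, 1272), forest imputation (reduced-tree mode), 150 reps,
    Q-learning + DR values with variances."""
    from ssdtr import run_replications
    cfg = SimConfig(setting="continuous2", n_labeled=135, N_unlabeled=1272)
    return run_replications(cfg, reps=150, seed=7000, learner="forest",
                            n_trees=100, do_value=True)


@pytest.fixture(scope="session")
def batch_large_spline():
    """(n, N) = (500, 10000), natural-spline imputation, 150 reps, Q only."""
    from ssdtr import run_replications
    cfg = SimConfig(setting="continuous2", n_labeled=500, N_unlabeled=10000)
    return run_replications(cfg, reps=150, seed=8000, learner="spline",
                            do_value=False)


@pytest.fixture(scope="session")
def batch_t3():
    """T = 3, (n, N) = (1000, 15000), forest imputation, 60 reps."""
    from ssdtr import run_replications
    cfg = SimConfig(setting="generalT", T=3, n_labeled=1000,
                    N_unlabeled=15000)
    return run_replications(cfg, reps=60, seed=9000, learner="forest",
                            n_trees=100, do_value=True, do_variance=False)


@pytest.fixture(scope="session")
def cont_value_oracle(cont_oracle):
    """True value of the population regime in the continuous setting."""
    from ssdtr import oracle_value
    from ssdtr.features import Policy
    cfg = SimConfig(setting="continuous2")
    pol = Policy({1: cont_oracle[1][2:], 2: cont_oracle[2][6:]})
    return oracle_value(cfg, pol, n_mc=10 ** 6, seed=77)
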