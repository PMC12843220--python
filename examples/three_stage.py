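"""Three-stage regimes: backward recursion and telescoping DR value.

The general-horizon machinery imputes O(T^2) linear and quadratic outcome
functionals (every mu_s and mu_rs the stage-wise normal equations need) and
reduces exactly to the two-stage pipeline at T = 2.
"""

from ssdtr import (SimConfig, backward_fit_ssl, backward_fit_sup,
                   build_designs, fit_all_propensities, impute_for_qlearning,
                   make_learner, simulate, value_dr_T)

cfg = SimConfig(setting="generalT", T=3, n_labeled=1000, N_unlabeled=15000,
                seed=21)
designs = build_designs(simulate(cfg))

sup = backward_fit_sup(designs)
lrn = make_learner("forest", seed=21, n_trees=100)
imps = impute_for_qlearning(designs, lrn, K=5, seed=21)
ssl = backward_fit_ssl(designs, imps)

print("treatment-interaction coefficients per stage (sup | ssl):")
for t in (1, 2, 3):
    print(f"  stage {t}: {sup.gamma(t).round(3)} | {ssl.gamma(t).round(3)}")

pifit = fit_all_propensities(designs)
v_sup = value_dr_T(designs, sup, pifit, variant="sup")
v_ssl = value_dr_T(designs, ssl, pifit, learner=lrn, K=5, seed=21,
                   variant="ssl")
print(f"DR value: supervised {v_sup.estimate:.3f} (SE {v_sup.se:.3f})  "
      f"SSL {v_ssl.estimate:.3f} (SE {v_ssl.se:.3f})")
# Imputation counts grow quadratically in T but stay linear/quadratic in
# the missing outcomes, so the same cross-fit + refit machinery applies.
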