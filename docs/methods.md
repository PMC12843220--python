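# Methods

## Problem and estimands

We observe a longitudinal two-stage (generally T-stage) observational study.
At stage t a patient presents covariates O_t, receives a binary treatment
A_t ∈ {0,1}, and later exhibits an outcome Y_{t+1} (larger is better) plus a
vector of post-treatment surrogates W_t that are predictive of Y_{t+1}
through the joint law but not part of the target conditional model.  The
outcomes are expensive to annotate (chart review), so they are observed only
on a small random subsample ℒ of size n; a much larger sample 𝒰 of size
N ≫ n carries everything except the outcomes.  Labelling is missing
completely at random by design, but the labelling fraction n/(n+N) → 0, so
classical missing-data positivity fails and inverse-labelling weighting is
not an option.

Two estimands:

1. the optimal linear dynamic treatment regime (DTR) within the working
   model class — stage rules d_t(H_t) = I(H_t1'γ_t > 0) obtained from
   linear Q-functions; and
2. its value V̄, the expected cumulative outcome E[Y_2 + ... + Y_{T+1}] if
   the population were treated by the learned regime.

Identification is by the standard sequential-causal assumptions:
consistency, sequential ignorability given the stage history, and
positivity of the behavioural treatment probabilities.

## Q-learning with working linear models

With features X_t = (H_t0', A_t H_t1')' and X̌_t prepending the previously
observed outcomes (X̌_1 = X_1, X̌_2 = (Y_2, X_2')'), the supervised backward
recursion solves stage-wise least-squares normal equations:

    P_n[ X̌_2 (Y_3 − X̌_2'θ_2) ] = 0,
    P_n[ X_1 (Y_2(1+β_21) + H_20'β_22 + [H_21'γ_2]_+ − X_1'θ_1) ] = 0,

where [x]_+ = x·I(x>0) and (β_21, β_22, γ_2) partition θ_2.  If the working
models are mis-specified, θ̄ is defined as the population solution of the
same equations (the L² projection onto the linear class); all inference
targets θ̄, so confidence statements remain valid under mis-specification.
Ties H_t1'γ = 0 map to action 0 — a fixed deterministic rule; ties are a
null event when H_t1 contains a continuous covariate.

## The semi-supervised estimator

Three steps make the same normal equations computable on ℒ ∪ 𝒰:

1. **Imputation.**  Flexible regressions of each needed outcome functional
   on the full surrogate-augmented history U = (O_1, A_1, W_1, ..., O_T,
   A_T, W_T), trained on K = 5 labelled folds leaving one out at a time.
   For T = 2 the targets are the conditional means of Y_2, Y_3, Y_2²,
   Y_2Y_3.
2. **Refitting.**  Each cross-fitted imputation is augmented with a linear
   correction solving, e.g. for Y_2,
   Σ_k Σ_{i∈fold k} X→_i (Y_{2i} − m̂_2^{(−k)}(U_i) − η_2'X→_i) = 0 with
   X→ = (1, X_1', X_2')'; quadratic targets get scalar offsets.  These
   moment constraints are exactly the ones the projection step needs, so
   the downstream estimator is consistent for θ̄ *even when the imputation
   models are arbitrarily wrong* — a constant-prediction learner is
   repaired by the refit (tested).
3. **Projection.**  The stage-2 equations with (Y_2, Y_3, Y_2², Y_2Y_3)
   replaced by (μ̂_2, μ̂_3, μ̂_22, μ̂_23) are linear in θ_2 and are solved
   over the projection sample as one stacked (1+p)-dimensional system;
   stage 1 regresses the imputed pseudo-outcome
   μ̂_2(1+β̂_21) + H_20'β̂_22 + [H_21'γ̂_2]_+ on X_1.

The projection set defaults to ℒ ∪ 𝒰 (all N+n subjects); a switch restricts
it to 𝒰.  With N ≫ n the two agree to O(n/N).

**Variance.**  The estimators are asymptotically linear with influence
functions driven purely by *imputation residuals* — e.g. the stage-2
γ-block score is H_21 A_2 [(Y_3 − μ̄_3) − β̄_21 (Y_2 − μ̄_2)] — so the more
the surrogates explain the outcomes, the smaller the sandwich variance;
with uninformative surrogates the SSL estimator matches (never trails) the
supervised one.  The bread is Σ̂_t = P_n[X̌_t X̌_t'] over labelled rows (an
exposed switch uses X_t instead; the two differ only through the observed
Y_2 column), and the meat is the sample-split estimate
n⁻¹ Σ_k Σ_{i∈fold k} ψ̂^{(−k)}ψ̂^{(−k)}', evaluating fold-k subjects with the
out-of-fold learners.  Stage 1 adds plug-in terms
P_n[X_1(Y_2, H_20')]·φ_β2 and P_n[X_1H_21' I(H_21'γ̂_2>0)]·φ_γ2 that
propagate the stage-2 estimation error through the pseudo-outcome; the
supervised sandwich uses the same structure with raw residuals in place of
imputation residuals (the package's construction; validated by ASE/ESE
agreement within 15% in Monte Carlo).  If more than 5% of labelled subjects
sit within 1e−8 of the stage-2 decision boundary a non-fatal warning about
near-degenerate treatment effects is emitted.

## Doubly robust value estimation

Propensities π_t = σ(Ȟ_t0'ξ_t) are logistic MLEs on labelled data (the
stage-2 design contains Y_2); predicted probabilities are clamped to
[1e−6, 1−1e−6] before weighting, and an optional closed-interval trim
(e.g. [0.1, 0.9]) flags poor-overlap subjects.  Under separation the fit
falls back to a small-ridge penalised IRLS.

With cumulative policy-matching weights
ω_t = Π_{s≤t} [d_s A_s/π̂_s + (1−d_s)(1−A_s)/(1−π̂_s)], the supervised DR
estimator is the telescoping augmentation

    V̂_SUPDR = P_n[ Q_1ᵒ + Σ_t ω_t (Y_{t+1} + Q_{t+1}ᵒ − Q_tᵒ) ],

(Q_tᵒ = Q_t at the rule's own action, Q_{T+1}ᵒ ≡ 0), consistent if either
the Q-models or the propensity models are correct, and exactly equal per
subject to its stage-2-decomposed rewriting (asserted at machine
precision).  The SSL variant rewrites the summand so the unobservables are
the atoms Y_2, ω_t, and Y_sω_t, imputes each atom by the same cross-fit +
refit machinery (weighted scalar refits: the Y_2 equation weighted by ω_1,
the lone-ω_t equation by its observable coefficient, the products plain
means), and projects the augmented summand onto ℒ ∪ 𝒰.  With oracle
imputations on the labelled set it reproduces V̂_SUPDR exactly (identity
test).

**Value variance.**  The influence expansion replaces the policy
indicators with a sigmoid kernel K_h(x) = σ(x/h) so the derivative
corrections for the estimated (θ, ξ) exist; those derivatives are computed
analytically (all terms written out in `value._smoothed_gradient`) and
contracted with the influence functions of θ̂ (sandwich above) and ξ̂
(logistic MLE).  The bandwidth default is h = 0.9·sd(H_t1'γ̂_t)·n^{−1/5}
per stage — vanishing in n so the smoothed weights converge to the exact
ones, scaled to keep them stable at n in the hundreds; it is exposed as an
argument.  As h → 0 the smoothed weights converge pointwise to the raw
weights off the decision boundary (tested).  For T > 2 the reported SE
uses the residual (ν) part of the expansion only; the T = 3 operating
characteristics reported here (ESE, RE) do not depend on it.

## General horizon T

At stage t the projection needs E[Y_s | U] for s = 2..T+1 and
E[Y_r Y_s | U] for r ≤ T — O(T²) targets, each linear or quadratic in the
missing outcomes.  The refit design for Y_s is (1, X_{s−1}, ..., X_T):
exactly the design blocks that multiply Y_s somewhere in the stage-wise
equations (for T = 2 this reproduces the canonical X→ for Y_2 and X_2 for
Y_3); products get scalar offsets.  The value telescoping needs ω_t and
Y_sω_t for s ≤ t+1.  Both recursions reduce to the two-stage pipeline at
T = 2 by an exact identity (tested).

## Imputation learners

* `forest`: scikit-learn RandomForestRegressor, 500 trees by default, with
  a reduced 100-tree mode for replication batches.  All targets of one run
  are fitted jointly as a multi-output forest per fold (targets
  standardised to training-fold mean/sd so no target dominates the split
  criterion).  Sharing the trees across targets cuts the fit count per
  replication by an order of magnitude; the refitting step corrects any
  per-target bias, and for linear-in-basis learners joint fitting is
  exactly equivalent to separate fits.
* `spline`: additive natural (restricted) cubic splines, two interior knots
  at the 33rd/67th training percentiles, boundary knots at the training
  range, binary inputs linear, ridge 1e−6 on the standardised basis.
  Natural splines are used rather than an unrestricted cubic basis because
  the unlabelled sample extends beyond the labelled range and cubic
  extrapolation there is catastrophic (observed: value-estimate ESEs an
  order of magnitude above the supervised ones); linear extrapolation is
  the standard cure.  Discrete inputs entering linearly is a choice the
  data cannot overrule — flagged for sensitivity analysis.

Fold assignment is one stratification-free shuffle from the run seed,
shared by every target and by the value imputations so the sample-split
variance sums are coherent.

## Synthetic data generators

Three seedable generators define the study conditions (coefficient vectors
in `dgp.CONTINUOUS2 / EHR2 / GENERALT`):

* **continuous2** — O1 ~ Bern(0.5); A1 ~ Bern(σ(0.3 − 0.5 O1));
  Y2 ~ N(1 + O1 + A1 − 2A1O1, 1); O2 ~ N((1,O1,A1,O1A1)'δ, 2);
  A2 ~ Bern(σ(H20'ξ2 + ξ26 O2²)); Y3 ~ N(m3, 2) with
  m3 = 0.1Y2 + H20'β22 + A2 H21'γ2 + β27 O2² Y2 sin{(O2²Y2+1)^{−1}};
  surrogates W_t = trunc(Y_{t+1} + Z_t), Z_t ~ N(0, σ_z²), trunc = integer
  part toward zero.
* **ehr2** — six Gaussian baseline covariates, binary outcomes, latent
  stage-2 scores Z_l = O_{1l} + ε with binarised indicators, 13- and
  19-dimensional stage designs, and bivariate surrogate panels
  W_t ~ N(1 + Y_{t+1}, I).  The stage-2 success probability is a linear
  predictor and is clipped to [0,1]; the clip rate is recorded on the
  trajectory set (≈0.9 under the default coefficients — the binary
  outcome model is intentionally crude) so the effect is auditable.
* **generalT** — the continuous design extended recursively: O_t, A_t and
  Y_{t+1} each depend on (O_{t−1}, A_{t−1}, O_t, Y_t), with the same
  sin-term mis-specification dial per stage.

Mis-specification dials (β27-type for outcomes, ξ26-type for treatment)
add highly non-linear terms no linear/logistic working model spans; 0
means correct specification.  σ_z,t defaults to 1 per stage.  Generation
is vectorised from a single seeded numpy Generator; identical
(setting, n, N, seed) yields identical tables (tested), which is the
reproducibility contract the replication harness needs — per-subject
counter streams were considered and rejected on the cost of 10⁶–10⁷
subject oracle runs.

The generators emulate scarce-label cohorts with informative post-treatment
surrogates and MCAR labelling.  They do not emulate: informative (MAR/MNAR)
labelling, measurement error in covariates, treatment non-adherence,
non-binary treatments, or the NLP-derived feature structure of real EHR
cohorts.  Passing tests therefore certify the estimators' statistical
behaviour under the stated sampling design, not robustness to those
real-data features.

## Oracle targets and operating characteristics

Bias/coverage targets come from the package's own oracles: θ̄ from one
n = 10⁶ supervised fit under the replication's mis-specification regime
(two independent mega-fits agree to ~2 decimals), and V̄ from ≥10⁶
Monte-Carlo policy rollouts.  The replication harness reports bias, ESE
(SD across replications), ASE (mean estimated SE), CovP (95% Wald
coverage), and RE = ESE_sup/ESE_ssl.

Reference tabulated values from the source study are reproduced where the
printed generative process supports them (regime values within ~5%,
coverage, efficiency orderings, T = 3 efficiency ratios).  Two reference
numbers are *not* reproducible from the printed process and the
discrepancy is documented in the acceptance tests rather than papered
over: the printed stage-2 population coefficients (0.8, 0.2, 0.5) differ
from the generative (1, 0.25, 0.5) even though the stage-2 working model
is exactly correctly specified (population OLS must return the generative
values), and correspondingly the printed regime value 6.08 differs from
the analytic/Monte-Carlo 6.40 of the printed process.  Our oracles define
the targets for bias and coverage purposes.

## Problem sizes used here

Replication batches run in reduced desk-scale modes: 200–600 replications
for the two-stage cells (150 in the test suite), 80 for T = 3 (60 in the
test suite), 100-tree forests, K = 5 throughout.  Monte-Carlo value oracles use 10⁶ rollouts
(SE ≈ 0.003).  The double-robustness grid runs at n = 1000 with the spline
learner, 50–60 replications per cell.

## Known limitations

* Sandwich variances are implemented for T = 2; T > 2 SEs use the ν-part
  of the expansion (point estimation and ESE-based comparisons are exact).
* The EHR generator's clipped linear probability model caps how well any
  working model can do; finite-sample bias there is visibly larger at
  n = 135 (matching the source study's observation).
* Propensity models are labelled-data MLEs; semi-supervised propensity
  estimation is out of scope.
* No A-learning/G-estimation, nonlinear Q-models, non-binary treatments,
  MAR labelling, or stabilised (weighted/MAGIC/IH-type) value estimators.
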