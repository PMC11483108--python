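# Methods

## Model and estimands

We assume the Neyman–Rubin potential-outcome framework for a two-arm trial:
each patient has potential outcomes `Y(+1)` and `Y(−1)`, of which only the
one matching the assigned arm `A ∈ {+1, −1}` is observed. With biomarkers
`X`, the observable regression decomposes as `E(Y|A,X) = Z(X)A + H(X)`,
where `Z(X)` is half the arm contrast and `H(X)` the prognostic main
effect. The package estimates a monotone transform `f(X)` of `Z(X)`;
`H(X)` is never estimated — the modified-loss construction removes it.

For a kernel `M(y, v)` that is (i) convex in `v` and (ii) has
`∂M/∂v |_{v=0}` monotone in `y`, both the A-learning loss
`L_A(f) = mean M(Yᵢ, cᵢ f(Xᵢ))`, `cᵢ = (Aᵢ+1)/2 − πᵢ`, and the
inverse-propensity weight-learning loss
`L_W(f) = mean wᵢ M(Yᵢ, Aᵢ f(Xᵢ))`, `wᵢ = 1/(Aᵢπᵢ + (1−Aᵢ)/2)`,
have population minimizers whose sign recovers the optimal rule
`sign(Z(X))` (Fisher consistency). The package verifies this empirically
(parameter-recovery simulations in the test suite); it does not reproduce
the theoretical proofs.

Kernels per endpoint:

- continuous: squared error `(v − y)²`;
- binary: Bernoulli negative log-likelihood with logit link,
  `log(1 + eᵛ) − yv`, computed with a stabilized log-sum-exp;
- survival: the modified Cox partial likelihood
  `−Σᵢ δᵢ 1(Zᵢ ≤ τ) (vᵢ − log Ê[eᵛ 1(Z ≥ Zᵢ)]) / N`, with the empirical
  risk-set mean over all patients, Breslow handling of ties (tied event
  times share the risk set `{j : Zⱼ ≥ Zᵢ}`), and a fixed horizon τ
  defaulting to the largest observed event time (τ must satisfy
  `P(Z ≥ τ) > 0`). Under weight-learning the weights multiply only the
  outer per-patient contribution by default; a
  `weight_inside_risk_set` switch moves them into the risk-set mean as
  well, since either convention is defensible.

A note on conventions: the binary kernel is stated here in the form that
satisfies both kernel conditions, and the weight-learning propensity
factor is applied as a divisor — i.e. genuine inverse-propensity weights,
`1/π` on the treated arm and `1/(1−π)` on controls — because a
multiplicative factor would down-weight rather than re-weight and would
break the equal-propensity identity `L_A(f) = L_W(f/2)/2` (continuous
case, π ≡ ½) that the tests assert exactly.

## Boosting

`fit_subgroup_model` trains an xgboost ensemble with the chosen composite
loss as a custom objective. The per-patient chain rule gives, with
multiplier `mᵢ = cᵢ` (A-learning) or `Aᵢ` (weight-learning) and outer
weight `uᵢ`:

- gradient `gᵢ = uᵢ mᵢ ∂M/∂v`, and
- diagonal curvature `hᵢ = uᵢ mᵢ² ∂²M/∂v²`,

exact for the continuous and binary kernels; the survival loss uses the
standard diagonal approximation `Σᵢ uᵢ δᵢ p_{ik}(1 − p_{ik})` with
`p_{ik}` the risk-set softmax weight, computed in O(N log N) by sorted
prefix sums. The curvature is floored at 1e−16 to keep the Newton step
defined. `loss_gradient` returns mean-scale derivatives (they match finite
differences of the mean loss directly); the boosting objective rescales
both by N so that the L2 leaf penalty λ acts on sum-scale statistics, the
convention the defaults below assume.

Default hyperparameters are the reference configuration for exploratory
subgroup search: learning rate 0.01, depth-1 stumps, λ = 5, 300 rounds,
histogram tree method. Training runs single-threaded with a fixed seed so
that refits are bit-identical. Early stopping is off by default (fixed
rounds); an optional validation split enables it. The training history
records the composite loss each round at full precision (the booster's own
evaluation log truncates to float32, so the history is recomputed in the
callback).

Sign conventions: for continuous and binary endpoints larger outcomes are
better, so `f̂ > 0` recommends treatment; the survival score is on the
log-hazard scale where benefit is a *lower* hazard, so `f̂ < 0` recommends
treatment. Both are overridable (`benefit_direction`). A score of exactly
zero carries no evidence of benefit and maps to control. Propensity scores
enter only through `cᵢ`/`wᵢ`; they are taken from the data (default 0.5,
a 1:1 randomized trial) or, on explicit request, estimated by logistic
regression — never silently. Categorical biomarkers are one-hot expanded
for fitting (importance re-aggregates the levels); missing numeric
biomarker values pass through to the trees' default-direction handling.

Importance is the ensemble's total split gain per biomarker, normalized to
sum to one, with split frequency reported alongside; ranks are dense by
descending gain.

## Cutoff and subgroup statistics

"Biomarker-positive" always means *strictly* meeting the direction
(`x > c` under `>`); values equal to the cutoff are negative. Rows missing
the analyzed biomarker are dropped and counted. Tests are two-sided; no
multiplicity adjustment is applied across candidate cutoffs (the intended
use is a small, pre-specified candidate list, as in companion-diagnostic
development), but the number of candidates is always visible in the
output. Selection maximizes Youden or kappa, or minimizes the association
p-value (Fisher exact for binary, Welch t for continuous, log-rank for
survival); p-value ties break toward the larger biomarker-positive group.
The Fisher exact p is the two-sided probability-mass definition, and the
test suite checks it against full hypergeometric enumeration.

Subgroup performance tables use scipy/statsmodels/lifelines for the
standard inferential machinery: Welch t and ANOVA, chi-square (Fisher for
sparse 2×2), Kaplan–Meier medians with lifelines' default log(−log)
confidence intervals, log-rank tests, and Cox models for hazard ratios
(Wald CIs on the log-HR). The treatment-by-group interaction p-value comes
from a single regression model — linear, logistic, or proportional
hazards by endpoint — containing group, arm, and group×arm (plus optional
linear adjusters), with a Wald test on the interaction coefficient; this
is the standard clinical convention. Cells with fewer than 2 patients per
arm are summarized but excluded from model-based contrasts. Degenerate
inputs (empty groups, all-censored groups, never-crossing KM curves)
produce flagged NA results rather than errors.

## Association diagnostics

ROC curves sweep all distinct thresholds (scikit-learn backend) with
trapezoidal AUC; `direction="auto"` orients the biomarker so AUC ≥ 0.5.
The eCDF is the usual right-continuous step function with exact
below/above fractions at any query cutoff.

The outcome and treatment-contrast smooths use a penalized cubic B-spline
authored in this package: exactly `k` basis functions (clamped cubic
B-splines, interior knots at quantiles; `k` reduced with a warning when
the distinct-value support is too small), a second-difference penalty on
the coefficients (so constants and straight lines are unpenalized), and a
penalty weight chosen by generalized cross-validation over a fixed
log-spaced grid; the logit link is fitted by penalized IRLS. Pointwise
bands are Wald bands from the sandwich covariance of the penalized fit.
Smooths are on the endpoint's natural link — identity, logit, or, for
survival, a Gaussian smooth of martingale residuals from a null
Nelson–Aalen model, the standard functional-form diagnostic. The contrast
curve is the arm(+1) smooth minus the arm(−1) smooth on a shared grid,
with variances added; it is exactly antisymmetric under arm relabeling.
Every plotting function first returns the plotted numbers; figures are
separate artifacts.

## Synthetic trials

The generator draws iid standard-normal biomarkers (optionally
exchangeably correlated, plus optional uniform categorical columns),
Bernoulli(π) arms, and outcomes from `E(Y|A,X) = h(X) + z(X)A` on the
natural scale: Gaussian noise (default sd 1) for continuous, logit for
binary, and exponential event times with rate `b·exp(h + zA)` for
survival, with independent exponential censoring whose rate is solved
numerically (Brent) so the expected censored fraction hits the target.
Effects `h` and `z` are serializable constant/linear/threshold specs, so
simulation settings are self-describing. The endpoint-aware benefit sign
(+1 iff `z > 0`, or `z < 0` on the hazard scale) lives in one function
used by both the generator and the tests, so generator and model can never
disagree about ground truth.

What the generator does *not* emulate: correlated biomarker blocks beyond
exchangeability, non-exponential baseline hazards, informative censoring,
measurement error, or missingness mechanisms. Passing recovery tests on
these trials therefore demonstrates correctness of the estimation
machinery under the stated generative model, not performance on any
particular real trial.

The built-in demonstration trial (`tutorial_fixture`) has 600 patients and
ten biomarkers, with `x1 ~ U(0,1)` driving a threshold effect at 0.5:
a binary response with a prognostic bump and a strong predictive benefit
only above the threshold, and a survival outcome where treatment lowers
the hazard only above it (~30% censoring). It is a synthetic emulation for
demonstrations and tests.

## Problem sizes and numerical choices

Simulation-based checks use N = 2000 (subgroup recovery), 20 replicates of
N = 1000 (importance ranking), 100 replicates of N = 800 (interaction
power/size), and N = 50 000 for generative-faithfulness bin checks —
sizes at which the Monte-Carlo error is comfortably below the asserted
margins while the whole suite runs in well under a minute of compute for
the statistical parts. Finite-difference gradient checks use central
differences with step 1e−6 and relative tolerance 1e−5; exact identities
are asserted at 1e−9 to 1e−12. CSV I/O uses pandas' round-trip float
parser so datasets survive write/load bit-for-bit.

## Known limitations

- Two arms only; no interval censoring, competing risks, or time-varying
  covariates.
- No Efron tie correction in the survival loss; no doubly-robust
  augmentation of the modified losses.
- No cross-fitting or post-selection inference on the value of the
  estimated rule; subgroup p-values are exploratory.
- The smoother's GCV can mildly undersmooth in small samples; the basis
  dimension `k` is the user's main control.
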