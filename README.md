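# itrboost

Individualized treatment rules and predictive biomarker analysis for
randomized two-arm clinical trials, built on gradient-boosted trees with
modified (main-effect-free) losses.

## The problem

In a two-arm trial the outcome model can be written

```
E(Y | A, X) = Z(X)·A + H(X),        A ∈ {+1, −1}
```

where `X` are baseline biomarkers, `H(X)` is the prognostic main effect and
`Z(X) = ½[E(Y|A=+1,X) − E(Y|A=−1,X)]` is the treatment contrast. The optimal
individualized treatment rule (ITR) treats exactly the patients with
`Z(X) > 0` — but fitting regression models with biomarker-by-treatment
interaction terms breaks down as the number of biomarkers grows.

`itrboost` instead estimates a monotone transform `f(X)` of `Z(X)` directly,
by minimizing one of two modified losses that make the main effect `H(X)`
drop out:

- **A-learning:** `L_A(f) = (1/N) Σᵢ M(Yᵢ, cᵢ f(Xᵢ))` with
  `cᵢ = (Aᵢ+1)/2 − π(Xᵢ)`,
- **weight-learning:** `L_W(f) = (1/N) Σᵢ wᵢ M(Yᵢ, Aᵢ f(Xᵢ))` with
  inverse-propensity weights `wᵢ = 1/(Aᵢπ(Xᵢ) + (1−Aᵢ)/2)`,

where `π(X) = P(A=+1|X)` is the propensity score (0.5 in a 1:1 randomized
trial) and `M(y, v)` is an endpoint-specific convex kernel:

| endpoint   | M(y, v) |
|------------|---------|
| continuous | `(v − y)²` |
| binary     | `log(1 + eᵛ) − y·v` |
| survival   | `−∫₀^τ (v − log Ê[eᵛ 1(Z ≥ u)]) dN(u)` (modified Cox partial likelihood, Breslow ties) |

Both losses are minimized over gradient-boosted regression trees (xgboost)
using exact analytic per-patient gradients and Hessians as a custom
objective. Thresholding the fitted score `f̂(X)` at zero gives the ITR;
the ensemble's split gains rank predictive biomarkers. The surrounding
toolkit covers candidate-cutoff selection (Youden, kappa, Fisher exact,
log-rank, two-sample tests), arm × biomarker-group performance tables with
interaction tests, ROC/eCDF diagnostics, and smoothed treatment-contrast
curves.

## Worked example

```python
import numpy as np
from itrboost import *
from itrboost.losses import LossConfig
from itrboost.cutoff_analysis import evaluate_cutoffs, dichotomize
from itrboost.subgroup_performance import subgroup_treatment_summary

ds = tutorial_fixture()            # 600 patients, biomarkers x1..x10, binary response
model = fit_subgroup_model(ds, LossConfig(ds.endpoint, A_LEARNING))
print(f"final modified loss: {model.history[-1]:.4f}")

rec = assign_subgroup(model, ds.X)
print(f"recommend treatment for {int((rec == 1).sum())} of {ds.n} patients")

imp = biomarker_importance(model)
print(imp.table.head(3).to_string(index=False))

results, cut = evaluate_cutoffs(ds, "x1", ds.endpoint, [0.1, 0.3, 0.5], ">", "fisher")
print(f"selected cutoff: x1 > {cut}")

group = np.where(dichotomize(ds.X["x1"].to_numpy(), cut, ">"),
                 "biomarker_positive", "biomarker_negative")
table = subgroup_treatment_summary(ds, group, ds.A, ds.endpoint)
print(table.cells.to_string(index=False))
print(f"interaction p = {table.interaction_p:.2e}")
```

Output:

```
final modified loss: 0.5737
recommend treatment for 316 of 600 patients
biomarker  gain_share  split_frequency  rank
       x1    0.967635         0.806667     1
       x4    0.018551         0.106667     2
       x5    0.010798         0.066667     3
selected cutoff: x1 > 0.5
             group       arm   n  responders     rate
biomarker_positive treatment 150         128 0.853333
biomarker_positive   control 166          35 0.210843
biomarker_negative treatment 152          45 0.296053
biomarker_negative   control 132          55 0.416667
interaction p = 2.15e-20
```

The demonstration trial has a predictive effect only above `x1 = 0.5`, and
the analysis recovers it end to end: `x1` dominates the importance ranking
(gain share 0.97), the Fisher-exact cutoff scan picks 0.5 from the three
candidates, the four-cell table shows treatment helping only the
biomarker-positive group (85% vs 21% response; 30% vs 42% in negatives),
and the treatment-by-group interaction is overwhelming.

The same pipeline is available from the shell:

```bash
itrboost workflow --out-dir results/demo          # built-in demo trial
itrboost workflow --config my_trial.yaml --seed 1 # your CSV + role config
```

with subcommands `simulate`, `fit`, `predict`, `subgroups`, `importance`,
`fixcut`, `cutperf`, `perf`, `roc`, `cdf`, `contrast` for individual steps.

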