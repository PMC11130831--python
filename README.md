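# mixedlink

Multinomial mixed-link models for ordinal risk prediction, built for
the gastric intestinal-metaplasia (IM) setting: predicting a
three-category tissue diagnosis — Normal, MIM (mild/low-risk IM), IM
(high-risk) — from an epigenetic mitotic-age score and gastric-atrophy
status.

## The model

Classical multinomial regressions (baseline-category, cumulative,
adjacent-categories, continuation-ratio logit models) force one link
function onto every category comparison.  A mixed-link model frees
that choice: for a J-category response,

```
g_j(rho_ij) = beta_0j + beta_j' x_i ,     j = 1, ..., J-1
```

where each `g_j` is its own link (logit, probit, loglog or cloglog)
and `rho_ij` is a ratio of category probabilities fixed by the
response structure — `pi_ij/(pi_ij + pi_iJ)` (baseline-category),
`pi_i1 + ... + pi_ij` (cumulative), `pi_ij/(pi_ij + pi_i,j+1)`
(adjacent-categories) or `pi_ij/(pi_ij + ... + pi_iJ)`
(continuation-ratio).  Proportional odds (`po`) shares one slope
vector across comparisons; `npo` gives each comparison its own.  With
all-logit links the four classical families fall out as special
cases.

Around the core estimator the package provides

- **selection** — the full candidate sweep (4 structures x 4^(J-1)
  link combinations x po/npo = 128 models at J = 3) ranked by AIC or
  BIC, with the usual one-row-per-family report;
- **validation** — k-fold cross-validated cross-entropy loss over
  repeated random partitions, and one-sided paired t-tests between
  model families;
- **epiTOC2** — the simplified mitotic clock
  `TNSC(s) = (1/nc) sum_i 2 beta_is / delta_i` turning a CpG
  beta-value matrix into the mitotic-age covariate;
- **synthetic data** — study-shaped generators with known ground
  truth for every stage, so the whole pipeline is testable offline.

The covariate sets mirror the study design: `tnsc` alone;
`tnsc+atrophy5` adding dummies for a 5-level atrophy factor (Marked
baseline); `tnsc+atrophy3` for the restricted cohort without
Marked/Unknown rows (Negative baseline).

## Worked example

Simulate a 124-sample study table from the cumulative po loglog/logit
reference model, run the full sweep, and compare the winner against
two classical models by cross-validated cross-entropy:

```python
import mixedlink as ml
from mixedlink.synthetic import simulate_dataset

data = simulate_dataset(model=1, n=124, seed=7)          # known ground truth
config = ml.StudyConfig(
    data=data,
    covariate_set="tnsc",
    baseline_specs={
        "baseline-npo-logit": ml.ModelSpec("baseline", ("logit", "logit"), "npo"),
        "cumulative-npo-logit": ml.ModelSpec("cumulative", ("logit", "logit"), "npo"),
    },
)
report = ml.run_study_pipeline(config)
```

Output (one row per model family, best link pair by AIC):

```
   structure odds link_j1 link_j2    AIC    BIC
  cumulative  npo  loglog cloglog 155.53 166.81
  cumulative   po  loglog   logit 155.62 164.08
    baseline  npo  loglog  loglog 156.28 167.56
continuation  npo  loglog  loglog 156.36 167.64
    adjacent  npo  loglog  loglog 156.96 168.24
    adjacent   po  probit   logit 159.85 168.31
continuation   po  probit   logit 162.42 170.88
    baseline   po  probit   logit 168.34 176.80

tnsc slope -0.0004676  95% CI (-0.0006342, -0.0003011)  p = 3.72e-08

mean CE over 10 partitions:
winner                  0.6323
baseline-npo-logit      0.6467
cumulative-npo-logit    0.6519

one-sided paired t-test p-values (row better than column):
                              winner  baseline-npo-logit  cumulative-npo-logit
H1: row better than column
winner                           NaN            0.000339              0.000049
baseline-npo-logit          0.999661                 NaN              0.000007
cumulative-npo-logit        0.999951            0.999993                   NaN
```

Reading it: the cumulative families that generated the data top the
ranking (at n = 124 the npo and po variants are within sampling noise
of each other); the mitotic-age slope is negative — higher mitotic
age shifts probability mass toward the high-risk IM category, since
IM is the baseline of the cumulative comparisons — and clearly
significant; and the winner's held-out cross-entropy beats both
classical logit models with p-values around 1e-4.

There is also a scikit-learn estimator for composing with pipelines
and model selection:

```python
from mixedlink import MultinomialMixedLink
est = MultinomialMixedLink("cumulative", ("loglog", "logit"), "po",
                           categories=["Normal", "MIM", "IM"])
est.fit(X, y).predict_proba(X_new)
```

and a CLI: `mixedlink simulate|tnsc|fit|select|cv|pipeline --help`.

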