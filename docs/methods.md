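# Methods

## Model

`mixedlink` fits multinomial regressions for an ordered J-category
response in which each non-baseline comparison may use its own link
function.  For covariate setting `x_i` with multinomial counts
`Y_i ~ Multinomial(n_i; pi_i1, ..., pi_iJ)` the model is

    g_j(rho_ij) = beta_0j + beta_j' x_i ,   j = 1, ..., J-1,

where `g_j` is one of four strictly increasing bijections from (0, 1)
onto the real line — logit, probit, loglog `-log(-log rho)`, or
cloglog `log(-log(1 - rho))` — and `rho_ij` is a ratio of category
probabilities determined by the response structure:

| structure      | rho_ij                                  |
|----------------|-----------------------------------------|
| baseline       | pi_ij / (pi_ij + pi_iJ)                 |
| cumulative     | pi_i1 + ... + pi_ij                     |
| adjacent       | pi_ij / (pi_ij + pi_i,j+1)              |
| continuation   | pi_ij / (pi_ij + ... + pi_iJ)           |

All four structures are handled uniformly through the matrix form
`rho_j = L_j'pi~ / (R_j'pi~ + pi_J b_j)` with constant 0/1 matrices
`(L, R, b)`; the per-structure closed forms are recovered exactly and
the matrix form supplies the Jacobian `d rho / d pi~` that the scoring
iterations need.  Under proportional odds (`po`) the slope vector is
shared across comparisons (`beta_j = beta`, p = d + J - 1 parameters);
under `npo` each comparison has its own (p = (d+1)(J-1)).  When every
link is the logit, the four structures reduce to the classical
baseline-category, cumulative, adjacent-categories and
continuation-ratio logit models; this special case is used as an
independent cross-check in the tests, never as the implementation.

The intended application is gastric intestinal-metaplasia risk: a
three-category response Normal < MIM < IM (J = 3, IM as the baseline
category j = 3), with the epiTOC2 mitotic-age score TNSC and
optionally a gastric-atrophy factor as covariates.

## Fitting

Maximum likelihood by Fisher scoring with a step-halving line search.
The chain rule `theta -> eta -> rho -> pi` gives the score and the
expected information in closed form; infeasible iterates (a cumulative
structure whose rho would be non-monotone) score `-inf` and are simply
rejected by the line search, so accepted steps never decrease the
likelihood.  When a full step fails, one or two Levenberg-damped
retries (`info + lambda * scale * I`) keep ascent possible near the
feasibility boundary.

Numerical choices, in order of appearance:

- **Initialization.**  Intercepts map the marginal category
  frequencies through the structure and links; slopes start at zero.
  This start is feasible for every structure, including cumulative.
- **Clipping.**  Inverse links clip probabilities to
  `[1e-12, 1 - 1e-12]`; this keeps likelihoods finite and is invisible
  at any reported precision.
- **Convergence.**  Relative log-likelihood change below 1e-10 *and*
  score max-norm below 1e-6, within 200 iterations.  The likelihood
  flatlines (at machine precision) several iterations before the score
  meets its tolerance, because the score converges linearly whenever
  the model is misspecified; up to 40 flat iterations are allowed
  before the fit is declared stalled.
- **Boundary detection.**  Five consecutive collapsed line searches
  (step below 1e-6) are taken to mean the likelihood supremum sits on
  the feasibility boundary and is not attained — typical for
  cumulative models whose two differently-linked curves want to cross
  inside the covariate range.  Such fits are flagged non-converged and
  retained; they are genuine features of the candidate space, not
  numerical failures.
- **Fallback.**  Any other non-convergence triggers a bounded
  Nelder-Mead polish from the current iterate.
- **Covariance.**  The reported `vcov` inverts the observed
  information, computed by central differences of the analytic score
  (step `1e-6 * max(1, |theta_k|)`); if that is unusable because the
  optimum sits on the feasibility boundary, the expected information
  is inverted instead, and a pseudo-inverse is the last resort.  The
  `vcov_kind` field records which route was taken.
- **MLE existence.**  For tiny or quasi-separated samples the MLE may
  not exist (the likelihood increases along a ray); the fit is then
  flagged.  Tests that compare against a generic optimizer use
  instances where the optimum is finite.

Wald inference (CI `theta_k -/+ z * SE_k` and a two-sided normal
p-value) covers the single-coefficient questions the pipeline reports;
likelihood-ratio and score tests are out of scope.  Intervals are
always reported as (lower, upper) with lower < upper.

## Model selection

`enumerate_candidates` builds the full cross-product — 4 structures x
4^(J-1) link combinations x {po, npo}, i.e. 128 candidates at J = 3 —
and `select_best` fits each and ranks by AIC = -2l + 2p or
BIC = -2l + log(n) p.  Non-converged candidates are kept and ranked
after every converged one (dropping them would silently bias the
selection); ties break toward fewer parameters, then the
lexicographic spec name, for determinism.  `group_table` reduces the
detail to one row per (structure, odds) family with its best link
combination — the shape in which such sweeps are usually reported.
The identity `BIC - AIC = (log n - 2) p` holds row by row and is
asserted in the tests.

## Cross-validation

`make_partition` draws a uniformly random balanced k-block partition
(sizes differ by at most one, reproducible from a seed).  The split is
unstratified by default — the plain random partition is the primitive
the loss is defined over — with stratified splitting available behind
a flag.  For a fixed model spec, `cross_entropy_loss` refits on each
block's complement and averages `-log pi-hat` of the true held-out
label; held-out probabilities are clipped at 1e-12 so a degenerate
fold cannot produce an infinite loss.  The model form is fixed across
folds (no per-fold re-selection): the comparison is between named
model families, not between selection procedures.  Defaults are 10
partitions of 10 folds with seeds 1..10, all recorded in the output.
Two specs are compared by a one-sided paired t-test on their
per-partition CE values; with zero-variance differences the p-value
degenerates to 0 or 1 by the sign of the mean, and identical vectors
raise.

## Mitotic-age covariate

`tnsc` implements the simplified epiTOC2 clock,
`TNSC(s) = (1/nc) sum_i 2 beta_is / delta_i`, over the nc = 163
PRC2-marked clock CpGs.  The per-CpG de novo methylation
probabilities `delta_i` are an input CSV — they ship with the
published clock code and are deliberately not vendored.  The default
missing-data policy is `strict` (every clock CpG present and
measured); `intersect` averages over the available subset with the
per-sample count reported and a warning, because silently subsetting
the clock changes the estimand.

## Synthetic data

The generator emulates the study shape end to end: TNSC drawn
Uniform(2000, 20000) — the range over which the reference models'
linear predictors (intercepts ~4-5, slope ~ -4.2e-4) traverse the
informative probability region — a 5-level atrophy factor with
default marginal (Marked 0.024, Moderate 0.20, Mild 0.30, Negative
0.29, Unknown 0.186; only the rare-Marked and Unknown shares are
anchored in the study description, the rest is a realistic spread and
freely overridable), and one response per sample drawn from a chosen
mixed-link model.  The restricted 3-class cohort uses
Negative/Mild/Moderate = 0.37/0.38/0.25.  Three published fitted
models (`study_model(1|2|3)`) serve as generating laws for recovery
and self-selection experiments.

`simulate_beta_matrix` inverts the clock: `beta_is = t_s delta_i / 2`
reproduces a TNSC target exactly, and jitter is added only in the
weighted null space of the clock functional (column-centred noise
scaled by `delta_i / 2`), shrunk if it would leave [0, 1].  The
synthetic `delta` table (`synthetic_epitoc_params`, deltas uniform in
[2e-5, 9e-5]) is a labelled stand-in for the published parameter
table; the range guarantees TNSC targets up to ~2e4 are reachable
per-probe (each probe caps contributions at 2/delta).

What the generator does **not** emulate: the empirical TNSC
distribution of any real cohort, 450k probe-probe correlation, batch
effects, or the joint distribution of atrophy and methylation.
Passing recovery tests therefore demonstrate correctness of the
estimator under the assumed model, not robustness to real-data
violations of it.

## Problem sizes used in the checks

Parameter-recovery runs use 20 replicates of n = 5000 samples per
reference model; the self-selection experiment runs the full
128-candidate sweep on 20 such datasets and asks that the generating
(structure, odds) family rank in the top 3 of the 8 family groups in
at least 80% of seeds.  These sizes give Monte-Carlo standard errors
a few times smaller than the effects being checked while keeping the
whole suite runnable on a laptop CPU in minutes.

## Known limitations

- Partial proportional odds (ppo), po-npo mixtures and two-group
  models are not implemented; the odds choice is all-or-nothing.
- Only the four named structures are exposed; the (L, R, b) machinery
  is internal and not user-extensible.
- The link round-trip `g(g^{-1}(eta)) = eta` is exact to 1e-8 only
  over the eta range where one float64 ulp of the probability moves
  eta by less than that (roughly |eta| < 17 for logit, |eta| < 5.3
  for probit, and one-sidedly for loglog/cloglog); outside it the
  inverse-link output resolution, and eventually the 1e-12 clip,
  dominates.  Fitted linear predictors in practice live well inside
  this range.
- Cross-validation requires individual-level rows (one trial per
  row); grouped-count tables are supported everywhere else.
- The full epiTOC2 estimator (cell-replication-rate and age terms) is
  out of scope; only the simplified weighted-average clock is
  implemented.
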