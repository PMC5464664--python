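# Methods

## Model

The estimand is the association between a composite area-level SES index and
a binary outcome (screening adherence), with the index learned jointly with
the association.  For individual j with component scores `q_j` (length c),
covariate indicators `z_j` and outcome `y_j ~ Bernoulli(mu_j)`:

```
training (per bootstrap b):  logit(mu) = b0 + b1 * (sum_i w_i q_i) + z'phi,
                             sum_i w_i|b = 1,  0 <= w_i|b <= 1
validation:                  logit(mu) = b0 + b1 * WQS + z'phi,
                             WQS = sum_i wbar_i q_i
```

The simplex constraint fixes the scale of the bilinear term `b1 * w` and
forces all components to act in one (hypothesised positive) direction;
`wbar_i` is interpreted as the relative importance of component i.  The data
are split 50/50 at random into a training half (weight estimation) and a
validation half (effect estimation), so the reported odds ratio
`exp(b1)` and its Wald CI are not contaminated by the weight search.

Assumptions worth stating: components are plausible members of one index
and act in the same direction or not at all; the outcome model is a plain
logistic regression (no spatial random effects — individuals sharing an
area share component values but are otherwise treated as independent); the
covariate *set* is fixed a priori, with coefficients re-estimated in every
fit.

## Estimation

**Constrained fit.** The Bernoulli log-likelihood is maximised jointly over
`(b0, b1, phi, w)` with SLSQP under the equality constraint `sum w = 1` and
box constraints `0 <= w_i <= 1`, using the analytic gradient
(`d ll / d w_i = b1 * q_i'(y - mu)`).  Start: equal weights, betas
warm-started from a logistic fit at those weights with `b1` floored at a
small positive value.  Objective tolerance 1e-8, max 300 iterations.  At the
optimum the betas are refined by an ordinary logistic refit with the index
fixed at the optimal weights — conditionally exact, and the source of the
Wald t statistic for `b1`.  The contract is "maximises the stated likelihood
on the simplex", not a particular algorithm; a two-component profile grid
oracle (101 points in w1, betas refit at each point) checks the optimum to
within 1e-3 log-likelihood units in the tests.  With c = 1 the constraint
degenerates to w = (1) and the fit is exactly the unconstrained logistic
regression.  Non-convergence and (quasi-)separation (|coef| > 30 or
se(b1) > 50) flag the estimate rather than raising.

**Bootstrap ensemble.** B resamples of size n with replacement from the
training half (default B = 100).  Final weights are the signal-weighted
average `wbar = sum_b s_b w_b / sum_b s_b` over converged bootstraps with
`b1 > 0` (the hypothesised direction); `s_b = |t_b|` by default, with `t^2`
and a significance indicator available.  If no bootstrap estimates a
positive `b1`, all converged bootstraps contribute with `s_b = |t|`.
Wrong-sign and non-converged bootstraps are excluded and their count
reported.  The average is renormalised onto the simplex exactly.

**Validation and comparison.** The validation fit is an ordinary logistic
regression of y on (1, WQS, z); OR = exp(b1), 95% CI = exp(b1 ± 1.96 se).
AIC = -2 loglik + 2k with k = 2 + dim(phi): the weights are training-half
quantities and are not counted as validation parameters.  Model portfolios
are always run on one shared split seed, and the tabulator refuses to
compare AICs across fits with different split provenance.  A tract-scale
variant of a block-group index reads the tract table's within-tract means
of the same variables.

## Scoring

Quartile mode (default, Q = 4 configurable): empirical 25/50/75% breaks are
computed on the *training* half only and applied everywhere — validation
rows never touch the breaks, so the held-out effect estimate sees no
leakage.  Scores are 0..Q-1, so a "unit increase" of the index is one
quartile step.  A value exactly equal to a break goes to the upper bin
(deterministic tie rule).  Direction alignment (x -> 1 - x for inverse-coded
[0,1] variables such as the income Gini) happens before scoring.  Z-score
mode standardises with training mean/sd (ddof = 1) and, combined with equal
weights, reproduces the conventional z-score-sum deprivation index as a
comparator; a constant component raises a named error there.

## Synthetic data generator

The generator emulates the structure such studies analyse without any real
data.  One standard-normal SES factor `f_t` per tract; the latent value of
variable v in block group j of tract t is
`a f_t + b u_tj + c e_tjv` with `a^2 = within_tract_corr`,
`a^2 + b^2 = between_var_corr`, `a^2+b^2+c^2 = 1` (so the two knobs are the
within-tract correlation of one variable and the pairwise correlation of two
variables in one block group; the model requires between >= within).
Latents become raw values through monotone maps — log-normal for income and
rent amounts, bounded affine for percentages — which quantile scoring is
invariant to.  Tract tables carry within-tract means of every block-group
variable plus tract-only variables; the income-inequality Gini is the
population mean-absolute-difference Gini of 80 simulated log-normal
household incomes per tract, with dispersion decreasing in `f_t` so raw Gini
is inversely coded (and enters specs through `1 - x`).

Defaults, fixed once as the package's study conditions: 200 tracts x 5 block
groups, n = 10,000 individuals, `within_tract_corr = 0.35`,
`between_var_corr = 0.55` (pairwise correlations in the range reported for
census SES variables), true weights (0.3, 0.25, 0.2, 0.15, 0.1, 0, 0, 0, 0,
0) over the ten block-group variables, `beta1 = 0.4`, covariate effects on
the scale of published adjusted odds ratios for screening adherence, and an
intercept calibrated by root-finding so the mean logistic probability equals
the 52.6% outcome prevalence typical of such cohorts.  Outcomes are
generated from population quartile scores, so the default estimator is
correctly specified; `generation_scoring="zscore"` provides a deliberate
misspecification toggle.  True-zero components are generated *just as
correlated* with the live components — the hard case for specificity.

What the generator does not emulate: real geography (area IDs are opaque
strings), spatial autocorrelation beyond the tract factor, missing data,
within-person correlation from repeated encounters, or outcome
misclassification.  Passing recovery tests therefore demonstrate estimator
correctness under the stated generating model, not robustness to those
real-data features.

## Simulation experiment design

Problem sizes were chosen to give each experiment adequate power within a
few minutes on one CPU:

- **Grid oracle**: n = 300, two components, 101-point profile grid.
- **Weight recovery**: 10 replicates; each generates 10,000 individuals
  under the default conditions, so the bootstraps draw from a training half
  of n = 5,000; B = 50.  Reported: per-component mean |error| averaged over
  components, and the mean estimated weight of the true-zero components.
  Under the default component correlation (0.55) this MAE sits near 0.05 —
  weight splitting among strongly correlated components is the binding
  source of error, and it shrinks with lower correlation or more areas.
- **CI coverage**: 200 replicates of a reduced study (n = 800, 60 x 4
  areas, 4 components with weights (0.4, 0.3, 0.2, 0.1), gender as the only
  varying covariate, B = 10), under `beta1 = 0.4` and under the null.
- **Estimated vs. equal weights**: 20 replicates at n = 6,000 (150 x 4
  areas), B = 25, unequal truth; win = lower validation AIC.
- **Scale recovery**: 20 replicates at n = 4,000 (120 x 4 areas), B = 20;
  block-group truth, tract variant via within-tract means.

Reduced runs use degenerate prevalences for all covariates except gender;
`run_wqs` drops zero-variance indicator columns (a level absent from the
sample has an unidentifiable coefficient) and records them in the fit's
provenance.

## Numerical choices and degenerate inputs

- All randomness flows through explicit integer seeds; replicate seeds are
  spawned from one entry seed via `numpy.random.SeedSequence`.  Equal seeds
  give byte-identical datasets and serialised fits.
- Quantile breaks use `numpy.quantile`'s linear interpolation; ties at a
  break go up.
- The Gini rejects all-zero, negative or length-< 2 input; a constant
  positive vector gives exactly 0.
- `average_weights` with an empty or all-non-converged estimate list
  raises; a signal vector that sums to zero (e.g. no significant
  bootstraps under the indicator signal) falls back to unweighted
  averaging.
- Separation in any logistic fit flags the estimate/fit as non-converged
  instead of raising; `bootstrap_weights` errors only if *no* resample
  converges.
- The equal-weight comparator is `w_i = 1/c` exactly; for the 11-component
  index this is 0.0909..., i.e. 0.091 at three decimals.

## Known limitations

- No spatial random effects or cluster-robust standard errors: individuals
  nested in one block group are treated as independent given the index, so
  at a high within-area share the Wald CI can be anticonservative.  The
  coverage experiment runs in a regime where nominal coverage holds.
- Weight identification degrades as component correlation approaches 1;
  with pairwise correlation 0.55 the per-component error at training
  n = 5,000 is already the dominant error term.
- The positive-direction restriction means a truly protective component is
  either absorbed with near-zero weight or excluded by the sign filter; the
  method is not designed for mixed-direction indices.
- Quartile scoring discards within-quartile variation by design; the
  z-score mode is provided for comparison, not as the default.
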