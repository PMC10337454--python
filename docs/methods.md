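# Methods

## The model

`gradedcat` implements Samejima's graded response model (GRM) for ordinal
items. An item with `K` response categories is described by a discrimination
`a > 0` and strictly increasing thresholds `b_1 < ... < b_{K-1}` on the
latent-trait (θ) scale. The cumulative curves are logistic,

    P(X >= k | θ) = 1 / (1 + exp(-a (θ - b_k))),

and category probabilities are adjacent differences. The logistic metric is
used **without** the historical 1.7 scaling constant — the modern convention —
so discriminations here are roughly 1.7× smaller than normal-ogive-metric
values; this matters when comparing parameters across software.

Fisher information of an item is `Σ_k P'_k(θ)² / P_k(θ)`; scale information is
the sum over items and `SEM(θ) = information^{-1/2}`. Reliability targets are
translated into SEM stop rules through `sem = sqrt(1 - reliability)` under a
unit-variance trait (0.9 → 0.32, 0.8 → 0.45, ..., 0.5 → 0.71).

## Calibration

Calibration is marginal maximum likelihood via EM on a fixed quadrature grid:
61 equally spaced nodes on [−6, 6] with renormalized Normal(0, 1) prior
weights. These defaults match common IRT software practice; accuracy is
guarded by dense-grid oracle tests (EAP agreement within 1e−3).

* **E-step**: each respondent's posterior over the grid; expected per-item
  category counts per node.
* **M-step**: each item's expected complete-data log-likelihood is increased
  by a damped Newton step on the reparameterization
  `(log a, b_1, log gap_2, ..., log gap_{K-1})`, which keeps thresholds
  ordered by construction. Steps are accepted only when they improve the
  objective (with backtracking and a gradient-step fallback), so the
  algorithm is a generalized EM and the marginal log-likelihood is
  non-decreasing across cycles — a contract the tests assert on every fit.
  One Newton iteration per cycle is used; further inner iterations change
  per-cycle cost but not the fixed point.
* **Convergence**: maximum absolute parameter change below 1e−4 (calibration)
  within 500 cycles; exceeding the cap flags `converged_ = False`. The DIF
  routine defaults to 3e−4 because its statistic is a log-likelihood
  difference, which stabilizes before the parameters do.
* **Degenerate categories**: never-observed categories are collapsed to a
  contiguous range with a recorded mapping (the item is fit with fewer
  thresholds); categories observed fewer than 5 times trigger a warning; an
  item with fewer than 2 observed categories is a named error.

Standard errors default to the cross-product ("XPD") estimator — the inverse
of the summed outer products of per-respondent scores of the marginal
likelihood. It is asymptotically equivalent to observed information, far
cheaper, and available in reference IRT software. A finite-difference
observed-information estimator (`se_method="observed"`) and a bootstrap
(default 200 resamples, also the fallback when the information matrix is not
positive definite) are provided.

Scoring is expected a posteriori (EAP): posterior mean as the estimate,
posterior SD as its standard error, on the same grid and prior. With no
responses the prior moments are returned.

**Marginal reliability** is defined as
`1 − E_θ[(I(θ) + 1/σ²)^{-1}] / σ²` under the trait prior — the expected
posterior error variance (test information plus prior information, a Laplace
approximation of the EAP posterior variance) relative to the prior variance.
A definition based on test information alone (`1 − E[1/I(θ)]`) is unbounded
below for weak scales, whereas this form is in [0, 1), vanishes for an
information-free scale, and matches a Monte-Carlo average of EAP posterior
variances within 0.02 on the test fixtures.

**Threshold ordering.** GRM structural thresholds are ordered by
construction, so the useful empirical check is on the category response
curves: an item is reported "ordered" when every category is modal over some
θ interval on a dense grid scan of [−6, 6]; items whose intermediate
categories are never modal are flagged.

## Scale diagnostics

* **Cronbach α** — the classical `k/(k−1)(1 − Σ var_i / var_total)`.
* **Mokken scaling** — polytomous Loevinger coefficients
  `H_ij = cov(X_i, X_j) / cov_max(X_i, X_j)`, with `cov_max` the maximum
  covariance attainable given both items' marginal category frequencies
  (comonotone coupling of the sorted marginals; population normalization
  throughout). Item and scale coefficients are ratio-of-sums aggregates; the
  scale SE is a bootstrap (default 200 resamples) — assumption-light, since
  no particular analytic estimator is canonical. Accuracy labels follow the
  conventional cut points exactly: H < 0.3 inaccurate, 0.3–0.4 low, 0.4–0.5
  moderate, ≥ 0.5 good. The automated item selection procedure (AISP) is the
  classical greedy algorithm: seed with the best significantly-positive pair
  above the bound, grow by the item maximizing the provisional scale H
  subject to the item bound, repeat on leftovers.
* **Monotonicity** — rest-score groups of at least `max(50, n/10)`
  respondents (the convention of the Mokken software family); a violation is
  a decrease of at least 0.03 in a cumulative category proportion across
  adjacent groups that is significant by a one-sided two-proportion z test at
  α = 0.05. Without the minimum-violation filter, the sheer number of
  adjacent-bin tests would guarantee false violations on clean data.
* **Yen's Q3** — residuals `x − E[X | θ̂_EAP]` per person and item, Pearson
  correlations between residual columns. The θ̂ source is recorded in the
  output because Q3 is estimator-dependent. Under local independence Q3
  centers near −1/(m−1) (a compensatory artifact of conditioning on an
  estimated trait), so the default flag is one-sided: pairs with Q3 > 0.20
  indicate local dependence; a two-sided option exists. The threshold is
  configurable since no single critical value suits all designs.
* **S-X²** — observed vs. model-expected item-category frequencies
  conditional on the rest summed score, expected frequencies from the
  generalized Lord–Wingersky recursion over the remaining items. Adjacent
  rest-score rows, then adjacent category cells within rows, are collapsed
  until every expected cell reaches 1. Degrees of freedom are the free cells
  (cells minus one per row) minus the item's parameter count; an RMSEA-style
  magnitude `sqrt(max(X²−df, 0)/(df·n))` accompanies the p-value. Items whose
  table collapses below positive df are reported untestable rather than
  forced.
* **Likelihood-ratio DIF** — a two-group GRM with all items constrained equal
  and the focal group's latent mean/SD free (reference group anchors the
  metric). Each candidate item is freed in turn — all-other-items-as-anchors,
  one-at-a-time — warm-started from the baseline solution, so the freed
  likelihood can never fall below the baseline. `LR = 2 Δ log L` on K degrees
  of freedom (one discrimination plus K−1 thresholds), Benjamini–Hochberg
  adjusted across items within the scale (configurable). Items with a group
  that never uses an observed category are skipped with a warning.

## The CAT engine

Administration follows select → elicit → update → check:

* **Selection**: maximum posterior-weighted information,
  `∫ I_item(θ) posterior(θ) dθ` on the grid, for the first and every
  subsequent item (no random start); ties break to the lowest item index for
  determinism. Exposure control is out of scope.
* **Estimation**: EAP after every response; sequential posterior updates
  equal batch EAP on the same pattern to machine precision (the likelihood
  factorizes), which the tests assert at 1e−10.
* **Stop rules**: SEM threshold (`stop_sem`; the SEM is the current posterior
  SD by default, with an expected-information alternative behind
  `sem_rule`), an optional minimum-information combination rule for small
  peaked banks, a `min_items` floor (default 1 — the depression scale
  genuinely terminates after 1–2 items for high-θ respondents), and a hard
  `max_items` cap. `stop_sem = 0` can never fire (the posterior SD is always
  positive), so reliability target 1.0 administers the full scale.

A vectorized batch runner implements identical semantics to the
per-respondent loop (asserted item-by-item in the tests) and makes 10,000
simulees × 6 stop levels run in seconds.

## Simulation study

Two modes: *simulated* (responses drawn from the bank at known θ; reference =
generating θ) and *recorded-response* (an observed matrix re-administered
adaptively; reference = full-bank EAP, the interpretation under which a zero
SEM stop rule yields r = 1.000 identically — adopted because it is the only
reading consistent with that printed value). One response matrix is drawn per
run and reused across all stop levels, so levels are compared on paired data.
Reported metrics: average items administered, Pearson correlation (Spearman
available via the records), bias = mean(θ̂ − reference), n. The θ-stratified
table uses width-0.6 strata from −3.0 to 3.0 with open tails; empty strata
are kept and marked not applicable. The default reliability grid is
{1.0, 0.9, 0.8, 0.7, 0.6, 0.5}.

## Synthetic data generator

The generator emulates a short 3-scale screening questionnaire: 3 scales × 7
items, 4 response categories, θ ~ Normal(0, 1) (10,000 respondents by
default). Discriminations are log-uniform on [0.8, 2.5]; thresholds are
sorted Normal draws (spread 1.0, minimum gap 0.05) around scale-specific
offsets straddling +1 — the scales are "peaked", most informative above the
population mean, as symptom inventories are in non-clinical samples. One
global seed is split into substreams (traits / bank / responses /
injections), so changing the cohort size never perturbs the bank. There is no
missing-data mechanism: the emulated design had complete responses, and
missingness support is an explicit non-goal.

Negative-control injections: `duplicate_item` (a copied column with optional
category jitter — a locally dependent pair for Q3) and `dif_shift`
(re-simulating one item for a labelled subgroup with shifted thresholds —
uniform DIF).

What the generator does **not** emulate: real demographic structure,
multidimensionality / method factors, response styles, careless responding,
or floor/ceiling measurement artifacts beyond what the GRM itself produces.
Passing tests therefore demonstrate the statistical machinery under the
model's own assumptions, not robustness to their violation.

The item parameters of the study this design emulates were never published,
so all fixture banks are synthetic stand-ins, not reconstructions; headline
table values that depend on those parameters are reproduced in *structure*
(monotone columns, exact forced entries, θ-profile of administration length),
not digit-for-digit.

## Numerical and design choices

* Quadrature 61 nodes on [−6, 6]: posterior moments agree with a
  10,001-point dense grid within 1e−3 on the tested patterns.
* Probabilities are floored at 1e−12 inside logs/ratios; thresholds gaps are
  floored at 1e−4 during optimization to avoid degenerate ties.
* An exact duplicate item makes the joint GRM likelihood degenerate (the
  pair's discriminations diverge); the Q3 negative control therefore scores
  the duplicate against the clean calibration, the workflow for vetting a
  candidate item against an operational bank.
* Monte-Carlo suites use 200 replicates at n = 1000 (or 500/group for DIF) —
  sizes chosen so the binomial error of an estimated 5% rate is ~1.5% while
  the whole suite stays quick to run.
* Deterministic seeds everywhere: generation is a pure function of
  (config, seed); CAT ties break by index; hypothesis property tests run
  derandomized.

## Known limitations

* Unidimensional GRM only — no bifactor/multidimensional IRT, no
  limited-information fit statistics (C2/M2*), no differential test
  functioning, no CFA: all outside this package's scope.
* The DIF baseline treats all other items as anchors; with many truly biased
  items the anchor set is contaminated and power degrades.
* XPD standard errors assume a correctly specified model; bootstrap is the
  robust (and slow) alternative.
* S-X² cell collapsing follows one reasonable convention (rows from the
  sparsest inward, then within-row categories); other software may collapse
  differently and give slightly different statistics on sparse data.
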