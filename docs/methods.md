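# Methods

## Model

All analyses assume Samejima's graded response model (GRM) for ordered
polytomous items on a unidimensional latent trait θ (here: vision-related
disability, higher = more disabled).  Item *i* has one slope α_i > 0 and
m ordered thresholds β_i1 ≤ … ≤ β_im (m + 1 response categories coded
0..m).  The cumulative probability of category j or higher is
logistic(α_i(θ − β_ij)); category probabilities are differences of
adjacent cumulative curves.  The population prior on θ is standard
normal and is held fixed for identification — fitted parameters are on
the N(0, 1) metric of the calibration sample, and no re-standardization
is applied after fitting.

The expected item score E[X_i | θ] = Σ_j j·P_ij(θ) = Σ_j P*_ij(θ) lives
on the 0..m raw-score scale.  Item information uses the graded-model
closed form I_i(θ) = α_i² Σ_j (w_j − w_{j+1})²/P_ij with w = P*(1 − P*),
which the test suite verifies against the generic score-function form
Σ_j (dP_ij/dθ)²/P_ij by finite differences.  Test information for a
dimension is the sum of item informations plus, by default, a unit term
for the standard-normal prior: marginal-estimation programs report
prior-inclusive information, and the reference information maxima and
SEs this package reproduces (e.g. 25.0 ↔ SE 0.20) are only consistent
with the prior term included — the bare item sum for the reading
dimension peaks at ≈ 24.1, not 25.  SE(θ) = 1/√I(θ).

## Calibration

`fit_grm` maximizes the marginal likelihood (responses integrated over
the trait prior) with Bock–Aitkin EM:

- **Quadrature**: 61 equally spaced points on [−6, 6] with renormalized
  N(0, 1) weights.  Against a 101-point grid the log-likelihood changes
  by < 1e−4 on the test fixtures.
- **E-step**: posterior mass over grid points per person; posterior
  expected category counts per item.
- **M-step**: per-item quasi-Newton maximization of the expected
  complete-data log-likelihood with analytic gradients, in the
  transformed parameterization (log slope, first threshold, log
  threshold increments) so every iterate has a positive slope and
  ordered thresholds.  A step that would not improve an item's expected
  log-likelihood is rejected, so the EM ascent property holds exactly
  and is asserted at every iteration.
- **Convergence**: absolute log-likelihood change < 1e−5 *and* maximum
  absolute parameter change < 1e−4; at most 500 iterations; running out
  of iterations flags `converged=False` rather than raising.
- **Start values**: unit slopes; thresholds from the marginal cumulative
  category proportions at unit slope.
- **Missing responses** are treated as ignorable and skipped in all
  likelihood products.  The generator's default non-response rate
  (4.5%, MCAR) matches the instrument's observed marginal rate; no
  imputation anywhere.
- **Unobserved categories**: an item category never observed in the
  sample is merged with its lower neighbor (rank recoding of observed
  codes); the mapping is reported in the calibration result, and
  downstream statistics must be computed on the recoded matrix
  (`apply_category_maps`).  An item with fewer than two observed
  categories is a hard error naming the item.
- **Standard errors** come from a finite-difference observed-information
  matrix (central differences of the analytic score) at the solution.

Person scores are EAP (posterior mean) with posterior SD from the same
grid; a person with no observed responses carries the prior mean and SD.
The index of subject separation is the empirical reliability
var(EAP) / (var(EAP) + mean posterior variance) over scored persons.
The exact formula behind the published separation indices (0.83–0.94)
is not recoverable from the source, and those values depend on the
original raw responses; the suite instead checks the qualitative floor
(≥ 0.85 for the most informative dimension at n = 1000 simulated).

## Item fit (S-X²)

The S-X² construction conditions on the **rest score** (scale total
minus the studied item).  Observed counts O_ks (item category k within
rest-score group s) are compared with expected counts
E_ks = N_s·E[P_k(θ) | rest = s], where the rest-score distribution at
each quadrature point comes from the generalized Lord–Wingersky
recursion and the conditional expectation integrates against the trait
prior.  Degrees of freedom are Σ_rows (cells − 1) minus the studied
item's free parameter count, floored at 1; misfit is flagged at
p < 0.01.

Cell collapsing is two-stage: adjacent rest-score groups are merged
toward the nearer tail until each retained group holds at least 10
persons (`min_row_count`); then, within each group, adjacent category
cells are merged until each expected count reaches 1.0
(`min_expected`).  An earlier variant that merged rows until *every*
category cell reached the floor collapsed the table to a handful of
degrees of freedom (the floor is unattainable at extreme rest scores
for 6-category items) and inflated the null rejection rate; the
row-count rule keeps the statistic calibrated (null rejection
12/1000 at α = 0.01; Kolmogorov distance of null p-values from uniform
0.078 at 200 replicates of a 5-item scale, n = 500).

By default only rows with a complete rest score enter the table
(`min_rest_fraction = 1.0`).  Rows with partially observed rest items
can be admitted; their expected proportions are then computed per
observed-item pattern so observed and expected stay calibrated, but
mixing patterns was measurably less well calibrated in null
simulations, hence the complete-case default.

## Local dependence screen

The residual correlation for an item pair is the observed Pearson
correlation of the two items' codes minus the model-implied correlation
through the common trait (computed by quadrature).  Under local
independence it is near zero; pairs with |r| ≥ 0.10 are flagged.
Person-level residuals against the EAP estimate (a Q3-type statistic)
were rejected for this purpose: conditioning on an estimate built from
the same items biases those correlations by roughly −1/(k − 1) with an
item-information-dependent spread (to −0.35 on a 7-item scale under
exact local independence), which would swamp a 0.10 flag threshold.

## DIF testing

For each item × binary grouping variable, three nested two-group models
are fitted: all other items of the dimension are anchors (constrained
equal across groups, no purification pass), the reference group's prior
is fixed at N(0, 1), and the focal group's prior mean **and SD** are
estimated so that a true group difference in the trait (impact) is not
mistaken for DIF.  The studied item is constrained `equal`,
`slope_equal`, or `free`.  The slope (non-uniform DIF) test is
G² = 2(LL_free − LL_slope_equal) on 1 df; only if it is non-significant
is the threshold (uniform DIF) test G² = 2(LL_slope_equal − LL_equal)
on m df performed — the hierarchical likelihood-ratio DIF scheme.
Significance is α = 0.01 per test, with no further multiplicity
correction (the stricter per-test level *is* the multiplicity control).

These constrained models are maximized directly by L-BFGS with analytic
gradients obtained from Fisher's identity (posterior expected
complete-data scores), warm-started along the constraint hierarchy from
the pooled single-group calibration.  EM and direct maximization target
the identical marginal likelihood; the direct route is used here because
each item × variable cell needs three fits and the likelihood-ratio
differences must be resolved precisely.  Null simulations (4-item
scale, 500 per group) give a slope-test rejection rate of 2/200 at
α = 0.01 and an empirical 0.99 quantile of G²_slope of 6.2 (χ²₁: 6.63).

DIF magnitude is the expected-score difference curve between groups
(reference minus focal, i.e. first-listed minus second in the reference
tables), scanned on θ ∈ [−8, 8] in steps of 0.01 — wide because
published maxima occur as far out as θ = 5.4.  ES_Δmax is the signed
value of largest magnitude; ties resolve to the smallest θ.

## Removal rule

An item is removed when any of:

(a) |ES_Δmax| > 1.0 raw-score points on a variable with significant DIF;
(b) significant DIF on ≥ 2 grouping variables;
(c) |ES(θ)| > 0.5 over a θ region carrying ≥ 50% of the standard-normal
    population, i.e. DIF over a large part of the disability continuum.

All thresholds are configurable.  The 50% mass default for clause (c)
was set from the reference decisions themselves: recomputing the
published two-group curves, the items that were *kept* despite
significant DIF show |ES| > 0.5 over 28–47% of the population, while
the removed "using tools" item shows 62% — a majority-of-the-population
criterion separates the documented keep/remove decisions, a 25%
criterion would not.

## Pipeline

Dimensions are calibrated independently (never jointly).  Per dimension:
calibrate → S-X² per item → DIF per item × variable → removal decisions
→ if items were removed, re-calibrate the reduced dimension and repeat
its DIF tests → report information curves (prior-inclusive, θ ∈ [−4, 4]
step 0.1) and subject separation.  Estimation failures in one cell are
recorded as warnings without aborting the run.  Reports are
deterministic given the configuration (including its seed): run metadata
carries the seed, a configuration hash and the package version, and no
wall-clock timestamps, so re-running a configuration yields byte-identical
`report.json`.

## Synthetic data

`simulate_responses` draws θ ~ N(0, 1) for the reference group and
N(focal_mean, focal_sd²) for the focal group, generates category codes
by inverse-CDF sampling from the group-specific GRM, and masks entries
MCAR.  Uniform DIF is injected as a constant (or per-threshold) shift of
the focal thresholds; non-uniform DIF as a multiplicative edit of the
focal slope.  Defaults mirror the reference study: n = 296, 6
categories, 4.5% non-response, focal share 61.8% (the sample's female
share).  The truth record retains θ, both groups' parameters and the
edits; identical designs reproduce identical data.

What the generator does **not** emulate: informative (non-MCAR)
missingness, multidimensional traits, response styles (e.g. extreme
responding), and local dependence between items.  Passing tests
therefore certify the estimators under the model's own assumptions, not
robustness to their violation.

## Problem sizes used in the test suite

Simulation-based checks run at: parameter recovery n = 1000 (7-item
scale); DIF null calibration 500 replicates at 500 per group (4-item
scale; the type-I-error check uses the first 200); S-X² null
calibration 200 replicates at n = 500 (5-item scale); DIF power spot
checks 6 replicates at 500 per group; end-to-end pipeline runs at
n = 400–600.  These sizes were chosen to match the reference study's
scale (hundreds of respondents, 4–8 items per dimension) while keeping
each check's Monte-Carlo error small relative to its acceptance band.

## Known limitations

- Binary grouping variables only; multi-group DIF and observed-score
  methods (Mantel–Haenszel, logistic regression) are out of scope.
- One latent dimension per scale; no joint multidimensional calibration.
- The S-X² reference distribution is asymptotic; at very small n or
  with extreme parameter values the collapsing floors matter, and both
  are exposed as arguments.
- Published G²/X² statistics, p-values, and separation indices from the
  reference study depend on its raw 296-person data, which is not
  deposited; the package reproduces the quantities derivable from the
  printed parameter tables and validates the rest by simulation.
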