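# Methods

## Models

Both models are dichotomous logistic IRT models. The Rasch model (RM) has
item response function P(X_vi = 1 | θ_v, β_i) = logistic(θ_v − β_i) with one
difficulty β_i per item. The linear logistic test model (LLTM) constrains
the difficulties to a weighted sum of p basic parameters,
β_i = Σ_j q_ij η_j + c, with the items × operations weight matrix Q given a
priori. The LLTM is therefore nested in the RM, with (k − 1) − p degrees of
freedom separating them (only difficulty *contrasts* are identified).

Assumptions inherited from the Rasch family: unidimensionality, local
independence, equal discrimination, binary scoring, no missing responses
(missing data are rejected, not imputed). The LLTM additionally assumes the
weight matrix is complete and correct — which is exactly the hypothesis the
validation procedure probes.

## Conditional maximum likelihood

Estimation conditions on each person's raw score r_v, which removes the
person parameters. Writing ε_i = exp(−β_i), the conditional probability of
response pattern x given score r is exp(−Σ_i x_i β_i)/γ_r(ε), where γ_r is
the elementary symmetric function (ESF) of order r. The data enter only
through the item totals and score counts of persons with non-extreme scores
(0 < r < k); extreme-score persons are retained in the containers for
bookkeeping but contribute exactly zero to the likelihood, and the effective
sample size reported (and used by default for BIC) counts only the interior
persons.

ESFs and their first derivatives are computed by the *summation* recursion
(items folded in one at a time), with derivative tables assembled from
prefix/suffix ESF products — stable far beyond the 17–23 item scale this
package targets. The easiness vector is rescaled by its geometric mean
(equivalently, difficulties are centred) before exponentiation; if a
pathological spread still overflows the linear-space tables, a logsumexp
variant of the same recursions takes over automatically.

The conditional log-likelihood is strictly concave on the identified
parameter space. Fitting minimizes its negative by BFGS with the analytic
gradient (observed minus expected conditional item margins; for the LLTM the
chain rule gives Qᵀ times the RM gradient). If BFGS stalls short of the
gradient tolerance — which happens routinely for reasons of floating-point
granularity, not of geometry — a damped Newton polish with a
finite-difference Hessian of the analytic gradient finishes the job. Its
line search accepts steps on sufficient decrease *or* on halving the
gradient norm, because near the optimum the true decrease sinks below
rounding noise in a log-likelihood of magnitude ~10³.

Numerical defaults: gradient max-norm tolerance 1e-6, 100 iterations
(both configurable). Exhausting the budget returns `converged=False` rather
than raising; downstream comparisons refuse non-converged fits and
simulation loops record such replicates as non-convergent. Identification:
reported RM difficulties and LLTM reconstructions are sum-zero normalized
(the conditional likelihood is shift-invariant), which makes the two vectors
directly comparable for the correlation statistic; the LLTM intercept is
recovered afterwards as c = −mean(Qη̂). Starting values: centred logits of
item failure rates (RM), their least-squares projection onto [Q | 1]
(LLTM). LLTM standard errors come from the observed information
(finite-difference Hessian at the optimum).

Preconditions: the RM requires every item to have both correct and incorrect
responses among interior persons (otherwise its CML estimate diverges; the
error names the offending items). The LLTM requires [Q | 1] to have full
column rank p + 1; rank-deficient matrices raise an identifiability error
that scenario loops convert into non-convergent records instead of
resampling, so exclusion counts stay visible.

## Model comparison

D = deviance_LLTM − deviance_RM is referred to χ² with (k−1) − p df
(upper tail only; the statistic is one-sided by construction). The
degenerate case df = 0 — a Q-matrix spanning the full contrast space — is
allowed and yields p = 1 when D ≈ 0. AIC = deviance + 2·n_params and
BIC = deviance + n_params·ln(n), with n defaulting to the effective
(interior-person) sample size and overridable; parameter counts are k − 1
(RM) and p (LLTM). "Favors the LLTM" means *strictly* smaller criterion
value; ties go to the Rasch model.

## The validation statistic and decision rule

The validity statistic is the Pearson correlation (Spearman available)
between β̂ (RM) and β̃ = Qη̂ + c (LLTM) — requested with at least three
items and non-constant vectors, else an undefined-correlation error.
Following the parallel-analysis logic, `validate_qmatrix` builds a null
distribution of this statistic from simulated weight matrices matched in
dimensions and declares the theoretical matrix **supported** iff its
empirical correlation *strictly* exceeds the null 95th percentile
(equivalently, exceedance < 0.05 with ≥ applied to ties). Percentiles use
linear interpolation between order statistics. Reports additionally quote —
clearly labelled as fixed literature heuristics, never recomputed — the
rule-of-thumb null mean of 0.50–0.55 and the 0.78 minimum meaningful
correlation. If fewer than 100 null replicates converge, a warning is
recorded and the decision still rendered.

Why a null mean near 0.5 is expected at all: for a random Q, β̃ behaves like
the projection of β̂ onto a random p-dimensional subspace of the
(k−1)-dimensional contrast space, so r² is approximately
Beta(p/2, (k−1−p)/2). For k = 23, p = 6 this gives E[r] ≈ 0.51; for k = 17,
p = 5, ≈ 0.55 — the test suite checks the simulated means against this
closed form.

## Simulation scenarios

**Scenario 1 (random Q, lower benchmark).** Entries q_ij are i.i.d.
Bernoulli(prop_ones); an exact-quota mode (exactly round(prop_ones·k·p) ones)
is available because the verbal description of "proportion of ones" admits
both readings — Bernoulli is the default. The observed data are fitted once
by the RM; each replicate fits the LLTM with a fresh random Q and records
the correlation, LR result and AIC/BIC. Defaults in `validate_qmatrix`
match prop_ones to the theoretical matrix's own density; the conventional
grid spans 0.30–0.70, over which the null mean is insensitive to prop_ones.

**Scenario 2 (row perturbations, graded benchmark).** Each replicate
misplaces m rows of the theoretical Q, with m drawn uniformly from
{2, …, k} and the permutation uniform among those displacing exactly m rows
(a uniform m-subset is deranged). A uniform permutation over all k!
orderings would *not* serve here: its expected number of fixed points is 1,
so mild perturbations would essentially never occur and the graded
benchmark would be empty below "large" — hence the stratified design. The
identity never occurs (m ≥ 2; no permutation displaces exactly one row).
Displacement counts are classified small/medium/large with cut-offs 2–7 /
8–15 / 16–23 at k = 23 and 2–6 / 7–12 / 13–17 at k = 17 (the two reference
test lengths); other lengths fall back to terciles of k. `n_misplaced`
counts moved *positions*: swapping two identical rows still counts as two
displacements (documented limitation).

**Scenario 3 (LLTM-generated data, upper benchmark).** Each replicate
simulates a fresh dataset from the LLTM at the configured person count,
refits both models *on that dataset*, and records the correlation, the LR
decision at α, and the per-replicate AIC/BIC preference (criteria are only
comparable within one dataset). The LR rejection rate estimates the type-I
risk and should sit near α; the correlations concentrate near 1.

All scenario runs are bit-reproducible given (seed, config); replicate-level
results serialize to CSV and summaries (min, p5, quartiles, median, mean,
p95, max, convergence counts, IC preference percentages, LR rejection rate)
to JSON.

## Synthetic data generator

The generator emulates the conditions of two operational language-test
analyses reported in the applied literature: person abilities
θ ~ N(0, 1), item difficulties spread evenly over [−2, 2], 23-item tests
with 6 operations and ~300 persons ("listening-sized") and 17-item tests
with 5 operations and ~400 persons ("reading-sized") — the person counts
back-derived from the reported BIC values, the difficulty range typical of
operational language tests. Theoretical-Q stand-ins are drawn once,
deterministically, at ~35–38% density (the densities reported for the two
empirical matrices) and re-drawn until identifiable with no constant
operation column. Basic parameters for LLTM-generated data span roughly
[−1.5, 1.5].

What the generator does **not** emulate: real response data violate the
Rasch family in ways Bernoulli simulation cannot (guessing, discrimination
spread, local dependence, multidimensionality, motivated missingness), and
real Q-matrices have structured, theory-driven sparsity rather than i.i.d.
entries. Passing tests therefore demonstrate that the machinery — CML
estimation, the null distributions, the decision rule, the type-I behaviour
of the LR test — is correct under the stated model, not that any particular
empirical Q-matrix is valid, and the published empirical correlations and
deviances are not reproducible here because those datasets are not public.

## Problem sizes used in the checked runs

The end-to-end checks and `scripts/acceptance.py` use 1,000 replicates per
scenario on one synthetic stand-in dataset per test size (N = 300 at k = 23,
N = 400 at k = 17), and parameter-recovery checks use 5,000 persons; these
sizes give Monte-Carlo error comfortably inside the asserted bands (SE of a
null-mean estimate ≈ 0.004 at 1,000 replicates).

## Known limitations

- Binary complete data only; no polytomous or multidimensional LLTM
  variants, no person-parameter point estimation.
- Standard errors are observed-information only (no sandwich or bootstrap).
- The χ² reference for D is asymptotic; no small-sample correction.
- The displacement-size cut-offs for test lengths other than 17 and 23 are
  a tercile convention, not an established standard.
- Scenario loops are serial; 1,000 replicates at the reference sizes take on
  the order of a minute, so parallelism has not been worth its complexity.
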