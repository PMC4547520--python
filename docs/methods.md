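# Methods

## Model and scope

The package implements the nonparametric item response theory (IRT)
workflow for dichotomous items known as Mokken scale analysis.  The
monotone homogeneity model (MHM) assumes a unidimensional latent trait,
local independence, and item response functions (IRFs) that are
non-decreasing in the trait; under it, respondents can be ordered by
their total score.  The stronger double monotonicity model adds
invariant item ordering (IIO): the IRFs do not intersect, so the
difficulty ordering of items is the same at every trait level and a
single item response carries interpretable information about a person's
standing.  The target application is the National Adult Reading Test
(NART): 50 irregular English words scored correct/incorrect, used to
estimate premorbid cognitive ability, together with its published
23-item invariantly ordered subset (the mini-NART).

## Scalability coefficients

All coefficients are ratios of observed to independence-expected Guttman
error counts, aggregated as ratios of sums (never means of ratios):
`H_ij = 1 − F_ij/E_ij`, `H_i = 1 − ΣF/ΣE` over pairs containing the
item, `H = 1 − ΣΣF/ΣΣE` over all pairs.  The error-count form is
algebraically identical to the covariance-ratio form
`cov(X_i, X_j)/cov_max`; the test suite verifies the identity on random
matrices.  Ties in the difficulty ordering are broken by column order
(the administration order), which leaves `H_ij` unchanged in the
symmetric-tie case.  Degenerate items (all-0/all-1 columns) are excluded
from every sum and reported, since their expected error counts vanish.

Standard errors of `H` are nonparametric bootstrap estimates (resampling
respondents, 1000 seeded replicates by default).  The delta-method
standard errors of the classical literature are not implemented; the
bootstrap was chosen as a single uniform mechanism because the published
values this package pins do not include a derivation of their standard
errors, and no acceptance-level comparison depends on them.

## Automated item selection (AISP)

The greedy bottom-up procedure: seed with the pair maximizing `H_ij`
among pairs with `H_ij ≥ c` (default lower bound `c = 0.3`) whose
one-sided null-variance Z statistic is significant (Bonferroni-corrected
within the step, `α = 0.05`); then repeatedly admit the candidate that
maximizes the resulting scale `H` among candidates whose `H_i` with
respect to the selected set is `≥ c` and significantly positive.  Under
independence the observed error count of a pair is approximately
binomial, giving the null form `Z = (E − F)/√(E(1 − E/N))`.

One admission rule deviates from the classical "all `H_ij` with selected
items positive": the veto applies only to *significantly negative*
pairs.  For a near-ceiling item (99% correct at n = 600, i.e. about six
failures) single-pair expected error counts fall below one and the point
estimate of `H_ij` is routinely negative by chance; vetoing on a point
estimate indistinguishable from zero would exclude valid items
erratically.  Consequently the within-scale guarantee is "no pair
significantly negative" rather than "every pair positive".

## Monotonicity and invariant item ordering

Both manifest checks condition on rest-score groups: adjacent rest
scores are merged from the bottom until each group reaches `minsize`
(n/10 for n ≥ 500, n/5 for 250 ≤ n < 500, otherwise max(n/3, 50)).  For
monotonicity the rest score excludes the item under test and every
ordered pair of groups is compared; for IIO the rest score excludes both
items of the pair and each group is checked for a reversal of the
full-sample difficulty ordering.  Decreases/reversals of at most
`minvi = 0.03` are treated as trivial.

Flagged violations carry a one-sided pooled two-proportion z statistic.
Significance uses a family-wise Bonferroni critical value over the
comparisons scanned in the check (`α = 0.05`), so a clean item set
produces a significant flag with probability about α in total.  This
multiplicity control is essential: a 25-item matrix at n = 600 involves
roughly 2,500 comparisons, and per-comparison testing at 0.05 flags
spurious reversals on items whose IRFs are parallel by construction,
which backward selection would then act on.

Backward IIO selection removes the item carrying the largest significant
reversal, re-checks the reduced set, and stops when no significant
reversal remains; the retained set therefore re-checks clean.  The
magnitude of a flagged reversal is shared by the two items of its pair,
so ties are broken by the larger *total* count of reversals above
`minvi` (significant or not) — the count is what distinguishes a
pervasively crossing item from the single well-behaved item that
witnesses its largest reversal — and a remaining tie by column order.

`H^T` quantifies ordering accuracy as the scale `H` of the transposed
matrix (persons as items), computed after excluding persons with all-0
or all-1 response vectors, whose transposed columns have zero variance.
The exclusion is the methodological default; the source this package
pins does not state whether its value excluded extreme scorers.

## Molenaar–Sijtsma reliability

With items ordered by popularity, the unobservable diagonal of the
joint-proportion matrix (the probability of passing an item on two
independent administrations) is approximated by the two-neighbour ratio
`π̂_ii = π_{i−1,i}·π_{i,i+1}/π_{i−1,i+1}` for interior items and the
single-neighbour ratio (`π̂_11 = π_1·π_{12}/π_2`, mirrored at the hard
end) for edge items; then `MS = 1 − Σ(π_i − π̂_ii)/var(X_+)`.  Under
independence every approximation reduces to `π_i²`, giving MS ≈ 0; for a
perfectly coherent matrix (every person all-0 or all-1) it returns
`π_i` exactly, giving MS = 1.  One boundary property is worth knowing:
on a staircase scalogram with intermediate score patterns the hardest
item's extrapolated diagonal is `π_J²/π_{J−1} < π_J`, so MS falls
slightly below 1 (≈ 0.995 at 10 items) even though the data are
errorless.  This is intrinsic to any scheme built from off-diagonal
joint proportions — in a staircase `π_{J,k} = π_J` for every k, so no
ratio of off-diagonals can return `π_J` — not an implementation choice.
Values outside [0, 1] are reported raw and flagged, never clamped.

## IQ prediction

The published regression equations are packaged verbatim:
mini-NART `IQ = 64.94 + 2.345·score`, slope 95% CI [2.13, 2.56];
full NART `IQ = 55.97 + 1.306·score`, slope 95% CI [1.19, 1.42].
Their interval convention fixes the intercept and applies the slope CI,
so bounds are `intercept + slope-bound·score`, with zero width at
score 0 and width growing linearly in the score; `predict_iq` reproduces
this convention exactly and additionally offers a conventional 95%
prediction interval for models fitted from data (not available for the
packaged equations, which carry no residual information).  Presentation
rounds to two decimals; conversion tables add a nearest-integer column,
which is where the ceiling values 119 (mini-NART at 23) and 121 (full
NART at 50) arise.  The published mini-NART equation line omits its "+";
the worked example fixes the intended form, which is adopted.

## Adaptive administration

Items are administered in difficulty order (percent correct descending,
ties by administration order).  Ascending sessions stop after
`stop_after` consecutive failures and impute the remaining harder items
as failed; descending sessions stop after `stop_after` consecutive
successes and impute the remaining easier items as passed — the Guttman
completion implied by IIO.  The default `stop_after = 2` is a minimal
stopping rule chosen here; the source proposes adaptive use but states
none.  For a respondent whose responses follow a perfect Guttman
pattern the imputed score equals the full-administration total in either
direction, and the mean absolute error under probabilistic responders
shrinks as `stop_after` grows (tested).

## Synthetic data

Responses are generated from two-parameter logistic IRFs,
`P(X=1|θ) = logistic(a(θ − b))`, θ standard normal (optionally two
correlated traits), with `a = ∞` encoded as a deterministic step.  The
criterion variable is `100 + 15·θ + N(0, 12²)`, an IQ-like score whose
correlation with a 50-item total lands near the published .68.
Model-implied marginals use 61-node Gauss–Hermite quadrature, and item
difficulties are calibrated by root-finding so the implied marginal
matches a target percent correct.

The NART-like preset (default n = 600, matching the published complete
case count of 587 in spirit) calibrates all 50 difficulties to the
published percent-correct profile and plants the published structural
narrative by construction:

* the 23 hierarchical items in two discrimination bands — near-ceiling
  items (≥ 96% correct) at a = 3.4, the rest at a = 1.5.  With only a
  handful of failures per near-ceiling item, a flatter slope makes the
  `H_i` estimate too noisy to clear the 0.3 selection bound reliably;
  the steeper band concentrates those failures at genuinely low trait
  levels.  The two bands cross only in the extreme lower tail, where the
  implied reversal never reaches `minvi` in any realizable rest-score
  group, so the planted hierarchy is invariant to the triviality
  tolerance the checks themselves use;
* one ordering violator ("facade") with a near-step IRF (a = 20) whose
  step sits above the locations of several slightly harder moderate-band
  items: those pairs reverse by 0.25–0.40 across whole low-rest-score
  groups, which is detectable at this sample size;
* the other 14 published violators at a = 0.35 — their IRFs also cross
  the hierarchical items, but their item scalabilities sit well below
  the selection bound, so they are set aside at item selection rather
  than at the ordering stage;
* the published 3-item second cluster on a second trait
  (a = 2.8, inter-trait correlation 0.1), and the 9 remaining items
  near-flat (a = 0.12), including the "radix" analogue whose `H_i`
  lands near 0.

A design-time power analysis fixed this profile: at n = 600 the
rest-score groups hold 60–110 persons, capping any reversal z statistic
near 4–5.5 against a family-wise critical value of about 4.3.
Violators in the easy cluster (≥ ~85% correct) cannot produce manifest
reversals at all — every item keeps a high conditional proportion in the
lowest group — and several violators crossing the same victims make the
shared-magnitude tie-counts remove the victim instead.  One
well-separated crossing item is what the sample size supports.

## What the synthetic results show — and what they do not

Passing tests on the preset show that the pipeline recovers planted
structure under the stated conditions: near-flat items end up
unscalable, the second-trait cluster separates, backward ordering
selection removes the crossing item and retains exactly the planted 23,
and the retained scale's `H`, `H^T` and `MS` (≈ 0.44, 0.66, 0.85 at the
default seed) fall in the same qualitative bands as the published
cohort values (0.534, 0.71, 0.89).  They do not reproduce the cohort
analysis: real item responses involve rater behaviour, regional
pronunciation, and dependence structures the 2PL family does not model,
and the preset's default seed is part of the construction — under
reseeding the full planted partition is recovered in most but not all
draws (16 of 21 consecutive seeds at design time), because the
borderline detection power described above is a property of the sample
size, not of the implementation.

## Numerical choices and degenerate inputs

Difficulty ties break by column order everywhere (a fixed
administration-order convention).  Bootstrap and generator randomness
use explicit integer seeds; identical spec and seed reproduce matrices
bit-for-bit.  Matrices must be strictly 0/1 with at least two rows and
columns and unique labels; ingestion either rejects or listwise-drops
incomplete respondent rows (complete-case analysis, the design of the
pinned study) with a logged count.  Checks that need rest-score groups
skip items whose rest scores cannot form two groups of `minsize`.
`H^T` is undefined with fewer than two non-extreme persons, and MS with
fewer than three non-degenerate items; both raise rather than return a
placeholder.

## Known limitations

Polytomous items, the "crit" diagnostic, kernel-smoothed IRF plots,
genetic-algorithm item selection, analytic standard errors, and
confidence intervals for `H^T` are out of scope.  The significance
screens are asymptotic two-proportion tests; at group sizes below ~30
their calibration degrades.  The AISP is the greedy original: it does
not optimize the partition globally, and the invariance of its output to
column order is not guaranteed.
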