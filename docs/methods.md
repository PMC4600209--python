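# Methods

This note records the statistical model, the numerical choices, and the
design decisions behind rehabrank, together with what the synthetic-data
tests do and do not demonstrate.

## Model and procedure

The outcome is a binary indicator of rehabilitation use within six months.
Predictors are assessment items: mostly categorical/ordinal with small
declared level sets, a few continuous (age, falls count). The pipeline is:

1. draw K frequency-matched samples of size n from a source cohort so each
   sample's joint distribution over five matching variables equals a fixed
   80-cell target distribution;
2. on each sample, rank all d included items twice — by group-lasso entry
   order and by random-forest permutation importance;
3. aggregate ranks per item into a mean rank r̄(j) and dispersion σ(j);
4. compare the two rankers' mean-rank vectors and the jointly-top items
   against the Rehabilitation Algorithm's expert item list.

The full-scale study profile is K = 100 samples of n = 10,000 over d = 239
items. The package's default profile is K = 10, n = 2,000, d ≈ 40: at
these sizes one double-ranker ensemble runs in well under a minute per
sample on a single core, and the planted-signal experiments remain
decisive. The full profile is available by configuration.

## Matching

- **Stratum definitions.** Gender = 1 if male; ADL = 1 if any of H2A–H2J
  ≥ 1; Cognition = 1 if B2A ≥ 1; Falls = 1 if K5 ≥ 1; age bins <50, 50–64,
  65–74, 75–84, >84, closed on the left ([50, 65) etc.), since the bin
  labels imply integer years.
- **Allocation.** Largest-remainder (Hamilton) apportionment: quotas
  n·pct/100 are floored and the shortfall is distributed to the largest
  fractional remainders. This preserves the total exactly and reproduces
  integer-exact quotas exactly. Hamilton apportionment is not monotone in
  n in general (the Alabama paradox); the scale-consistency test is
  therefore asserted on the packaged table at specific sizes, not
  universally. Tables whose printed cells total slightly off 100 (within
  ±0.05, two-decimal rounding) are handled by retracting/adding units at
  the smallest remainders.
- **Draws** are uniform without replacement within stratum; drawing with
  replacement is opt-in for short strata (logged, duplicate client ids
  disambiguated). Across the K ensemble samples strata are redrawn
  independently from the fixed source, so a client may appear in several
  samples — consistent with repeated sampling from one database.

## Synthetic cohorts

The generator emulates exactly what the analysis assumes: the published
joint distribution of the matching variables (multinomial cell assignment,
or exact largest-remainder counts when a guaranteed-coverage source is
needed); raw items back-filled consistently with the derived flags (when
ADL = 1 the number of elevated H2 items is uniform on 1..10, levels uniform
on 1..3; B2A and K5 analogous); a configurable extra battery defaulting to
30 binary items (prevalences cycling 0.1–0.5), 10 three-level items
(0.6/0.3/0.1) and 2 standard-normal continuous items; and a Bernoulli
outcome with logit equal to an intercept plus planted main effects and
optional product interactions. The default intercept (−1.5 to −1.6) gives
roughly 20 % outcome prevalence — a plausible service-use rate chosen as a
free parameter, not an empirical estimate.

One global seed expands into fixed per-stage substreams (matching block,
back-fill, battery, outcome), so cohorts are pure functions of their spec.
The raw matching items are excluded from the ranked set by default (the
`include_matching_items` switch restores them) so that the default ranked
battery has d ≈ 40.

What the generator does **not** emulate: realistic inter-item correlation
beyond the matching variables, missing data, longitudinal structure, or
item batteries resembling the true 239-item instrument. Passing recovery
tests therefore show that the machinery finds the signal it is pointed at
under the stated noise model — not that it would rank real assessment
items identically.

## Group-lasso path solver

- **Objective.** Mean negative log-likelihood plus λ Σ w_g‖β_g‖₂, intercept
  unpenalized, w_g = √(group size) so multi-level items are not favoured.
  Parameterizing per observation keeps λ, gradients and KKT residuals
  comparable across sample sizes.
- **λ_max** is computed analytically from the intercept-only optimum:
  max_g ‖X_gᵀ(ȳ − y)‖ / (n w_g); the first grid point is recorded as the
  exact zero solution.
- **Grid.** 100 points, log-spaced down to 10⁻³·λ_max by default. Entry
  order, not coefficient accuracy, is the product; ambiguous entries are
  refined by bisection rather than by a denser grid.
- **Optimizer.** Blockwise proximal descent (each group majorized by its
  Lipschitz bound ‖X_g‖²/(4n), exact group soft-thresholding, incremental
  linear-predictor updates, one-dimensional Newton steps for the
  intercept), plus an active-set Newton polish on the smooth region once
  the active set stabilizes. Convergence is declared only when the full
  KKT residual — active groups' stationarity and inactive groups'
  subgradient bound — is below 10⁻⁶; non-convergence raises an error
  naming the grid point and residual.
- **Entry order.** Groups are ranked by decreasing first-entry λ. Groups
  first appearing in the same grid interval are separated by geometric
  bisection with warm-started refits until brackets are narrower than
  10⁻⁴·λ_max; what still ties is ordered by the pre-entry gradient norm
  ‖∇_g‖/w_g (the quantity whose threshold crossing defines entry), and
  exact residual ties receive averaged ranks. Groups that never enter —
  including groups of constant columns, which have zero gradient — share
  the averaged worst ranks, keeping every ranking complete so that mean
  ranks over K samples always average to (d+1)/2 across items.
- The solver deliberately considers main effects only; with d = 239 there
  are already 28,441 two-way interaction terms, which is the combinatorial
  reason interactions are delegated to the forest ranker.

## Forest ranker

Defaults follow the classic algorithm: 500 trees (100 in the scaled-down
profile — the planted-effect rankings stabilize well before that), Gini
impurity, minimum leaf 5, √p candidate columns per split. Candidate
sampling happens at the dummy-column level (the tree library samples
columns, not item groups); importance is nevertheless aggregated per
original item by permuting all of an item's dummy columns jointly among
each tree's out-of-bag records and averaging the out-of-bag accuracy drop
over trees and permutation repeats. Accuracy is used as the performance
metric, matching the classical permutation-importance definition.
Bootstrap resamples are drawn explicitly so per-tree out-of-bag index sets
are exact; a record that is in-bag for every tree triggers a warning.

## Ensemble aggregation and comparison

σ(j) is reported as the standard error of the mean rank, SD({r(j,k)})/√K
(ddof = 1; defined as 0 at K = 1), because dispersions on that scale are
the ones small enough to be informative about r̄; the raw SD is emitted
alongside. Sample k uses seed master_seed + k. "Top" items are those with
r̄ ≤ 20 by default, read as numerically-smaller-is-better. Effect
directions come from a joint unpenalized logistic fit of the top items
(sign of the largest-magnitude level coefficient for categorical items);
under separation the sign is taken from a lightly L2-penalized refit and
flagged, as are items whose |coefficient| < 2 standard errors.

## Planted-signal study conditions

The recovery experiment plants three strong main effects (+1.5, +1.6,
−1.7) on battery items of 0.3–0.4 prevalence and one interaction-only
pair: two p = 0.5 binary items with zero main effects and a +2.0 product
coefficient. The pair's implied marginal association is ≈1.1 log-odds —
deliberately weaker than every planted main effect, so the main-effects
path ranker must place the pair behind the mains, while the forest, which
conditions on the partner item inside trees, can credit the full joint
effect. This is the mechanism by which the two rankers are expected to
diverge on interaction-driven items, and the paired comparison (pair mean
rank under forest vs path, over 10 master seeds) tests exactly that.

## RA scorer

The Self-Reliance indicator is hard-coded: impaired iff C1 = 1 or any of
C2A–C2D = 1 (monotone by construction). The split structure of the
scoring tree is configuration-driven; the packaged default tree is a
synthetic stand-in using only the published ingredients (ADL decline D5 at
the root, Self-Reliance, stair climbing D4D, housework D4B), with every
score 1–5 reachable. It is explicitly non-canonical and must not be
presented as the licensed algorithm. Missing items are scoring errors,
never imputed — a screening decision should not be silently fabricated.
The item crosswalk between instruments maps ADL decline (H3 ↔ D5) and
stair climbing (H5 ↔ D4D); published materials label the stair-climbing
item inconsistently (H5 vs H4B), and the crosswalk follows the
item-to-label mapping of the ranked-items table.

## Numerical and degenerate-input choices

- Standardization (centre, unit sample SD, ddof = 1) is on by default for
  the path ranker so the penalty treats mixed-scale columns evenly;
  constant columns are centred (hence zero), left unscaled, flagged, and
  can never enter. Trees use the unstandardized design.
- Reference-cell dummy coding drops each item's first level, keeping one
  group per item.
- Missing cohort values are validation errors; no imputation.
- Single-class outcomes are rejected by both rankers.
- K = 1 ensembles are legal; σ is defined as 0.

## Known limitations

- The bisection refinement assumes local monotonicity of group activation;
  group-lasso paths can in principle re-enter, and only the first (largest
  λ) activation is ranked.
- Permutation importance is the marginal, potentially biased variant;
  conditional importance is out of scope.
- The default scoring tree is illustrative, not clinically validated.
- Synthetic cohorts cannot validate behaviour under real-data pathologies
  (correlated batteries, informative missingness, coding drift).
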