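# Methods

## Problem and data model

In vitro dermal-absorption experiments apply a dosed formulation to excised
human skin in a diffusion cell and, after a sampling period, quantify the
active substance in each compartment: receptor fluid, chamber wash, the
skin itself, and successive adhesive tape strips that remove stratum
corneum layers. One *replicate* is one skin sample; all replicates testing
the same concentration of the same substance in the same formulation type
within one study form an *experiment* (the within-study group of the
model). The quantity of regulatory interest is **potential absorption**:
the fraction of the applied dose that has crossed, or may still cross, the
skin — receptor fluid + chamber wash + whole skin + retained tape strips.

Two filtering rules are applied before analysis, at experiment level:

- **Mass-balance recovery**: experiments whose mean recovery lies strictly
  outside [90%, 110%] are removed in full. The bounds are inclusive
  (90.0 and 110.0 are retained) because the exclusion rule is phrased as
  strictly-below / strictly-above. Missing recovery excludes the record
  with a logged warning — silent retention would bias the dataset toward
  poorly documented studies.
- **Tape strips**: if on average ≥ 75% of the material was absorbed after
  half the sampling duration, absorption is considered complete and all
  strip material is counted as unabsorbed residue (no strips retained);
  otherwise only the two outermost strips — which mostly carry unabsorbed
  surface material — are excluded and strips 3+ count toward absorption.
  The 75% boundary itself counts as complete. A missing half-duration
  value defaults to the incomplete branch (strips 3+ retained), the
  conservative choice since it keeps more mass in the absorbed fraction;
  this is configurable.

Fractions are modelled on the logit scale. The logit is applied without
epsilon-clipping: observed fractions in real datasets of this kind span
roughly 10⁻⁵ to 0.8, never touching 0 or 1, so a boundary value indicates
a data error and is rejected rather than silently truncated.

## Classification

Eight analysis cells: formulation category (organic solvent: EC, EW, DC,
ME, OD, OL, SE; water-based: FS, SC, SD, SL; solid: AP, DP, GR, SG, WG,
WP; other: GD, CS, ZC) × concentration status. Unknown formulation codes
are an error, never binned into "other" — that category is a closed set.
Status is determined either by the commercial flag (undiluted product) or
by the 50 g/L cut-off, with the inequality strict at the cut-off
(exactly 50 g/L is a dilution, matching the phrasing that defines
dilutions as "equal to or lower than" the threshold). g/kg for solids is
treated as numerically interchangeable with g/L.

Plausibility checks (dose consistency |total − area dose × skin area|
within 5% relative tolerance by default; concentrates below 1 g/L;
dilutions above 500 g/L) produce advisory flags only. The thresholds for
the two concentration checks are package defaults exposed in the API —
their reference procedure is manual review, so the flags are deliberately
conservative and never auto-drop records.

## Empirical route

Per cell, the default-value candidates are the sample 95th percentile and
its distribution-free upper 95% confidence limit, the k-th order statistic
with k = min{k : BinomialCDF(k; n, 0.95) ≥ 0.95}. The percentile uses
linear interpolation between order statistics (the common statistical-
software default; configurable, since different conventions shift the
percentile by at most one order-statistic gap). The confidence limit is
always an exact order statistic — no interpolation, because the binomial
argument is exact only at observation points. Replicate-level values are
pooled (not per-experiment means), matching how reference tables report n
as replicate counts. The implementation uses the binomial quantile
function with an explicit boundary guard; tests verify it against direct
pmf summation with exact integer binomial coefficients for every
n ≤ 500.

## Mixed model

Response: y = logit(potential absorption) per replicate. Fixed effects:
intercept (dilution, organic solvent), concentrate contrast, and three
category contrasts (other, solid, water-based). Random effects: a
substance-within-status pair (b_D, b_C)′ ~ N₂(0, G) — a random slope that
estimates between-substance variance separately for dilutions and
concentrates together with their correlation ρ; a study intercept
(σ²_study); a within-study group intercept (σ²_within); residual σ²_e.
A skin-donor effect is deliberately not modelled: donor identifiers are
rarely unique across studies, and donor-to-donor variation within a study
is absorbed by the study effect.

### Priors

The derivation this package follows does not fix priors, so the defaults
are weakly-informative proper conjugate choices, all overridable:

| parameter | prior | default |
|---|---|---|
| fixed effects | N(0, τ²) each | τ² = 10⁴ |
| σ²_study, σ²_within, σ²_e | scaled-inv-χ²(ν₀, s₀²) | ν₀ = 1, s₀² = 1 |
| G | inverse-Wishart(ν_G, S) | ν_G = 3, S = I₂ |

τ² = 10⁴ is effectively flat on the logit scale (|effects| < 6 in
practice) while keeping every full conditional proper. ν₀ = 1 with unit
scale puts negligible weight against the data at the dataset sizes
involved (hundreds of groups). ν_G = 3 is the smallest integer df giving
a proper inverse-Wishart for a 2×2 matrix.

### Sampler

Blocked Gibbs with a joint location update: all fixed and random effects
are drawn in one multivariate-normal step from their exact full
conditional (precision = Z′Z/σ²_e + prior block-diagonal, solved by dense
Cholesky; the cross-product Z′Z is precomputed once from the sparse
incidence matrices). Variances then follow their conjugate updates:
inverse-Wishart for G from the substance-effect outer product,
scaled-inv-χ² for the scalar variances. The joint location step avoids
the slow mixing of one-at-a-time updates under the strong
intercept/random-effect correlation of unbalanced designs. Substances
observed in only one status still carry both effect columns; the
unobserved column is drawn from its conditional prior given G, the
standard data augmentation for random slopes. Positive-definiteness of
every G draw is asserted. Default chain: 2000 retained draws after 500
burn-in, no thinning, single chain; the draw sequence is bit-identical
for identical seeds.

Diagnostics: effective sample size by Geyer's initial-positive-sequence
truncation of the autocorrelation sum (FFT-based autocovariances);
highest-posterior-density intervals as the shortest contiguous window
containing the requested mass of the sorted draws. Both are cross-checked
against arviz in the test suite but implemented independently, since they
are part of the package's reported outputs.

Posterior point summaries use the mean (matching the convention of the
reference parameter tables); ρ is a derived quantity per draw,
G₀₁/√(G₀₀G₁₁), summarised like any parameter.

## Prediction intervals

For a cell (category, status) and per posterior draw, the upper 95% limit
of the 90% prediction interval is

    100 · inv_logit( lp + z·√V ),   z = Φ⁻¹(0.95) = 1.6448536…

with V summing the random-effect variances at one of three nested levels:
substance only (σ²_{S:status}, status-specific), + study, + within-study.
z is stored at full double precision, never the rounded 1.645. The
residual variance is never part of V: the interval targets the mean
absorption of a new substance/study/group, not a single future replicate.
Mean predictions for one predictor hold the other at its reference
category. Draw vectors are summarised by median, 95th percentile (the most
conservative default-value basis) and 95% HPDI; report tables round to
whole percent (one decimal for cell means) while machine-readable outputs
keep full precision.

Evaluating the prediction formulas on a single pseudo-draw containing
published posterior means reconstructs the published default values; this
plug-in is exact for the mean predictions and integer-robust for most but
not all prediction-interval cells (the published numbers are posterior
medians of full draw distributions, which the plug-in approximates by the
median-at-the-mean; cells near a rounding boundary, e.g. solid dilutions,
can differ by one percent).

## Synthetic-data generator

The generator draws a dataset shape first — substances appear in
1 + Poisson(1.3) studies, studies hold 1–4 concentration groups (mean
≈ 2.55), groups hold 4–10 replicates — which at the default 155 substances
yields ≈ 356 studies and ≈ 6300 replicates, the scale of the reference
dataset. Category assignment defaults to weights proportional to the
reference per-cell replicate counts; each substance carries one
formulation category, and each group is a concentrate with the
category-specific conditional probability. Target concentrations are
log-uniform, concentrates on [20, 960] g/L and dilutions on
[0.003, 80] g/L — spanning the observed concentration range and
straddling the 50 g/L cut-off from both sides so the two concentrate
definitions genuinely disagree on some groups.

Logit responses follow the model exactly, so parameter recovery is a
well-posed check. Raw-record generation decomposes each fraction into
compartments such that the preprocessing pipeline reconstructs it exactly
under the correct tape-strip branch (complete-absorption experiments put
all strip mass in excluded strips; incomplete ones put 10% of the
absorbed fraction in strips 3+), and plants recovery values inside or
outside [90, 110] per scenario.

What the generator does **not** emulate: concentration-dependent
absorption within a status (the model treats concentration only through
the grouping), non-normal logit-scale residuals, missing-data patterns,
correlations between formulation type and exposure duration, and
multi-substance studies. Passing recovery tests therefore demonstrate
correctness of the inference machinery under the model's own assumptions,
not robustness to their violation in real datasets.

## Problem sizes and test calibration

Recovery studies run at a reduced scale chosen to keep every cell
identifiable: 40 substances with balanced category weights (≈ 10
substances per category, ≈ 100 studies, ≈ 2000 replicates), 5
replications, 2000 retained draws each. At this scale the posterior SD of
a category fixed effect is ≈ 0.25–0.3 on the logit scale (dominated by
between-substance variance over ~10 substances), so recovery is asserted
as 95%-HPDI coverage of ≥ 8 of the 10 reported parameters in ≥ 4 of 5
replications plus a bound of 0.15 on the deviation of posterior means from
truth averaged over effects and replications — an unbiasedness check with
real power at this replication count. Sampler correctness is established
separately where exact answers exist: with random effects omitted the
Gibbs draws match the closed-form conjugate linear-regression posterior
(KS < 0.05 per marginal), and a degenerate generator (all random-effect
variances zero, residual 0.01) pins the fixed effects to truth.

## Numerical choices

- `inv_logit` uses the numerically stable branch split at y = 0.
- The location update solves via dense Cholesky of the precision matrix;
  at reduced scale the dimension is ~500, at full reference scale ~2900
  (still feasible, ~seconds per hundred iterations).
- Empirical percentile ties need no tie-breaking: the k-th smallest value
  is well-defined under any stable sort.
- HPDI requires ≥ 20 draws; ESS ≥ 10; a constant chain reports ESS = n
  with a warning rather than failing.
- Degenerate generator truths (zero variances) are supported through an
  eigendecomposition-based factor of G instead of a strict Cholesky.

## Known limitations

- Single-chain default: between-chain diagnostics (R-hat) are not
  computed; multi-seed refits serve that role in the tests.
- The plug-in reconstruction of published default values is approximate
  for cells whose posterior median is near a rounding boundary (see
  above); exact reproduction requires refitting the original dataset.
- The model predicts for new substances/studies only; conditional
  (BLUP-style) prediction for an observed substance is out of scope.
- Concentration enters only through classification; dose-response
  modelling of absorption versus concentration is out of scope.
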