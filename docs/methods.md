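# Methods

## Model

Each modeled indicator — the reference-dose coverage plus two conditional or
ratio indicators — follows a binomial geostatistical model.  At cluster
location s_i with n(s_i) trials and y(s_i) successes,

    y(s_i) | p(s_i) ~ Binomial(n(s_i), p(s_i)),
    logit p(s_i) = x(s_i)'β + ω(s_i) + ε(s_i).

ω is a zero-mean Gaussian field with Matérn covariance of smoothness ν = 1
(fixed for identifiability), marginal variance σ² and effective range r —
the distance at which the correlation has fallen to ≈ 0.1; the scale
parameter is κ = √(8ν)/r, and the ν = 1 correlation is c(d) = κd·K₁(κd).
ε is an iid Gaussian nugget with variance σ²_ε capturing non-spatial
overdispersion.  The binomial coefficient is omitted from the likelihood
(the posterior is defined up to proportionality), which also makes the
likelihood well defined for the fractional success counts produced by the
ratio-based pseudo counts and by deterministic simulation.

Coordinates are treated as planar with Euclidean distances in the user's
units; r is in those units.  Counts are stored as reals; integer-ness is
enforced only behind the `integer_counts` reader flag.  Missing covariate
values are an error, never imputed.  Clusters with fewer than `min_n = 2`
children are dropped before modeling.

## Monotone constructions

With the first dose as reference, the CP construction models p1, p2|1 and
p3|2 from (n, y1), (y1, y2), (y2, y3); the RB construction models p1, p21 =
p2/p1 and p32 = p3/p2 from (n, y1), (n, n·y2/y1), (n, n·y3/y2).  The two
intermediate indicators are numerically identical (p2|1 = p21, p3|2 = p32);
the constructions differ only in the trial sizes, which is exactly what the
simulation study probes.  Composition p2 = p1·mid, p3 = p2·last keeps every
posterior draw monotone because all factors lie in [0, 1].

Clusters with a zero denominator (y1 = 0 for the mid indicator, y2 = 0 for
the last) are excluded from that indicator's dataset rather than scored as
zero: a 0/0 conditional proportion carries no likelihood information, and
exclusion keeps the CP/RB empirical equivalence exact.

With the last dose as reference the series composes upward through
complements: 1−p2 = (1−p3)·q with q = P(no dose 2 | no dose 3) estimated
from (n−y3, n−y2), and likewise for dose 1.  This keeps every factor a
probability in [0, 1] (a direct ratio p2/p3 ≥ 1 would not be), so upward
composition is monotone by the same argument.

## Priors

β ~ N(0, 10³) per coefficient (precision 10⁻³).  Penalised-complexity
priors: exponential tails on both standard deviations, P(σ > 3) = P(σ_ε >
3) = 0.01 (rate λ = −ln α/u ≈ 1.5351), and the d = 2 joint PC form for the
range with an exponential tail on the inverse range, P(r < r0) = 0.01
(density λ_r r⁻² exp(−λ_r/r), λ_r = −r0 ln α).  r0 is set to 5% of the
study-window height by default (`r0_fraction`), mirroring the convention of
anchoring it to the north–south extent of the study region.

## Posterior computation

The sampler works on the exactly collapsed latent u = ω + ε, whose prior is
N(0, σ²C(r) + σ²_ε I); this marginalisation changes nothing about the
posterior of (β, σ², r, σ²_ε) and halves the latent dimension.  One sweep
per iteration:

1. **Covariance hyperparameters** (log σ, log r, log σ_ε): Gaussian
   random-walk Metropolis in two interwoven parametrisations (ASIS),
   alternating per iteration: a *whitened* move holds v = L⁻¹u fixed so the
   field re-scales coherently with the proposed covariance (likelihood
   changes, Gaussian prior of v does not), and a *centered* move holds u
   itself fixed so the likelihood is invariant and only the Gaussian
   density of u under the proposed covariance enters.  With informative
   data the whitened move alone stalls (any covariance change perturbs the
   fitted field and is likelihood-penalised into tiny steps) and the
   centered move alone leaves the field stuck; interweaving mixes where
   neither does.  Step sizes adapt toward 25% acceptance during burn-in
   only.  The chain initialises the range at the first quartile of the
   pairwise distances and both variances from a method-of-moments split of
   the residual variance of the empirical logits around a non-spatial fit.
2. **Latent field**: elliptical slice sampling of v against the binomial
   likelihood (two sweeps per iteration).
3. **Coefficient–field swaps**: for each column x_j of the design, propose
   β_j → β_j + δ with v → v − δ·L⁻¹x_j, leaving the linear predictor — and
   hence the likelihood — unchanged.  The nugget component of u can absorb
   any covariate pattern, so β and u are strongly correlated along these
   directions and the blockwise updates alone cross that ridge very slowly;
   the swap moves sample it directly.  Without them the β posteriors are
   visibly underdispersed.
4. **β**: independence Metropolis from the iteratively-reweighted-least-
   squares Gaussian approximation to the conditional β | u (Newton from
   zero, state-independent), acceptance ≈ 1.

Defaults: 1000 draws after 1000 burn-in iterations, thinning 1, seeds
mandatory and recorded.  Covariates are standardised internally and
coefficients reported on the original scale.  Diagnostics carry the
Metropolis acceptance rates and a crude autocorrelation-based effective
sample size; low values trigger a warning rather than an error.

Inside the sampler the ν = 1 correlation is evaluated from an 8000-point
table of x·K₁(x) (max absolute error ≈ 1.3×10⁻⁶, ~10× faster than the
Bessel call on the matrices rebuilt every step); `matern_cov` itself and
everything used in prediction evaluate the Bessel function exactly.  A
jitter of 10⁻⁸·r0 stabilises Cholesky factorisations; duplicate coordinates
are allowed (the nugget disambiguates).

Prediction at new locations conditions u* on the fitted u under each draw's
covariance (exact kriging with the nugget on the data diagonal), draws u*
jointly from the conditional Gaussian, and by default adds a fresh nugget —
the held-out quantity is then a new cluster's coverage rather than the
latent surface (`predict_nugget` switches this off).  Factorisations are
cached across consecutive draws with identical hyperparameters (Metropolis
rejections), which makes the per-draw cost a matrix–vector product.

## Synthetic-data generator

The generator reproduces the reference simulation design: observation
locations uniform on an 8×8 window (its size chosen so the first quartile
of pairwise distances ≈ 2.62, the default range, matching the convention of
deriving r from that quartile; `range_from_quartile` recomputes it), three
covariates iid N(0,1), Gamma(1,1), t(2), true β = (0.5, 0.8, 0.8, 0.2),
σ² = 1, r = 2.62, σ²_ε = 1, and incremental shifts δ₂ = −1.3, δ₃ = −2.5
added to the shared logit-scale predictor so that p1 > p2 > p3 everywhere.
Sample sizes are discrete-uniform U{2,K} for the ladder K = 10, 20, …, 80
(the `small_sizes` preset uses K = 8, 10, 12, 15, 20, 25, 30, 35); success
counts are the deterministic fractions y_k = n·p_k — no binomial noise —
which preserves exact monotonicity and makes the truth recoverable.  One
truth realisation is shared by all datasets; the default 8 families × 3
target indicators give 24 datasets.  The default study size in this package
is 300 observation locations (desk-scale), with a 10×10 prediction grid.

The shifts act on the shared (ω, ε) realisation; the `redraw_residuals`
variant redraws the nugget per dose and then restores monotonicity with a
running minimum, covering the alternative reading of "changes in the
residual terms".  The spatially-uncorrelated scenario simply omits ω.

What the generator does *not* emulate: real cluster geometries (locations
are uniform, real surveys cluster around population), survey weights,
displacement error, recall bias, and binomial sampling noise in the counts.
Passing tests therefore demonstrate the correctness and internal
calibration of the machinery under the stated design, not survey-specific
robustness.

Geography fixtures are synthetic: a rectangular grid, two nested levels of
rectangular admin units (2×2 "states", 4×4 "districts") and log-normal cell
populations.

## Validation and post-processing choices

Cross-validation folds are random near-equal splits of clusters (not
children), k = 10 by default.  Held-out intermediate indicators are scored
against their own empirical proportions (eg y2/y1), the quantity the model
targets.  The reported correlation is Pearson.  Direct admin estimates are
unweighted ratios Σy/Σn (survey weights are out of scope).

Admin aggregation is computed per posterior draw and then summarised, so
monotonicity and full uncertainty survive aggregation.  Dropout rates are
computed per draw with posterior-mean reporting.  Zero-dose counts use the
admin-level coverage draws with populations held fixed; the grid-level
variant (cell population × cell draw, summed) is available behind
`grid_level=True` and agrees exactly when coverage is flat within a unit,
but can produce wider intervals.  A unit with zero total population falls
back to an unweighted mean with a warning; a unit with no grid cells is
skipped with a warning.

## Numerical notes and scaled-down test sizes

Dense Matérn covariances (exact GP) are used throughout — appropriate for
≤ ~2000 locations; there is no SPDE mesh.  The acceptance-style checks run
the reference design at 300 locations: parameter recovery over 20 seeded
replicates (chains of 2200 iterations, ~8 min), and the simulation study
scaled to three size families U{2,10}, U{2,40}, U{2,80} with three seeded
replicates and 650-iteration chains on a 7×7 grid (~10 min).  RMSE-ordering
assertions allow a 5% relative Monte Carlo margin, fixed in advance of any
runs.

Known limitations.  The deterministic-counts design removes the binomial
sampling noise the likelihood budgets for: the model attributes roughly
E[1/(n·p·q)] of logit-scale variance to sampling noise that the data do not
contain, so the posterior nugget variance lands below its generating value
and both credible and predictive intervals contract below nominal —
frequentist coverage of 95% intervals for β sits in the low-to-mid 80s per
component, and out-of-sample 95% prediction intervals on the grid cover in
the mid 80s for the reference indicator (both measured by the test suite).
This is a property of the design, not of the inference: with counts that
actually carry binomial noise the likelihood matches the generative process
and the contraction disappears.  Composed targets (p2, p3) undercover
further because their draws
multiply independent posteriors from separately fitted indicators while the
generating surfaces share a single (ω, ε) realisation.  The PC priors also
shrink σ when the window holds only ~(8/2.62)² ≈ 9 effective range patches.
The sampler is single-chain; multi-chain convergence diagnostics (R-hat)
are not computed.  GeoTIFF raster input/output is not supported — grids and
surfaces are exchanged as delimited text, admin polygons as GeoJSON.
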