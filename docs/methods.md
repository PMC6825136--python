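# Methods

This note documents the models and procedures implemented in `paleotf`,
their assumptions, the defaults and why, the numerical choices made where
the design was genuinely open, and what the synthetic-data tests do and do
not demonstrate about real pollen data.

## Calibration methods

All eight methods share one contract: `fit_model(spec, X, y)` takes a
site × taxon **percentage** matrix (rows summing to 100) and a climate
response vector; the fitted model predicts from any matrix with the same
taxon columns. The square-root transform of the species data is applied
*only* inside the weighted-averaging family (WA, WAPLS); tree ensembles are
invariant to monotone predictor transforms and the network methods take
proportions (percent / 100).

**MAT (modern analogue technique).** k-nearest-neighbour prediction in
assemblage space under the squared-chord dissimilarity
`d(p,q) = Σ(√p−√q)² ∈ [0,2]`, the standard pollen distance. Default k = 5.
The prediction is the inverse-distance weighted mean of the k analogues'
climate values, `ŷ = Σ y_j/d_j ÷ Σ 1/d_j`; analogues at distance < 1e-12
short-circuit to their unweighted mean (exact matches would otherwise
produce infinite weights). Ties at the k-th distance break by training-row
order, making the method fully deterministic.

**WA (weighted averaging).** On Y = √(percent): optimum `u_k` =
abundance-weighted mean of y; tolerance `t_k` = abundance-weighted SD.
Tolerances are floored at max(1 % of the response range, the smallest
positive tolerance) so a taxon occurring at a single site (raw tolerance 0)
cannot dominate the tolerance down-weighted score. Raw scores are deshrunk
by one of three rules: *inverse* (OLS of y on scores), *classical* (OLS of
scores on y, inverted), or *monotonic* — isotonic (pool-adjacent-violators)
regression of y on scores with linear interpolation between knots and
end-segment-slope extrapolation beyond the fitted range. Monotonic with
tolerance down-weighting is the default parameterization. Isotonic
regression was chosen for the monotonic rule because it fulfils the
monotonicity contract without committing to any spline basis; its
end-segment extrapolation is linear, so predictions for fossil samples
slightly outside the modern score range degrade gracefully rather than
clamping.

**WAPLS.** The standard iterative cycle: each component takes the current
response residual into taxon scores by weighted averaging
(`u = Yᵀe / colsum`), projects back to site scores (`r = Yu / rowsum`),
orthogonalizes against earlier components under the site-total weights, and
normalizes. The response is then regressed on *all* component scores by
**ordinary (unweighted) least squares**, whose residual seeds the next
component. The unweighted readout has two useful consequences, both
verified by tests: WAPLS with one component reproduces WA with inverse
deshrinking (no tolerance down-weighting) exactly, and training RMSE is
non-increasing in the component count (nested OLS). Default: 3 components.
Rank deficiency (a component norm collapsing) stops extraction with a
warning rather than aborting.

**Tree ensembles and networks** are adapters over scikit-learn with the
standard parameterizations: RF = 100-tree random forest; ETREES = extremely
randomized trees (100 trees; the backend draws one random cut per candidate
feature — the multi-random-cut variant of some R implementations is not
available and the difference is immaterial to the contract); BRT =
squared-error gradient boosting, learning rate 0.025, depth-4 trees, bag
fraction 0.5, up to 3000 trees with the tree count selected by an internal
5-fold CV over staged predictions (the `gbm.step` procedure); NNET = one
sigmoid hidden layer with linear output trained by L-BFGS (max 500
iterations, no weight decay); ELM = an extreme learning machine, the mean
of 5 networks with Uniform(−1,1) hidden weights, rectified ("positive")
linear activation and least-squares output weights. NNET/ELM hidden-layer
sizes are dataset-specific in practice and therefore *required*
configuration — the toolkit errors rather than guessing. Their response is
standardized internally (and de-standardized on predict) for optimizer
stability; a constant response short-circuits to a constant predictor. All
stochastic methods are exact functions of `spec.seed`.

**BRT relative influence** is the per-taxon reduction-in-squared-error
across all splits, normalized to sum to 100 — the standard interpretability
diagnostic for checking that a model uses ecologically plausible indicator
taxa.

## h-block cross-validation

For test site *i* the training set is every site at great-circle distance
strictly greater than *h* km (haversine on a sphere of radius 6371.0088 km;
geodesic refinement is immaterial at 100-km granularity). The ball is
closed — a neighbour at exactly *h* is excluded — so *h* = 0 removes only
the test site and is literally leave-one-out. Exclusion sets are nested in
*h*, which forces the data-loss and best-analogue diagnostics to be
monotone.

A fold whose training set falls below the method's minimum viable size
(max(k, n_components + 1, 10)) yields a missing prediction with a warning
instead of aborting: at large *h* entire regions lose their training data
and this is informative, not exceptional. Stochastic methods are re-seeded
deterministically per (method, h, fold) from the master seed, so a full
series is reproducible and folds may run in any order.

Summary metrics per (h, method): RMSEP (missing excluded); maximum bias —
the largest absolute mean residual over the 10 equal-length segments of the
observed climate gradient (empty segments skipped), a worst-segment error
measure; R² as the squared Pearson correlation of observed and predicted
(the alternative 1 − SSE/SST definition differs when predictions are biased;
the correlation form was chosen and is flagged here); the median data-loss
fraction `1 − n_train/(n−1)`; and the median best-analogue squared-chord
distance.

## Variogram-based choice of h

The optimal radius is estimated as the range of a circular variogram fitted
to the residuals of a WA model (default parameterization) under
leave-one-out CV. The empirical variogram uses 15 equal-width bins to half
the maximum pairwise distance (standard geostatistical practice);
`γ(lag)` = mean of `½(r_i − r_j)²` over pairs in the bin. The circular
model `γ(d) = c₀ + c·[1 − (2/π)arccos(d/a) + (2d/πa)√(1 − d²/a²)]`
(nugget c₀, partial sill c, range a; sill reached exactly at the range) is
fitted by least squares weighted by pair counts, with multi-start over
eight initial ranges; the fitted range is bounded at 1.25× the maximum lag
because longer ranges are not identifiable from the data. Weighted (rather
than ordinary) least squares was chosen because bin precision varies by an
order of magnitude across lags. The estimate is rounded **up** to the
h-grid granularity (100 km). Two degenerate outcomes are flagged as "no
spatial structure" and collapse the estimate to the smallest grid value:
a partial sill below 5 % of the total sill, and a fitted range inside the
first lag bin (pure nugget at every observable distance).

## Variable selection

Spearman correlations (average-rank ties) screen a candidate variable pool
to a subset with all pairwise |ρ| < 0.7. The subset search is exact
(branch-and-bound over the conflict graph, equivalent to maximum
independent set) up to 25 variables and greedy max-degree-removal beyond;
ties break by variable name, and a `keep` list can force variables in.
Survivors are ranked by mean cross-validated R² across a pluggable ensemble
of calibration methods (default: this package's eight methods). The final
primary/secondary designation is an ecological judgment — ordination
independence and autecological plausibility are deliberately left to the
analyst, and the CLI says so.

## Reconstruction and SiZer

Fossil and calibration matrices are restricted to their shared taxa, both
re-normalized to 100, with the percentage mass each sample lost reported.
Each requested method is fitted on the full aligned calibration set and
applied to every fossil sample; the per-sample minimum squared-chord
distance to the calibration set is recorded as an analogue-quality
diagnostic, plus a multi-method median/min/max/range.

SiZer smooths the reconstruction with local-linear Gaussian-kernel fits on
a 101-point time grid over 25 log-spaced bandwidths (from 2× the median
age spacing to half the age range). Per cell, the local slope and its
standard error come from the weighted fit with a local residual-variance
estimate; significance uses a simultaneous normal quantile Bonferroni-
adjusted for `max(1, range/2b)` effectively independent blocks at bandwidth
b. Cells with effective sample size `Σw/max(w)` below 5 are classified
*insufficient*; otherwise *rise*/*fall*/*flat* by the sign of the
confidence interval. Slopes are taken with respect to increasing age by
default; `time_forward=True` flips the sign convention. The categories are
invariant under positive affine rescaling of the values, and reversing the
age axis swaps rise and fall cell-for-cell — both are tested.

## Synthetic data: what it emulates, and what it does not

Each climate variable is a zero-mean Gaussian random field with circular
covariance (positive within the configured range, zero beyond), sampled at
sites scattered uniformly in a km-scale box around a reference latitude and
affinely mapped to realistic units (July temperature 8–22 °C, water balance
−300 to 300 mm). Cross-variable correlation is induced by shared-component
mixing to a target ρ. Taxon expected abundances are products of Gaussian
response surfaces in the two variables — configurable fractions of
primary-only indicators, secondary indicators, and generalists — and
observed assemblages are multinomial draws of `count_depth` grains,
converted to percentages. An optional spatially autocorrelated observation
error can be added to the *recorded* primary climate values (taxa still
respond to the truth), which plants a known autocorrelation range in
transfer-function residuals for testing the variogram estimator.

The default preset (300 sites, 3000-km box, 400-km field range, ρ = 0.05,
30 taxa, pollen sum 300) keeps a full CV series in the minutes range on a
single CPU; tests and the acceptance script scale site counts between 50
and 300 and cap BRT at 800–1000 trees for the same reason, and those sizes
are stated in each test.

What passing tests demonstrate: the estimators recover what the generator
plants — spatial range, cross-correlation, taxon optima, planted fossil
trajectories, indicator identity — under unimodal responses and
multinomial noise. What they do not demonstrate: robustness to the features
of real pollen data the generator deliberately omits — taphonomic and
dispersal distortion, taxonomic harmonization error, multi-modal or skewed
responses, long-distance transport, secular change in climate covariance
structure, and age-model uncertainty (ages are taken as given throughout).

## Known limitations

* WA optima are estimable only for taxa whose true optima lie within the
  sampled climate gradient; optima beyond the edge truncate toward it, and
  compositional closure adds scatter. The optimum-recovery test therefore
  plants within-gradient optima.
* The variogram-range estimate inherits any long-range structure in the WA
  residuals (e.g. large-scale model bias), occasionally inflating the
  estimated h; the RMSEP-vs-h curve should always be inspected alongside
  it.
* The ELM backend reproduces the documented contract but, like its R
  counterpart, can be unstable when training folds thin out at large h;
  treat its CV curves as a stress diagnostic rather than a recommendation.
* The NNET/ELM hidden-layer sizes, and BRT's tree cap, must be re-tuned
  per dataset; the defaults here are desk-scale.
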