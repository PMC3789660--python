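# Methods

This note documents the models implemented in `denscape`, the assumptions
behind them, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the numerical choices that a
maintainer would otherwise have to reverse-engineer.

## Study design being modelled

A den-dependent canid (the motivating case is the Indian fox in a
human-modified short-grassland mosaic) selects breeding den sites at two
nested scales:

- **Home-range scale** (third-order selection): where within a ~200 ha
  neighbourhood does the den sit relative to land-cover edges and roads?
- **Den-area scale**: given a candidate neighbourhood, which microsite is
  chosen, as a function of prey availability (rodent-burrow counts),
  visibility (a 0–15 pole index, low to high), shrub density (a fruit
  index) and denning substrate (earthen bund / boulder pile / other)?

## Home-range scale: Euclidean distance ratios

For den *i* and feature *j* (grassland, plantation, agricultural, fallow,
ploughed, built-up, roads — in this fixed order, which also breaks
boundary-containment ties):

r*ij* = d(den*i*, *j*) / mean over the den's random points of d(·, *j*),

where d is the nearest planar Euclidean distance, defined as 0 for the
class containing the point (only for that class; other classes use boundary
distance). Random points are uniform on the 800 m disc (exact areal
transform r = R√u), 200 per den by default, one RNG subseed per den spawned
from the master seed.

Defaults: radius 800 m (a circular buffer of ~200 ha, midway between
documented male and female annual home ranges of the motivating species),
200 random points per buffer (~100 points/km²), 1000 bootstrap replicates,
α = 0.05. The one-sample MANOVA is computed through Hotelling's
T² = n(r̄−1)′S⁻¹(r̄−1); in the one-sample case the eigenvalue spectrum of
the hypothesis matrix has a single non-zero root, so Pillai's trace is the
monotone transform T²/(T²+n−1) and F = (n−p)T²/(p(n−1)) with (p, n−p) df is
exact under normality. Raw ratios (not log ratios) enter the MANOVA and
t-tests; the compact letter display is built from the maximal cliques of
the "not significantly different" graph of pairwise paired t-tests, letters
ordered by mean ratio. No multiple-testing correction is applied across the
seven features (raw p-values are reported, mirroring standard practice for
this analysis); the bootstrap CI and the t-test are both computed
deliberately, as redundant corroborating checks.

Random points falling in any land-cover class, including built-up areas,
are kept (no rejection sampling): whether such points should count as
"available" is a design question the analysis leaves to the data provider,
and rejection would distort the availability sample the ratios assume.

Degenerate inputs: zero-variance ratio columns abort the t-test with an
explicit error (never silently reported as t = 0); a constant non-zero
pairwise difference in the ranking is treated as non-significant and
logged; a singular ratio covariance aborts the MANOVA with a suggestion to
drop a column; 0/0 ratio cells (all random points inside the focal class)
are defined as 0.

### Calibration domain and a known bias

The ratio statistic assumes the buffer samples availability representatively
around each den. Two violations bias it *low* even under uniform den
placement:

1. **Map-edge inflation** — if the mapped landscape simply stops, nearest
   distances inflate near the map edge, which only random points (not dens)
   reach. The pipeline therefore places synthetic dens inset from the map
   boundary by more than the buffer radius (1800 m inset for an 800 m
   buffer), mirroring field practice where the land-cover map extends
   beyond every buffer.
2. **Coarse fragmentation** — the den's own distance (disc centre) and the
   random points' mean (disc average) are spatially correlated draws from
   the distance field; when patch spacing approaches the buffer radius the
   centre-vs-average covariance difference biases the mean ratio below 1
   and inflates type-I error. Null calibration is therefore verified in the
   fine-fragmentation regime (patch scale ~140 m ≪ 800 m buffer: 5000
   Voronoi patches and 60 road chords on a 10 km square), where 500-replicate
   simulations put both MANOVA and per-feature t rejection at the nominal
   5% (±2%). On coarse mosaics the method should be interpreted with this
   anti-conservatism in mind; this is a property of the statistic, not of
   the implementation.

## Den-area scale: matched conditional logit

Each choice set holds one used and m available rows (m = 4 in the
motivating design: available sites 300 m away in the four cardinal
directions). The likelihood is the conditional logit
ℓ(β) = Σ_s [x_used′β − log Σ_j exp(x_sj′β)] with no intercept (it cancels
within sets). Continuous covariates are z-scored ((x−mean)/sd); the literal
reading of "dividing by its sample mean and standard deviation"
(x/(mean·sd)) is implemented behind a `literal=True` flag for sensitivity
checks but rejected as a default, being neither location-adjusting nor
conventional.

Fitting is damped Newton from a zero start with analytic gradient and
Hessian; the log-likelihood is concave, so step-halving guarantees ascent.
Convergence: sup-norm of the gradient < 1e-8 within 500 iterations. SEs
come from the inverse observed information at the optimum. Separation is
reported three ways: coefficients diverging past |β| = 35 (standardized
scale), a singular information matrix, or a fitted log-likelihood within
1e-6 of its supremum 0 (complete separation saturates the per-set
probabilities, so the gradient vanishes at finite β — the likelihood check
is the reliable detector). `fit_condlogit` raises by default;
`raise_on_separation=False` returns the capped fit, which cross-validation
uses because prediction only needs the coefficient direction.

Model comparison: AICc = −2ℓ + 2K + 2K(K+1)/(n−K−1) with n = number of
choice sets (the likelihood has one contribution per set) and K = number of
estimated betas. Published tables for this design sometimes count one extra
parameter per model; a `k_offset` option reproduces that convention without
changing ranks or weights. Akaike weights w_i ∝ exp(−Δ_i/2). Model
averaging uses the ΔAICc ≤ 4 confidence set with weights renormalized in
the set; each term is averaged over the models containing it (natural
averaging, weights renormalized again over those models) — zero
substitution (β = 0, SE = 0 for absent terms) is available as a flag. The
unconditional SE is Σ w_i √(SE_i² + (β_i−β̄)²); odds-ratio CIs are Wald,
exp(β̄ ± 1.96·Un.SE) — the CI construction for published tables of this
kind is typically unstated, so printed CIs should be treated as indicative.

Separation detection scans every non-trivial level subset (categorical) or
threshold rule (continuous) as a used-row classifier; sensitivity =
specificity = 1 flags complete separation, both ≥ 0.9 quasi-complete. Den
substrate enters only descriptively (within-group proportions and the
separation report) and is never fitted — with used sites overwhelmingly in
artificial substrates and available sites overwhelmingly in "other", its
coefficient would be unbounded.

Cross-validation: sets are shuffled into k folds (k = 10 default; k = n
gives leave-one-out, accommodating the common "K = 1" reporting convention
of older software); the held-out prediction is the alternative with maximal
x′β̂ and delta is the fraction of held-out sets predicted wrong; chance
level is 1 − 1/(m+1).

## Synthetic generator

The generator exists to give every analysis stage a known truth:

- **Landscape**: a labelled Voronoi tessellation of uniform seed points
  clipped to the extent; patches are assigned greedily (largest patch to
  the class with the largest remaining area deficit), so realized class
  fractions track the targets within a few percent at a few hundred
  patches. Default proportions follow the motivating region's reported mix
  (grassland 0.25, plantation 0.22, agricultural 0.24, fallow 0.12,
  ploughed 0.10, built-up 0.07); default 400 patches and 12 road chords on
  a 10 km square give a mosaic with ~500 m patch scale. Roads are random
  chords, which suffices because only nearest-distance to a polyline is
  exercised downstream.
- **Dens**: importance sampling over 20 000 uniform candidate locations
  with weight exp(Σ_f coef_f · (−d_f/1000)) — coefficients are per-km
  log-weights, positive = attraction; all-zero coefficients give exactly
  uniform placement. The default truth uses grassland 12/km and roads
  1.5/km, reproducing the motivating pattern (strong grassland selection,
  mild road attraction).
- **Choice sets**: burrow and shrub counts are Poisson (means 3 and 2),
  visibility uniform on [0, 15]; the used row follows the conditional logit
  under true betas on raw covariate scales (defaults 1.2, 0.33, 0.04 —
  chosen so that z-scored fits land near the magnitudes reported for the
  motivating study). Substrate is stamped after the choice: available rows
  draw from the availability distribution (0.05, 0.03, 0.92 over bund,
  boulder, other) and the used row from probabilities ∝ availability ×
  exp(substrate log-odds offset) (defaults 5.76, 5.33, 0) — a discrete
  choice over substrate availability. This reproduces the observed
  used-vs-available near-separation, which is unreachable within a
  5-alternative exchangeable set when artificial substrates are rare; the
  cost is that substrate is generated outside the within-set logit, which
  is acceptable because substrate is never fitted.

What the generator does **not** emulate: spatial autocorrelation of
microhabitat covariates between nearby sites (sites are independent),
overlap screening between available points and other dens, water bodies,
real road networks, or the actual geography of any study area. Passing
tests therefore demonstrate correctness of the estimators under the stated
models, not robustness to spatially structured field data.

## Reproducibility

All randomness flows from explicit seeds; a master seed is expanded via
`numpy.random.SeedSequence.spawn` into fixed-order per-stage seeds
(landscape, den placement, random points, bootstrap, choice data, CV), and
per-den random-point streams are spawned from the random-points seed. Run
manifests echo the config, per-stage seeds, row counts and warnings, and
outputs are byte-identical for identical config + seed.

## Simulation sizes used by the test suite

Monte-Carlo checks use sizes chosen for a single CPU: null calibration runs
500 replicate landscapes (5000 patches, 60 roads, 10 km extent) with 26
dens and 100 random points per buffer; bootstrap coverage uses 500
replicates of 26×7 matrices with 400 resamples; Wald coverage uses 200
replicates of 100 choice sets; parameter recovery uses 800 sets; the null
cross-validation check uses 25 replicates of 100 sets. Analysis defaults
(200 random points, 1000 bootstrap reps) are unchanged by these choices.

## Known limitations

- The distance-ratio statistic is anti-conservative on coarse mosaics (see
  above) and its MANOVA/t inference assumes approximate normality of
  ratios, which fails for features the dens frequently sit inside (a point
  mass at 0).
- Exact zero-variance columns (every den inside the focal class) abort
  rather than degrade.
- The conditional logit assumes independence of choice sets and no random
  effects; mixed discrete-choice models are out of scope.
- GeoJSON is the only vector format read/written; coordinates must be
  planar metric, and geographic coordinates are rejected outright.
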