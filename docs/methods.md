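# Methods

This note records the statistical model the package implements, the
defaults and numerical choices that matter, what the synthetic-data
generator does and does not emulate, and the known limitations.

## Survey model and estimator

The data are a stratified aerial line-transect survey with two observers
on the same platform. Each detected animal group contributes a
perpendicular distance *x* (m), sighting covariates *z*, a group size, and
a capture history in {pilot-only, backseat-only, both}. The strip under
the aircraft up to *w_b* (default 22 m) is invisible and handled as left
truncation; distances beyond *w* (default 1000 m) are right-truncated.
Defaults follow the survey this package is benchmarked against; both are
configurable.

**Two-piece normal distance model.** Detection probability is unimodal
with apex μ off the line, modelled as a split normal with log-linear
scale: `ln σ(x,z) = β₀ + β_A·1[x>μ] + Σ β_c z_c`, optionally with
`1[x>μ]`-by-covariate interactions so a covariate can act on one side of
the apex only. Ties x = μ take the left scale (the asymmetry indicator
requires the distance to *exceed* the apex). The fit maximises the
conditional likelihood of the distances; the normalising integral is the
closed-form sum of two Gaussian pieces, exact to machine precision
(verified against adaptive quadrature at 1e−8 relative). Distances enter
exactly (no binning); binning exists only in the goodness-of-fit tests.

**Conditional mark-resight model.** Given detection, history cells follow
the dual-observer multinomial with per-seat logistic probabilities. The
design row for the pilot carries the pilot-group covariate and
`observer = 0`; the backseat row carries `observer = 1` and the
observer-group covariate, so the two seats never share a crew effect, and
a crew-group covariate is only admitted together with the observer-role
term. Distance enters in raw metres.

**Point independence.** Independence of the observers is assumed only at
the apex: p̂•(μ̂,z) = p̂₁+p̂₂−p̂₁p̂₂ evaluated at x = μ̂ converts the
distance model's within-strip average detection into an absolute
probability, p̂(z) = p̂•(μ̂,z)·∫g/(w−w_b). Away from the apex the distance
model carries the dependence. A full-independence mode exists in the
simulator only, for studying the bias that assumption induces.

**Apex-detection averaging.** The reported p̂•(μ̂) is a weighted average
over detections; the default weights are the Horvitz–Thompson weights
1/p̂ᵢ (the estimator-consistent choice), with an unweighted switch. On
data at the study's scale the two differ by well under one standard error.
The standard error is a delta-method propagation of the MR covariance.

**Abundance and variance.** Per stratum, N̂_s = (A_s/a_s)·Σ sizeᵢ/p̂(zᵢ)
with covered strip a_s = 2(w−w_b)L_s; the strip may exceed the habitat
area when strips overlap (it does at the benchmark survey's effort) —
Horvitz–Thompson scaling is unchanged by overlap under random placement,
and the estimator logs a note. The CV combines two components in
quadrature:

- *encounter rate*: the among-transect, length-weighted R2 estimator
  `var(n/L) = K/(L²(K−1)) Σ l_k²(n_k/l_k − n/L)²` applied to individuals
  per transect, stratum-specific (the dominant component in practice);
- *model*: the delta method through Σ sizeᵢ/p̂(zᵢ), using a block-diagonal
  covariance for the two stages (their likelihoods share no parameters;
  the cross-covariance is not estimable from separate fits and is taken
  as zero).

Stratified totals add the encounter-rate variances across strata and
propagate the model component jointly through the shared parameters.
Intervals are log-normal, N̂/C to N̂·C with C = exp(z₀.₉₇₅√ln(1+CV²)).
Harvest rate is H/(H+N̂) with the interval mapped monotonically from the
abundance interval and SE = CV·rate; biennial seasons average the open and
closed year. No uncertainty is attached to the reported-harvest count
itself (mandatory sealing makes it effectively a census of legal kill).

## Selection, screening, and goodness of fit

Forward AIC selection adds the candidate with the largest drop while the
drop is below −2, with ties broken by candidate order; the distance model
always contains the asymmetry term, and the crew-group pairing rule is
enforced in the MR stage. A final model must have χ² GOF p > 0.05 and pass
the probability screen (no p̂ < 0.1; at most 5% of p̂ < 0.2); if the
greedy winner fails, selection walks back to the last eligible model.
Pooled-versus-stratified fits are compared by ΔAIC = AIC_pooled −
ΣAIC_strata, valid because the strata partition the data.

GOF for the distance stage bins distances into equal-count bins — default
count `round(√n)`, which at the benchmark sample sizes (359/253/106)
reproduces the published degrees of freedom — with expected counts from
each record's own fitted density, df = bins−1−k, automatic merging of
bins with expected < 1, and the apex bin's contribution reported. The KS
test and QQ pairs use the per-record probability integral transform. The
MR stage crosses history with distance bin (default `round(0.75√n)` bins);
per-bin totals are fixed, so df = 2·bins−k.

*Calibration caveat*: with parameters refitted by ML, the χ² statistic's
null distribution lies between χ²(bins−1−k) and χ²(bins−1)
(Chernoff–Lehmann); using df = bins−1−k, the 5% test rejects a correct
model ≈8% of the time at n = 350. The package keeps that df convention
(it is the one the benchmark survey reports); the calibration test in the
suite therefore evaluates the machinery against a fixed generating model,
where p-values are uniform as expected. KS p-values are asymptotic and
carry the usual estimated-parameter caveat.

## Numerical choices

- **Optimisation**: L-BFGS-B on (ln μ, β) jointly, covariates affinely
  rescaled to [−5, 5] internally (coefficients and covariance mapped back,
  so reported values are on the data scale; AIC is invariant to the
  rescaling). Five deterministic starts — apex at the 0.1/0.2/0.3
  distance quantiles with spread-based scale inits, plus halved/doubled
  scales — guard the piecewise-smooth surface. Relative tolerance 1e−12
  on the objective, gradient tolerance 1e−8.
- **Scale barrier**: a smooth quadratic penalty keeps σ within
  [1 m, 100·(w−w_b)]. Without it the split model admits degenerate spike
  optima (σ_left → 0 with the apex below the smallest observation); a
  sub-metre detection scale is physically meaningless for aerial survey
  of large mammals.
- **Variance of the distance stage**: the log-likelihood is kinked in μ
  at every data point, so a small-step numeric Hessian understates the
  curvature; the covariance is instead the inverse of the
  outer-product-of-scores (BHHH) information, which restores nominal Wald
  coverage in simulation. The MR stage uses the inverse observed Hessian.
- **Estimator behaviour at moderate n**: the apex MLE is heavy-tailed
  when few detections fall left of the apex (≈50 of 359 at the benchmark
  configuration); occasional samples place the global optimum 2–3
  standard errors from the truth, so marginal Wald coverage for ln μ runs
  a few points below nominal even though the abundance interval's
  coverage is within its nominal band. Profile or bootstrap intervals
  would be the remedy where μ itself is the target of inference.
- AIC is reported to 2 decimals; complete separation in the MR stage is
  detected by runaway coefficients (>30 on the logit scale) or unbounded
  standard errors and raised as an error naming the covariate.

## Synthetic-data generator

`study_scenario()` encodes the benchmark survey's conditions: two strata
with habitat areas 8648.2 and 2868.7 km², 363 and 219 transects with the
published total efforts, truncation [22, 1000] m, true detection
parameters at the published combined-model coefficients, covariate
frequencies at the observed marginal rates (bedded 64/359, long search
distance 61/359, straight/hinged transect 87/359, crew-group rates 4/5
and 1/6), group sizes zero-truncated Poisson with mean 1.7 (the observed
means are 1.81 and 1.64 bears/group), and stratum densities solved by
exact enumeration over the covariate law so the expected detected group
counts are 253 and 106. The percent-cover law (mass 0.35 at 0% thinning
to 0.005 at 100%) is a modelling choice for an open, leaf-off spring
landscape; no recorded frequency table pins it, and the MR stage's cover
coefficient is insensitive to it at these sample sizes.

Groups are placed by a Poisson process on each transect's strip with
distances uniform in [w_b, w]. In the default *estimator-exact* mode a
group is detected with probability p•(μ,z)·g(x,z) and its history drawn
from the conditional multinomial at x — exactly the model the
point-independence estimator inverts, so recovery experiments are
unambiguous: over 200 replicates at study scale the estimator's relative
bias is under 2% and log-normal 95% interval coverage sits in the low
90s. The *full-independence* mode lets each observer detect independently
with p_j(x,z)·g(x,z), for misspecification studies.

What the generator does **not** emulate — and hence what passing tests do
not establish about field data: responsive movement, double counting,
distance measurement error, unmodelled detection heterogeneity beyond the
covariates, non-uniform animal placement with respect to the line, and
terrain-driven transect geometry (transects are abstracted to lengths).

## Problem sizes used in the test suite

Simulation-based tests run at the survey's own scale (≈360 detections per
replicate): 200 replicates for parameter recovery, 500 for GOF
calibration at n = 350, 100 for the selection-versus-exhaustive
comparison, and single large runs (≥1e5 detections) for distributional
checks.

## Limitations

- The study's deposited data files are required to reproduce the
  published coefficient tables and abundance point estimates; without
  them the package validates against its own synthetic truth and the
  published summary arithmetic.
- Only the two-piece normal detection family is provided (a gamma shape
  is incompatible with a single apex and hence with point independence);
  no density-surface modelling or spatial smoothing.
- The GOF χ² bin edges of the original analysis are not published;
  equal-count binning with the default counts reproduces its degrees of
  freedom, but exact χ² statistics on the study data may require the
  explicit-edges override.
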