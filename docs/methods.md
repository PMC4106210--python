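# Methods

## The model

A multi-environment trial (MET) observes y_ijk, the performance of
genotype i in environment j and block k.  The environmental index
x_j — the mean of all genotypes' cell means in environment j — serves as a
one-dimensional measure of environment quality in trait units.  Each
genotype's reaction norm y̅_ij = f_i(x_j) + ε is modelled under one of six
families: the joint-regression straight line a + b·x, the parabola,
the reciprocal quadratic 1/(a + bx + cx²), the Cauchy curve
k/(1 + ((x − x_max)/r)²), the logistic 1/(a + b·cˣ) with 0 < c < 1 (so the
curve rises monotonically toward the asymptote 1/a), and the Gaussian
k/√(2πr²)·exp(−(x − x_max)²/(2r²)).  For the peaked families, k sets the
peak scale, x_max locates the optimum on the index axis and r (> 0) is
the scale of the response range; standardizing x′ = (x − x_max)/r and
y′ = y/k maps a Cauchy curve onto 1/(1 + x′²) with peak 1 at x′ = 0.
Near the optimum every family is locally quadratic — the standardized
Cauchy curve differs from 1 − x′² by exactly x′⁴/(1 + x′²) — so families
are distinguishable only when the trials span a wide quality range.

k is the fitted peak in trait units rather than being constrained to
[0, 1]; the unit-peak convention is recovered by `standardize`.  Real
yields are not pre-scaled, and constraining k would silently rescale the
data.  The Gaussian exponent is negative (bell-shaped); a positive
exponent has no optimum and cannot describe a reaction norm with sub- and
super-optimal decline.

## Estimation

Cell means are formed by averaging blocks; the index is the per-column
mean of the cell-means matrix (per year, per site — never pooled across
years).  Linear and parabola fits are ordinary least squares; the
reciprocal quadratic is OLS of 1/y on (1, x, x²) (a transform-scale fit,
with the residual sum of squares reported on the original trait scale for
cross-family comparability, and the transform-scale RSS retained on the
fit object).

The three remaining families use the natural linearization of each family
to initialize, then refine by damped (trust-region) non-linear least
squares on the original scale with the analytic Jacobian:

* **Cauchy** — 1/y is quadratic in x for an exact curve; from the fitted
  quadratic, x_max = −b/(2c), then k and r.  If the reciprocal quadratic
  opens downward (no interior optimum on the reciprocal scale), a seeded
  multi-start takes over: 20 starts with x_max uniform over the observed
  x-range, r uniform over [0.1, 2]× the range, peak uniform over
  [0.5, 2]× max y; each start gets a short refinement pass, the best RSS
  wins (ties broken toward smaller r) and only the winner is polished at
  full tolerance.
* **logistic** — for fixed base c the model is linear in 1/y; c is
  profiled over 50 log-spaced values in [0.01, 0.99] (judged on the
  transform-scale RSS, the scale on which the profile is exact), refined
  by bounded scalar minimization around the best grid point, then the
  full triple (a, b, c) is polished with a > 0, b ≥ 0, 0 < c < 1.  A best
  profile slope b < 0 describes a monotone-decreasing response, which the
  constrained family cannot represent; the fit is returned with b
  projected to 0 and flagged unconverged.
* **Gaussian** — log y is quadratic in x with negative curvature; that
  quadratic initializes (k, x_max, r) with the same multi-start fallback
  when it opens upward.

Tolerances: gradient norm 1e-8, step norm 1e-10, at most 500 residual
evaluations per refinement.  Refinement is monotone: a refined solution
is never accepted if it worsens the initializer's RSS.  Families
requiring y > 0 (reciprocal quadratic, Cauchy, logistic, Gaussian) reject
non-positive responses outright rather than silently shifting the data —
a shift changes the model, so users must pre-shift explicitly.  The
minimum number of environments per genotype is the free-parameter count
plus one (3 for the line, 4 for the three-parameter families).  A flat
response leaves r unidentifiable and is reported unconverged.

## Partitioning the interaction

The usual balanced two-way decomposition gives SS_G, SS_E, SS_GxE and the
within-cell error, with blocks acting as replicates (df_error =
GE(r − 1)).  Unbalanced data are reduced to the genotypes present in all
environments (no imputation; the exclusions are logged), and unequal
replication within the remaining cells is an error.

The interaction component is then split per family: per-cell deviations
δ_ij = y̅_ij − f̂_i(x_j) are double-centered (row, column and grand means
removed) and SS_residual = n_reps·Σ(centered δ)²,
SS_explained = SS_GxE − SS_residual.  Double-centering removes whatever
additive structure the curves missed, so only genuine interaction is
credited to a family.  This construction was chosen because it (a)
reduces exactly to the classical heterogeneity-of-regressions sum of
squares n_reps·Σ_i(b_i − 1)²·S_xx in the linear case and (b) guarantees
the decomposition identity for every family.  A fit worse than the
additive model would give a negative explained SS; it is floored at zero
and flagged.  The explained share is reported as a percentage of SS_GxE
(to 2 decimals in CSV output), per year, with an across-year average when
several year strata are present.

Invariance: the explained percentage is unchanged by positive rescaling
of all observations for every family (each family is closed under
y → s·y), and by additive shifts for the linear and parabola families.
The peaked and reciprocal families are *not* closed under additive
shifts, so exact shift invariance cannot hold for them; in practice the
effect of a modest shift is small.

Stability classes use a two-sided t-test of H₀: b = 1 at a configurable
level (default 0.05) rather than the raw comparison b ≷ 1, which would
classify every genotype as non-average under noise.  The slope's standard
error is √(dev_ms/S_xx) with dev_ms = RSS/(n − 2).  A genotype is
Eberhart–Russell stable when its class is average, its deviation mean
square is low — not significantly above the pooled error mean square
(placed on a cell-mean basis) by an F-test when replicates provide one,
otherwise at or below the across-genotype median — and its mean yield is
above the median genotype mean.  No multiplicity correction is applied
across genotypes.  Degrees of freedom of the explained component
(Σ(p_i − 1)) are reported for reference only; no F-tests are attached to
the non-linear components.

## Marker scans at representative environments

DH lines' phenotypes at the three evaluation points — poor (minimum
index), average (mean), good (maximum) — are the fitted values of each
line's linear reaction norm at those x values (observed cell means at the
extreme environments are available behind `mode="observed"`; fitted
values are the default because they pool information across all
environments instead of a single noisy column).  Marker effects then come
from minimizing

    (1/2n)‖y − Xβ‖² + λ[α‖β‖₁ + (1 − α)‖β‖²/2]

by cyclic coordinate descent with the univariate soft-threshold update,
warm-started along a log-spaced λ path from λ_max = max_k|x_kᵀy|/(nα)
(the all-zero point) down to λ_max·10⁻³ (50 path points by default).
Markers are coded −1/+1 for the two homozygous DH classes — centering the
classes symmetrically, so an effect is half the class-mean difference —
standardized to unit variance for the fit, and reported back on the
allele-coding scale.  λ is chosen by seeded 10-fold cross-validation
(minimum mean MSE), with per-fold re-standardization; α = 0.5 (elastic
net) and α = 1 (LASSO) are the two shipped presets, and α is freely
configurable.

Numerical contract: at convergence the KKT stationarity conditions hold
to 1e-7 (|x_kᵀ(y − Xβ)/n| ≤ λα for zero coefficients, subgradient
equality with the coefficient's sign otherwise).  Single-penalty fits
from a cold start first descend a short internal λ path, because a cold
start at a small penalty with p ≫ n converges very slowly.  Path fits
used inside cross-validation run at a relaxed tolerance (1e-6) and stop
descending once the active set exceeds 60% of the training lines — that
saturated tail is a gross overfit that cross-validation never selects but
is the most expensive part of the path to polish.  Monomorphic markers
carry no signal and keep a zero effect.

## Synthetic data

`simulate_met` emulates a randomized-complete-block cultivar trial
series: y_ijk = f_i(x*_j) + block_k + ε_ijk, with genotype parameters
drawn from per-parameter normal distributions, block effects
N(0, (σ/2)²) (nuisance scale, fixed by convention) and plot error
N(0, σ²).  The defaults describe a cereal-yield-like series: 30 genotypes
× 20 environments × 3 blocks, environment quality on an evenly spaced
2–8 t/ha grid, plot noise σ = 0.3 t/ha, Cauchy reaction norms with
k ~ N(6, 0.8), x_max ~ N(5, 1.5), r ~ N(2, 0.5).  Draws violating a
family constraint, or whose expected curve dips below 4σ over the
simulated environments (so noise cannot push yields negative, outside
the positive domain the non-linear fitters require), are redrawn; more
than 1000 redraws is a configuration error.  The generator writes the
*latent* quality x*; the analysis re-estimates the index from the
simulated data, so index-estimation error is part of every end-to-end
check — as it is with real data.

`simulate_dh_population` generates a biparental DH panel by a Markov walk
along the marker map: per chromosome the first allele is ±1 with equal
probability and each subsequent marker recombines with probability given
by Haldane's map function r = ½(1 − e^(−2d/100)) for a spacing of d cM
(no interference — Kosambi-style interference is irrelevant to effect-
size questions); chromosome doubling makes lines fully homozygous.
Defaults mirror a classic barley mapping panel: 150 lines, 223 markers
over 7 chromosomes (37/37/31/33/29/22/34), 150 cM per chromosome (an
assumption — the map length is configurable), markers evenly spaced.
`simulate_dh_phenotypes` plants QTL whose additive effects are
base + scale·x*_j, so positive scaling makes effects — and between-line
variance — grow with environment quality; the residual sd is set to hit a
target line-mean heritability (default 0.7) at the median environment,
with 16 environments of quality 3–7 by default.

What the simulators do **not** emulate: missing plots and unbalanced
layouts beyond whole-genotype absence, spatial field trend, epistasis,
multi-parental designs, genotype-dependent error variance, and
year-to-year parameter drift.  Passing tests therefore demonstrate the
correctness and calibration of the estimators under the stated generating
models, not robustness to every pathology of real field data.

## Problem sizes and test design

The test suite and the acceptance script run everything at desk scale:
50 random layouts for the ANOVA oracle, 100 replicate METs of 30×20×3 for
the family-ranking check (with a 30×60×3 parallel-response control, where
60 environments keep the expected noise-driven explained share, roughly
(p − 1)/(E − 1) per genotype parameter, well below the 5% bound), 200
simulated genotypes per family for recovery medians at 10/20/40
environments, 20 DH populations of 150 lines × 223 markers for the scan
contrasts, and 10,000 lines for the Haldane calibration.  All randomness
flows from explicit seeds; repeated runs are byte-identical, including
written reports (JSON keys sorted, floats rounded to 10 decimals,
no timestamps).

## Known limitations

* The environmental index is estimated from the same data it is regressed
  on; with few genotypes this induces the usual joint-regression bias
  (the mean fitted linear slope is exactly 1 by construction).
* Fixed-effects sums of squares are used throughout; no REML/mixed-model
  variance components, and no AMMI/GGE-style multiplicative
  decompositions.
* The logistic family is monotone by construction and cannot represent
  rise-and-fall responses; on peaked data it converges to a saturating
  approximation and may be flagged unconverged at the b ≥ 0 boundary.
* Explained-share comparisons across families are descriptive; the
  package deliberately attaches no significance tests to them.
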