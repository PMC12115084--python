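# Methods

This note documents the models implemented in `invade`, the choices made
where the design was genuinely open, and what the synthetic data
generator does and does not emulate.

## Survey statistics (`invade.survey`)

Plots are 1 m × 1 m herbaceous quadrats; each species in a plot carries
an abundance (individual count), a mean height (cm) and a cover
(fraction of the plot, stored as percent on disk). For a plot with
per-species quantities `x_s`, the relative metric is
`rel_x(s) = x_s / Σ_s x_s`, and the importance value is the weighted
mean of the three relatives, `IV = (rel_height + rel_cover +
rel_abundance) / 3` by default. The equal-weight three-term mean is the
standard convention for herbaceous vegetation when frequency is not
recorded per subplot; the weights are an argument of
`relative_metrics` because some studies fold in relative frequency. A
metric whose plot total is zero yields zero relatives and a warning
rather than an error, so degenerate plots don't abort batch processing.

Shannon–Wiener diversity uses abundance shares and the natural log
(nats), `H = −Σ p_i ln p_i`; base 2 is available. `p_i` from cover is a
defensible alternative but abundance shares are the default because
cover is the noisier field measurement at quadrat scale.

Community types are defined by the dominant species (largest IV, ties
broken lexicographically so the grouping is reproducible); the summary
reports the dominant's own cover and height as mean ± SD, matching how
such tables are conventionally footnoted. The two-group growth
comparison is Welch's unequal-variance *t* test — the safer default when
the invader's trait variance differs from the residual community's —
with significance tiers \*, \*\*, \*\*\* at 0.05, 0.01, 0.001.

## Risk engine (`invade.risk`)

Indicators are scored on [0, 4] so the composite spans the published
classification range [0, 4]; the scale travels with the scoresheet JSON
so other frameworks can reuse the engine. The aggregation is a weighted
sum (introduction), two geometric means (spread, composite), a maximum
(impact) and an arithmetic mean (control). Geometric means make the
composite annihilate when any component is zero — no spread capacity
means no realized risk regardless of impact. Boundary values (1.2, 2.8)
are assigned to the higher-risk level: when a score sits exactly on a
published band edge, the conservative call is the riskier one. The
composite is computed on unrounded components; rounding to two decimals
is display-only.

## Driver GLM (`invade.drivers`)

The response is the invader's plot-level importance value, zero where it
is absent — absence is informative about invasibility, so those rows are
kept. Default predictors are Shannon H plus five bioclimatic variables
(bio1 annual mean temperature, bio6 coldest-month minimum, bio8
wettest-quarter mean temperature, bio17 driest-quarter precipitation,
bio18 warmest-quarter precipitation), sampled from the raster stack at
each plot's grid cell; plots on nodata are dropped and counted.

The family is Gaussian with identity link, fitted by OLS, because the
natural fit statistic for a bounded score reported with a plain R² is
least squares; a quasi-binomial logit alternative sits behind
`family="quasibinomial"` for users worried about the [0, 1] bounds.
Predictors are z-scored (population SD) before fitting so coefficient
magnitudes are comparable effect sizes. Collinearity screening is a
greedy pairwise Spearman filter at |ρ| > 0.75 (the same threshold used
on the SDM side), dropping the member less correlated with the
response.

## Maximum-entropy SDM (`invade.maxent`)

### Model

Presence–background maxent: the species' distribution over cells is the
Gibbs form `q_λ(x) ∝ exp(λ·f(x))` with the partition function computed
over a uniform background sample of valid cells (default 10,000,
seeded, without replacement). Fitting minimizes the L1-penalized
negative presence log-likelihood; raw probabilities over the background
therefore sum to exactly 1 after every fit (a tested invariant).

### Features

Per continuous variable: linear, quadratic, and forward+reverse hinges
at five interior quantile knots; per categorical variable (land cover):
one indicator per observed class. Product features exist but are off by
default — at the presence counts this package targets they mostly add
variance. Every feature is min–max scaled to [0, 1] over the
background, and evaluation *clamps* to those bounds: a presence or
projection cell more extreme than any background cell is pinned to the
background range, the standard maxent treatment (without it the
likelihood is unbounded whenever the presence mean lies outside the
background hull).

### Regularization

`β_j = reg_multiplier × class_β × sd_j(background) / √m`, with class
multipliers 1.0 (linear/quadratic/product), 0.5 (hinge), 0.25
(category) and `m` the presence count — penalties shrink as evidence
accumulates, following common maxent practice, behind a single
user-facing `reg_multiplier`. A tiny ridge term (`l2_penalty = 1e-5`)
keeps the optimum bounded and unique when features are near-collinear
(e.g. a linear and quadratic term of a narrow-range layer); for weights
of ordinary size its contribution is orders of magnitude below the L1
penalty.

### Optimizer

Monotone FISTA: proximal (soft-threshold) gradient steps with Nesterov
momentum, backtracking line search on the smooth majorization, and
momentum restart whenever an accelerated step would raise the penalized
objective — so the recorded objective trace is non-increasing (tested
to 1e-10). Convergence is declared at an iteration improvement < 1e-7
or an L1 subgradient (KKT) residual < 1e-5; the cap is 5000 iterations
and a fit that reaches it unconverged raises, carrying the final gap.

Each iteration's objective drop is credited to variables in proportion
to their features' first-order share `|Δλ_j · ∇_j|`; the accumulated
credits, normalized to 100, are the percent-contribution diagnostic.
Two exactly symmetric copies of one signal therefore split the credit
evenly, and a single-variable model gets 100 %.

### Evaluation and diagnostics

The presence split is 75/25 (train fraction `floor(n·ratio)`, clamped so
both sides are non-empty), seeded. AUC is the rank-based
(Mann–Whitney) probability that a presence outscores a background
point, ties counted ½ — cross-checked against scikit-learn in the test
suite. Permutation importance pools each variable's presence and
background values, permutes them jointly, and normalizes the AUC drops
to 100; variables with all-zero weights score exactly 0. Jackknife
gains report the regularized training gain (`log N_bg` minus the
penalized loss, floored at 0) of the model restricted to each
variable's own features and of the model without them. Response curves
sweep one variable over its background range with the others fixed at
background means (categoricals at their mode). The tuner grid-searches
regularization multipliers × feature-class sets, scored by AICc on the
presence likelihood (k = non-zero weights) by default, or by test AUC.

The output transform is cloglog, the modern maxent default,
`1 − exp(−e^H · q_λ)` with `H` the entropy of the background raw
distribution; logistic and raw are selectable.

### Variable screening

Before fitting, pairwise Spearman |ρ| over presence + background values
above 0.75 marks a pair; the member with the lower single-variable
training gain (linear+quadratic quick fit) is dropped. Constant layers
are flagged and excluded outright.

## Natural breaks and areas (`invade.suitability`)

`jenks_breaks` is the exact Fisher–Jenks dynamic program (vectorized
O(k·n²)) minimizing within-class sum of squared deviations; inputs
above 10,000 values are first subsampled (seeded) and the exact DP runs
on the subsample. Breaks are reported as the minimum value of each
upper class, so classification intervals are left-closed/right-open
with the top class closed — a value exactly on a break belongs to the
higher class. The DP is tested against exhaustive enumeration of all
contiguous partitions for n ≤ 12 over 100 seeded trials.

Areas are cell count × cell area; percentages use the valid
(non-nodata) cell count as denominator, and "total suitable" pools the
low/medium/high classes. Scenario comparison classifies future surfaces
on the *current* surface's breaks, so area deltas reflect suitability
change rather than re-binning; per-scenario re-binning is available by
flag (`invade suitability classify` on each surface). Class deltas on a
fixed domain sum to zero, and the delta operator is antisymmetric —
both tested.

## Synthetic data (`invade.synth`)

The generator produces the study conditions the analyses are tested
under.

* **Landscape**: each layer is moving-average-smoothed white noise
  (kernel width 5 cells by default) rescaled to a subtropical monsoon
  coastal envelope (annual mean ≈ 17.4 °C, annual precipitation
  ≈ 1480 mm; per-layer centers and spreads in `LAYER_RANGES`).
  Cross-correlations are planted by mixing latent fields
  (`child = ρ·parent + √(1−ρ²)·own`); the default plan correlates
  bio16↔bio12 at 0.9 and bio11↔bio1 at 0.85, giving the screening step
  something real to remove while leaving the six driver variables
  mutually below |ρ| = 0.75. Land cover is a five-class quantile
  quantization of its own latent field. A contiguous nodata region can
  be carved from a smooth latent.
* **Occurrences** are sampled from the same Gibbs form the SDM fits
  (probability ∝ exp of a known linear/quadratic predictor on raw
  layers), which is what makes parameter recovery a meaningful test:
  fitted weights, mapped back to raw scale, match the truth
  coefficients within 15 % at 2000 presences / 10,000 background.
* **Surveys**: per plot, companions are drawn from a 30-species ruderal
  pool with Dirichlet abundance shares of varying concentration (so
  Shannon H spreads, ~0.3–2.2 nats); the invader's abundance is pinned
  to a typical companion share so measured H is insensitive to the
  noise term, and its target importance
  `clip(β0 + β_H·H + β_bio6·(bio6 − 2 °C) + ε, 0, 0.95)` is realized
  through its height and cover shares (cover respects the physical
  cover ≤ 1 cap; the residual discretization slack is ±0.05, verified
  at σ = 0). Defaults: β0 = 0.9, β_H = −0.4 (diversity resists
  invasion), β_bio6 = 0.04 /°C (cold limits invasion), σ = 0.20. σ was
  calibrated once so the driver GLM's R² sits near 0.45 at n = 595
  (measured mean 0.44–0.46 across seeds); an earlier construction that
  realized the target through invader abundance was discarded because
  it made measured H co-move with ε (endogeneity), pinning R² near
  0.65 regardless of σ.
* **Scoresheets** are rejection-sampled from level-matched proposal
  ranges until the assessment lands on the requested level; bounded and
  deterministic under the seed.
* **Future scenarios** are independently perturbed stacks: temperature
  layers shifted by 0.9–2.8 °C and precipitation scaled by 0.2–1.2 %
  depending on SSP × period, each with a smooth spatially varying
  component. They emulate warming direction and ordering, not any GCM's
  trajectory.

What passing tests on these data do *not* show: robustness to spatial
sampling bias, detection error, taxonomic misidentification, disjoint
climate extrapolation beyond the background hull (clamped by design),
or real coastline/port geometry. The generator's plots are placed
uniformly over valid cells, so spatial autocorrelation of residuals —
present in any real survey — is absent, and the GLM's standard errors
are accordingly optimistic relative to field data.

## Problem sizes

The test suite and demo run at sizes chosen to exercise every code path
at interactive speed: landscapes 40×40–60×60 cells, 150–400 occurrences,
80–595 plots, 900–10,000 background points; the sign-recovery check runs
100 generator seeds at the full survey size n = 595. The end-to-end demo
(`invade run`) completes in well under a minute on one core.

## Known limitations

* GeoTIFF input is not supported; rasters are ESRI ASCII grids on a
  planar (metric) grid, and no reprojection is performed.
* Percent contribution depends on the optimization path (as in any
  maxent implementation); permutation importance and jackknife gains
  are the path-independent complements.
* The risk engine does not derive indicator values from data; they are
  expert inputs.
* `tune_model`'s AICc uses non-zero weight count as k, a convention
  rather than an exact effective-dimension estimate under L1.
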