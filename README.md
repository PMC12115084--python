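# invade

An invasion-ecology analysis toolkit for port and urban-fringe plant
invasions. It takes the three data streams a field campaign on an
invasive plant typically produces — quadrat community surveys, species
occurrence points, and stacked environmental rasters — and runs them
through a complete, reproducible analysis chain:

1. **Survey statistics** — relative height / cover / abundance, the
   importance value (IV), Shannon–Wiener diversity, occurrence rates,
   family composition, community-type summaries, and Welch *t* contrasts
   of the invader against co-occurring species.
2. **Risk scoring** — a weighted multi-criteria invasion-risk engine:
   fourteen expert-scored indicators (0–4) aggregate into four component
   scores and a composite that maps onto three risk levels.
3. **Driver regression** — a Gaussian identity-link GLM of plot-level
   invader importance on community diversity and bioclimatic predictors,
   with standardized coefficients and significance tiers.
4. **Distribution modelling** — a from-scratch presence–background
   maximum-entropy SDM (linear/quadratic/hinge/categorical features,
   L1-regularized, cloglog output) with AUC evaluation, percent
   contribution, permutation importance, jackknife gains, response
   curves, and an AICc-based tuner over regularization settings.
5. **Suitability classification** — Fisher–Jenks natural breaks into
   non/low/medium/high classes, per-class area accounting (km²), and
   climate-scenario comparisons (SSP1-2.6 / SSP2-4.5 / SSP5-8.5 ×
   2050s / 2070s).
6. **Synthetic data** — generators for correlated environmental stacks,
   Gibbs-sampled occurrences, surveys with a built-in
   diversity-resistance structure, and risk scoresheets, all with known
   ground truth, so the full pipeline runs and is testable without any
   external downloads.

## The models

**Risk score.** With indicator scores `P11 … P43` on a 0–4 scale:

    P1 = 0.3·P11 + 0.3·P12 + 0.2·P13 + 0.2·P14   (introduction & colonization)
    P2 = (P21·P22·P23·P24)^(1/4)                  (spread)
    P3 = max(P31, P32, P33)                       (impact)
    P4 = (P41 + P42 + P43) / 3                    (control difficulty)
    P  = (P1·P2·P3·P4)^(1/4)

and `P ∈ [2.8, 4.0] → level 1 (high)`, `[1.2, 2.8) → level 2`,
`[0, 1.2) → level 3`.

**MaxEnt.** The SDM is the Gibbs distribution over landscape cells

    q_λ(x) = exp(λ·f(x)) / Z_λ,   Z_λ = Σ_background exp(λ·f(x)),

with feature vector `f` scaled to [0, 1] over the background. The
weights minimize the L1-penalized negative presence log-likelihood

    J(λ) = −(1/m) Σ_presences λ·f(x) + log Z_λ + Σ_j β_j |λ_j|,

a convex problem solved by monotone accelerated proximal descent.
Suitability is reported through the cloglog transform
`1 − exp(−e^H · q_λ)` with `H` the background entropy.

**Drivers.** `IV_i = β0 + β_H·H_i + Σ_k β_k·bio_k(x_i) + ε_i`, with
predictors z-scored so coefficients are comparable effect sizes;
a negative, significant `β_H` is the signature of Elton's
diversity–invasibility hypothesis (diverse communities resist invasion).

## Worked example

The whole chain runs on synthetic inputs with one command:

```bash
invade run --output-dir demo_out --seed 42
```

Per-stage summaries from that exact run (also recorded in
`demo_out/manifest.json`):

```
inputs       595 plots, 400 occurrences, 6 future-scenario stacks
survey       occurrence rate 87.1 %
risk         composite 3.54 → level 1 (high risk)
drivers      GLM R² = 0.415 on 595 plots
sdm          test AUC = 0.784, 19 of 21 variables retained
suitability  natural breaks (0.193, 0.395, 0.681); 48.4 % currently suitable
```

Reading the numbers: the synthetic invader occurs in 87.1 % of generated
plots; its scoresheet lands at a composite of 3.54, inside the 2.8–4.0
high-risk band. The driver GLM explains 41.5 % of the variance in the
invader's importance value, with the Shannon-diversity coefficient
negative and highly significant (see `demo_out/glm_coefficients.csv`) —
the diversity-resistance structure the generator plants. The SDM
separates presences from background with AUC 0.784 on the held-out 25 %
split after two collinear variables (|Spearman ρ| > 0.75) were screened
out, and the classified suitability map puts 48.4 % of the valid area in
the low/medium/high classes under the current climate, expanding under
every warming scenario (`demo_out/scenario_table.csv`).

Each stage is also exposed on its own: `invade simulate ...` writes
synthetic inputs, `invade sdm fit|predict|evaluate|contributions|
response|tune` drives the SDM, `invade suitability
classify|areas|compare` does the classification and area accounting, and
`invade risk score` evaluates a scoresheet JSON. The same operations are
importable from `invade.survey`, `invade.risk`, `invade.drivers`,
`invade.maxent`, `invade.suitability` and `invade.synth`.

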