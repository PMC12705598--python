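# Methods

## The model

`fernfusion` fits multi-species, spatiotemporal integrated species
distribution models (ISDMs) of the state-space kind: a latent intensity
process per species, and one observation model per species and data stream.
The latent distribution of species *j* is a log-Gaussian Cox process with
intensity λ_j(s,t) = exp(η_j(s,t)) over grid cells *s* and years *t*, with

    η_j(s,t) = Σ_i β_i X_i(s,t) + u(s,t) + δ_j(s,t) + ω_j(s)·T(s,t)

- **β**: environmental fixed effects, either shared across species or
  species-specific (the shared-component-modelling switch).  Each species
  additionally carries a count-model intercept (always species-specific;
  the source description leaves this implicit, and without it species would
  differ only through their random fields).
- **u(s,t)**: a spatio-temporal field shared by all species, separable as a
  Matérn (ν = 1) spatial field × stationary AR(1) in years; its precision is
  the Kronecker product of the SPDE precision and the unit-marginal-variance
  AR(1) precision.  One configuration replaces it with a purely spatial
  shared field.
- **δ_j(s,t)**: species-specific fields of the same separable form,
  capturing deviations from the common pattern.
- **ω_j(s)**: a spatially varying coefficient (SVC) on the centered year
  code T(s,t) = year − series midpoint.  One spatial field is estimated;
  species 2 and 3 use exact linear scalings α_j·ω with α_1 ≡ 1 and
  Normal(0, 10) priors on α_2, α_3.  Centering T reduces confounding
  between the SVC and the intercepts.

Observation models:

- **Counts.** Population totals surveyed inside fixed polygons are
  redistributed to grid cells proportionally to polygon–cell intersection
  area (largest-remainder integerization, so cell counts sum exactly to the
  population total), with the intersection area |a_s| as offset:
  Y ~ Poisson(|a_s|·λ_j(s,t)) for species 1 and 3, and negative binomial
  (mean μ, variance μ + μ²/ψ) for the overdispersed species 2.
- **Presences.** Opportunistic records are treated as timeless (one spatial
  pattern replicated as independent Bernoulli records in every year) and
  modeled with the complementary log-log link, p = 1 − exp(−exp(η_total)),
  which is exactly the probability of a nonzero count under the latent
  Poisson process.  η_total adds a species presence intercept and an
  observational covariate γ·log(distance to roads) absorbing accessibility
  bias.  By default only the retained presence records enter the
  likelihood (mirroring the "47 locations × 10 years" bookkeeping); a
  utility can expand the support to all cells as explicit Bernoulli trials.

The 22 catalogued configurations (M1–M22) toggle data fusion, shared vs
independent fixed effects, and the three random-effect blocks; the shipped
matrix fixes the catalogue row for row (including the duplicated M4/M5
rows of the original tabulation).

## Priors

Penalized-complexity (PC) priors, calibrated as in the study:

| component | prior | calibration |
|---|---|---|
| Matérn range (u, δ) | π(r) = λ r⁻² e^(−λ/r) | P(r < 5000 m) = 0.1 |
| Matérn marginal sd (u, δ) | exponential | P(σ > 2) = 0.5 |
| AR(1) correlation | PC with base ρ = 1, d = √(1−ρ) | P(ρ > 0) = 0.9 |
| SVC range / sd | same families | P(r < 3000) = 0.5, P(σ > 2) = 0.5 |
| overdispersion ψ | exponential PC on d(ψ) = 1/√ψ | P(ψ < 1) = 0.5 |
| fixed effects | Normal(0, 1000) | — |
| SVC scalings α_j | Normal(0, 10) | — |

The Matérn convention is κ = √8/range (ν = 1), which makes the correlation
at distance = range ≈ 0.139 ("approximately 0.13"); τ is set so σ is the
marginal standard deviation, and the AR(1) precision is scaled to unit
marginal variance so σ remains the marginal sd of the space-time field.

The overdispersion parameterization is genuinely underdetermined by the
study description ("PC prior applied to the gamma parameter"); the choice
here — exponential shrinkage of the excess coefficient of variation 1/√ψ
toward the Poisson limit, calibrated by P(ψ < ψ₀) = α with default
ψ₀ = 1, α = 0.5 — is isolated in `priors.pc_overdispersion_logpdf` and
swappable.

## Mesh

Latent fields live on a Delaunay triangulation built from a deterministic
hexagonal node lattice: spacing just under the inner maximum edge length
(default 1000 m) inside the boundary, a coarser lattice (≤ 2000 m edges) in
a 2000 m extension ring that absorbs the SPDE boundary condition, and a
200 m minimum node distance.  A lattice (rather than iterative refinement)
keeps mesh generation exactly reproducible and honors the edge/cutoff
constraints by construction; the lattice is stretched to land on the
boundary so hull edges stay within the cap.  Note the minimum-distance
guarantee requires max_edge_inner ≥ 2 × cutoff (satisfied by the defaults).

## Inference

Inference is a nested Laplace approximation implemented from first
principles on sparse matrices:

- **Inner loop** — for fixed hyperparameters θ, Newton optimization of the
  latent field x (fixed effects + fields stacked) on the penalized
  likelihood, with backtracking line search; the Gaussian approximation at
  the mode has precision Q_post = Q_prior(θ) + AᵀWA with the per-observation
  curvature W.  Systems are solved by dense Cholesky below 600 latent
  dimensions and sparse LU above.  Convergence: gradient ∞-norm < 1e-6,
  ≤ 50 iterations.
- **Outer loop** — Nelder-Mead on the Laplace-approximate log marginal
  posterior of θ in transformed coordinates (log for positives, arctanh for
  correlations), started at prior medians with an explicit initial simplex
  (step 0.5) and warm-started inner solves.  The latent determinant terms
  use analytic AR(1) determinants and dense Cholesky of the small spatial
  precisions.
- **Hyperparameter uncertainty** — a Gaussian at the outer mode with
  finite-difference Hessian (step 0.05, eigenvalue-floored to positive
  definite).  This replaces full grid integration over θ; posterior
  sampling draws θ from this Gaussian, re-solves the inner problem at each
  draw, and samples the latent field from the resulting Gaussian, so both
  levels of uncertainty propagate into predictions, change maps, WAIC,
  coverage metrics, and cross-validation densities.  Numerically extreme θ
  draws (clipped at ±12 transformed units; non-factorizable precisions)
  fall back to the mode.
- By default the species-specific fields share one (range, σ, ρ) triple
  (`tie_species_hypers=True`), keeping the outer problem ≤ ~8 dimensions at
  desk scale; per-species hyperparameters are available but multiply outer
  cost.

Degenerate inputs: cloglog probabilities are clamped away from {0,1}
(intensity clipped to [1e-12, 50], with a warning); NegBin terms are
computed via log-sum-exp forms that are stable for extreme μ; zero-count
cells contribute −μ exactly.

## Model comparison and diagnostics

- **LPOCV log-score**: each fold removes *all* count observations of one
  population (cells of a population share redistributed individuals, so
  per-observation folds would leak), refits, and scores held-out
  observations by Rao-Blackwellized posterior predictive densities (count
  pmf averaged over posterior draws of μ and ψ).  The log-score is the mean
  log density over non-missing held-out observations (records with no
  observed value cannot be scored, an interpretation the source leaves
  open).  Folds are refit explicitly; fold seeds derive from population
  identifiers so the score is independent of row order.  A
  `freeze_hyperparameters` option fixes θ at the full-data mode and refits
  only the latent field per fold — a speed option used by the scaled-down
  comparison experiments; the default re-optimizes θ per fold.
- **WAIC** = −2(lppd − p_waic) from pointwise posterior log-likelihood
  samples.
- **Coverage report**: percentage of observed counts inside central
  posterior intervals of μ = |a_s|·λ (75/95%), and inside 95% intervals of
  simulated predictive counts; interval amplitudes overall and at missing
  survey years; MAE between observed counts and posterior-mean μ.
- **Spatial redundancy**: percentage of one point set within a buffer
  radius of another (used to compare monitoring and opportunistic
  locations at the posterior-median spatial range).

## Synthetic data

The real monitoring data are restricted-access, so a generator reproduces
their statistical shape end to end: 3 species; 22/17/11 population polygons
with areas drawn log-uniformly inside the observed per-species ranges
(0.24–1.15, 0.34–1.26, 0.65–2.6 ha); per-population missing-year
probabilities from a Beta(1.3, 3.3) clipped to the observed 7–82% band
(median ≈ 27%); counts drawn from the species' observation families with
the polygon–cell intersection offsets; 47 presence locations (24/13/10)
sampled proportionally to intensity × a logistic accessibility weight
decreasing in log road distance (roads are random line segments), then
replicated across all 10 years (470 records).  Covariates are Gaussian
random fields sampled through the same SPDE machinery (one tested sampler),
with optional linear year trends; canopy strata are a softmax of three
fields (closed compositions); a log road-distance surface is always
produced.

Generator defaults the source does not pin down were chosen once for a
stable desk-scale system and are stated here rather than hidden: a
10 km × 10 km domain with 100 m cells; field ranges 3000–5000 m; marginal
sds near 1 (the study's 2–5 on a small domain would exponentiate into
astronomically varying intensities); AR(1) ρ = 0.7 (the study's ≈ 0.99 is
boundary-adjacent and unidentifiable from ≤ 10 annual transitions);
ψ = 0.05 (the study's estimate); intercepts ≈ −6 so per-cell counts land in
the tens.  The scaled-down acceptance experiments state their own sizes:
parameter recovery uses a 4 km domain, 500 m cells, 8 years, 19
populations, ~20-node mesh; the model-comparison experiment uses 6 years,
10 populations, and field scales anchored to the study's magnitude order
(sd ≈ 1, ρ = 0.9) since the reference ordering (spatio-temporal structure
improves prediction) is a claim about data with strong spatio-temporal
signal.

What the generator does **not** emulate: real GBIF metadata beyond the
fields the quality filters touch, raw LiDAR point clouds or DEM
derivatives (the package consumes preprocessed height-class histograms and
covariate grids), non-rectangular study boundaries in the fixture, and
spatial clustering of populations in ravine networks.  Passing tests
therefore demonstrate correctness of the machinery and calibration under
the assumed model, not robustness to the field data's misspecifications.

## Known limitations

- The Gaussian approximation of hyperparameter uncertainty can be poor when
  a variance component is weakly identified (finite-difference Hessians
  then produce very wide, occasionally unstable intervals; these err toward
  over-coverage).
- Nelder-Mead with a bounded iteration budget can stop short on flat
  marginal surfaces; `converged` is reported and perturbation tests guard
  the mode, but multi-start is not automatic.
- The point process is aggregated to grid cells throughout (as in the
  source analysis); no continuous-space LGCP likelihood with integration
  weights is provided.
- Extrapolated-year prediction is refused unless covariates for those years
  are supplied (e.g. via `extrapolate_climate`).
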