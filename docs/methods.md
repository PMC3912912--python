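# Methods

## Meta-regression of discrimination on dietary δ¹⁵N

### Model

Each controlled feeding study *i* contributes an observed diet δ¹⁵N and an
observed consumer δ¹⁵N (or equivalently a discrimination factor
Δ¹⁵N = consumer − diet), with study-level errors treated as known:

    δ¹⁵N_d,i(obs) ~ Normal(θ_d,i, σ_d,i)
    δ¹⁵N_c,i(obs) ~ Normal(θ_c,i, σ_c,i)
    θ_c,i = θ_d,i + β₀ + β₁·θ_d,i + x_iᵀβ_cov + ε_i,   ε_i ~ Normal(0, τ)
    θ_d,i ~ Normal(μ_d, ω_d)

Optional covariates (diet source: artificial vs natural; environment: marine
vs freshwater) enter as intercept offsets for the non-reference level.

The population layer on the latent diets, θ_d,i ~ Normal(μ_d, ω_d), is
essential rather than decorative: it is what lets the model undo the bias
that diet measurement error induces in a naive regression. An alternative —
centring each latent diet's prior on its own observation — was considered
and rejected, because conditioning the prior on the data collapses the
marginal model to the naive regression and forfeits exactly that correction.
Note the direction of the bias here: because the response Δ¹⁵N contains
−δ¹⁵N_d, diet error pushes the naive slope toward −1 (it *inflates* |β₁|),
and the latent-state model corrects |β₁| back toward the truth; the familiar
attenuation-toward-zero statement applies to the structural consumer-on-diet
slope (1 + β₁).

### Marginalization and sampling

All layers are Gaussian, so the latent states integrate out exactly; each
study contributes a bivariate-normal likelihood with

    mean  = (μ_d, (1+β₁)·μ_d + β₀ + x_iᵀβ_cov)
    Var_d = ω_d² + σ_d,i²
    Var_c = (1+β₁)²·ω_d² + τ² + σ_c,i²
    Cov   = (1+β₁)·ω_d²

leaving a 5-to-7-parameter posterior sampled with emcee's affine-invariant
ensemble sampler (vectorized log-posterior; τ and ω_d sampled on the log
scale with Jacobians). Latent-state draws are recovered afterwards by exact
conjugate conditional sampling given each retained parameter draw — θ_d,i
combines its population prior, the diet observation and the consumer
observation through the line; θ_c,i then mixes the line prediction with the
consumer observation. Zero sigmas are handled as numerically infinite
precision (floor 1e-12).

Studies are canonically sorted by study id and observed values before the
likelihood is assembled, so the fit is exactly invariant to the row order of
the input table.

### Priors (defaults)

| parameter | prior | rationale |
|---|---|---|
| β₀, β₁, covariate offsets | Normal(0, 10²) | weakly informative; data-dominated at n ≈ 60 |
| τ (between-study residual, ‰) | half-Cauchy(5) | heavy-tailed, proper |
| μ_d (diet population mean, ‰) | Normal(0, 20²) | spans the experimental diet range |
| ω_d (diet population spread, ‰) | half-Cauchy(10) | as τ |

### Sampler settings

`McmcConfig` counts ensemble moves per chain; kept draws per chain are
(iterations − burn-in)/thin × walkers. The default configuration is the
long-run protocol (100 000 iterations, 80 000 burn-in, thin 10, 20 walkers,
2 independent ensembles, seed 1234). Because the marginalized posterior is
low-dimensional and nearly Gaussian, the ensemble mixes quickly, and the
package's tests and acceptance script use `McmcConfig.short()`
(6 000/3 000/thin 5; ~40 000 retained draws) or a 2 500-move replicate
configuration for repeated-simulation studies; recovered medians agree with
long runs to well within posterior uncertainty.

Convergence is assessed by split-R̂ and ESS (ArviZ), computed across the
independent ensembles: each full ensemble, flattened time-major, is one
chain. Walkers within an ensemble interact, so treating every walker as its
own chain would overstate non-convergence. A fit whose maximum R̂ exceeds
1.01 raises `ConvergenceError` (flagged, never silent); the check can be
disabled for replicate studies where the coverage statistic itself is the
quantity of interest.

Determinism: identical data + config + seed reproduce the posterior draws
and summary tables bit-for-bit.

### Model comparison

Covariate structures are compared two ways, labelled separately in the
output because they answer the question on different model spaces:

- **AIC (ML, marginal)** — a maximum-likelihood fit of the non-latent
  regression Δ¹⁵N_obs ~ Normal(β₀ + β₁·δ¹⁵N_d,obs + x βcov, τ² + σ_c² + σ_d²),
  where AIC is classically defined. The per-study variance omits the
  second-order slope-coupling term σ_d²(1+β₁)²; at the sigmas typical of
  feeding trials (≲0.5‰) this is negligible relative to τ.
- **WAIC (Bayesian)** — computed from the pointwise marginal log-likelihood
  of the hierarchical fit (deviance scale, lower better).

## The scaled framework

A valid narrowing line (β₀ > 0, −1 < β₁ < 0) makes the one-step map
x ← x + β₀ + β₁x an affine contraction with fixed point δ¹⁵N_lim = −β₀/β₁
and factor 1 + β₁ = e^(−k), hence k = −ln(1 + β₁). The forward curve and its
inverse (see README) follow. Edge regimes:

- β₁ ≥ 0: no saturation; the scaled framework is undefined and the additive
  estimator is advised (error raised).
- β₁ ≤ −1: the map overshoots/oscillates; invalid (error raised).
- β₁ → 0⁻: δ¹⁵N_lim → ∞, k → 0 and the scaled estimator converges to the
  additive one with constant step β₀ (verified to 1e-3 at β₁ = −1e-6).

Consumers at or above δ¹⁵N_lim have no finite scaled TP. At point-estimate
level this raises `UndefinedTPError` carrying the offending value; in
posterior propagation the undefined tail mass is reported as
`undefined_fraction` and quantiles are computed over the defined draws
(keeping the median finite while exposing the tail), with an opt-in flag to
treat undefined draws as +∞ instead. Food-web estimation lists fully
undefined specimens in a side report rather than dropping them silently.
Extrapolation below the baseline TL is permitted with a warning — negative
TP offsets are mathematically valid.

Reporting precision is two decimals for TP and δ¹⁵N (‰ throughout); internal
computation is full double precision. TL convention: primary producers TL1,
herbivorous zooplankton TL2; baselines must be TL2 or TL3.

### Known discrepancy in per-step grid values

From the posterior-median line (β₀ = 5.92, β₁ = −0.27) and a 5.2‰ TL2
baseline, the computed per-step discrimination runs 4.52‰ (TL2→3) down to
1.28‰ (TL6→7); from a 10.2‰ baseline, 3.17‰ down to 0.90‰. Published
summaries of the same framework quote 5.1→0.9‰ and 3.3→0.6‰ for these webs —
values that cannot be reproduced by plugging the printed coefficient medians
into the closed form and that plausibly arise from full-posterior summaries
of the derived steps rather than plug-in medians. The package always reports
its computed grid; the in-package recursion oracle (iterating the line map)
confirms the computed values are self-consistent.

## Food-web pipeline

- Baseline pooling is the unweighted arithmetic mean over individuals of the
  listed baseline species (SD and n carried for reporting).
- Group summaries (mean ± SD per functional group) aggregate individuals,
  not species means; a species-level summary is provided separately.
- Baselines are never shared across sites; a specimen table is single-site
  by contract.
- The scaled/additive comparison reports per-specimen differences
  (scaled − additive), per-group aggregates and the maximum absolute
  difference; `crossing_point` locates the non-trivial δ¹⁵N where the two
  estimators agree (both also agree trivially at the baseline).

## Synthetic data

`simulate_experiments` emulates a compilation of fish feeding trials: true
diets Uniform over [0, 20]‰ (the range spanned by the experimental
literature), true discrimination from the line plus Normal(0, τ) residual,
observations plus Normal(0, σ) noise. Defaults are the conditions of the
fish meta-analysis — 59 studies, β₀ = 5.92‰, β₁ = −0.27, τ = 0.4‰,
σ_d = σ_c = 0.3‰ (typical reported study errors). `simulate_foodweb` places
species at known true TPs on the scaled curve and adds Normal individual
variation (default SD 0.4‰, with a 16-individual, 0.8‰-SD zooplankton
baseline pool emulating field baselines).

Ground truth is always emitted as a separate table and never consumed by
estimators. What the generators do **not** emulate: ontogenetic diet shifts,
movement between food webs, taxa beyond fish, tissue-specific
discrimination, non-Gaussian noise (a Student-t option exists for robustness
checks only), and spatial/temporal baseline variation. Passing tests
therefore demonstrate correctness of the estimators under the assumed model,
not robustness to these real-data complications.

## Problem sizes

Test and acceptance runs use the 59-study design at short sampler settings,
20-replicate coverage studies at 2 500 ensemble moves, and food webs of
~100–200 individuals; these sizes give stable summaries (tens of thousands
of retained draws) while keeping a full run to about a minute.

## Limitations

- Single pelagic baseline per web; no dual-baseline (pelagic + benthic)
  mixing.
- Coefficients are fish-specific; other taxa need their own meta-regression.
- The exchangeability, determinism and recovery guarantees are for the
  implemented Gaussian model; heavy-tailed contamination of feeding-trial
  data will widen, not bias-correct, the posterior.
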