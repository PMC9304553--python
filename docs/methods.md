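# Methods

This note documents the models, the defaults and why they were chosen, the
numerical choices inside the samplers, and what the synthetic data can and
cannot say about real cohorts.

## Genotype model

Haplotypes are simulated per LD block from a Gaussian copula: a latent AR(1)
process `x_1 = e_1`, `x_j = rho · x_{j-1} + sqrt(1 - rho²) · e_j` is
thresholded at the per-variant MAF quantile, and the dosage is the sum of two
independent haplotypes. Defaults: `block_size = 50`, `rho = 0.6`, MAF uniform
on `[0.05, 0.5]`, all variants biallelic A/G at 1 kb spacing on one
pseudo-chromosome.

Two properties matter downstream. First, dichotomization attenuates
correlation: two latent variables with correlation `r`, both thresholded at
the median, yield a genotype correlation of `(2/π)·arcsin(r)` (≈ 0.33 for
`r = 0.5`), and more attenuation at skewed MAFs. The package's LD is
therefore moderate even at `rho = 0.6` — deliberately so, since the
benchmark's conclusions require LD to exist, not to replicate any specific
panel. Second, blocks are exactly independent, which lets every Gibbs
sampler run block-local chains.

A dedicated `reference` cohort (default 2,000 individuals) plays the role of
an external LD reference panel: the LD matrices consumed by the PRS methods
are estimated there, never on the GWAS training data. Per-block sample
correlations get a ridge `eps = 0.01` added to the diagonal and are
renormalized to unit diagonal; this keeps every block positive definite even
at modest reference sizes.

## Architecture and phenotypes

Per-sex causal counts are `round(p_causal · M)`; a `shared_fraction` of them
is common to both sexes, the rest private per sex. Shared effects are
bivariate normal with per-variant variances `h²_s / m_s` and correlation
`rg`; `|rg| = 1` is handled analytically (proportional vectors) instead of a
singular Cholesky. Sex-only effects are drawn independently — the genetic
correlation parameter governs only the shared set.

Effects live on the standardized-genotype scale, so `h² = Σ β²`; after
sampling, each sex's vector is rescaled to hit its `h²` exactly. That makes
the configured heritability a controlled truth rather than an expectation,
which removes one layer of Monte-Carlo noise from recovery tests.
Phenotypes are `y = g + ε` with `g = Z β` on per-sex standardized dosages
(means/SDs computed over all individuals of that sex) and
`ε ~ N(0, 1 − h²_s)`, so within-sex phenotypic variance is 1 in expectation.

## GWAS

Synthetic cohorts are unrelated with no structure, so the association model
is plain per-variant OLS — the limit that mixed models reduce to here. The
phenotype is residualized on an intercept (plus a sex indicator for the
pooled scan; configurable) and standardized, dosages are standardized within
the analyzed stratum, and `beta_hat_j = z_j·y / z_j·z_j` with the usual
t-based SE and p-value at `df = n − 1 − #covariates`. Zero-variance variants
are emitted with `se = +inf` and excluded by all downstream samplers.

## LD-score heritability anchor

Under the polygenic model `E[chi²_j] = 1 + n · l_j · h² / M` with
`l_j = Σ_k r²_jk` the within-block LD score. The default estimator fixes the
intercept at 1 — the simulation has no confounding, and with weak or absent
LD the LD scores are nearly constant, leaving a free-intercept slope
unidentified — and reads `h²` off the through-origin regression of
`chi² − 1` on `n·l/M`, clamped to `[0.001, 1]`. A free-intercept variant is
available and raises a degenerate-input error when the LD scores carry no
variation.

## Point-normal sampler

The classical spike-and-slab summary-statistics model: each standardized
effect is 0 with probability `1 − p`, else `N(0, h²/(M·p))`. One Gibbs sweep
visits each variant in block order, forms the LD-residualized marginal
estimate `btilde_j = beta_hat_j − (R γ)_j + γ_j`, computes the closed-form
posterior inclusion probability and slab moments, and samples. The reported
weight is the average over post-burn-in sweeps of the per-iteration
posterior mean `π_j μ_j` (dense) or of the sampled effects with variants
whose inclusion frequency falls below 0.1 zeroed (sparse — this is what
produces exact zeros).

Numerics: the residual vector `R γ` is maintained by rank-one updates and
only touched when a sampled effect actually changes, which makes sparse
cells nearly free; inclusion log-odds are clipped at ±35 before
exponentiation; a divergence guard (any |effect| > 10 on the standardized
scale) restarts the offending block once with the LD ridge doubled and
raises otherwise. Defaults `n_iter = 500`, `burn_in = 100`; there are no
convergence diagnostics, the iteration budget is fixed. The grid is 17
log-spaced `p` values in `[1e-5, 1]`, `h²` multipliers `{0.7, 1, 1.4}`
applied to the LD-score anchor and clamped to `(0, 1]`, and both
dense/sparse — 102 candidate weight vectors.

## Continuous-shrinkage sampler

Global–local prior `β_j ~ N(0, φ ψ_j)` with residual variance fixed at 1
(phenotypes are standardized; this removes one Gibbs step). Conditionals per
block: `β | ψ` is multivariate normal with precision
`n(R + diag(1/(φψ)))` and mean solving `(R + D) μ = beta_hat`;
`ψ_j | β_j, δ_j ~ GIG(a − 1/2, 2δ_j, n β_j²/φ)`;
`δ_j | ψ_j ~ Gamma(a + b, rate = ψ_j + 1)`. Shapes default to the
Strawderman–Berger choice `a = 1`, `b = 1/2`. The global parameter is tuned
on validation over `{1e-6, 1e-4, 1e-2, 1}`; `1e-8` can be added via the
`phi_grid` argument (it is pure extra shrinkage and never wins on these
scales).

The coupled two-stratum variant shares one `ψ_j` per variant across sexes:
the β-step runs independently per sex, the ψ-step pools both sexes,
`GIG(a − K/2, 2δ_j, Σ_s n_s β_sj²/φ)` with `K = 2`. Sample sizes come from
each stratum's summary statistics.

Numerics: each block's full chain is one numba-compiled call (hand-rolled
Cholesky and triangular solves); `1/(φψ)` arguments and GIG parameters are
clamped to `[1e-12, 1e12]`; GIG draws use Devroye's rejection algorithm for
the log-concave standardized form (validated against scipy's `geninvgauss`
density in the tests — scipy's own sampler is ~1000× too slow at one draw
per variant per iteration). In the coupled sampler, each stratum's Gaussian
innovations are keyed to a digest of that stratum's data rather than its
argument position, and the shared shrinkage draws use a common stream; as a
result swapping the two inputs swaps the outputs bit-for-bit and identical
inputs produce identical outputs.

## Tuning, combination, evaluation

All tuning happens on the validation cohort restricted to the sex being
predicted; test phenotypes are touched only by the final R². Single-stratum
scores pick the grid cell with the highest squared correlation (ties to the
first cell in deterministic grid order). Combined sex-specific scores
regress the validation phenotype on `(1, PRS_F, PRS_M)` with unconstrained
coefficients; by default the two component grid cells and the combination
weights are searched jointly over all cell pairs (closed-form two-predictor
R² from cached cross-products, so the 102×102 point-normal pair search is a
single vectorized pass), with a cheaper greedy mode (tune each sex first,
then combine) as an option. Near-collinear profiles fall back to a
single-profile fit. Scoring standardizes dosages with the scored cohort's
own moments and flips weight signs when the effect allele matches the
panel's other allele.

## Benchmark scale

The full pipeline is designed for desk scale: scenario defaults use
`M = 10,000` variants. The ordering suite in the acceptance tests runs
`M = 1,200` with training sizes 1,000/sex (small) and 4,000/sex (large),
6 replicates per scenario, with `p_causal = 0.01` so each panel carries 12
causal variants — at 0.1% causal a desk-scale panel would hold one or two
causal variants and orderings would be dominated by their idiosyncrasies.
Absolute R² at these sizes is *not* comparable to biobank-scale analyses
(per-variant power `n·h²/m_c/M` sits in a different regime); what transfers
are the qualitative orderings: pooling wins at high `rg` or small `n`,
combining sex-specific scores wins at low `rg` and large `n`, and the
coupled sampler's combination dominates the uncoupled one.

## What the generator does not emulate

No relatedness, population structure, sex chromosomes, dominance/epistasis,
genotyping error or missingness, MAF–effect-size coupling, or binary
traits. LD is block-diagonal with no long-range structure, and blocks have
homogeneous latent autocorrelation. Consequently, passing tests demonstrate
correctness of the estimators and the direction of strategy trade-offs under
the stated model — not calibrated performance on any real cohort.

## Known limitations

* The point-normal sampler's fixed iteration budget is sized for desk-scale
  blocks; very large `n·h²` regimes may need more iterations for the `p = 1`
  cells to mix.
* `estimate_h2_ldscore` assumes no confounding (intercept 1); applying it to
  external summary statistics with population stratification will inflate
  the anchor (the multiplier grid partially absorbs this).
* `recommend_strategy` encodes verbal decision rules with configurable
  numeric cut-offs (`rg < 0.8` "low", per-sex `n ≥ 100,000` "large",
  ratio ≥ 5 "unbalanced", h² ratio ≥ 2 "unequal"); the cut-offs are
  interpretations, not estimates.
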