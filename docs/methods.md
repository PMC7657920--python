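# Methods

## The model

`twingfa` implements group factor analysis (GFA): a Bayesian latent
factor model for `M` data views `X^(m) ∈ R^{N×D_m}` sharing the same
`N` samples. Here the samples are within-pair differences of
monozygotic twin pairs (heavier twin minus leaner twin, ordered by
BMI), and the views are clinical, cytokine, genotype, methylation and
dietary matrices. The generative model is

    x_n^(m) ~ N(W^(m) z_n, Σ^(m)),        Σ^(m) = diag(1/τ^(m))
    z_n     ~ N(0, I_K)
    w_dk^(m) ~ h_mk · N(0, 1/α_dk^(m)) + (1 − h_mk) · δ_0
    h_mk    ~ Bernoulli(π_k)
    π_k     ~ Beta(a_π, b_π)
    α_dk^(m) ~ Gamma(a_α, b_α)            (shape–rate)
    τ_d^(m)  ~ Gamma(a_τ, b_τ,d)          (shape–rate)

The beta-Bernoulli layer switches entire per-view loading columns on or
off, so each component is active in an arbitrary subset of views:
components active in two or more views capture shared variation,
single-view components capture view-specific structure, and components
active nowhere ("empty") indicate that `K` was set large enough.
The spike is an exact point mass: loadings are stored as exact zeros
whenever the indicator is off.

Assumptions worth stating: diagonal (per-variable) noise, Gaussian
likelihood for every view (including 0/1/2 genotype dosages and
squashed methylation differences — the model is applied to these
matrices as-is), ignorable missingness (missing cells simply contribute
no likelihood term), and exchangeable components (the posterior is
invariant to jointly permuting/sign-flipping component indices, which
is why comparisons between runs go through assignment matching).

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `K` | 40 | number of components (upper bound; surplus components empty out) |
| `n_iter` | 2000 | Gibbs iterations |
| `burnin_frac` | 0.9 | first 90% discarded; 200 retained draws |
| `noise_target` | 1/3 | prior-mean residual variance as a fraction of column variance |
| `a_π, b_π` | 1, 1 | flat prior on component inclusion probability |
| `a_α, b_α` | 1e-3, 1e-3 | vague ARD prior on slab precisions |
| `a_τ` | 14 | noise-prior strength; `b_τ,d = noise_target·(a_τ−1)·var_d` |

`K`, the iteration budget, burn-in fraction and the noise target follow
the reference analysis protocol. The Beta/Gamma hyperparameters and
the noise-prior strength are not pinned down by that protocol; the
values above are standard weakly-informative choices and all are
configuration keys. With `a_τ = 14` the noise prior is informative
enough to keep residual variances near the target for 43 samples while
still letting clearly explained variables escape it. For standardized
views the prior anchors at unit column variance; the genotype view is
neither centered nor scaled, so its noise prior anchors at each
column's observed variance.

## Preprocessing

Per pair, the twin with larger BMI is "heavier"; an exact BMI tie is a
hard error unless a tie-break variable is configured (the design
presumes discordance, so silent tie-breaking would hide a data
problem). Non-pair-constant variables carry heavier-minus-leaner
differences (missing if either twin is missing). Pair-constant
variables — genotype dosage, age, gender, study year, liver-fat
discordance flags — carry the shared value taken from the heavier
twin, with a hard error if the twins actually disagree. Smoking
(never/former/current) is one-hot encoded before differencing, so its
difference columns take values in {−1, 0, 1}.

Filters, in order: cytokine variables with more than 25% missing
values at the twin level are dropped; after differencing, any variable
with more than 50% missing pairs is dropped; SNPs with nonzero dosage
in three or fewer pairs, or in more than 38 pairs, are removed (alleles
nearly absent or nearly universal cannot explain within-pair
contrasts; "carrier" counts pairs with dosage > 0). All views except
genotype are then mean-centered and scaled to unit column variance.
Centering is not part of the stated reference protocol but is standard
for a factor model with no intercept term; it is configurable
(`center_columns`). The chosen operation order (encode → twin-level
cytokine filter → order pairs → difference → missingness filter →
carrier filter → scale) makes each filter's threshold refer to
pair-level counts; the filters are idempotent.

## Inference

All full conditionals are conjugate. `Z` rows are Gaussian with
precision `I + Σ_m W'·diag(τ)·W` restricted to each row's observed
cells. The `(h, w)` pair for one view/component is updated as a block:
the slab weights are integrated out analytically, giving per-variable
marginal-likelihood ratios `sqrt(α/λ)·exp(b²/2λ)` with
`λ = α + τ·Σ z²`, `b = τ·Σ z·r` over observed cells of the residual
excluding that component; the indicator is drawn from the resulting
Bernoulli and, if on, weights from `N(b/λ, 1/λ)`. Blocking avoids the
mixing pathology of flipping `h` against fixed weights. `π`, `α` and
`τ` follow standard Beta/Gamma updates; where an indicator is off, the
corresponding `α` entries are refreshed from the prior, which is what
keeps the chain invariant for the *full* joint (freezing them would
fail the joint-distribution test below).

Numerical choices: marginal-likelihood ratios are computed in log
space with the log-odds capped at ±700 before the logistic; precision
matrices are factorized (Cholesky), never inverted; Gamma draws with
vague shapes (1e-3) underflow to exact zero about half the time in
double precision, so precision draws are floored at 1e-290. Chains
start from a tame dispersed state (all indicators on, small random
loadings, prior-mean precisions) rather than a prior draw, because a
vague ARD prior can produce astronomically large initial loadings.
The sweep order is `Z` → blocked `(h, w)` per view/component → `π` →
`α` → `τ`. Residuals are maintained incrementally so a sweep costs
`O(N·ΣD_m·K)`. Runs are bit-reproducible from the seed. The log joint
density is recorded every iteration as a convergence trace; no formal
diagnostic is applied automatically.

Storage: full retained draws for `H`, `π` and `Z` (small), streaming
means/variances for `W`, `α`, `τ` (large at thousands of variables),
bounding memory at the full study dimensions.

## Component summaries

A component is *active* in a view when its posterior inclusion
probability (mean of `h` draws) exceeds 0.5 — the threshold is a
documented package choice, configurable, since no posterior criterion
for "empty" is pinned down by the reference protocol. Components
active nowhere are pruned. Variance explained per component and view
is `Σ_d w̄²_dk / (Σ_k' Σ_d w̄²_dk' + Σ_d 1/τ̄_d)`, i.e. the share of
model-implied variance under unit-variance scores. Matching between a
fit and ground truth (or another fit) solves the exact assignment
problem maximizing summed |Pearson r| between score columns, because
the model identifies components only up to permutation and sign.

## The synthetic cohort

The generator plants within-pair differences drawn from the model
itself with a known view×component activity mask, then reconstructs
twin-level values (pair mean ± half the difference) so that the
preprocessing chain reproduces the planted matrices exactly. Defaults
mirror the emulated study design where it states numbers: 43 pairs, 25
of them BMI-discordant beyond 3 kg m⁻², five views, noise variance
one-third, pair-identical genotype. Scaled-down view dimensions
(20/20/60/60/20) keep routine tests fast; the `paper-scale` preset
(42/71/1587/1605/63) reproduces the full dimensions. The clinical
width includes the BMI, smoking-indicator and demographic columns the
generator always adds, so the preprocessed clinical view comes out at
its stated width. Genotype dosages are Hardy–Weinberg draws with minor
allele frequencies uniform on (0.05, 0.5), subjected to the carrier
filter like real data. Methylation-like columns are an affine squash
of the Gaussian differences into [0, 1]; no logit transform, since the
model is applied to such values directly. Missingness is injected
completely at random, at modest default rates (1–5% depending on the
view; no rates are stated for the emulated study) — MCAR is a design
choice and a config hook, not a claim about real missingness
mechanisms.

Ground-truth activity masks use *distinct* per-component activity
patterns. Two components active in exactly the same set of views are
identified only up to rotation (the Gaussian slab is rotation-invariant
within a shared pattern), so score-correlation recovery against truth
is ill-posed for repeated patterns; with distinct patterns the
sparsity structure pins each component down. Recovery simulations in
the test suite use a fixed such mask over three views.

What passing the synthetic tests does **not** show: robustness to
non-Gaussian tails, informative missingness, LD structure among SNPs,
methylation autocorrelation, or dietary measurement error — none of
which the generator emulates.

## Validation strategy

* Every conditional is checked against a closed form or an independent
  oracle: the blocked inclusion probability against 1-D quadrature over
  the slab weight (to 1e-8), the Gaussian/Beta/Gamma updates against
  analytic moments, the log joint against an explicit term-by-term
  summation with scipy.stats.
* A joint-distribution test (successive-conditional vs
  marginal-conditional simulation) runs 2×10⁵ sweeps on a tiny instance
  (N=5, M=2, D=(3,4), K=2) and compares first and second moments of
  five monitored scalars within 4 Monte-Carlo standard errors; this
  jointly validates every conditional against the generative joint.
  The test uses moderate hyperparameters (ARD shape 6) because the
  monitored second moment of `w²` has no finite variance under vaguer
  shapes, which would invalidate the z-test, not the sampler.
* Parameter recovery: data planted with 6 components across 3 views
  (N=100, D=30/40/50, noise 1/3), fit with K=15 for 2000 iterations,
  must recover ≥5 of 6 components at |r| ≥ 0.8 with ≥90% activity-mask
  agreement in ≥4 of 5 seeds; K_true=3 data fit at K=10 must leave a
  retained-component count with mode 3 across 20 seeds.
* The full-dimension load check times a short chain at the complete
  study scale (five views, ~3300 variables, K=40) and projects the
  2000-iteration cost, which comes out near 9 minutes on one CPU.

## Known limitations

Single chain by default (matching the reference protocol); assessing
between-chain component stability requires running `run_chain` with
several seeds and `match_components`. Posterior summaries for `W` are
streaming means/variances, not full draws. The Gaussian likelihood is
a modelling approximation for dosage and beta-valued data. No
automatic convergence decision is made; inspect `log_joint_trace`.
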