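# Methods

## The model

The package models the probability that a *conception* cycle yields a
female baby, as a function of which days of the fertile window had
intercourse and of the woman's follicular-phase length.  Only cycles that
ended in conception enter the likelihood; the mucus-peak day (last day of
best-quality cervical mucus, a retrospective proxy for ovulation) anchors
the 12-day fertile window, relative days −8 … +3.

Let `Y_i ∈ {0, 1}` (0 = male, 1 = female) be the sex of the baby from
cycle `i`, `X_ik ∈ {0, 1}` the intercourse indicator for window day `k =
1..12`, and `z_i ∈ {1..4}` the follicular-length class (≤13, 14–16, 17–19,
>19 days from first menstruation day to the mucus reference day).  Each
intercourse day is an independent Bernoulli opportunity to "produce a male";
the cycle yields a female only if no day does (the aggregated Bernoulli
structure — the cycle outcome, not the responsible act, is observed):

    P(Y_i = 1 | X_i, z_i) = ∏_k (1 − q_ik)^{X_ik}

with complementary log-log day hazards

    q_ik = 1 − exp(−λ_k ξ_i),     ξ_i = ∏_{h=1}^{z_i − 1} γ_h .

* `λ_k > 0` — hazard-scale baseline for day `k`.  It is **not** itself a
  probability (its gamma prior is unbounded above); the implied single-day
  male probability `1 − exp(−λ_k ξ)` is available as a reporting option in
  `summarize(..., include_day_probability=True)`.
* `γ_h > 0` — multiplicative effect of moving from follicular class `h` to
  `h+1`; `γ_h = 1` means "no effect of that step".
* `ξ_i` — the cycle-level multiplier; class-1 cycles have `ξ = 1`, so `γ`
  is not identified from class-1 cycles alone.

The survival form makes `P(female) = exp(−ξ_i Σ_k X_ik λ_k)`; a cycle with
no fertile-window intercourse would contribute `exp(0) = 1` regardless of
the parameters, so such records are rejected at ingest.

## Priors and hypothesis testing

`λ_k ~ Gamma(a0k, b0k)` independently, default `a0k = b0k = 1` (diffuse,
mean 1).  Each `γ_h` gets a **one-inflated gamma** prior: a point mass at 1
with probability `π_h`, else `Gamma(a0h, b0h)`.  Defaults `π_h = 0.5^{1/3}`
— so the joint null "no follicular-length effect at any step" has prior
probability exactly 0.5 — and `a0h = b0h = 0.1`, diffuse under the
alternative.  Because the sampler sets the point-mass state *exactly*,
`P(γ_h = 1 | data)` is estimated as the fraction of retained draws equal to
1 (exact `==` comparison is valid, and is how the summary computes it).

## Posterior computation

Augment with independent `W_ik ~ Poisson(λ_k ξ_i X_ik)`: the cycle is male
iff `Σ_k W_ik ≥ 1`.  Gibbs sweeps use a fixed scan (latents, λ₁..λ₁₂,
γ₁..γ₃), all moves exact conditional draws:

1. **Latents.**  Female cycles: `W = 0`.  Male cycles: the total is drawn
   from a ≥1-truncated Poisson with rate `η_i = ξ_i Σ_k X_ik λ_k` by exact
   inverse CDF — a pmf-recursion scan for rates ≤ 30 and `poisson.ppf`
   above (no rejection loop, so tiny rates cannot stall) — then allocated
   across intercourse days multinomially with weights `λ_k X_ik`,
   implemented as a chain of conditional binomials vectorised over cycles
   (distributionally identical to a per-cycle multinomial draw).
2. **λ update.**  Conjugate:
   `λ_k | · ~ Gamma(a0k + Σ_i W_ik, b0k + Σ_i X_ik ξ_i)`.
3. **γ update.**  For each `h`, with `A_h = Σ_{i: z_i>h} Σ_k W_ik` and
   `B_h = Σ_{i: z_i>h} Σ_k X_ik λ_k ∏_{h'<z_i, h'≠h} γ_{h'}`, the full
   conditional is again one-inflated gamma: point mass at 1 with weight
   `π_h e^{−B_h}` against `(1−π_h) b0h^{a0h}/Γ(a0h) ·
   Γ(a0h+A_h)/(b0h+B_h)^{a0h+A_h}`, else `Gamma(a0h + A_h, b0h + B_h)`.
   The mixture weight is evaluated in log space (`gammaln`, `logaddexp`),
   stable for latent-count sums beyond 10⁴.

Initialisation: λ from its prior, γ at 1 (inside the point-mass state, so
both mixture branches are exercised immediately).  Chains use numpy's
PCG64 generator with per-chain seeds `seed + chain_index`, making runs
bit-reproducible across platforms.  Defaults mirror common practice for
this model class: 5,000 burn-in, 40,000 retained iterations, 2 chains,
no thinning.

### Correctness oracle

`brute_force_posterior` integrates prior × likelihood *without*
augmentation on instances with ≤ 3 continuous dimensions (days with any
intercourse + class steps any cycle crosses).  Each dimension is
transformed to prior-quantile space, so every 1-D integral is an
expectation of a smooth bounded function evaluated by the midpoint rule
(this also absorbs the integrable density singularity at 0 when the gamma
shape is < 1); point masses are handled by enumerating which γ's sit at 1
and weighting branches by `π_h` / `1−π_h`.  Error decreases as the grid is
refined (checked by a refinement test); at the default 200 points per
dimension the quadrature error is far below the Monte-Carlo error of the
chains it arbitrates.

The sampler is additionally validated by a successive-conditional
simulation (`prior_preservation_draws`): draw parameters from the prior,
simulate data, alternate one Gibbs sweep with re-simulation of the data.
A correct sampler leaves the parameter marginals exactly at the prior;
the test suite compares them by Kolmogorov–Smirnov distance and point-mass
frequency, with thresholds slackened ~3× over the iid bounds to absorb
sweep-to-sweep autocorrelation.

## Summaries and diagnostics

`summarize` pools post-burn-in draws across chains: mean, median, SD, and
the 95% equal-tailed credible interval as the 2.5%/97.5% empirical
quantiles with linear interpolation (numpy's default), so summaries are
reproducible to the digit.  Equal-tailed intervals are the convention here;
HPD intervals are deliberately not offered.

Diagnostics are the classical forms, implemented in-package because the
contracted behaviours (exact `sqrt((n−1)/n)` at zero between-chain
variance, defined errors on constant chains) differ from the
rank-normalised variants in modern libraries:

* **Geweke z** — means of the first 10% and last 50% of a chain,
  standardised by spectral-density-at-zero variance estimates (via the
  integrated autocorrelation time).
* **Gelman–Rubin** — classic PSRF `sqrt(((n−1)/n · W + B/n)/W)` on the
  chains as given (no splitting, no df correction).
* **ESS** — `n / (1 + 2 Σ ρ_t)`, autocovariances via FFT, the sum
  truncated by Geyer's initial-positive-sequence rule (adjacent-pair
  sums kept while positive).

Constant chains raise `DegenerateChainError`; the CLI's diagnostics table
records NaN for that parameter and continues.

## Synthetic data

Real cycle-level data of this kind are restricted-access, so the generator
is a first-class module.  Per cycle it draws: intercourse indicators
independently per day with the observed per-day marginal frequencies of
the joined European/Italian studies (day 0 = 0.3896, …); a follicular
class with the observed proportions (0.2821, 0.2975, 0.2284, 0.1919,
renormalised — the published percentages sum to 99.99 from rounding); and
the sex from the model at configurable true parameters (defaults λ ≡ 0.5,
γ ≡ 1, a realistic no-effect regime giving female fractions near the
observed order).  Default `n = 521` matches the joined studies.

Choices worth knowing:

* Days are independent within a cycle.  Only marginal day frequencies are
  published, any correlation structure would be invention, and the
  inference model assumes conditional independence anyway.  Real intercourse
  patterns are certainly serially dependent; passing tests therefore say
  nothing about robustness to that dependence.
* All-zero intercourse draws are redrawn (keeping `n` exact), which
  inflates every day marginal by the factor `1/(1 − ∏(1 − p_k))` ≈ 1.028;
  the tests check the conditioned marginals against exactly that target.
  With `min_one_intercourse=False` the raw draw is exposed and all-zero
  rows are dropped instead (they cannot form valid cycles).
* Each class is given a representative in-bin length (12, 15, 18, 22 —
  class 1's bin has no lower edge, so a literal midpoint does not exist);
  only the class enters the model.
* Study labels EU/IT/NZ are attached with weights 375:141:78 (the
  studies' conception-cycle counts) purely to exercise subset refits; the
  generator does not model between-study differences.
* Women contribute one cycle each; the model treats cycles as independent
  anyway (no random effects), so within-woman dependence is deliberately
  not simulated.

`parameter_recovery_experiment` wires generator → sampler → summaries into
a replicated truth-recovery report (coverage of 95% intervals, posterior
point-mass mass under null and non-null truths).

## Problem sizes used in the shipped tests

Oracle-agreement checks run 30-cycle, two-day reduced instances with
1,000 + 8,000 iteration chains against a 160–200-point/dimension
quadrature; recovery runs 10 replicates of n = 2,000 (null truth) and 3 of
n = 5,000 (γ₁ = 3) at 1,000 + 5,000 iterations; prior preservation uses
12,000 sweeps at n = 10, thinned by 4.  These sizes keep Monte-Carlo
standard errors well inside the tolerances being asserted while the whole
suite stays fast; they are package defaults for testing, not statements
about what real analyses should use (for those, the 5,000 + 40,000
defaults apply).

## Known limitations

* No woman-level random effects: repeated cycles from one woman are
  treated as independent, as in the model equations.
* The follicular-length effect is categorical and multiplicative-ordinal;
  continuous or day-by-class interaction effects are out of scope.
* Missing follicular length is tolerated at the data layer; such cycles
  are simply excluded (with a logged count) when the covariate model is
  fitted.
* The Geweke window fractions (0.1/0.5) and the ESS truncation rule follow
  common practice; other choices would give slightly different numbers.
* Identification of the mucus peak from raw mucus scores, and reconciling
  the two studies' different mucus scales, happen upstream of this package:
  inputs arrive with the window already anchored.
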