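# Methods

## Model

The package implements the standard contrast-based hierarchical model for
network meta-analysis of aggregate trial data.

**Likelihoods.** A two-arm trial reporting a relative effect contributes one
log-scale datum `y_i ~ Normal(δ_i, V_i)` with `V_i = SE_i²` treated as known.
A trial with `m+1` arms contributes `m` contrasts against its baseline arm.
Arm-level binary data enter as `r_ak ~ Binomial(n_ak, p_ak)` with
`logit p_ak = μ_a + δ_ak·1[k ≠ baseline]`; the per-study baselines `μ_a` are
nuisance parameters with Normal(0, 15²) priors.

**Hierarchy.** Under random effects the trial-specific true contrasts follow
`δ_i ~ Normal(d_t2(i) − d_t1(i), σ²)`, with covariance `σ²/2` between
contrasts of the same multi-arm trial (the exchangeable-arms structure).
Under fixed effects `δ_i = d_t2 − d_t1`. The basic parameters `d_k` (one per
treatment, reference fixed at 0) get `Normal(0, s²)` priors with
`s = 15·max(1, max|y|)` by default — vague relative to the log-ratio range
the model is used on (natural-scale ratios of roughly 0.03–40) — and
`σ ~ Uniform(0, 5)`. Both scales are configurable.

**Inconsistency.** The unrelated-mean-effects (UME) structure replaces the
consistency relation with one free mean per observed comparison; comparing
its DIC with the consistency model's is the global inconsistency check.
Node-splitting decouples one comparison's direct contrasts onto a free
parameter; the indirect estimate is the network's functional value
`d_B − d_A`, and the two-sided Bayesian p-value is
`2·min(Pr(diff>0), Pr(diff<0))` over jointly sampled draws, floored at
`2/draws` so it is never reported as 0.

## Sampling

All conditionals under the normal likelihood are Gaussian, so the sampler is
a Gibbs scheme: vectorized conjugate updates for the `δ` of independent
two-arm trials, joint multivariate-normal block updates for the `δ` of a
multi-arm trial (the 2×2/3×3 posterior precision is `C⁻¹/σ² + Σ_data⁻¹`; we
draw the block jointly via its Cholesky factor rather than through the
conditional-univariate decomposition — both are exact, the joint draw is
simpler and mixes at least as well), a joint conjugate draw for `d`, and
slice sampling (stepping-out with shrinkage) for σ on its bounded support.
Binomial-logit parameters (`μ_a` and the `δ` of binary studies) use
random-walk Metropolis with per-parameter scales adapted toward 44%
acceptance during burn-in only, so the retained chain is Markov. A
fixed-effect model on purely normal data has an exact Gaussian posterior and
the "chains" are i.i.d. draws from it.

Chains are initialized deterministically from the seed: chain `c` starts the
basic parameters at the `c`-th of {0, +0.5, −0.5, +1}·(prior SD/10) and σ at
equally spaced quantiles of its prior. Each chain's RNG derives from
`SeedSequence([seed, chain])`, so reruns are bit-identical and pooling is
order-invariant. Defaults mirror common practice for this model class —
4 chains × 100 000 iterations including 50 000 burn-in, thinning 10
(5000 retained per chain); the test suite and acceptance script use reduced
settings (2 × 1500/500/2 for random effects, 2 × 3000/1000/1 for exact
fixed-effect posteriors), which the Gibbs sampler's near-i.i.d. mixing on
these small networks makes sufficient.

**Deviance.** Residual deviance is `(y−θ)ᵀΣ⁻¹(y−θ)` per normal block
(θ = δ for random effects, Xd for fixed) and the saturated binomial deviance
per arm. `pD = Dbar − D(θ̄)` uses the plug-in at the posterior mean of the
shrunken effects, `DIC = Dbar + pD`. On well-specified data `Dbar/n ≈ 1`;
because a single 12-contrast network gives that ratio a sampling SD near
0.3, the calibration check averages 20 replicate datasets.

**Diagnostics.** Split-chain PSRF is computed directly (two frozen chains at
different values report ∞ rather than an exception; a single chain reports
PSRF unavailable), autocorrelations at lags 1–50 by FFT, and effective
sample size via ArviZ.

## Derived summaries

League tables take medians and credible bounds of `d_col − d_row` on the log
scale and exponentiate, so reciprocal cells satisfy
`cell(r,c)·cell(c,r) = 1` to machine precision. Rank probabilities tally a
direction-aware ordering of each posterior draw (reference included at 0;
exact ties broken by treatment order, a measure-zero event); SUCRA is the
mean cumulative rank probability over ranks `1..a−1`, giving
`Σ_k SUCRA_k = a/2` identically. The clustered ranking pairs the SUCRA of an
efficacy outcome with that of a safety outcome; k-means labels (seeded
centroids, k = 3 by default) are optional cosmetics, while the non-dominated
set is the principled summary. Funnel points are centered on the
comparison-specific fixed-effect pool regardless of the heterogeneity rule —
the funnel asks about asymmetry around the common effect — and single-study
comparisons are centered to exactly zero.

## Effect reconstruction

Three conversions recover `(log effect, SE)` from published summaries:

- From a ratio with a 95% (or other) CI: `SE = (ln U − ln L)/(2z)`. The
  round trip is exact only for log-symmetric intervals; published rounded
  intervals reproduce to ~2 decimal places.
- From a two-sided log-rank p-value with total events and arm sizes:
  `V = e·n1·n2/(n1+n2)²`, `log effect = ∓Φ⁻¹(1−p/2)/√V`, sign chosen by the
  favoured arm.
- From tabulated survival curves sharing a time grid: each interval
  contributes `ln(ln S_t ratio / ln S_c ratio)` of conditional survivals
  (equal to the log hazard ratio under proportional hazards) with variance
  `1/e_c + 1/e_t` from expected events `e = n_eff·(S(t_a)−S(t_b))/S(t_a)`;
  `n_eff` comes from reported numbers at risk when available, otherwise from
  the censoring-free expectation `n_enrolled·S(t_a)`. Intervals with fewer
  than one expected event in either arm are dropped and the rest pooled by
  inverse variance. Which conversion applies to which study is the data
  curator's choice; the reader rejects duplicate (study, comparison) rows
  rather than resolving competing estimates itself.

## Synthetic data

The generators emulate the structure of a first-line targeted-therapy
evidence base, and their defaults are the package's reference study
conditions: 5 treatments (placebo and an active standard as hubs), 12 trials
of 2–3 arms, exactly one closed loop so node-splitting has one testable
cycle, per-arm event counts of 80–260 giving contrast SEs near 0.1, true
log hazard ratios between −0.5 and 0.15, and σ = 0.15 (the low end of the
heterogeneity posteriors typical for survival endpoints; adverse-event
networks run nearer 1). Observed effects add independent data-level noise
`N(0, V)` with `V = 1/e₁ + 1/e₂`. The binary generator draws baseline logits
`N(−0.85, 0.4²)` (event rates near one third) and binomial arm counts. The
Kaplan–Meier generator uses exponential survival with uniform censoring on
(horizon/2, horizon) and tabulates lifelines' KM estimate with numbers at
risk.

What the generators do **not** emulate: correlated data-level errors within
multi-arm trials (published HRs come without baseline-arm covariances, so
the model also treats them as independent at the data level unless a
covariance is supplied — matching limitation, made explicit), non-proportional
hazards, informative censoring, outcome-reporting selection, and
between-trial differences in effect modifiers. Passing recovery tests
therefore validates the estimation machinery under the stated model, not
robustness to those violations.

## Validation design

- Fixed-effect NMA is checked against an independent generalized-least-
  squares solution (max |difference| < 0.02), and a two-step chain against
  the closed-form sum of normals.
- Random-effects recovery uses 200 replicate networks at σ = 0.15 with
  reduced MCMC: 95% CrI coverage must land in [0.90, 0.99] and mean bias
  within ±0.03.
- Node-split error rates are measured on a minimal triangle with contrast
  SEs of 0.1, generated with σ = 0 and fitted with fixed effects — the
  sharpest calibration condition, and the one matching the z-test oracle
  `y_AB vs y_AC + y_CB`: type-I rate 0.05 ± 0.03 over 200 replicates and
  ≥ 80% power at an offset of 1.0 over 50.
- League/ranking identities are asserted at machine precision; pooling
  formulas against hand computations and statsmodels.

## Known limitations

- Contrast-level multi-arm input without a supplied data covariance is
  treated as independent at the data level (the σ²/2 random-effect
  correlation is always applied).
- Node-splitting assigns a trial to the direct parameter only when it
  reports an explicit contrast on the split pair; a multi-arm trial touching
  both endpoints only through its baseline stays in the network part.
- The binomial path relies on random-walk Metropolis and needs more
  iterations than the conjugate normal path for the same precision.
- P-scores, meta-regression, arm-based models and design-by-treatment
  interaction tests are out of scope.
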