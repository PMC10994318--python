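# Methods

## Model

Let tᵢ⁽F⁾ and tᵢ⁽S⁾ be the signed group-difference statistics for
functional and structural connectivity on link *i* (i = 1…L unordered
region pairs), and write tᵢ = |tᵢ⁽F⁾|, sᵢ = |tᵢ⁽S⁾|.  The two-group
mixture is

- wᵢ ∈ {0, 1} latent, P(wᵢ = 1 | sᵢ) = πᵢ = logit⁻¹(η₀ + η₁ sᵢ);
- wᵢ = 0 (null): tᵢ ~ folded normal with zero mean and variance σ²,
  density f₀(t) = √(2/(πσ²)) · exp(−t²/2σ²);
- wᵢ = 1 (alternative): tᵢ ~ Gamma(α(sᵢ), β) with rate β and log-linear
  shape α(s) = exp(γ₀ + γ₁ s).

The BLfdr of link *i* is the posterior probability that wᵢ = 0 given
(tᵢ, sᵢ).  Conditional on the parameters it is the two-component Bayes
ratio; the reported value is the posterior mean of 1 − wᵢ over MCMC
draws, i.e. marginalized over parameter uncertainty.

Key assumptions: the null statistic magnitude is folded-normal with a
*common* variance across links (σ² is estimated, not pinned to 1, so a
variance-inflated empirical null is representable); SC influences FC
non-nullness only through |t⁽S⁾|, monotonically on the logit scale; the
alternative magnitude distribution is right-skewed gamma whose shape —
not rate — carries the SC modulation.  Signs are not modeled; they are
used downstream to classify hyper- vs hypoconnectivity.

## Priors and sampler

Defaults (all proper, weakly informative on the t-statistic scale):
(γ₀, γ₁) and (η₀, η₁) iid Normal(0, 10²) per coordinate; σ² ~
Inverse-Gamma(2, 2); β ~ Gamma(1, 1) (shape/rate).

Metropolis-within-Gibbs per iteration:

1. wᵢ | rest ~ Bernoulli(1 − BLfdrᵢ(params)), independent across links;
2. σ² | w: conjugate Inverse-Gamma(a₀ + n₀/2, b₀ + Σ_{w=0} tᵢ²/2)
   (half-normal likelihood);
3. β | w, γ: conjugate Gamma(c₀ + Σ_{w=1} α(sᵢ), d₀ + Σ_{w=1} tᵢ);
4. (γ₀, γ₁) and (η₀, η₁): Gaussian random-walk Metropolis, one 2-vector
   block each.

Proposal covariances are adapted during burn-in only (isotropic tuning
for the first 200 iterations, then the adaptive-Metropolis rule
2.38²/d × empirical covariance of the recent burn-in draws with a
Robbins–Monro acceptance correction toward 0.3) and frozen afterwards,
so the kept draws come from a valid fixed-kernel chain.  Without the
covariance adaptation the strongly correlated (β, γ₀) pair mixes poorly
(split-R-hat ≈ 1.5 at 8 000 iterations; ≈ 1.02 with it).

Defaults: 4 chains × 10 000 iterations, 5 000 burn-in, thinning 5; seeds
are spawned per chain from one master `SeedSequence`.  R-hat (via arviz)
is reported per scalar parameter and values above 1.1 are flagged on the
result.  Replicate studies in the test-suite and acceptance script use
2 chains × 4 000 (2 000 burn-in, thin 2), which the recovery results
show is adequate at L ≈ 3 741.

Numerical choices: densities are evaluated in log space; |t| is floored
at 1e-8 before gamma-density evaluation (α < 1 makes f₁ unbounded at 0);
α(s) is capped at 1e6 to keep exp() finite; a non-finite sampler state
raises immediately with the iteration index.  Links are canonicalized
(sorted by region pair) before sampling, so results are invariant to
input row order.

## Decision rule

Sort BLfdr ascending and reject the largest prefix whose running mean is
≤ q (running means of sorted values are nondecreasing, so feasible
prefixes form an initial segment).  The estimated FDR of the rejected
set — the mean BLfdr among rejections — is ≤ q by construction.  Links
tied at the cutoff value enter together or not at all; since including a
split tie group can only raise the running mean above q, such a group is
dropped entirely, preserving the bound.

## Stage-1 statistics

`welch`: per-link Welch t, oriented disease − control.  `lmm`: a joint
model over all links and subjects, y_ij = μᵢ + δᵢ g_j (+ per-link
covariate terms, e.g. age) + b_j + ε_ij with b_j ~ N(0, τ²) shared
across links within subject and Var(ε_ij) = σ²_{i,g(j)} specific to
link × group; tᵢ = δ̂ᵢ / SE(δ̂ᵢ).

Estimation alternates (i) per-link weighted least squares of y − b̂ on
the subject-level design, (ii) BLUPs of b given the variances, and
(iii) closed-form variance updates, to relative tolerance 1e-8 within
200 iterations.  Two numerical points matter:

* τ² is updated by solving its profile score equation directly
  (method-of-moments on the precision-weighted subject residual sums),
  not by EM, which crawls at O(1/k) near the τ² = 0 boundary; estimates
  within one null-sampling sd of zero are pinned to the boundary, with
  hysteresis so the estimate cannot oscillate on and off it.
* The subject effect's projection onto the subject-level design (its
  group-mean difference, in the balanced case) is confounded with the
  fixed effects and cannot be absorbed by the BLUPs, so the coefficient
  covariance adds τ²·A(XᵀW²X)A, A = (XᵀWX)⁻¹ — for a balanced two-group
  design exactly τ²(1/n₀ + 1/n₁) on the group contrast.  Omitting this
  term anti-conservatively inflates every tᵢ when subjects differ in
  overall level.

When τ̂² = 0 and no covariates are present, tᵢ equals Welch's t exactly
(residual variances use n_g − 1 denominators).  Zero-variance links are
dropped with a warning.  statsmodels' MixedLM cannot express the
link-by-group heteroscedasticity, so this estimator is implemented
directly.

## Efron baseline

Two-sided unimodal local fdr on the signed t⁽F⁾ alone: the marginal
density f is fitted by Poisson regression of histogram counts (120 bins)
on a natural cubic spline basis (df = 7, patsy `cr`, statsmodels GLM);
the empirical null N(δ₀, s₀²) is fitted by truncated-normal maximum
likelihood on the central 10th–90th percentile window, and p₀ is the
window mass ratio (clamped to 1).  lfdr = min(1, p₀ f₀ / f).  The
central window is wider than the conventional interquartile choice
because a ±0.67 sd window barely identifies s₀ (errors of 30–60% on
pure-null draws in our checks); ±1.28 sd recovers s₀ within a few
percent while staying predominantly null under sparse alternatives.
Decisions use the same cumulative-mean rule as the multimodal method, so
method comparisons are rule-matched.

## Synthetic data

`simulate_statistics` draws directly from the mixture model: a fraction
`sc_alt_frac` (default 0.1) of links take s from Gamma(4, 1) (elevated
SC signal), the rest from |N(0, 1)|; then w | s ~ Bernoulli(π(s)) and
|t⁽F⁾| from the matching component; signs are uniform ±.  Defaults
(σ² = 1, β = 1, γ₀ = 1, γ₁ = 0.2, η₀ = −4, η₁ = 0.6 at L = 3741) give
≈ 4–5% non-null links with mean alternative magnitudes around 4–6 —
sparse but identifiable, the regime the method targets.  Because w | s
is exactly logistic, this generator is model-faithful and supports
parameter-recovery and FDR-control checks.

`simulate_subjects` generates the full pipeline's input: 87 regions,
21 + 21 subjects (the scale of the motivating LLD study); FC per
(link, subject) is Normal(0.3 + 1{disease, disrupted}·0.25, 0.2²) in
Fisher-z units, i.e. disrupted links shift by 1.25 within-subject sd,
which puts their expected |t| near 4 — the magnitude range of the
published significant links; SC is Poisson fiber counts (mean 40, or 48
for disease on SC-disrupted links), cube-root transformed.  About 21 of
3741 links are FC-disrupted (`prop_disrupted = 21/3741`); an
FC-disrupted link is SC-disrupted with probability `coupling` (default
0.9), other links at the base rate — the partial coupling that makes
|t⁽S⁾| informative.  Poisson counts at these means make SC group
differences easy to detect (|t⁽S⁾| ≈ 5–10 on disrupted links), so the
generator represents a favourable-but-plausible multimodal scenario.

What these generators do **not** emulate: spatial correlation between
links sharing a region, heavy-tailed or site-dependent FC noise,
overdispersed fiber counts, motion artifacts, or atlas misregistration.
Passing tests therefore demonstrate correctness of the inferential
machinery under the stated model and scale, not robustness to every
property of real connectomes.

## Validation studies (tests/test_acceptance.py, scripts/acceptance.py)

Problem sizes were chosen to make each study informative while keeping
the default suite comfortably runnable on one CPU: 50 replicates of
3 741 links for realized-FDR control, 20 subject-level replicates for
the multimodal-vs-unimodal sensitivity comparison, 20 replicates for
parameter recovery and credible-interval coverage, all with 2 × 4 000
MCMC.  The closed-form BLfdr is checked against brute-force
normalization in 80-bit extended precision on 10⁴ random
(t, s, parameter) points at 1e-10.

## Known limitations

* One auxiliary modality; the weight and shape links are linear in s on
  their respective scales.
* The Efron baseline's empirical null is estimated from the center of
  the data and can be noticeably mis-scaled in unlucky samples, making
  its realized FDR volatile in either direction; the cumulative-mean
  rule then amplifies small lfdr biases.  The multimodal method is less
  exposed because σ² is estimated inside the full likelihood.
* The mixed model assumes one observation per (link, subject) and a
  balanced design (every subject observed on every link).
* Cross-sectional two-group comparison only; no longitudinal designs.
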