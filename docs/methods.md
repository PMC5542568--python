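# Methods

This note documents the statistical machinery implemented in `gad7irt`,
its assumptions, defaults, and the limits of what the test suite
establishes.

## The measurement model

The package analyses ordered categorical questionnaire data — its
motivating instrument is the GAD-7, seven anxiety items scored 0–3 — under
a unidimensional **graded response model (GRM) with logistic errors**. For
item *j* with discrimination λ_j > 0 and strictly increasing thresholds
τ_j1 < τ_j2 < τ_j3, the cumulative response curves are

    P(X_j ≥ c | θ) = 1 / (1 + exp(−(λ_j θ − τ_jc))),   c = 1..3,

and category probabilities are adjacent differences of these curves. The
latent trait θ is given a standard normal distribution; this fixes the
location and scale of the parameters, so λ and τ are only interpretable on
that convention (ratios of λ's are invariant to it). The package ships a
seven-item parameter table estimated on a large primary-care sample
(`gad7irt/params/gad7_grm.csv`); `default_gad7_parameters()` loads it.

Note the *slope–intercept* form λθ − τ, not the slope–difficulty form
λ(θ − b). The shipped τ values (up to 6.37) only make sense in the former.
The three reference response patterns whose published optimal scores the
test suite reproduces to the printed precision are the decisive check of
this reading.

## Optimal scoring (EAP)

The "best predictor" of a respondent's trait given pattern x is the
posterior mean

    E[θ | x] = ∫ θ L(x|θ) φ(θ) dθ / ∫ L(x|θ) φ(θ) dθ,

the minimum-MSE predictor. Missing items simply drop out of L. Quadrature
is a fixed trapezoid rule on [−6, 6] with 401 points; an oracle test checks
agreement to 1e-4 with a 10×-finer grid exhaustively over all 64 patterns
of a 3-item model and on random 7-item patterns. The posterior sd is
reported alongside; user-facing output rounds to 2 decimals. An all-missing
pattern returns the prior (0, 1) and is flagged.

Item information is the expected negative second derivative of the
log category probability, Σ_k P_jk(θ)[−∂²/∂θ² ln P_jk(θ)], which
algebraically reduces to Σ_k P′_jk(θ)²/P_jk(θ); derivatives of the
logistic curves are analytic (∂θ P* = λP*(1−P*)). A finite-difference
oracle pins the implementation at 1e-5. Test information is the sum over
a subset of items; the short-form analysis compares the 21 two-item
curves on a θ grid.

## Bayesian fitting

`GradedResponseModel.fit()` runs a Metropolis-within-Gibbs sampler:

* **θ_i** — one random-walk proposal per respondent per sweep, vectorised
  across respondents; prior N(0, 1).
* **λ_j** — random walk on log λ; prior log λ ~ N(0, 1), which keeps the
  slope positive and is diffuse over the plausible range (0.1–10). No
  reflection ambiguity remains once λ > 0.
* **τ_jc** — single-site random walk; prior N(0, 10²) restricted to
  increasing order, enforced by rejecting disordering proposals (valid for
  symmetric proposals, since the target density is zero there).

Missing cells contribute nothing to the likelihood — marginalisation,
which under MAR given θ is equivalent to imputing them and simpler.
Proposal scales adapt every 50 sweeps during burn-in toward ~35%
acceptance and are frozen afterwards. Defaults mirror the published
analysis: 5 chains × 6000 iterations, burn-in 2000, and 1000 retained
draws in total (thinning chosen per chain; the latest draws are kept when
the division is inexact). Runtime is ≈2.5 min at n=3404 on one CPU.

`GRMResults` exposes posterior means/sds, central 95% intervals and
split-chain R̂ (via ArviZ; ≥2 chains required, single-chain fits warn and
omit it). A reference run at n=3404 with the shipped generating values
gives R̂max ≈ 1.02 and recovers every slope within ±0.2. Items whose top
category is never observed have weakly identified thresholds; the model
flags them and the sampler proceeds under the prior.

Initialisation is data-driven (thresholds from marginal cumulative
frequencies on a λ≈2 scale, traits from standardised mean scores); with a
2000-iteration burn-in results are insensitive to it.

## Nonparametric unidimensionality checks

Three necessary conditions of any unidimensional monotone latent variable
model, checked model-free:

1. **Pairwise correlations ≥ 0** (pairwise-complete Pearson; zero-variance
   pairs reported undefined, never counted as zero).
2. **Conditional covariances ≥ 0**: cov(X_i, X_j | X_l = c) over all pairs
   (i, j), all conditioners l and all observed values c. Strata with fewer
   than `min_stratum` (default 10) complete cases are skipped and counted.
3. **Monotonicity of P(X_i ≥ c | restscore)**: complete cases are binned
   by the restscore S_−i = Σ_{j≠i} X_j into contiguous groups of at least
   `min_group` respondents (default: N/10 for N ≥ 500, N/5 for N ≥ 250,
   else N/3 — the sample-size rule of the standard implementation of this
   check); a violation is a decrease between adjacent groups exceeding
   `minvi` (default 0.03; `minvi=0` is the strict mode).

On data simulated from the shipped model at the study's n=3404 all three
counts are zero — the profile the method is designed to certify — and the
suite asserts this, as well as sensitivity: a reversed item, a
two-dimensional generator, and a permuted item each produce violations.
Small samples (n of a few hundred) can show stray negative conditional
covariances in thin strata; that is sampling noise, not misfit.

## Posterior predictive checks

For each of `n_replicates` retained draws (default: all; subsampled evenly
across the retained sequence if fewer), a replicate dataset of identical
dimensions is simulated at freshly drawn N(0,1) traits, the observed
missingness mask is re-applied, and the 21 pairwise correlations are
computed pairwise-complete. Per pair the p-value is 2·min(F(t_obs),
1−F(t_obs)) with F the empirical CDF of replicate correlations (mid-rank
at ties, so a t_obs at the replicate median gives exactly 1). Mask reuse
makes observed and replicate correlations commensurable — the stricter
reading of "same size". Degenerate replicate columns are excluded per pair
and counted. Calibration is checked at 200 replicates: near-uniform
p-values when the fitted model generated the data, and a far-tail p-value
for a pair with an injected local dependence (40% response copying between
items 5 and 6).

## Classical statistics and maximal reliability

`describe()` reports item means/SDs, pairwise correlations, item-restscore
correlations (complete cases for the focal item's restscore) and Loevinger
scalability: H_ij = cov(X_i,X_j)/covmax, where covmax is attained by the
comonotonic sort-and-pair coupling of the two observed marginals; H_i
pools numerator and denominator over an item's pairs. Cronbach's α is
deliberately not computed.

The weighted composite fits a linear one-factor model to the
pairwise-complete item covariance matrix by ML (scipy L-BFGS on the
Wishart discrepancy log|Σ| + tr(SΣ⁻¹); uniquenesses parameterised on the
log scale; Heywood cases floored at 1e-4 of the item variance and
flagged). Weights ∝ loading/uniqueness maximise composite reliability
Σ(λ²/ψ)/(1 + Σ(λ²/ψ)). Weights are reported rescaled to mean 1: only
their ratios are interpretable, and the normalisation of the historically
printed weights is not recoverable. The 95% CI is a percentile bootstrap
over respondents (B=1000 by default).

## Differential item functioning

Per item, two nested proportional-odds logistic regressions of the item
score (statsmodels `OrderedModel`): on the EAP trait estimate alone, and
on trait + group. The effect size is the gain in Nagelkerke pseudo-R²,
ΔR² = R²_N(trait+group) − R²_N(trait), with the intercept-only model as
the R²_N baseline (its likelihood has the closed form of the marginal
category frequencies). Items with ΔR² ≥ 0.009 — the conventional
negligibility bound — are flagged; non-convergent fits are flagged
unestimable rather than skipped. The trait is estimated once (no
purification loop): a deliberate simplification, adequate in the
negligible-DIF regime this scan certifies and detectably conservative
otherwise (an injected one-point threshold shift on one item at n=3404 is
the clear maximum and exceeds the bound in the test suite).

## Synthetic data

`simulate_responses` draws θ ~ N(0,1), generates scores from the GRM
category distributions via one uniform per cell against the cumulative
curves, then masks cells missing. Defaults state the emulated sample:
n=3404, the shipped parameters, 3% cell-wise MCAR missingness (matching
3303/3404 complete scale scores), group ~ Bernoulli(0.60) (the sample's
female share). MCAR is the simplest mechanism consistent with the MAR
analysis assumption; a `missing_prob_fn(θ)` hook generates genuinely MAR
patterns for stress tests. Optional DIF injection shifts one item's
thresholds additively for group 1.

What the generator does **not** emulate: local dependencies between
adjacent items (present in the real instrument — the posterior predictive
checks exist to find exactly that), response-order effects, co-measures,
and any demographic structure beyond a binary group. A green test on
synthetic data therefore establishes the correctness of the machinery
under the stated model, not the psychometric verdict on any real sample;
the pipeline accepts real CSV data for that purpose.

## Numerical choices

* Quadrature grid [−6, 6] × 401, trapezoid; probabilities clipped at
  1e-300 before logs.
* EAP cache: identical response patterns are scored once per matrix.
* Degenerate statistics (zero variance, zero covmax, empty strata) are
  NaN-flagged and excluded from counts, never silently zeroed.
* Sum-score severity bands: minimal < 5 ≤ mild < 10 ≤ moderate < 15 ≤
  severe; incomplete patterns are summed over observed items and flagged.
* Determinism: every stochastic routine takes a seed; chains spawn
  independent generators from one `SeedSequence`; pipeline runs are
  byte-reproducible.

## Known limitations

* The sampler is single-site random walk — robust but not fast-mixing;
  R̂ < 1.05 needs chain lengths of a few thousand. Gradient-based samplers
  are out of scope.
* Strictly ordering all seven discriminations is not achievable at
  n=3404 where true values are tied or separated by less than the
  posterior noise (items 5/6 identical; items 1/4 differ by 0.10); tests
  assert the ordering only across well-separated pairs and the
  first-four/last-three contrast.
* Exact priors of the historical WinBUGS analysis are unknown; posterior
  means can differ in the second decimal from the printed table.
* The maximal-reliability bootstrap refits the factor model ~1000 times;
  at very large n this dominates `describe()` runtime (use
  `n_bootstrap=0` to skip).
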