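# Methods

## The model class

`longirt` fits unidimensional item-response-theory (IRT) mixed models to
repeated ordinal questionnaire items, the data produced by instruments such
as the EORTC QLQ-C30. Subject *i* answers item *j* (categories
0..M<sub>j</sub>) at visit *v*. Conditionally on the subject's random
effects, the response is multinomial with probabilities determined by three
choices:

* a **probability ratio** r — cumulative (Pr(Y ≥ m)), adjacent
  (π<sub>m</sub>/(π<sub>m</sub>+π<sub>m−1</sub>)) or sequential
  (continuation ratio) — which fixes the family of the model;
* a **CdF** F — logistic, Gaussian, Gumbel-min or Gumbel-max — the inverse
  link applied to each ratio, r<sub>m</sub> = F(η<sub>m</sub>);
* the IRT **linear predictor** η<sub>m</sub> = α<sub>j</sub>(θ<sub>iv</sub> −
  δ<sub>jm</sub>), with item thresholds δ<sub>jm</sub> (strictly increasing
  for the cumulative family) and discriminations α<sub>j</sub> fixed at 1 so
  the model stays a GLMM.

The latent trait decomposes linearly,
θ<sub>iv</sub> = x<sub>iv</sub>′β + u<sub>v</sub>′ξ<sub>i</sub>, with
ξ<sub>i</sub> ~ N(0, Σ). Two fixed designs are built in — time-only
(θ = (t−t₀)β₁ + …) and the two-arm trial design
(θ = gβ₁ + (t−t₀)β₂ + g(t−t₀)β₃ + …) — and two random structures: M₁
(intercept ξ₀) and M₂ (intercept plus time slope ξ₁). Neither design has a
fixed intercept, so θ at baseline with ξ = 0 is exactly zero; this is what
identifies the thresholds, and Σ is estimated freely (no standard-normal
constraint on θ). Ratio-family conventions follow the descending order
common in IRT (η<sub>m</sub> = θ − δ<sub>m</sub>); the sequential family is
written in the ascending continuation-ratio form, the only one the ratio
equations pin down unambiguously.

Reversing the category order (m → M − m) maps cumulative and adjacent
models with a symmetric CdF onto themselves with β → −β and thresholds
negated and order-reversed; the sequential family has no such property.
This matters in practice because functional scales are coded in the
direction opposite to symptom scales, and `reverse_functional_scale`
exploits it. The cumulative family is additionally invariant under merging
adjacent categories, which the fitter uses to collapse categories that were
never observed.

## Estimation

The marginal likelihood integrates the conditional multinomial likelihood
over ξ. The integral is evaluated by adaptive Gauss–Hermite quadrature:
for each subject the integrand's mode is found by a safeguarded Newton
iteration (all three families have log-concave conditionals), the nodes are
recentred and rescaled by the curvature there, and the standard AGQ weight
correction is applied. Defaults: 9 nodes per dimension (81 for M₂),
adaptation on. Non-adaptive quadrature (prior-scaled nodes) is available
via `QuadratureConfig(adaptive=False)`.

The optimiser is L-BFGS-B on an unconstrained vector: cumulative-family
thresholds are parameterised as (δ₁, log-increments); variances as log
standard deviations, bounded to [e⁻⁹, e³] (estimates at the lower bound are
reported as 0 with a boundary flag — no likelihood-ratio boundary
correction is attempted, as structure choice is by BIC); the unstructured
2×2 covariance as its Cholesky factor. The gradient is analytic throughout
(closed-form ∂log π/∂η per family, chain rule through the parameter
transforms, posterior-weighted aggregation over nodes), with the node
adaptation held fixed; the neglected adaptation term is of the order of the
quadrature error (verified ≲ 1% relative against central differences).
Convergence: scipy defaults with ftol 1e−11 / gtol 1e−6, up to 3 jittered
restarts. Starting values: thresholds from the pooled inverse-CdF of
observed category frequencies, β = 0, σ₀² = 1, σ₁² = 0.05; the M₂ fit in
`fit_random_structures` warm-starts from the M₁ estimates.

Standard errors come from the inverse observed information (central
differences of the analytic gradient), mapped to the natural scale by the
delta method; Wald p-values are two-sided normal. BIC is
−2ℓ + p·log(n) with n = the number of subjects, the independent sampling
unit; the same convention is used for the score LMM so the two arms are
comparable. `bic_select` prefers the smaller BIC and breaks ties (< 1e−8)
toward the parsimonious M₁. Missing (subject, visit, item) records simply
drop out of the likelihood product.

## The score comparator

`eortc_score` averages a dimension's items at a visit and rescales to
0–100; visits missing any item are dropped (the half-rule of the official
scoring manual is deliberately out of scope). `fit_lmm` fits the linear
mixed model with fixed intercept and time slope and random intercept
(optionally plus independent random slope) by plain maximum likelihood —
not REML — through statsmodels MixedLM, so that BIC comparisons across
random structures are valid.

## The simulator and what the tests show

`simulate_dataset` draws ξ₀ ~ N(0, σ₀²) and, when σ₁² > 0, an independent
ξ₁ ~ N(0, σ₁²), builds θ from the time-only design and draws one
multinomial response per (subject, visit, item) by inverting the category
CdF on a single uniform, in subject-major order — datasets are
bit-reproducible from the seed. Defaults encode the study conditions:
two items with four categories, n = 300 subjects, σ₀² = 1.5, visit months
(0, 1, 2, 4, 6, 8, 10, 12) (an alternative grid (0, 0.5, 1, 2, 4, 6, 8, 10)
ships as `VISITS_ALT`), and two threshold presets — "near"
δ₁ = (−1.6, 1, 1.45), δ₂ = (−0.8, 1.15, 1.9) and "far"
δ₁ = (−2.1, 1, 2.75), δ₂ = (−1.25, 1.4, 3.3) — chosen so that the adjacent
generator spreads responses across categories while the cumulative one
concentrates them on categories 0, 1 and 3 (near set), or vice versa.

The generator emulates balanced, complete follow-up with independent
random effects and no dropout, item-level missingness, informative visit
timing or covariate-dependent thresholds. Passing tests therefore
demonstrate correctness of the probability maps, integration, optimisation
and selection logic under those idealised conditions — not robustness to
the missingness and heterogeneity of real trial data.

`simstudy.run_cell` ties the pieces together: per replicate it simulates
once, fits the requested analysis models (score LMM, adjacent, cumulative)
under M₁ and M₂, and tabulates the percentage of BIC selections.
Replicates that fail to converge are excluded from the denominator and
counted; a cell with more than 20% exclusions is flagged invalid.
Replicate seeds are spawned deterministically from the base seed
(`replicate_seeds`), so results are independent of execution order. The
shipped selection runs use N = 20 replicates per cell (the original study
used 500); N is a parameter everywhere.

## Numerical notes

* Adjacent probabilities are computed entirely in the log domain
  (log-odds cumulative sums + logsumexp), so |η| of several hundred cannot
  overflow; with the logistic CdF the log-odds equal η exactly and the
  kernel reduces to the familiar exponential partial-credit form.
* Cumulative log-probabilities use a two-branch log-difference
  (whichever of the lower/upper tail is better conditioned), keeping
  interior-category probabilities accurate deep in the tails.
* CdFs, densities and quantiles are direct `scipy.special` expressions
  (expit/log_expit, ndtr/ndtri, Gumbel closed forms); agreement with the
  `scipy.stats` distributions is regression-tested.
* Degenerate variances: σ² below ~e⁻¹⁸ is numerically indistinguishable
  from a point mass at 0 and the marginal likelihood collapses onto the
  conditional at ξ = 0 (tested to 1e−6).
* Category labels must be contiguous integers from 0; other labellings are
  rejected at I/O rather than silently recoded.

## Known limitations

Free discrimination parameters (graded-response / generalised partial
credit), multidimensional latent traits, nominal-response reference ratios
and time-to-deterioration endpoints are out of scope. The Wald tests are
asymptotic normal approximations; no small-sample or boundary corrections
are applied. The probability-curve utilities condition on ξ = 0 (the
median subject) rather than averaging over the random-effect distribution;
the two differ for nonlinear links, and the conditional version is the one
whose baseline values line up with threshold-only calculations.
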