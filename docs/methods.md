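# Methods

## Estimand and identification

The package estimates the average treatment effect (ATE) of a binary
intervention, τ = E[Y(1)] − E[Y(0)], from unit-level observational data
z_i = (y_i, d_i, x_i). Identification rests on strong ignorability:
conditional independence of potential outcomes and assignment given the
covariates, common support (0 < Pr(D=1|X=x) < 1), and SUTVA. The package
validates the data-level parts of these assumptions — both arms non-empty at
ingestion, and overlap trimming of units with extreme estimated propensity
scores — while the conditional-independence assumption itself is, as always,
untestable and must be argued from the covariate set.

## Estimators

Three causal point estimators share the counterfactual-prediction kernel:

* **Outcome regression (OR)**: fit Ψ⁻¹{m(D, X; ξ)} and average the
  counterfactual contrast over the empirical covariate distribution,
  τ̂ = n⁻¹ Σᵢ [Ψ⁻¹{m(1, xᵢ)} − Ψ⁻¹{m(0, xᵢ)}].
* **Inverse propensity weighting (IPW)**: the Horvitz–Thompson contrast
  τ̂ = n⁻¹ Σᵢ [dᵢyᵢ/π̂ᵢ − (1−dᵢ)yᵢ/(1−π̂ᵢ)] with π̂ from a logistic
  assignment model.
* **Doubly robust (DR)**, in weighted-model form: form
  κ̂ᵢ = dᵢ/π̂ᵢ + (1−dᵢ)/(1−π̂ᵢ) and refit the OR model solving the
  κ-weighted estimating equation
  Σᵢ κ̂ᵢ (1/φ) ∂e/∂ξᵀ [yᵢ − e(dᵢ, xᵢ; ξ)] = 0,
  then apply the OR contrast. The estimator is consistent if *either*
  component model is correctly specified: a correct OR model is unhurt by
  weighting (only efficiency can suffer), while a correct propensity model
  makes the weighted score correct the bias of a wrong mean model.

The working variance φ is held constant (Gaussian working model); it scales
the estimating equation without moving its root, so it is never estimated.
The identity link makes the weighted fit exact (weighted least squares); the
log link is solved by damped Gauss–Newton under the same constant-φ
quasi-likelihood; the logistic assignment model is standard (penalized)
binomial maximum likelihood with damped Newton steps.

The augmentation form of DR estimation and ATT estimation are deliberately
out of scope: the weighted-model form matches how site-level evaluations
weight a differenced outcome regression, and the ATE is the natural estimand
when every matched site could in principle receive the intervention.

## Approximate Bayesian inference

DR models are defined by moment restrictions, not a likelihood, so standard
Bayesian updating is unavailable. The package instead uses the Bayesian
bootstrap: treating the empirical distribution as multinomial with an
improper Dirichlet prior, the posterior over observation probabilities is
uniform Dirichlet, and a posterior draw of the model parameters is obtained
by solving the weighted estimating equation under weights
wᵢ = n·eᵢ/Σeⱼ, eᵢ iid standard exponential. Repeating L times gives the
empirical posterior p_n(ξ̃). Conventions:

* Weights are normalized to sum to n (not 1) so weighted fits keep an
  effective sample size of n; the estimating-equation root is invariant to
  this scale.
* The propensity model is fitted **once** and κ̂ held fixed across draws;
  propensity-estimation uncertainty is not propagated. The per-draw weights
  are wᵢ⁽ˡ⁾·κ̂ᵢ.
* L defaults to 200: the Monte-Carlo error of a posterior mean is then an
  order of magnitude below the sampling variation between replicate
  datasets, and the full simulation study stays desk-scale.
* A failed inner refit (possible under extreme weights) is retried with
  fresh weights up to 3 times, then raised.

### Prior information: Muliere–Secchi mixture resampling

To admit prior information without a likelihood, the bootstrap posterior is
extended by mixture resampling: given a parametric prior p₀ with "measure of
faith" k, draw m support points from (k·p₀ + L·p_n)/(k+L), attach
independent Gamma((L+k)/m, 1) masses vᵢ, and resample with probabilities
vᵢ/Σvⱼ to form the discrete posterior p_m. The shape (L+k)/m makes the
total random mass concentrate at L+k — the combined information count —
which is the scaling under which k=0 collapses to plain bootstrap
resampling and k → ∞ hands the target coordinate to the prior. Choices:

* m = L by default.
* The prior is declared on a single coordinate (the treatment coefficient);
  a support point drawn "from the prior" takes its remaining coordinates
  from a uniformly resampled p_n row, keeping the prior purely marginal.
* Simulation default: Normal centred at the true effect with sd 10 and k=1 —
  weakly informative by construction, so the prior's role is structural
  (support beyond observed draws) rather than corrective. Both are exposed
  in configuration.

### Posterior predictive ATE

Each of M (default 1000) predictive draws pairs one parameter vector from
p_m with a uniform with-replacement resample of V (default n) covariate
rows and averages the counterfactual contrast over the resample. With the
identity link and a pure main-effect treatment term the covariate terms
cancel exactly in the contrast, so every draw equals the drawn treatment
coefficient and the covariate resample is skipped — an exact shortcut, not
an approximation. Summaries are the mean, sd, and the central 95% interval
from the 2.5/97.5 empirical percentiles; they are pure functions of the
draw vector.

For pure IPW pipelines the parameter posterior is over the assignment
coefficients. Here each Dirichlet draw is treated as a reweighted empirical
measure and the Horvitz–Thompson functional is evaluated *coherently under
that measure*: the logistic model is refitted with the draw's weights and
the same weights average the per-unit contrast. Evaluating the contrast
under a different measure (e.g. a uniform resample) against the weighted
refit leaves a second-order convexity bias from the near-one propensity
tail — measured at about −0.12 at n=1000 — which the coherent form avoids
by preserving the score balance of the weighted fit. No prior mixing is
applied to IPW pipelines: the declared prior concerns an outcome-model
coefficient, which a pure weighting estimator does not have.

## Simulation study

The data-generating process is X ~ N(0, 10), D ~ Bernoulli(expit(2 + 0.2X)),
Y ~ N(10 + 5D + 0.2X, 5), with both dispersion parameters read as
**variances**. This reading was fixed by an independent oracle before any
pipeline was run: numerical integration gives an omitted-X confounding bias
of +0.38 under variance 10 (versus +2.58 under sd 10), matching the
intended ≈ +0.35 bias of the misspecified outcome model. The true ATE is
the treatment coefficient, τ = 5.

Seven configurations cross component-model correctness (see module
docstring): correct/incorrect OR alone, IPW with fitted/random propensity,
and the three DR crosses. The random "propensity" is drawn per unit from
Uniform(0,1) and used **unclipped**, deliberately preserving the documented
instability of inverse weighting under severe misspecification; fitted
propensity scores elsewhere are clipped to [0.01, 0.99] before κ is formed,
bounding any single weight by 100. Each scenario is summarised over
replicate datasets by the mean, empirical variance (n_runs − 1 denominator)
and MSE (mean squared deviation from τ, n_runs denominator) of the
posterior-mean ATEs, so mse = bias² + var·(n_runs−1)/n_runs exactly.

Default scale: 1000 replications of n=1000 datasets with L=200, M=1000 —
about two minutes on one CPU thanks to a vectorised weighted-least-squares
kernel that solves all L estimating equations of a replication at once (the
batched and single-fit paths are tested against each other to 1e-8).

## Matching

Nearest-neighbour propensity matching: 1:1, without replacement, treated
units processed in descending propensity order, ties broken by lowest
index, optional caliper. These are conventional defaults; none is
prescribed by theory. Matching improves covariate balance only in the
control-rich regime it is designed for (the site application screens ~6
candidate controls per treated site); with treated units in the majority
there is no reservoir to draw balance from, and the balance tests are
framed accordingly.

## Synthetic site panels

The generator emulates the structure of a speed-camera evaluation: sites of
0.4–1.5 km with road type, speed limit (30/40 mph), minor-junction count
and traffic flow (AADF) covariates; a log-linear latent annual collision
rate with a time-invariant site effect (sd 0.35) and length as exposure;
three pre-years and three post-years of Poisson counts. Treatment
probability rises sharply (soft sigmoid thresholds) once the site-selection
guidelines are met — at least 8 personal-injury collisions and 4
fatal/serious collisions per km over the prior three years — plus a mild
flow effect, with off-criteria selection possible, mirroring how sites are
chosen in practice. The selection window doubles as the pre-period, which
embeds regression to the mean: sites are selected partly on upward Poisson
noise, so naive before–after contrasts overstate any reduction (the
generator reproduces this signature even under a null effect). The
embedded treatment effect multiplies expected post-period counts at treated
sites.

The analysis model is kept deliberately mismatched to the generator: a
Gaussian identity-link regression on the differenced count (post − pre),
as used in practice, against Poisson truth. Differencing removes the
latent site effect exactly; the differenced outcome also makes percentage
reporting a convention rather than a model quantity, so percentage output
is labelled as such (denominator: a user-supplied mean untreated outcome).
Speed-distribution covariates (85th-percentile speed, % over limit) are
not generated: for 30/40 mph sites their distributions are similar across
arms, so their exclusion should not damage the propensity model, and the
generator follows that argument. What passing these tests shows is that
the full matched, trimmed, κ-weighted, differenced pipeline recovers known
multiplicative effects embedded in realistic count panels with
history-driven selection; it does not validate the conditional-independence
assumption on any real road network, nor spatial spillover (traffic
diversion is represented only through the flow covariate).

## Numerical choices

* Propensity clipping ε = 0.01 (off where a scenario prescribes raw random
  scores). Logistic fits detect perfect separation (collapsing information
  with |η| > 20) and raise a dedicated error rather than returning a
  divergent fit.
* Iterative fits: tolerance 1e-8 on the coefficient step, 100 iterations,
  damped steps (objective-based halving). Every stored posterior draw is
  checked against its estimating equation (max score component / n below
  1e-6 in tests).
* Smooth terms are cubic B-spline bases (default dimension 10, interior
  knots at training quantiles, centred for identifiability) with a
  second-difference penalty chosen by GCV on a log-spaced grid. They are an
  optional refinement of the linear default, not a reconstruction of any
  particular mixed-model software; random effects are not implemented —
  differencing of the outcome is the intended substitute for time-invariant
  site effects.
* Degenerate inputs fail loudly: rank-deficient designs, non-binary
  treatment coding without an explicit mapping, single-arm data, empty
  overlap after trimming.

## Known limitations

* Propensity uncertainty is not propagated into the posterior (by design of
  the resampling scheme); the posterior can be anti-conservative when the
  propensity model is hard to estimate.
* The Bayesian-bootstrap posterior mean of the IPW functional carries a
  small positive finite-sample offset (~1% at n=1000) relative to the
  frequentist estimator, from the curvature of inverse weights.
* Percentage-scale effects are a reporting convention with an explicit
  denominator choice, not an estimand.
* The across-replication variance of posterior-mean estimates includes a
  small resampling component from the finite (m = L) mixture posterior,
  visible as a few-percent inflation over the corresponding frequentist
  point-estimator variance.
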