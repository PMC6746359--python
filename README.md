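# bayesdr

Approximate Bayesian **doubly-robust (DR)** estimation of average treatment
effects for observational intervention studies, built around the evaluation
of road-safety measures (speed cameras) on site-level collision counts.

## The problem

Safety interventions are not assigned at random: speed cameras go to sites
with bad recent collision history, so naive before–after comparisons mix the
true effect with confounding — most visibly regression to the mean. Causal
adjustment can go through a model for the outcome (outcome regression, OR)
or a model for the assignment mechanism (the propensity score, PS); each is
only as good as its specification. The DR estimator combines them and is
consistent when *either* one is correct.

Writing the observed data as z_i = (y_i, d_i, x_i), the package estimates
the ATE τ = E[Y(1)] − E[Y(0)] by:

* **OR**: τ̂ = n⁻¹ Σ [Ψ⁻¹{m(1, xᵢ; ξ̂)} − Ψ⁻¹{m(0, xᵢ; ξ̂)}]
* **IPW**: τ̂ = n⁻¹ Σ [dᵢyᵢ/π̂ᵢ − (1−dᵢ)yᵢ/(1−π̂ᵢ)]
* **DR**: the OR contrast after refitting the outcome model weighted by
  κ̂ᵢ = dᵢ/π̂ᵢ + (1−dᵢ)/(1−π̂ᵢ)

Because DR estimators solve estimating equations rather than maximise a
likelihood, ordinary Bayesian updating is unavailable. The package obtains a
posterior by the **Bayesian bootstrap** — repeatedly re-solving the
κ-weighted estimating equations under Dirichlet(1,…,1) observation weights —
and incorporates prior information through **Muliere–Secchi mixture
resampling** (a prior p₀ with "measure of faith" k is mixed into the
bootstrap draws and Gamma-reweighted), yielding a posterior predictive
distribution for τ with credible intervals. See `docs/methods.md` for the
full account.

A nearest-neighbour PS matching step, overlap trimming, and a synthetic
speed-camera-site generator (history-driven assignment, Poisson counts,
differenced outcomes, known embedded effect) complete the pipeline used in
site-level evaluations.

## Worked example

Estimate the ATE on a simulated confounded dataset (true effect 5.0):

```python
import numpy as np
from bayesdr import (ModelSpec, fit_propensity, kappa_weights,
                     posterior_ate_pipeline)
from bayesdr.simulation_study import DGPParams, generate_sim_dataset

data = generate_sim_dataset(DGPParams(n=1000), np.random.default_rng(7))

ps = fit_propensity(data, ModelSpec("logit", ("x",), include_treatment=False))
kap = kappa_weights(ps.fitted_ps, data.d)

# deliberately misspecified outcome model (x omitted) — the kappa weights
# from the correct propensity model supply the doubly-robust correction
post = posterior_ate_pipeline(data, ModelSpec("identity", ()), kappa=kap,
                              L=200, rng=np.random.default_rng(8))
print(post.summaries)
```

```
{'mean': 5.303, 'sd': 0.232, 'ci_2.5': 4.765, 'ci_97.5': 5.765}
```

The posterior mean 5.30 sits close to the true effect 5.0 with a 95%
credible interval (4.77, 5.77) that covers it, even though the outcome model
omits the confounder; the same misspecified model *without* weighting, or
the naive arm contrast, is biased upward (5.61 on this dataset — the
analogue of the regression-to-the-mean overstatement in before–after site
studies). The same pipeline is available from the shell:

```bash
bayesdr estimate units.csv --outcome y --treatment d --covariates x --estimator dr
# {"tau": 5.256..., "scale": "absolute", "estimator": "DR", "n_used": 1000, ...}
bayesdr simulate-table1 --runs 200 --seed 42 --out table1.csv
bayesdr synth-sites --config sites.yaml --seed 3 --out sites.csv
```

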