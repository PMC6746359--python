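"""Frequentist point estimators of the average treatment effect.

These are the inner kernels of every posterior draw as well as standalone
estimators: the outcome-regression plug-in, the Horvitz-Thompson inverse
propensity weighted contrast, the doubly-robust weighted-model form, and the
naive unadjusted difference in means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .component_models import (
    ModelSpec,
    ORFit,
    fit_outcome,
    fit_propensity,
    kappa_weights,
    predict_counterfactual,
)
from .data_model import EffectEstimate, ObservationalDataset

__all__ = ["EstimatorConfig", "ate_or", "ate_ipw", "ate_dr", "ate_naive", "to_percent"]


@dataclass(frozen=True)
class EstimatorConfig:
    estimator: str = "DR"
    or_spec: Optional[ModelSpec] = None
    ps_spec: Optional[ModelSpec] = None

    def __post_init__(self):
        if self.estimator not in ("OR", "IPW", "DR", "NAIVE"):
            raise ValueError(f"unknown estimator {self.estimator!r}")
        if self.estimator in ("OR", "DR") and self.or_spec is None:
            raise ValueError(f"{self.estimator} requires an outcome model spec")
        if self.estimator in ("IPW", "DR") and self.ps_spec is None:
            raise ValueError(f"{self.estimator} requires a propensity model spec")


def ate_or(fit: ORFit, data: ObservationalDataset, estimator: str = "OR") -> EffectEstimate:
    """Plug-in ATE: mean counterfactual contrast over the covariate sample,

        tau = (1/n) sum_i [Psi^{-1}{m(1, x_i)} - Psi^{-1}{m(0, x_i)}].
    """
    mu1 = predict_counterfactual(fit, data.X, 1)
    mu0 = predict_counterfactual(fit, data.X, 0)
    return EffectEstimate(float(np.mean(mu1 - mu0)), "absolute", estimator)


def ate_ipw(data: ObservationalDataset, ps: np.ndarray) -> EffectEstimate:
    """Horvitz-Thompson inverse-propensity-weighted ATE."""
    ps = np.asarray(ps, dtype=float)
    if np.any(ps <= 0.0) or np.any(ps >= 1.0):
        raise ValueError("propensity scores must lie strictly inside (0, 1)")
    d = data.d
    tau = np.mean(d * data.y / ps - (1 - d) * data.y / (1.0 - ps))
    return EffectEstimate(float(tau), "absolute", "IPW")


def ate_dr(
    data: ObservationalDataset,
    or_spec: ModelSpec,
    ps_spec: Optional[ModelSpec] = None,
    ps: Optional[np.ndarray] = None,
    clip_eps: float = 0.01,
) -> EffectEstimate:
    """Doubly-robust ATE: fit the propensity model (or accept a fixed ``ps``
    vector), form kappa weights, fit the kappa-weighted outcome model, and
    evaluate the plug-in contrast on it."""
    if ps is None:
        if ps_spec is None:
            raise ValueError("ate_dr needs either ps_spec or a ps vector")
        ps = fit_propensity(data, ps_spec, clip_eps=clip_eps).fitted_ps
    kappa = kappa_weights(ps, data.d)
    fit = fit_outcome(data, or_spec, kappa)
    est = ate_or(fit, data, estimator="DR")
    return est


def ate_naive(data: ObservationalDataset) -> EffectEstimate:
    """Unadjusted difference in arm means (the no-covariate OR model)."""
    y, d = data.y, data.d
    tau = y[d == 1].mean() - y[d == 0].mean()
    return EffectEstimate(float(tau), "absolute", "NAIVE")


def to_percent(estimate: EffectEstimate, untreated_mean: float) -> EffectEstimate:
    """Express an absolute ATE as a percentage of a mean untreated outcome.

    The denominator convention (here: the mean predicted or observed outcome
    under no treatment) is a reporting choice, not part of the estimand.
    """
    if untreated_mean == 0:
        raise ZeroDivisionError("percent scale undefined for zero baseline")
    return EffectEstimate(
        100.0 * estimate.tau / untreated_mean, "percent", estimate.estimator
    )
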