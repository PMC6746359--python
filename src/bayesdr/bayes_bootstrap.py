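"""Approximate posterior for outcome-model parameters via the Bayesian
bootstrap.

Treating the empirical distribution of the data as multinomial with an
improper Dirichlet prior, the posterior over observation probabilities is
uniform Dirichlet; a draw from it is simulated as n iid standard exponential
variates standardised to sum to one (here rescaled to sum to n).  Solving the
kappa-weighted outcome estimating equation under repeatedly drawn Dirichlet
weights yields draws ``xi^(l)`` whose empirical distribution ``p_n`` is an
approximate posterior that inherits the doubly-robust property of the
weighted estimating equation.

The propensity model is fitted once and kappa held fixed across draws;
propensity-estimation uncertainty is deliberately not propagated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._exceptions import BayesDRError
from .component_models import ModelSpec, ORFit, batched_wls, fit_outcome
from .data_model import ObservationalDataset, WeightSet

__all__ = ["BBWeights", "EmpiricalPosterior", "draw_bb_weights", "empirical_posterior"]


@dataclass(frozen=True)
class BBWeights:
    """One draw of Dirichlet(1,...,1) weights, rescaled so sum(w) = n."""

    w: np.ndarray
    draw_index: int = 0

    def __post_init__(self):
        if np.any(self.w <= 0) or not np.isfinite(self.w).all():
            raise ValueError("Bayesian-bootstrap weights must be positive, finite")


def draw_bb_weights(n: int, rng: np.random.Generator, draw_index: int = 0) -> BBWeights:
    """Draw one set of Bayesian-bootstrap weights of length n.

    Weights are n iid standard exponentials standardised to the simplex and
    rescaled by n, so a weighted fit keeps an effective sample size of n.
    The estimating-equation root is invariant to that overall scale.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    e = rng.standard_exponential(n)
    return BBWeights(n * e / e.sum(), draw_index)


def bb_weight_matrix(n: int, L: int, rng: np.random.Generator) -> np.ndarray:
    """L draws of Bayesian-bootstrap weights, shape (L, n)."""
    e = rng.standard_exponential((L, n))
    return n * e / e.sum(axis=1, keepdims=True)


@dataclass
class EmpiricalPosterior:
    """The Bayesian-bootstrap posterior ``p_n``: one row of ``draws`` per
    solved weighted estimating equation."""

    draws: np.ndarray  # (L, p)
    L: int
    kappa_used: Optional[WeightSet]
    fit: ORFit = field(repr=False, default=None)  # point fit; carries the design

    def __post_init__(self):
        if self.L < 2 or self.draws.shape[0] != self.L:
            raise ValueError("need L >= 2 posterior draws")

    @property
    def treatment_index(self) -> Optional[int]:
        return self.fit.design.treatment_index if self.fit is not None else None

    def treatment_draws(self) -> np.ndarray:
        idx = self.treatment_index
        if idx is None:
            raise BayesDRError("outcome model has no treatment coefficient")
        return self.draws[:, idx]


def empirical_posterior(
    data: ObservationalDataset,
    or_spec: ModelSpec,
    kappa: Optional[np.ndarray] = None,
    L: int = 200,
    rng: Optional[np.random.Generator] = None,
    max_retries: int = 3,
) -> EmpiricalPosterior:
    """Build ``p_n`` by solving the weighted estimating equation L times.

    ``kappa`` (inverse-propensity weights) is fixed across draws; each draw
    multiplies it elementwise by fresh Dirichlet weights.  Plain linear
    identity-link specs use a vectorised weighted-least-squares solver; other
    specs refit per draw, retrying a failed draw with fresh weights up to
    ``max_retries`` times.
    """
    if rng is None:
        rng = np.random.default_rng()
    if L < 2:
        raise ValueError("L must be >= 2")
    kap = np.ones(data.n) if kappa is None else np.asarray(kappa, dtype=float)
    wset = WeightSet.from_kappa(kap)
    point_fit = fit_outcome(data, or_spec, kap)
    W = bb_weight_matrix(data.n, L, rng) * kap

    if or_spec.is_plain_linear:
        D = point_fit.design.matrix(data.X, data.d)
        draws = batched_wls(D, data.y, W)
    else:
        rows = []
        for l in range(L):
            w = W[l]
            for attempt in range(max_retries + 1):
                try:
                    rows.append(fit_outcome(data, or_spec, w).xi)
                    break
                except BayesDRError:
                    if attempt == max_retries:
                        raise
                    w = draw_bb_weights(data.n, rng).w * kap
        draws = np.vstack(rows)
    return EmpiricalPosterior(draws, L, wset, point_fit)
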