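"""Component models for doubly-robust estimation.

Two models are fitted around the causal contrast:

* the propensity-score (assignment) model ``pi(D|X; alpha)`` — a weighted
  binomial logit, optionally with penalized-spline smooth terms;
* the outcome-regression model ``Psi^{-1}{m(D, X; xi)}`` — fitted by solving
  the weighted estimating equation

      sum_i c_i (1/phi) de/dxi^T [y_i - e(d_i, x_i; xi)] = 0,

  where ``c_i`` are prior unit weights (inverse-propensity ``kappa`` weights,
  Bayesian-bootstrap weights, or their product) and ``phi`` is a constant
  working variance that cancels at the root.  With the identity link this is
  weighted least squares; with the log link it is a Gauss-Newton quasi fit.

Weighting the outcome model with kappa weights built from a consistent
propensity model makes the implied average-treatment-effect estimator doubly
robust: consistent when either component model is correct.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
from scipy.interpolate import BSpline
from scipy.special import expit

from ._exceptions import (
    ConvergenceError,
    SchemaError,
    SeparationError,
    SingularDesignError,
    SupportError,
)
from .data_model import ObservationalDataset, WeightSet

__all__ = [
    "Term",
    "ModelSpec",
    "PSFit",
    "ORFit",
    "fit_propensity",
    "kappa_weights",
    "fit_outcome",
    "predict_counterfactual",
]

_LINKS = ("identity", "logit", "log")


@dataclass(frozen=True)
class Term:
    """One covariate term: a linear column or a penalized cubic-spline smooth."""

    name: str
    kind: str = "linear"
    df: int = 10  # basis dimension for smooth terms

    def __post_init__(self):
        if self.kind not in ("linear", "smooth"):
            raise ValueError(f"unknown term kind {self.kind!r}")
        if self.kind == "smooth" and self.df < 3:
            raise ValueError("smooth basis dimension must be >= 3")


def _coerce_terms(terms) -> tuple:
    out = []
    for t in terms:
        out.append(Term(t) if isinstance(t, str) else t)
    return tuple(out)


@dataclass(frozen=True)
class ModelSpec:
    """Specification of a component model: link ``Psi``, covariate terms,
    whether the treatment indicator enters, and the working variance ``phi``.

    ``phi`` only rescales the estimating equation and never moves its root;
    it is kept for completeness of the quasi-likelihood bookkeeping.
    """

    link: str = "identity"
    terms: tuple = ()
    include_treatment: bool = True
    working_variance: Union[float, str] = "unit"

    def __post_init__(self):
        if self.link not in _LINKS:
            raise ValueError(f"link must be one of {_LINKS}")
        object.__setattr__(self, "terms", _coerce_terms(self.terms))
        if self.working_variance != "unit" and not self.working_variance > 0:
            raise ValueError("working_variance must be positive or 'unit'")

    @property
    def is_plain_linear(self) -> bool:
        """Identity link with purely linear terms: fits reduce to WLS."""
        return self.link == "identity" and all(t.kind == "linear" for t in self.terms)


class DesignInfo:
    """Builds design matrices for a spec against a fixed training dataset.

    Smooth terms use a cubic B-spline basis with interior knots at training
    quantiles; the basis is centred on the training data so the intercept
    stays identifiable.  The same knots are reused at prediction time.
    """

    def __init__(self, spec: ModelSpec, X: np.ndarray, column_names: Sequence[str]):
        self.spec = spec
        self.column_names = tuple(column_names)
        self._col = {c: j for j, c in enumerate(self.column_names)}
        self._knots = {}
        self._centers = {}
        self.term_slices = {}
        names = ["intercept"]
        if spec.include_treatment:
            names.append("d")
        for t in spec.terms:
            if t.name not in self._col:
                raise SchemaError(f"covariate {t.name!r} not in dataset columns")
            if t.kind == "linear":
                self.term_slices[t.name] = slice(len(names), len(names) + 1)
                names.append(t.name)
            else:
                x = X[:, self._col[t.name]]
                self._knots[t.name] = _spline_knots(x, t.df)
                basis = _spline_basis(x, self._knots[t.name])
                self._centers[t.name] = basis.mean(axis=0)
                self.term_slices[t.name] = slice(len(names), len(names) + basis.shape[1])
                names += [f"{t.name}.s{j}" for j in range(basis.shape[1])]
        self.names = tuple(names)
        self.p = len(names)
        self.treatment_index = 1 if spec.include_treatment else None

    def matrix(self, X: np.ndarray, d) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n = X.shape[0]
        if X.shape[1] != len(self.column_names):
            raise SchemaError(
                f"covariate matrix has {X.shape[1]} columns, spec expects "
                f"{len(self.column_names)}"
            )
        cols = [np.ones(n)]
        if self.spec.include_treatment:
            d = np.broadcast_to(np.asarray(d, dtype=float), (n,))
            cols.append(d)
        for t in self.spec.terms:
            x = X[:, self._col[t.name]]
            if t.kind == "linear":
                cols.append(x)
            else:
                basis = _spline_basis(x, self._knots[t.name]) - self._centers[t.name]
                cols.append(basis.T)
        return np.column_stack([c.T if c.ndim > 1 else c for c in cols])

    def penalty(self) -> np.ndarray:
        """Block-diagonal second-difference roughness penalty (zero on
        intercept, treatment and linear terms)."""
        S = np.zeros((self.p, self.p))
        for t in self.spec.terms:
            if t.kind != "smooth":
                continue
            sl = self.term_slices[t.name]
            k = sl.stop - sl.start
            D2 = np.diff(np.eye(k), n=2, axis=0)
            S[sl, sl] = D2.T @ D2
        return S

    @property
    def has_smooth(self) -> bool:
        return bool(self._knots)


def _spline_knots(x: np.ndarray, df: int) -> np.ndarray:
    """Cubic B-spline knot vector with df basis functions."""
    n_interior = df - 4
    lo, hi = np.min(x), np.max(x)
    span = max(hi - lo, 1e-8)
    lo -= 0.001 * span
    hi += 0.001 * span
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(x, qs)
    else:
        interior = np.array([])
    return np.concatenate([[lo] * 4, interior, [hi] * 4])


def _spline_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    x = np.clip(x, knots[0], knots[-1])
    return BSpline.design_matrix(x, knots, 3).toarray()


@dataclass
class PSFit:
    """A fitted propensity model: coefficients, clipped fitted probabilities."""

    alpha: np.ndarray
    fitted_ps: np.ndarray
    spec: ModelSpec
    converged: bool
    design: DesignInfo = field(repr=False, default=None)
    clip_eps: float = 0.0

    def predict(self, X: np.ndarray) -> np.ndarray:
        eta = self.design.matrix(X, 0.0) @ self.alpha
        ps = expit(eta)
        if self.clip_eps > 0:
            ps = np.clip(ps, self.clip_eps, 1 - self.clip_eps)
        return ps


@dataclass
class ORFit:
    """A fitted (weighted) outcome-regression model."""

    xi: np.ndarray
    spec: ModelSpec
    weights_used: Optional[WeightSet]
    converged: bool
    design: DesignInfo = field(repr=False, default=None)
    ee_residual: float = 0.0

    def predict(self, X: np.ndarray, d, xi: Optional[np.ndarray] = None) -> np.ndarray:
        """Mean prediction ``Psi^{-1}{m(d, x; xi)}``; ``xi`` defaults to the
        fitted coefficients but may be any posterior draw."""
        xi = self.xi if xi is None else np.asarray(xi, dtype=float)
        eta = self.design.matrix(X, d) @ xi
        return _inverse_link(eta, self.spec.link)


def _inverse_link(eta: np.ndarray, link: str) -> np.ndarray:
    if link == "identity":
        return eta
    if link == "log":
        return np.exp(eta)
    return expit(eta)


def kappa_weights(ps: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Inverse-propensity weights kappa_i = d_i/ps_i + (1-d_i)/(1-ps_i)."""
    ps = np.asarray(ps, dtype=float)
    d = np.asarray(d, dtype=float)
    if ps.shape != d.shape:
        raise ValueError("ps and d must have equal length")
    if np.any(ps <= 0.0) or np.any(ps >= 1.0):
        raise ValueError("propensity scores must lie strictly inside (0, 1)")
    return d / ps + (1.0 - d) / (1.0 - ps)


def fit_propensity(
    data: ObservationalDataset,
    spec: ModelSpec,
    unit_weights: Optional[np.ndarray] = None,
    clip_eps: float = 0.01,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> PSFit:
    """Fit the logit assignment model by (weighted) maximum likelihood.

    Fitted probabilities are clipped to ``[clip_eps, 1 - clip_eps]`` before
    any kappa weights are formed, bounding individual weights by
    ``1/clip_eps``.  Pass ``clip_eps=0`` to disable.
    """
    if spec.link != "logit":
        raise ValueError("propensity model requires the logit link")
    if spec.include_treatment:
        spec = replace(spec, include_treatment=False)
    design = DesignInfo(spec, data.X, data.column_names)
    Z = design.matrix(data.X, 0.0)
    w = np.ones(data.n) if unit_weights is None else np.asarray(unit_weights, float)
    if np.any(w <= 0) or not np.isfinite(w).all():
        raise ValueError("unit weights must be strictly positive and finite")
    S = design.penalty()
    lam = _select_logit_penalty(Z, data.d, w, S) if design.has_smooth else 0.0
    alpha = _logit_irls(Z, data.d.astype(float), w, lam * S, max_iter, tol)
    eta = Z @ alpha
    ps = expit(eta)
    if np.max(np.abs(eta)) > 30 and (
        np.all((ps > 0.5) == (data.d == 1)) or np.ptp(eta) > 60
    ):
        raise SeparationError(
            "propensity model separates the arms perfectly; consider trimming "
            "or removing the offending covariate"
        )
    if clip_eps > 0:
        ps = np.clip(ps, clip_eps, 1.0 - clip_eps)
    return PSFit(alpha, ps, spec, True, design, clip_eps)


def _penalized_nll(Z, y, w, P, alpha):
    eta = np.clip(Z @ alpha, -500, 500)
    ll = w @ (y * eta - np.logaddexp(0.0, eta))
    return -ll + 0.5 * alpha @ (P @ alpha) if np.ndim(P) else -ll


def _logit_irls(Z, y, w, P, max_iter, tol):
    """Damped Newton-Raphson for the (penalized) weighted binomial
    log-likelihood; steps are halved until the objective improves."""
    alpha = np.zeros(Z.shape[1])
    wy = w * y
    alpha[0] = np.log(max(wy.sum(), 0.5) / max(w.sum() - wy.sum(), 0.5))
    nll = _penalized_nll(Z, y, w, P, alpha)
    for _ in range(max_iter):
        eta = Z @ alpha
        mu = expit(eta)
        grad = Z.T @ (w * (y - mu)) - P @ alpha
        info = (Z * (w * mu * (1 - mu))[:, None]).T @ Z + P
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            if np.max(np.abs(eta)) > 20:
                # the likelihood is unbounded along a separating direction:
                # fitted probabilities hit 0/1 and the information collapses
                raise SeparationError(
                    "propensity model separates the arms perfectly; consider "
                    "trimming or removing the offending covariate"
                ) from exc
            raise SingularDesignError("singular information matrix in logit fit") from exc
        for _ in range(40):
            new = _penalized_nll(Z, y, w, P, alpha + step)
            if new <= nll + 1e-12 * abs(nll):
                break
            step = step / 2
        alpha = alpha + step
        nll = new
        if np.max(np.abs(step)) < tol:
            return alpha
        if not np.isfinite(alpha).all():
            raise ConvergenceError("logit fit diverged")
    # a flat penalized likelihood can dither below tol only slowly; accept a
    # small final step, otherwise report separation/non-convergence
    if np.max(np.abs(step)) < 1e-4:
        return alpha
    if np.max(np.abs(Z @ alpha)) > 30:
        raise SeparationError("propensity model separates the arms perfectly")
    raise ConvergenceError("logit fit did not converge")


def _select_logit_penalty(Z, y, w, S, grid=None):
    """Pick the smooth penalty by (approximate) GCV on the working response."""
    grid = np.logspace(-3, 4, 15) if grid is None else grid
    best, best_lam = np.inf, grid[0]
    for lam in grid:
        try:
            alpha = _logit_irls(Z, y.astype(float), w, lam * S, 50, 1e-6)
        except (ConvergenceError, SingularDesignError):
            continue
        mu = expit(Z @ alpha)
        wt = w * mu * (1 - mu)
        H = Z @ np.linalg.solve((Z * wt[:, None]).T @ Z + lam * S, (Z * wt[:, None]).T)
        edf = np.trace(H)
        dev = -2 * np.sum(w * (y * np.log(mu + 1e-12) + (1 - y) * np.log(1 - mu + 1e-12)))
        gcv = len(y) * dev / (len(y) - edf) ** 2
        if gcv < best:
            best, best_lam = gcv, lam
    return best_lam


def fit_outcome(
    data: ObservationalDataset,
    spec: ModelSpec,
    weights: Optional[np.ndarray] = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> ORFit:
    """Solve the weighted outcome estimating equation for ``xi``.

    ``weights`` are the prior unit weights ``c_i`` (kappa, Bayesian-bootstrap,
    or combined); the root is invariant to their overall scale.  Identity link
    reduces to weighted least squares; log link is solved by Gauss-Newton
    under a constant working variance.
    """
    if weights is None:
        c = np.ones(data.n)
        wset = None
    elif isinstance(weights, WeightSet):
        c = weights.combined
        wset = weights
    else:
        c = np.asarray(weights, dtype=float)
        wset = WeightSet(np.ones(data.n), c)
    if c.shape[0] != data.n or np.any(c <= 0) or not np.isfinite(c).all():
        raise ValueError("weights must be strictly positive, finite, length n")
    design = DesignInfo(spec, data.X, data.column_names)
    D = design.matrix(data.X, data.d)
    S = design.penalty()

    if spec.link == "identity":
        lam = _select_wls_penalty(D, data.y, c, S) if design.has_smooth else 0.0
        xi = _solve_wls(D, data.y, c, lam * S)
        converged = True
    elif spec.link == "log":
        xi, converged = _gauss_newton_log(D, data.y, c, S, design, max_iter, tol)
        if not converged:
            raise ConvergenceError("log-link outcome fit did not converge")
    else:  # logit outcome (binary response)
        xi = _logit_irls(D, data.y, c, 0.0 * S, max_iter, tol)
        converged = True
    fit = ORFit(xi, spec, wset, converged, design)
    fit.ee_residual = estimating_equation_residual(fit, data, c)
    return fit


def _solve_wls(D, y, c, P=0.0):
    G = (D * c[:, None]).T @ D
    G = G + P if np.ndim(P) else G
    b = D.T @ (c * y)
    if np.ndim(P) == 0 or not P.any():
        # unpenalized: guard against rank deficiency
        if np.linalg.matrix_rank(G, tol=1e-8 * max(1.0, np.linalg.norm(G))) < D.shape[1]:
            raise SingularDesignError("weighted design matrix is rank deficient")
    return np.linalg.solve(G, b)


def _select_wls_penalty(D, y, c, S, grid=None):
    grid = np.logspace(-4, 5, 19) if grid is None else grid
    best, best_lam = np.inf, grid[0]
    n = len(y)
    Dc = D * c[:, None]
    G0 = Dc.T @ D
    b = D.T @ (c * y)
    for lam in grid:
        try:
            xi = np.linalg.solve(G0 + lam * S, b)
        except np.linalg.LinAlgError:
            continue
        r = y - D @ xi
        edf = np.trace(np.linalg.solve(G0 + lam * S, G0))
        gcv = n * np.sum(c * r * r) / (n - edf) ** 2
        if gcv < best:
            best, best_lam = gcv, lam
    return best_lam


def _gauss_newton_log(D, y, c, S, design, max_iter, tol):
    lam = 0.0  # penalty on smooths selected on a linearized fit
    if design.has_smooth:
        z = np.log(np.clip(y, 1e-3, None))
        lam = _select_wls_penalty(D, z, c, S)
    eta = np.full(len(y), np.log(max(np.average(y, weights=c), 1e-3)))
    xi = np.zeros(D.shape[1])
    xi[0] = eta[0]
    for _ in range(max_iter):
        mu = np.exp(np.clip(D @ xi, -30, 30))
        J = D * mu[:, None]
        grad = J.T @ (c * (y - mu)) - lam * (S @ xi)
        H = (J * c[:, None]).T @ J + lam * S
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise SingularDesignError("singular Gauss-Newton system") from exc
        # damped step for stability far from the root
        for _ in range(30):
            if np.max(np.abs(D @ (xi + step))) < 30:
                break
            step = step / 2
        xi = xi + step
        if np.max(np.abs(step)) < tol:
            return xi, True
        if not np.isfinite(xi).all():
            return xi, False
    return xi, False


def estimating_equation_residual(fit: ORFit, data: ObservationalDataset, c=None) -> float:
    """Max-norm of the weighted estimating-equation score at the fitted xi,
    normalized by n (phi = 1)."""
    if c is None:
        c = np.ones(data.n) if fit.weights_used is None else fit.weights_used.combined
    D = fit.design.matrix(data.X, data.d)
    eta = D @ fit.xi
    mu = _inverse_link(eta, fit.spec.link)
    if fit.spec.link == "identity":
        J = D
    elif fit.spec.link == "log":
        J = D * mu[:, None]
    else:
        J = D * (mu * (1 - mu))[:, None]
    score = J.T @ (c * (data.y - mu))
    return float(np.max(np.abs(score)) / data.n)


def predict_counterfactual(fit: ORFit, X: np.ndarray, d: int) -> np.ndarray:
    """Counterfactual mean ``Psi^{-1}{m(d, x_i; xi)}`` for every row of X."""
    if d not in (0, 1):
        raise ValueError("d must be 0 or 1")
    return fit.predict(X, float(d))


# ---------------------------------------------------------------------------
# batched kernels used by the Bayesian bootstrap (many weight vectors, one
# dataset); kept here so the single-fit and batched paths share conventions.

def batched_wls(D: np.ndarray, y: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Solve L weighted least-squares problems at once.

    ``W`` has shape (L, n); returns coefficients with shape (L, p).
    """
    G = np.einsum("ln,np,nq->lpq", W, D, D, optimize=True)
    b = np.einsum("ln,np->lp", W * y, D, optimize=True)
    return np.linalg.solve(G, b[..., None])[..., 0]


def batched_logit(
    Z: np.ndarray, y: np.ndarray, W: np.ndarray, max_iter: int = 60, tol: float = 1e-8
) -> np.ndarray:
    """Newton-Raphson for L weighted binomial logits at once; W is (L, n)."""
    L, n = W.shape
    p = Z.shape[1]
    alpha = np.zeros((L, p))
    wy = W @ y
    ws = W.sum(axis=1)
    alpha[:, 0] = np.log(np.maximum(wy, 0.5) / np.maximum(ws - wy, 0.5))
    active = np.ones(L, dtype=bool)
    for _ in range(max_iter):
        eta = Z @ alpha.T  # (n, L)
        mu = expit(eta)
        Wsc = W * (y[:, None] - mu).T
        grad = np.einsum("ln,np->lp", Wsc, Z, optimize=True)
        Winfo = W * (mu * (1 - mu)).T
        info = np.einsum("ln,np,nq->lpq", Winfo, Z, Z, optimize=True)
        info += 1e-10 * np.eye(p)
        step = np.linalg.solve(info, grad[..., None])[..., 0]
        alpha[active] = alpha[active] + step[active]
        done = np.max(np.abs(step), axis=1) < tol
        active &= ~done
        if not active.any():
            return alpha
    raise ConvergenceError("batched logit did not converge for every draw")
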