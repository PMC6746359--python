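"""Core data containers and delimited-table I/O.

The unit of analysis is one observational record ``z_i = (y_i, d_i, x_i)``:
an outcome (e.g. a differenced collision count), a binary treatment
indicator, and a vector of pre-treatment covariates.  Identification of the
average treatment effect additionally requires strong ignorability
(conditional independence, common support, SUTVA); the data-level parts of
those preconditions — both arms non-empty, propensity overlap — are
validated here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._exceptions import SchemaError, SupportError, TreatmentCodingError

__all__ = [
    "ObservationalDataset",
    "EffectEstimate",
    "WeightSet",
    "OverlapResult",
    "load_dataset",
    "write_dataset",
    "check_overlap",
]


@dataclass
class ObservationalDataset:
    """One row per unit: outcome ``y``, binary treatment ``d``, covariates ``X``.

    Parameters
    ----------
    y : array of float, shape (n,)
        Observed outcome per unit.
    d : array of int, shape (n,)
        Treatment indicator, coded 0/1.
    X : array of float, shape (n, p)
        Pre-treatment covariates.  ``p`` may be zero.
    column_names : sequence of str
        Labels for the columns of ``X``.
    """

    y: np.ndarray
    d: np.ndarray
    X: np.ndarray
    column_names: tuple = ()

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        self.d = np.asarray(self.d)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.size == 0:
            self.X = self.X.reshape(len(self.y), 0)
        if self.X.shape[0] != len(self.y) and self.X.shape[1] == len(self.y):
            self.X = self.X.T
        self.column_names = tuple(self.column_names)
        n = len(self.y)
        if n < 2:
            raise SchemaError(f"need at least 2 units, got {n}")
        if len(self.d) != n or self.X.shape[0] != n:
            raise SchemaError(
                f"length mismatch: y={n}, d={len(self.d)}, X rows={self.X.shape[0]}"
            )
        if self.column_names and len(self.column_names) != self.X.shape[1]:
            raise SchemaError("column_names length does not match X columns")
        if not self.column_names:
            self.column_names = tuple(f"x{j}" for j in range(self.X.shape[1]))
        vals = np.unique(self.d)
        if not np.all(np.isin(vals, (0, 1))):
            raise TreatmentCodingError(f"treatment must be coded 0/1, found {vals}")
        self.d = self.d.astype(int)
        if not (np.isfinite(self.y).all() and np.isfinite(self.X).all()):
            raise SchemaError("y and X must be finite (no missing values)")
        if self.d.sum() == 0 or self.d.sum() == n:
            raise SupportError(
                "common support requires at least one treated and one control unit"
            )

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def n_treated(self) -> int:
        return int(self.d.sum())

    def subset(self, idx) -> "ObservationalDataset":
        """Row subset (e.g. after matching or overlap trimming)."""
        idx = np.asarray(idx)
        return ObservationalDataset(
            self.y[idx], self.d[idx], self.X[idx], self.column_names
        )

    def to_frame(self, outcome: str = "y", treatment: str = "d") -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.column_names))
        df.insert(0, treatment, self.d)
        df.insert(0, outcome, self.y)
        return df


@dataclass(frozen=True)
class EffectEstimate:
    """A point estimate of the average treatment effect.

    ``scale`` is 'absolute' (same units as the outcome) or 'percent'
    (100 * tau / mean predicted untreated outcome — a reporting convention,
    since the percentage denominator is not uniquely defined).
    """

    tau: float
    scale: str = "absolute"
    estimator: str = "DR"

    def __post_init__(self):
        if not np.isfinite(self.tau):
            raise ValueError("ATE estimate must be finite")
        if self.scale not in ("absolute", "percent"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.estimator not in ("OR", "IPW", "DR", "NAIVE"):
            raise ValueError(f"unknown estimator {self.estimator!r}")


@dataclass
class WeightSet:
    """Bayesian-bootstrap weights ``w``, inverse-propensity weights ``kappa``,
    and their elementwise product, which multiplies the outcome-model score."""

    w: np.ndarray
    kappa: np.ndarray
    combined: np.ndarray = field(default=None)

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float)
        self.kappa = np.asarray(self.kappa, dtype=float)
        if self.w.shape != self.kappa.shape:
            raise ValueError("w and kappa must have equal length")
        for name, v in (("w", self.w), ("kappa", self.kappa)):
            if not (np.isfinite(v).all() and (v > 0).all()):
                raise ValueError(f"{name} entries must be strictly positive and finite")
        if self.combined is None:
            self.combined = self.w * self.kappa
        else:
            self.combined = np.asarray(self.combined, dtype=float)
            if not np.allclose(self.combined, self.w * self.kappa):
                raise ValueError("combined must equal w * kappa elementwise")

    @classmethod
    def from_kappa(cls, kappa: np.ndarray) -> "WeightSet":
        """Unit bootstrap weights (no resampling) with the given kappa."""
        kappa = np.asarray(kappa, dtype=float)
        return cls(np.ones_like(kappa), kappa)


@dataclass(frozen=True)
class OverlapResult:
    retained: np.ndarray
    n_dropped_treated: int
    n_dropped_control: int


def load_dataset(
    path,
    outcome: str,
    treatment: str,
    covariates: Sequence[str],
    treatment_mapping: Mapping | None = None,
) -> ObservationalDataset:
    """Read a comma-separated table (header row, '.' decimal) into a dataset.

    ``treatment_mapping`` maps raw treatment codes to {0, 1} explicitly; no
    silent inference is attempted for non-numeric codings.  Rows with missing
    outcome, treatment or covariate values are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in [outcome, treatment, *covariates] if c not in df.columns]
    if missing:
        raise SchemaError(f"columns not found in {path.name}: {missing}")
    d_raw = df[treatment]
    if treatment_mapping is not None:
        unknown = set(d_raw.unique()) - set(treatment_mapping)
        if unknown:
            raise TreatmentCodingError(
                f"treatment values {sorted(map(str, unknown))} not in mapping"
            )
        d = d_raw.map(treatment_mapping).to_numpy()
    else:
        d = d_raw.to_numpy()
        if not np.all(np.isin(np.unique(d), (0, 1))):
            raise TreatmentCodingError(
                "treatment column is not 0/1 coded; pass treatment_mapping"
            )
    sub = df[[outcome, *covariates]]
    if sub.isna().any().any() or pd.isna(d).any():
        raise SchemaError("missing values in outcome, treatment or covariates")
    return ObservationalDataset(
        y=sub[outcome].to_numpy(float),
        d=np.asarray(d),
        X=sub[list(covariates)].to_numpy(float),
        column_names=tuple(covariates),
    )


def write_dataset(
    data: ObservationalDataset, path, outcome: str = "y", treatment: str = "d"
) -> None:
    """Write a dataset back to CSV, mirroring the input dialect."""
    data.to_frame(outcome, treatment).to_csv(path, index=False)


def check_overlap(
    data: ObservationalDataset,
    ps: np.ndarray,
    bounds: tuple = (0.0, 1.0),
) -> OverlapResult:
    """Trim units whose propensity score falls outside ``bounds``.

    Enforces the common-support assumption empirically: units with extreme
    estimated assignment probabilities have no effective counterparts in the
    other arm.  With ``bounds=(0, 1)`` this is the identity.
    """
    lo, hi = bounds
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError(f"malformed overlap bounds {bounds}")
    ps = np.asarray(ps, dtype=float)
    if ps.shape[0] != data.n:
        raise SchemaError("propensity vector length does not match dataset")
    if np.any(ps <= 0.0) or np.any(ps >= 1.0):
        raise ValueError("propensity scores must lie strictly inside (0, 1)")
    keep = (ps >= lo) & (ps <= hi)
    if not keep.any():
        raise SupportError("overlap trim removed every unit")
    dropped = ~keep
    return OverlapResult(
        retained=np.flatnonzero(keep),
        n_dropped_treated=int((dropped & (data.d == 1)).sum()),
        n_dropped_control=int((dropped & (data.d == 0)).sum()),
    )


def summaries_to_json(obj: dict, path) -> None:
    """Write a summary dictionary (fit or posterior) as JSON."""
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(obj, indent=2, default=_default))
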