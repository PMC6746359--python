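"""Nearest-neighbour propensity-score matching.

Matching constructs a control group whose propensity distribution resembles
the treated group's before the doubly-robust model is fitted.  Defaults are
the conventional ones: 1:1, without replacement, treated units processed in
descending propensity order (hard-to-match units first), ties broken by
lowest control index, no caliper.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._exceptions import SupportError

__all__ = ["MatchResult", "nearest_neighbor_match"]


@dataclass
class MatchResult:
    matched_pairs: list  # [(treated index, control index), ...]
    unmatched_treated: list
    retained: np.ndarray  # sorted union of matched units

    @property
    def n_pairs(self) -> int:
        return len(self.matched_pairs)

    def diagnostics(self, ps: np.ndarray) -> dict:
        ps = np.asarray(ps, dtype=float)
        gaps = [abs(ps[t] - ps[c]) for t, c in self.matched_pairs]
        return {
            "n_pairs": self.n_pairs,
            "n_unmatched_treated": len(self.unmatched_treated),
            "mean_abs_ps_gap": float(np.mean(gaps)) if gaps else 0.0,
        }


def nearest_neighbor_match(
    ps: np.ndarray,
    d: np.ndarray,
    ratio: int = 1,
    replacement: bool = False,
    caliper: Optional[float] = None,
) -> MatchResult:
    """Match each treated unit to its ``ratio`` nearest controls by |PS gap|.

    Without replacement a control is consumed once; if controls run out the
    remaining treated units are left unmatched (reported, not an error).
    A caliper discards candidate pairs whose gap exceeds it.
    """
    ps = np.asarray(ps, dtype=float)
    d = np.asarray(d)
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    treated = np.flatnonzero(d == 1)
    controls = np.flatnonzero(d == 0)
    if treated.size == 0 or controls.size == 0:
        raise SupportError("matching requires both arms non-empty")

    # descending PS, ties by lowest index (stable sort on -ps)
    order = treated[np.argsort(-ps[treated], kind="stable")]
    available = np.ones(controls.size, dtype=bool)
    c_ps = ps[controls]
    pairs, unmatched = [], []
    for t in order:
        got = 0
        for _ in range(ratio):
            if replacement:
                cand = np.arange(controls.size)
            else:
                cand = np.flatnonzero(available)
                if cand.size == 0:
                    break
            gaps = np.abs(c_ps[cand] - ps[t])
            j = cand[np.argmin(gaps)]  # argmin takes the first => lowest index
            if caliper is not None and abs(c_ps[j] - ps[t]) > caliper:
                break
            pairs.append((int(t), int(controls[j])))
            if not replacement:
                available[j] = False
            got += 1
        if got == 0:
            unmatched.append(int(t))
    used = sorted({i for pair in pairs for i in pair})
    return MatchResult(pairs, unmatched, np.asarray(used, dtype=int))
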