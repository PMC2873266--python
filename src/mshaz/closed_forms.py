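"""Analytic reference formulas for the pure multistage (Armitage-Doll) limit.

With no intermediate-cell proliferation or death and small constant
mutation rates, a k-stage model's incidence rate is approximately the
power law

    h(t) = C * t^(k-1),    C = X * M_0 * M_1 * ... * M_{k-1} / (k-1)!

These closed forms serve as fast approximations and as independent oracles
for the ODE hazard engine in its small-rate regime.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["ArmitageDollParams", "armitage_doll_hazard", "loglog_slope"]


@dataclass(frozen=True)
class ArmitageDollParams:
    """k stages, X stem cells, k constant mutation rates (per cell-year)."""

    k: int
    X: float
    M: tuple[float, ...]

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        M = tuple(float(m) for m in self.M)
        if len(M) != self.k:
            raise ValueError(f"need {self.k} mutation rates, got {len(M)}")
        if any(m < 0 for m in M):
            raise ValueError("mutation rates must be >= 0")
        object.__setattr__(self, "M", M)

    @property
    def C(self) -> float:
        """The power-law constant X * prod(M) / (k-1)!."""
        return self.X * math.prod(self.M) / math.factorial(self.k - 1)


def armitage_doll_hazard(p: ArmitageDollParams, t):
    """Power-law hazard C * t^(k-1) (small-rate approximation)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("age must be >= 0")
    out = p.C * t_arr ** (p.k - 1)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def loglog_slope(curve, window) -> float:
    """Least-squares slope of log h versus log t over an age window.

    For a pure k-stage power-law hazard this is k - 1; departures measure
    how far a model is from Armitage-Doll behaviour.  ``curve`` is any
    object with ``ages`` and ``hazard`` arrays (e.g. a HazardCurve).
    """
    lo, hi = float(window[0]), float(window[1])
    if lo <= 0.0 or hi <= lo:
        raise ValueError("window must satisfy 0 < lo < hi")
    ages = np.asarray(curve.ages, dtype=float)
    haz = np.asarray(curve.hazard, dtype=float)
    mask = (ages >= lo) & (ages <= hi)
    if mask.sum() < 2:
        raise ValueError("need at least two grid ages inside the window")
    if np.any(haz[mask] <= 0.0):
        raise ValueError("hazard must be positive throughout the window")
    slope, _ = np.polyfit(np.log(ages[mask]), np.log(haz[mask]), 1)
    return float(slope)
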