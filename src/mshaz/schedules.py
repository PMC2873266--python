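"""Piecewise-constant rate schedules in age.

All model parameters (mutation, division, death and destabilization rates,
and the stem-cell count) are step functions of age: constant on half-open
intervals ``[b_i, b_{i+1})``, with the last interval extending to infinity.
Evaluation is right-continuous, so a rate change "at age t0" affects
``[t0, inf)`` — the convention needed for instantaneous-perturbation
studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["RateSchedule", "evaluate_rate"]


@dataclass(frozen=True)
class RateSchedule:
    """A nonnegative step function of age (years).

    Parameters
    ----------
    breakpoints:
        Strictly increasing ages; the first must be 0.0.  ``values[i]``
        applies on ``[breakpoints[i], breakpoints[i+1])`` and the last value
        extends to infinity.
    values:
        Nonnegative, finite rates (per cell per year, or cells for the
        stem-cell schedule), one per interval.
    """

    breakpoints: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        bp = tuple(float(b) for b in self.breakpoints)
        vals = tuple(float(v) for v in self.values)
        if len(bp) == 0:
            raise ValueError("schedule needs at least one interval")
        if bp[0] != 0.0:
            raise ValueError("first interval must start at age 0")
        if len(vals) != len(bp):
            raise ValueError(
                f"got {len(vals)} values for {len(bp)} breakpoints"
            )
        if any(b2 <= b1 for b1, b2 in zip(bp, bp[1:])):
            raise ValueError("breakpoints must be strictly increasing")
        if any(not math.isfinite(v) or v < 0.0 for v in vals):
            raise ValueError("rates must be finite and >= 0")
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "values", vals)

    @classmethod
    def constant(cls, value: float) -> "RateSchedule":
        return cls((0.0,), (float(value),))

    @classmethod
    def zero(cls) -> "RateSchedule":
        return cls((0.0,), (0.0,))

    @property
    def is_constant(self) -> bool:
        return len(self.values) == 1 or len(set(self.values)) == 1

    @property
    def is_zero(self) -> bool:
        return all(v == 0.0 for v in self.values)

    def __call__(self, t):
        """Evaluate at age(s) ``t`` (right-continuous at breakpoints)."""
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0.0):
            raise ValueError("age must be >= 0")
        idx = np.searchsorted(self.breakpoints, t_arr, side="right") - 1
        out = np.asarray(self.values, dtype=float)[idx]
        return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out

    def scaled(self, factor: float, from_age: float = 0.0,
               to_age: float = math.inf) -> "RateSchedule":
        """Multiply the schedule by ``factor`` on ``[from_age, to_age)``.

        Used to express instantaneous perturbations and exposure windows.
        """
        if factor < 0.0:
            raise ValueError("factor must be >= 0")
        if to_age <= from_age:
            raise ValueError("to_age must exceed from_age")
        edges = sorted(set(self.breakpoints) | {from_age}
                       | ({to_age} if math.isfinite(to_age) else set()))
        edges = [e for e in edges if e >= 0.0]
        vals = []
        for e in edges:
            v = self(e)
            if from_age <= e < to_age:
                v *= factor
            vals.append(v)
        return RateSchedule._simplified(edges, vals)

    @staticmethod
    def _simplified(edges, vals) -> "RateSchedule":
        keep_e, keep_v = [edges[0]], [vals[0]]
        for e, v in zip(edges[1:], vals[1:]):
            if v != keep_v[-1]:
                keep_e.append(e)
                keep_v.append(v)
        return RateSchedule(tuple(keep_e), tuple(keep_v))


def evaluate_rate(schedule: RateSchedule, t) -> float:
    """Value of ``schedule`` at age ``t`` (right-continuous)."""
    return schedule(t)
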