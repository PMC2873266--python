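"""Independent Monte-Carlo oracle: exact branching-process simulation.

The conditional-independence assumption — cell lineages evolve
independently given their ancestry and the parameter history — licenses
clone-by-clone simulation: per subject, initiations leave the
deterministic stem-cell pool as an inhomogeneous Poisson process, each
initiated clone then evolves by exact event-driven stochastic simulation
with the per-cell rates G, D, M, A, and the subject's first-malignancy age
is the minimum over clones.  The simulator shares nothing with the ODE
hazard engine beyond the compiled rate arrays, so agreement between the
two validates both.

Seed contract: subject ``i`` of a cohort draws from an independent stream
keyed ``(master_seed, subject_index)`` via ``numpy.random.SeedSequence``,
so a cohort of n subjects equals the concatenation of two half-cohorts run
with the same master seed and ``start_index`` 0 and n/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from ._compile import compile_model
from .model import ModelSpec

__all__ = ["SimResult", "SimulationError", "simulate_cohort",
           "empirical_cumulative_incidence", "clone_no_malignancy_prob"]


class SimulationError(RuntimeError):
    """A clone exceeded the configured size cap."""


@dataclass(frozen=True)
class SimResult:
    """Cohort outcome: detection ages for affected subjects, censoring at
    the horizon for the rest.  ``subject_times`` keeps the per-subject
    detection age (NaN when censored) in subject order."""

    n: int
    times: np.ndarray          # sorted first-malignancy (detection) ages
    censored_at: float         # horizon age for unaffected subjects
    seed: int
    subject_times: np.ndarray | None = None

    @property
    def n_affected(self) -> int:
        return len(self.times)

    @property
    def n_censored(self) -> int:
        return self.n - len(self.times)


def _subject_seeds(master_seed: int, n: int, start_index: int) -> np.ndarray:
    out = np.empty(n, dtype=np.int64)
    for i in range(n):
        ss = np.random.SeedSequence((int(master_seed), start_index + i))
        out[i] = int(ss.generate_state(1, dtype=np.uint32)[0])
    return out


def _cap_error(cm, cap):
    net = -np.inf
    worst = None
    for i, c in enumerate(cm.comps):
        if i == 0:
            continue
        loss = cm.Dm[:, i] + cm.Mm[:, i] + cm.Am[:, i, :].sum(axis=1)
        g = float((cm.Gm[:, i] - loss).max())
        if g > net:
            net, worst = g, c
    return SimulationError(
        f"clone exceeded the {cap:g}-cell cap; fastest-growing compartment "
        f"is {worst} with net growth rate {net:.4g}/year")


def simulate_cohort(spec: ModelSpec, n: int, horizon: float, seed: int,
                    cap: int = 1_000_000,
                    start_index: int = 0) -> SimResult:
    """Simulate ``n`` independent subjects to age ``horizon``.

    Returns the sorted detection ages (first malignant cell plus the fixed
    latency) of affected subjects; the rest are censored at ``horizon``.
    Raises :class:`SimulationError` if any clone outgrows ``cap`` cells.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    cm = compile_model(spec)
    t_stop = horizon - cm.spec.latency
    if t_stop <= 0.0:
        return SimResult(n=n, times=np.empty(0), censored_at=horizon,
                         seed=seed, subject_times=np.full(n, np.nan))
    seeds = _subject_seeds(seed, n, start_index)
    init_n = np.round(cm.init_n).astype(np.int64)
    times, errs = _kernels.simulate_cohort_kernel(
        seeds, cm.tau_ext, cm.Xv, cm.Gm, cm.Dm, cm.Mm, cm.Am, cm.Mtgt,
        cm.Atgt, cm.An, cm.f0, cm.init_idx, init_n, float(t_stop),
        int(cap))
    if np.any(errs != _kernels.OK):
        raise _cap_error(cm, cap)
    subject_times = np.where(np.isfinite(times), times + cm.spec.latency,
                             np.nan)
    affected = np.sort(times[np.isfinite(times)]) + cm.spec.latency
    return SimResult(n=n, times=affected, censored_at=horizon, seed=seed,
                     subject_times=subject_times)


def empirical_cumulative_incidence(res: SimResult, grid) -> np.ndarray:
    """Fraction of the cohort affected by each grid age (a nondecreasing
    step function; at the horizon it equals affected / n)."""
    grid = np.asarray(grid, dtype=float)
    if np.any(grid < 0) or np.any(grid > res.censored_at):
        raise ValueError("grid must lie within [0, horizon]")
    return np.searchsorted(res.times, grid, side="right") / res.n


def clone_no_malignancy_prob(spec: ModelSpec, compartment, t: float,
                             s: float = 0.0, n: int = 10_000,
                             seed: int = 0, cap: int = 1_000_000) -> float:
    """Monte-Carlo estimate of phi_c[t, s]: the probability that a single
    cell placed in ``compartment`` at age ``s`` produces no malignant
    descendant by age ``t``.  Cross-checks the backward-ODE engine."""
    if not 0.0 <= s <= t:
        raise ValueError("need 0 <= s <= t")
    cm = compile_model(spec)
    c0 = cm.index[tuple(compartment)]
    seeds = _subject_seeds(seed, n, 0)
    times, errs = _kernels.clone_batch_kernel(
        seeds, c0, float(s), float(t), cm.tau_ext, cm.Gm, cm.Dm, cm.Mm,
        cm.Am, cm.Mtgt, cm.Atgt, cm.An, int(cap))
    if np.any(errs != _kernels.OK):
        raise _cap_error(cm, cap)
    return float(np.mean(~np.isfinite(times)))
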