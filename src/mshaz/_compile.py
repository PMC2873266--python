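"""Flat array representation of a validated model.

Both the ODE hazard engine and the Monte-Carlo simulator consume the same
compiled form: a global grid of age breakpoints (the union over all
schedules) and per-interval, per-compartment rate matrices, plus integer
transition targets.  The malignant class is the sentinel index ``n_comp``.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .model import (ModelSpec, ROOT, destabilization_targets,
                    enumerate_compartments, mutation_target, validate_model)


class CompiledModel(NamedTuple):
    spec: ModelSpec                 # the validated source spec
    comps: tuple                    # ordered CompartmentIndex tuple
    index: dict                     # CompartmentIndex -> row
    tau: np.ndarray                 # interval starts, tau[0] == 0
    tau_ext: np.ndarray             # tau with +inf appended
    Xv: np.ndarray                  # stem cells per interval
    Gm: np.ndarray                  # [n_int, n_comp] division rates
    Dm: np.ndarray                  # [n_int, n_comp] death rates
    Mm: np.ndarray                  # [n_int, n_comp] cancer-stage rates
    Mtgt: np.ndarray                # [n_comp] target row (n_comp = malignant)
    Am: np.ndarray                  # [n_int, n_comp, amax] destabilization
    Atgt: np.ndarray                # [n_comp, amax] target rows
    An: np.ndarray                  # [n_comp] number of A targets
    f0: float                       # initial fraction at the root
    init_idx: np.ndarray            # rows of non-root initial compartments
    init_n: np.ndarray              # cell counts there at age 0

    @property
    def n_comp(self) -> int:
        return len(self.comps)

    @property
    def malignant(self) -> int:
        return len(self.comps)

    def interval_of(self, t: float) -> int:
        return int(np.searchsorted(self.tau, t, side="right") - 1)


def compile_model(spec: ModelSpec) -> CompiledModel:
    spec = validate_model(spec)
    comps = tuple(enumerate_compartments(spec))
    index = {c: i for i, c in enumerate(comps)}
    n = len(comps)

    breaks = set(spec.X.breakpoints)
    for mapping in (spec.M, spec.G, spec.D):
        for sched in mapping.values():
            breaks.update(sched.breakpoints)
    for sched in spec.A.values():
        breaks.update(sched.breakpoints)
    tau = np.array(sorted(breaks), dtype=float)
    n_int = len(tau)

    Xv = np.array([spec.X(t) for t in tau], dtype=float)
    Gm = np.zeros((n_int, n))
    Dm = np.zeros((n_int, n))
    Mm = np.zeros((n_int, n))
    amax = max(1, spec.r)
    Am = np.zeros((n_int, n, amax))
    Mtgt = np.full(n, n, dtype=np.int64)
    Atgt = np.zeros((n, amax), dtype=np.int64)
    An = np.zeros(n, dtype=np.int64)

    for c, i in index.items():
        Mm[:, i] = spec.M[c](tau)
        if c != ROOT:
            Gm[:, i] = spec.G[c](tau)
            Dm[:, i] = spec.D[c](tau)
        up = mutation_target(spec, c)
        Mtgt[i] = n if up is None else index[up]
        for j, (d, tgt) in enumerate(destabilization_targets(spec, c)):
            Am[:, i, j] = spec.A[(c, d)](tau)
            Atgt[i, j] = index[tgt]
            An[i] += 1

    fractions = spec.initial_fractions
    f0 = float(fractions.get(ROOT, 0.0))
    others = [(index[c], f) for c, f in fractions.items()
              if c != ROOT and f > 0.0]
    x0 = spec.X(0.0)
    init_idx = np.array([i for i, _ in others], dtype=np.int64)
    init_n = np.array([f * x0 for _, f in others], dtype=float)

    return CompiledModel(spec=spec, comps=comps, index=index, tau=tau,
                         tau_ext=np.append(tau, np.inf), Xv=Xv, Gm=Gm,
                         Dm=Dm, Mm=Mm, Mtgt=Mtgt, Am=Am, Atgt=Atgt, An=An,
                         f0=f0, init_idx=init_idx, init_n=init_n)
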