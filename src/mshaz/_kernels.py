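"""Numba event-driven kernels for the branching-process simulator.

Exact stochastic simulation with piecewise-constant rates: waiting times
are exponential in the current total propensity, redrawn (by memorylessness)
whenever age crosses a schedule breakpoint, so no event ever straddles a
rate discontinuity.  All rate matrices are indexed [interval, compartment];
the malignant class is the sentinel compartment index ``n_comp``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# error codes returned alongside the first-malignancy time
OK = 0
CAP_EXCEEDED = 1


@njit(cache=True)
def _interval_of(tau_ext, t):
    lo, hi = 0, tau_ext.size - 1   # tau_ext[-1] == inf
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if tau_ext[mid] <= t:
            lo = mid
        else:
            hi = mid
    return lo


@njit(cache=True)
def _run_clone(c0, t_start, t_stop, tau_ext, Gm, Dm, Mm, Am, Mtgt, Atgt,
               An, cap):
    """Evolve one clone founded by a single cell in compartment ``c0`` at
    age ``t_start``; return (first-malignancy age or inf, error code)."""
    n_comp = Mtgt.size
    counts = np.zeros(n_comp, dtype=np.int64)
    counts[c0] = 1
    total = 1
    t = t_start
    iv = _interval_of(tau_ext, t)
    while True:
        rate = 0.0
        for c in range(n_comp):
            if counts[c] > 0:
                rc = Gm[iv, c] + Dm[iv, c] + Mm[iv, c]
                for j in range(An[c]):
                    rc += Am[iv, c, j]
                rate += counts[c] * rc
        if rate <= 0.0:
            return np.inf, OK     # frozen clone: no further events possible
        dt = np.random.exponential(1.0 / rate)
        if t + dt >= tau_ext[iv + 1]:
            t = tau_ext[iv + 1]
            iv += 1
            if t >= t_stop:
                return np.inf, OK
            continue
        t += dt
        if t >= t_stop:
            return np.inf, OK
        # select (compartment, event type)
        u = np.random.random() * rate
        acc = 0.0
        for c in range(n_comp):
            if counts[c] == 0:
                continue
            nc = counts[c]
            acc += nc * Gm[iv, c]
            if u < acc:                       # symmetric division
                counts[c] += 1
                total += 1
                if total > cap:
                    return t, CAP_EXCEEDED
                break
            acc += nc * Dm[iv, c]
            if u < acc:                       # death / differentiation
                counts[c] -= 1
                total -= 1
                break
            acc += nc * Mm[iv, c]
            if u < acc:                       # cancer-stage mutation
                tgt = Mtgt[c]
                if tgt == n_comp:
                    return t, OK              # first malignant cell
                counts[tgt] += 1
                total += 1
                if total > cap:
                    return t, CAP_EXCEEDED
                break
            hit = False
            for j in range(An[c]):            # destabilizing mutation
                acc += nc * Am[iv, c, j]
                if u < acc:
                    counts[Atgt[c, j]] += 1
                    total += 1
                    hit = True
                    break
            if hit:
                if total > cap:
                    return t, CAP_EXCEEDED
                break
        if total == 0:
            return np.inf, OK                 # clone extinct


@njit(cache=True)
def _simulate_subject(tau_ext, Xv, Gm, Dm, Mm, Am, Mtgt, Atgt, An, f0,
                      init_idx, init_n, t_stop, cap):
    """First-malignancy age (or inf) for one subject."""
    n_comp = Mtgt.size
    best = t_stop
    # clones present at birth (two-populations-at-birth feature)
    for ii in range(init_idx.size):
        for _ in range(init_n[ii]):
            tm, err = _run_clone(init_idx[ii], 0.0, best, tau_ext, Gm, Dm,
                                 Mm, Am, Mtgt, Atgt, An, cap)
            if err != OK:
                return best, err
            if tm < best:
                best = tm
    # initiations out of the deterministic stem-cell pool: inhomogeneous
    # Poisson process with intensity f0 * X(t) * (M_root(t) + sum_d A_d(t))
    t = 0.0
    iv = 0
    while t < best:
        lam = Mm[iv, 0]
        for j in range(An[0]):
            lam += Am[iv, 0, j]
        lam *= f0 * Xv[iv]
        if lam <= 0.0:
            if tau_ext[iv + 1] >= best:
                break
            t = tau_ext[iv + 1]
            iv += 1
            continue
        dt = np.random.exponential(1.0 / lam)
        if t + dt >= tau_ext[iv + 1]:
            t = tau_ext[iv + 1]
            iv += 1
            continue
        t += dt
        if t >= best:
            break
        # thin to assign the destination compartment
        wtot = Mm[iv, 0]
        for j in range(An[0]):
            wtot += Am[iv, 0, j]
        u = np.random.random() * wtot
        if u < Mm[iv, 0]:
            tgt = Mtgt[0]
        else:
            acc = Mm[iv, 0]
            tgt = Atgt[0, 0]
            for j in range(An[0]):
                acc += Am[iv, 0, j]
                if u < acc:
                    tgt = Atgt[0, j]
                    break
        if tgt == n_comp:                     # k = 1: initiation IS malignancy
            best = t
            break
        tm, err = _run_clone(tgt, t, best, tau_ext, Gm, Dm, Mm, Am, Mtgt,
                             Atgt, An, cap)
        if err != OK:
            return best, err
        if tm < best:
            best = tm
    if best < t_stop:
        return best, OK
    return np.inf, OK


@njit(cache=True)
def simulate_cohort_kernel(seeds, tau_ext, Xv, Gm, Dm, Mm, Am, Mtgt, Atgt,
                           An, f0, init_idx, init_n, t_stop, cap):
    n = seeds.size
    times = np.empty(n)
    errs = np.zeros(n, dtype=np.int64)
    for i in range(n):
        np.random.seed(seeds[i])
        times[i], errs[i] = _simulate_subject(
            tau_ext, Xv, Gm, Dm, Mm, Am, Mtgt, Atgt, An, f0, init_idx,
            init_n, t_stop, cap)
    return times, errs


@njit(cache=True)
def clone_batch_kernel(seeds, c0, t_start, t_stop, tau_ext, Gm, Dm, Mm, Am,
                       Mtgt, Atgt, An, cap):
    """First-malignancy times for independent single-cell clones."""
    n = seeds.size
    times = np.empty(n)
    errs = np.zeros(n, dtype=np.int64)
    for i in range(n):
        np.random.seed(seeds[i])
        times[i], errs[i] = _run_clone(c0, t_start, t_stop, tau_ext, Gm,
                                       Dm, Mm, Am, Mtgt, Atgt, An, cap)
    return times, errs
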