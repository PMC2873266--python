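"""Hazard computation on the compartment lattice via backward ODEs.

For one cell sitting in non-malignant compartment ``c`` at age ``s``, let
``phi_c[t, s]`` be the probability that none of its descendants is
malignant by age ``t`` (the partial probability generating function of the
cell-count process evaluated at the point with malignant coordinate 0).
With per-compartment rates G (symmetric division), D (death or
differentiation), M (division producing a daughter plus a cell one cancer
stage up) and A (division producing a daughter plus a cell one
destabilization level up), ``phi`` satisfies the Kolmogorov backward
equations in ``s``; differentiating them with respect to ``t`` propagates
``dphi/dt`` alongside, and two augmentation variables accumulate the
hazard ``h(t)`` and cumulative hazard ``H(t)`` contributed by the
deterministic stem-cell pool ``X(t)``:

    S(t) = exp(-H(t)),   h(t) = g(t, s)|_{s=0},   H(t) = K(t, s)|_{s=0}.

Numerically the engine propagates ``chi = 1 - phi`` (the probability that
the cell DOES seed malignancy by ``t``) and ``w = d(chi)/dt``:

    d(chi)/ds = (D - G) chi + G chi^2 - M (1-chi) chi_up
                - sum_j A_j (1-chi) chi_tgt_j,            chi[t, t] = 0,

with ``chi`` of the malignant class identically 1.  In the small-rate
(Armitage-Doll) regime ``chi`` can be ~1e-40; propagating ``phi`` itself
would round it to exactly 1.0 in double precision, whereas ``chi`` keeps
full relative accuracy — hence the very small default ``atol``, which makes
the error control effectively relative, component by component.

When every schedule is constant the process is time-homogeneous,
``phi[t, s]`` depends only on ``t - s``, and one forward integration of
``chi(tau)`` over the whole age range yields the entire curve; the engine
uses this path automatically and falls back to one backward solve per grid
age otherwise.  Integrations are split at every schedule breakpoint so the
rate discontinuities never fall inside a solver step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from ._compile import CompiledModel, compile_model
from .model import ModelSpec, scale_parameter

__all__ = [
    "HazardCurve", "PGFState", "NumericalError", "compute_hazard",
    "backward_rhs", "backward_state", "no_malignancy_prob",
    "perturbation_jump", "JumpResult", "excess_risk_decay", "ExcessRisk",
    "DEFAULT_GRID",
]

DEFAULT_GRID = np.arange(0.0, 110.0 + 1e-9, 0.25)

# Negative hazards of magnitude below this are round-off and clipped to 0;
# anything more negative indicates a real numerical failure.
_NEG_CLIP = 1e-12


class NumericalError(RuntimeError):
    """The ODE solver failed or produced an inconsistent result."""


@dataclass(frozen=True)
class PGFState:
    """Augmented backward-ODE state at one (t, s).

    ``phi`` holds the partial-PGF values (no-malignancy probabilities), one
    per non-malignant compartment in the deterministic ordering;
    ``dphi_dt`` their t-derivatives; ``g`` and ``K`` accumulate the
    stem-cell-pool hazard and cumulative hazard.
    """

    phi: np.ndarray
    dphi_dt: np.ndarray
    g: float
    K: float


@dataclass(frozen=True)
class HazardCurve:
    """Hazard h(t), cumulative hazard H(t) and survival S(t) on an age grid."""

    ages: np.ndarray
    hazard: np.ndarray
    cumulative: np.ndarray

    @property
    def survival(self) -> np.ndarray:
        return np.exp(-self.cumulative)

    def hazard_at(self, age):
        return np.interp(age, self.ages, self.hazard)

    def cumulative_at(self, age):
        return np.interp(age, self.ages, self.cumulative)

    def survival_at(self, age):
        return np.exp(-self.cumulative_at(age))


# ---------------------------------------------------------------------------
# Right-hand sides

def _piece_rates(cm: CompiledModel, iv: int):
    return cm.Gm[iv], cm.Dm[iv], cm.Mm[iv], cm.Am[iv], cm.Xv[iv]


def _chi_w_rhs(cm, iv, chi, w):
    """d(chi)/ds and dw/ds inside one schedule interval (backward system)."""
    G, D, M, A, _ = _piece_rates(cm, iv)
    chi_ext = np.append(chi, 1.0)       # malignant class: chi = 1
    w_ext = np.append(w, 0.0)
    chi_up = chi_ext[cm.Mtgt]
    w_up = w_ext[cm.Mtgt]
    one_m = 1.0 - chi
    dchi = (D - G) * chi + G * chi * chi - M * one_m * chi_up
    dw = (D - G) * w + 2.0 * G * chi * w + M * (w * chi_up - one_m * w_up)
    for j in range(A.shape[1]):
        Aj = A[:, j]
        if not Aj.any():
            continue
        ct = chi_ext[cm.Atgt[:, j]]
        wt = w_ext[cm.Atgt[:, j]]
        dchi -= Aj * one_m * ct
        dw += Aj * (w * ct - one_m * wt)
    return dchi, dw


def _pool_terms(cm, iv, chi, w):
    """Pool seeding terms: d(-K)/ds-like and d(-g)/ds-like integrands."""
    _, _, M, A, X = _piece_rates(cm, iv)
    chi_ext = np.append(chi, 1.0)
    w_ext = np.append(w, 0.0)
    root = 0
    k_term = M[root] * chi_ext[cm.Mtgt[root]]
    g_term = M[root] * w_ext[cm.Mtgt[root]]
    for j in range(cm.An[root]):
        k_term += A[root, j] * chi_ext[cm.Atgt[root, j]]
        g_term += A[root, j] * w_ext[cm.Atgt[root, j]]
    return cm.f0 * X * g_term, cm.f0 * X * k_term


def _backward_rhs_flat(cm, iv, y):
    n = cm.n_comp
    chi, w = y[:n], y[n:2 * n]
    dchi, dw = _chi_w_rhs(cm, iv, chi, w)
    dg, dK = _pool_terms(cm, iv, chi, w)
    return np.concatenate([dchi, dw, [-dg, -dK]])


def backward_rhs(spec: ModelSpec, t: float, s: float,
                 state: PGFState) -> PGFState:
    """Derivative (with respect to ``s``) of the augmented backward system.

    Exposed in PGF coordinates (``phi``, ``dphi/dt``); the engine itself
    integrates the equivalent ``chi = 1 - phi`` system.
    """
    if not 0.0 <= s <= t:
        raise ValueError(f"need 0 <= s <= t, got s={s}, t={t}")
    cm = compile_model(spec)
    y = np.concatenate([1.0 - state.phi, -state.dphi_dt,
                        [state.g, state.K]])
    dy = _backward_rhs_flat(cm, cm.interval_of(s), y)
    n = cm.n_comp
    return PGFState(phi=-dy[:n], dphi_dt=-dy[n:2 * n],
                    g=float(dy[2 * n]), K=float(dy[2 * n + 1]))


# ---------------------------------------------------------------------------
# Backward path: one ODE solve (in s, from s = t down) per requested age

def _boundary_state(cm, t):
    n = cm.n_comp
    y = np.zeros(2 * n + 2)
    iv = cm.interval_of(t)
    malignant = cm.Mtgt == cm.malignant
    y[n:2 * n][malignant] = cm.Mm[iv][malignant]   # w(t, t)
    return y


def _solve_backward(cm, t, s_stops, rtol, atol, solver="RK45"):
    """Integrate s from t down to min(s_stops); return state at each stop."""
    s_stops = sorted(set(float(s) for s in s_stops), reverse=True)
    if any(s > t or s < 0.0 for s in s_stops):
        raise ValueError("s stops must lie in [0, t]")
    cuts = sorted({t, *s_stops,
                   *(b for b in cm.tau if min(s_stops) < b < t)},
                  reverse=True)
    y = _boundary_state(cm, t)
    out = {}
    if cuts[0] == t and t in s_stops:
        out[t] = y.copy()
    for s_hi, s_lo in zip(cuts, cuts[1:]):
        iv = cm.interval_of(0.5 * (s_hi + s_lo))
        sol = solve_ivp(lambda s, yy: _backward_rhs_flat(cm, iv, yy),
                        (s_hi, s_lo), y, method=solver, rtol=rtol,
                        atol=atol, dense_output=False)
        if not sol.success:
            raise NumericalError(
                f"backward solve failed on [{s_lo}, {s_hi}] at t={t}: "
                f"{sol.message}")
        y = sol.y[:, -1]
        if s_lo in s_stops:
            out[s_lo] = y.copy()
    return out


def _h_H_from_state(cm, t, y):
    n = cm.n_comp
    chi, w = y[:n], y[n:2 * n]
    g, K = y[2 * n], y[2 * n + 1]
    h = g
    H = K
    iv = cm.interval_of(t)
    if cm.Mtgt[0] == cm.malignant:
        # k = 1: the pool seeds malignancy directly (boundary term).
        h += cm.f0 * cm.Xv[iv] * cm.Mm[iv, 0]
    for i, nc in zip(cm.init_idx, cm.init_n):
        h += nc * w[i] / max(1.0 - chi[i], 1e-300)
        H += nc * (-math.log1p(-min(chi[i], 1.0 - 1e-300)))
    return h, H


def backward_state(spec: ModelSpec, t: float, s: float = 0.0,
                   rtol: float = 1e-8, atol: float = 1e-60) -> PGFState:
    """Solve the augmented backward system from s = t down to ``s``."""
    cm = compile_model(spec)
    y = _solve_backward(cm, t, [s], rtol, atol)[float(s)]
    n = cm.n_comp
    return PGFState(phi=1.0 - y[:n], dphi_dt=-y[n:2 * n],
                    g=float(y[2 * n]), K=float(y[2 * n + 1]))


def no_malignancy_prob(spec: ModelSpec, compartment, t: float,
                       s: float = 0.0, rtol: float = 1e-10,
                       atol: float = 1e-60) -> float:
    """phi_c[t, s]: probability that one cell in ``compartment`` at age
    ``s`` has produced no malignant descendant by age ``t``."""
    cm = compile_model(spec)
    state = backward_state(spec, t, s, rtol=rtol, atol=atol)
    return float(state.phi[cm.index[tuple(compartment)]])


# ---------------------------------------------------------------------------
# Homogeneous fast path: constant rates => phi[t, s] = phi[t - s, 0]

def _is_homogeneous(cm) -> bool:
    return len(cm.tau) == 1


def _forward_rhs(cm, y):
    chi, = (y[:cm.n_comp],)
    G, D, M, A, _ = _piece_rates(cm, 0)
    chi_ext = np.append(chi, 1.0)
    one_m = 1.0 - chi
    dchi = (G - D) * chi - G * chi * chi + M * one_m * chi_ext[cm.Mtgt]
    for j in range(A.shape[1]):
        Aj = A[:, j]
        if Aj.any():
            dchi += Aj * one_m * chi_ext[cm.Atgt[:, j]]
    return dchi


def _h_from_chi(cm, chi):
    G, D, M, A, X = _piece_rates(cm, 0)
    chi_ext = np.append(chi, 1.0)
    h = M[0] * chi_ext[cm.Mtgt[0]]
    for j in range(cm.An[0]):
        h += A[0, j] * chi_ext[cm.Atgt[0, j]]
    h *= cm.f0 * X
    if len(cm.init_idx):
        dchi = _forward_rhs(cm, chi)
        for i, nc in zip(cm.init_idx, cm.init_n):
            h += nc * dchi[i] / max(1.0 - chi[i], 1e-300)
    return h


def _homogeneous_curve(cm, t_eval, rtol, atol, solver="RK45"):
    n = cm.n_comp
    ts, inverse = np.unique(t_eval, return_inverse=True)
    t_max = float(ts[-1]) if len(ts) else 0.0

    def rhs(_t, y):
        dchi = _forward_rhs(cm, y[:n])
        return np.append(dchi, _h_from_chi(cm, y[:n]))

    h = np.empty_like(ts)
    H = np.empty_like(ts)
    if t_max == 0.0:
        chi0 = np.zeros(n)
        h[:] = _h_from_chi(cm, chi0)
        H[:] = 0.0
    else:
        sol = solve_ivp(rhs, (0.0, t_max), np.zeros(n + 1), method=solver,
                        rtol=rtol, atol=atol, t_eval=ts)
        if not sol.success:
            raise NumericalError(f"forward solve failed: {sol.message}")
        for i in range(len(ts)):
            h[i] = _h_from_chi(cm, sol.y[:n, i])
        H[:] = sol.y[n, :]
    return h[inverse], H[inverse]


# ---------------------------------------------------------------------------
# Public entry point

def compute_hazard(spec: ModelSpec, t_grid=None, rtol: float = 1e-8,
                   atol: float = 1e-60, method: str = "auto",
                   solver: str = "RK45") -> HazardCurve:
    """Hazard, cumulative hazard and survival for ``spec`` on an age grid.

    ``method="auto"`` uses the single-pass time-homogeneous reduction when
    every schedule is constant and the per-age backward solves otherwise;
    ``"backward"`` forces the general algorithm, ``"homogeneous"`` forces
    the reduction (an error for time-varying specs).  A fixed detection
    ``latency`` L shifts the curve: the hazard reported at age t is the
    first-malignant-cell hazard at t - L (zero before L).
    """
    cm = compile_model(spec)
    t_grid = DEFAULT_GRID if t_grid is None else np.atleast_1d(
        np.asarray(t_grid, dtype=float))
    if np.any(np.diff(t_grid) < 0) or np.any(t_grid < 0):
        raise ValueError("t_grid must be ascending and nonnegative")
    t_eff = np.maximum(t_grid - cm.spec.latency, 0.0)

    if method == "auto":
        method = "homogeneous" if _is_homogeneous(cm) else "backward"
    if method == "homogeneous":
        if not _is_homogeneous(cm):
            raise ValueError("homogeneous path needs constant schedules")
        h, H = _homogeneous_curve(cm, t_eff, rtol, atol, solver)
    elif method == "backward":
        uniq, inverse = np.unique(t_eff, return_inverse=True)
        h_u = np.empty_like(uniq)
        H_u = np.empty_like(uniq)
        for i, t in enumerate(uniq):
            if t == 0.0:
                h_u[i], H_u[i] = _h_H_from_state(
                    cm, 0.0, _boundary_state(cm, 0.0))
            else:
                y0 = _solve_backward(cm, t, [0.0], rtol, atol, solver)[0.0]
                h_u[i], H_u[i] = _h_H_from_state(cm, t, y0)
        h, H = h_u[inverse], H_u[inverse]
    else:
        raise ValueError(f"unknown method {method!r}")

    bad = h < -_NEG_CLIP
    if np.any(bad):
        raise NumericalError(
            f"hazard is negative beyond round-off (min {h.min():.3e}); "
            "tighten rtol/atol")
    h = np.clip(h, 0.0, None)
    H = np.maximum(np.maximum.accumulate(H), 0.0)
    return HazardCurve(ages=t_grid, hazard=h, cumulative=H)


# ---------------------------------------------------------------------------
# Perturbation analyses

@dataclass(frozen=True)
class JumpResult:
    """Instantaneous hazard response to a parameter step at age t0.

    ``relative`` is the discontinuity of the excess hazard across t0,
    normalized by the pre-perturbation hazard; ``absolute`` the
    unnormalized discontinuity.  ``zero_baseline`` flags h(t0-) = 0, in
    which case ``relative`` is NaN and only ``absolute`` is meaningful.
    """

    relative: float
    absolute: float
    baseline: float
    zero_baseline: bool


def perturbation_jump(spec: ModelSpec, handle: str, t0: float,
                      factor: float, eps: float = 1e-3,
                      rtol: float = 1e-10,
                      atol: float = 1e-60) -> JumpResult:
    """Size of the step in h at ``t0`` when one parameter is multiplied by
    ``factor`` on [t0, inf).

    Parameters acting late in the process (the last-stage mutation rate and
    the last-stage proliferation/death rates) produce an order-one step;
    early-stage parameters change the hazard only gradually and measure as
    (numerically) zero here.  The smooth drift of the baseline hazard over
    [t0-eps, t0+eps] is removed by differencing against the unperturbed
    curve, so the result isolates the discontinuity itself.
    """
    if factor <= 0.0:
        raise ValueError("factor must be > 0")
    if t0 - eps <= 0.0:
        raise ValueError("t0 must be interior to the age range")
    pert = scale_parameter(spec, handle, factor, from_age=t0)
    ts = np.array([t0 - eps, t0 + eps])
    h_b = compute_hazard(spec, ts, rtol=rtol, atol=atol,
                         method="backward").hazard
    h_p = compute_hazard(pert, ts, rtol=rtol, atol=atol,
                         method="backward").hazard
    excess = h_p - h_b
    absolute = abs(excess[1] - excess[0])
    baseline = h_b[0]
    if baseline <= 0.0:
        return JumpResult(relative=float("nan"), absolute=absolute,
                          baseline=baseline, zero_baseline=True)
    return JumpResult(relative=absolute / baseline, absolute=absolute,
                      baseline=baseline, zero_baseline=False)


@dataclass(frozen=True)
class ExcessRisk:
    """Excess hazard after a transient parameter perturbation."""

    ages: np.ndarray
    baseline: np.ndarray
    perturbed: np.ndarray

    @property
    def excess(self) -> np.ndarray:
        return self.perturbed - self.baseline


def excess_risk_decay(spec: ModelSpec, handle: str, window, factor: float,
                      horizon: float, t_grid=None, rtol: float = 1e-8,
                      atol: float = 1e-60) -> ExcessRisk:
    """Excess hazard from scaling one parameter by ``factor`` during the
    age window ``[t0, t1)``, followed out to ``horizon``."""
    t0, t1 = float(window[0]), float(window[1])
    if not t1 > t0:
        raise ValueError("window must satisfy t1 > t0")
    if t_grid is None:
        t_grid = np.arange(0.0, horizon + 1e-9, 1.0)
    pert = scale_parameter(spec, handle, factor, from_age=t0, to_age=t1)
    base_curve = compute_hazard(spec, t_grid, rtol=rtol, atol=atol)
    pert_curve = compute_hazard(pert, t_grid, rtol=rtol, atol=atol)
    return ExcessRisk(ages=np.asarray(t_grid, dtype=float),
                      baseline=base_curve.hazard,
                      perturbed=pert_curve.hazard)
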