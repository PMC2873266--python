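"""Poisson likelihood for age-incidence tables, MLE fitting, synthetic
tables, and numerical parameter-identifiability analysis.

Under the rare-disease assumption the population incidence rate is equated
with the model hazard, so the expected case count in an age band
``[lo, hi)`` with person-years PY is PY times the band-average hazard,
``PY * (H(hi) - H(lo)) / (hi - lo)``, and observed counts are Poisson.

Identifiability is probed numerically: the sensitivity matrix
``S[i, j] = dh(t_i) / d log(theta_j)`` (central finite differences in
log-parameters) is decomposed by SVD, and the number of estimable
parameter combinations is the count of singular values above a relative
threshold.  The two-mutation model's classical redundancy — only three
combinations of (X, M0, M1, G1, D1) are estimable from the hazard — and
the at-least-(r+1)-redundancies rule for models with r destabilization
types both appear as near-zero trailing singular values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln
from scipy.stats import qmc

from .hazard import compute_hazard
from .model import ModelSpec, parameter_schedule, validate_model, with_parameter

__all__ = [
    "IncidenceTable", "FitResult", "InferenceError", "default_bands",
    "expected_cases", "loglik", "fit", "sensitivity_matrix",
    "numerical_rank", "generate_synthetic_incidence",
    "overdispersion_scale",
]


class InferenceError(RuntimeError):
    """Optimization failed from every start."""


@dataclass(frozen=True)
class IncidenceTable:
    """Age-banded incidence: half-open bands [lo, hi), case counts and
    person-years at risk (SEER-style structure)."""

    age_low: np.ndarray
    age_high: np.ndarray
    cases: np.ndarray
    person_years: np.ndarray

    def __post_init__(self):
        lo = np.asarray(self.age_low, dtype=float)
        hi = np.asarray(self.age_high, dtype=float)
        cases = np.asarray(self.cases)
        py = np.asarray(self.person_years, dtype=float)
        if not (len(lo) == len(hi) == len(cases) == len(py)) or len(lo) == 0:
            raise ValueError("columns must be equal-length and nonempty")
        if np.any(hi <= lo):
            raise ValueError("each band needs age_high > age_low")
        if np.any(lo[1:] < hi[:-1]):
            raise ValueError("bands must be ascending and non-overlapping")
        if np.any(lo < 0):
            raise ValueError("ages must be >= 0")
        if np.any(cases < 0) or not np.allclose(cases, np.round(cases)):
            raise ValueError("cases must be nonnegative integers")
        if np.any(py <= 0):
            raise ValueError("person_years must be > 0")
        object.__setattr__(self, "age_low", lo)
        object.__setattr__(self, "age_high", hi)
        object.__setattr__(self, "cases", np.round(cases).astype(np.int64))
        object.__setattr__(self, "person_years", py)

    @property
    def n_bands(self) -> int:
        return len(self.age_low)

    @property
    def rate(self) -> np.ndarray:
        """Crude incidence rate per person-year, band by band."""
        return self.cases / self.person_years


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood fit with its local identifiability diagnosis."""

    estimates: dict
    loglik: float
    n_params: int
    singular_values: np.ndarray
    n_estimable: int
    converged: bool = True
    spec: ModelSpec | None = field(default=None, repr=False)


def default_bands(width: float = 5.0, max_age: float = 90.0) -> np.ndarray:
    """Band edges of the standard SEER-like layout: 5-year bands to 90."""
    return np.arange(0.0, max_age + 1e-9, width)


def _band_arrays(band):
    if isinstance(band, IncidenceTable):
        return band.age_low, band.age_high
    lo, hi = band
    return (np.atleast_1d(np.asarray(lo, dtype=float)),
            np.atleast_1d(np.asarray(hi, dtype=float)))


def expected_cases(spec: ModelSpec, band, person_years,
                   rtol: float = 1e-8, atol: float = 1e-60):
    """Expected Poisson count: person-years times band-average hazard.

    ``band`` may be a single (lo, hi) pair or an :class:`IncidenceTable`
    (whose own person-years are ignored in favour of ``person_years``,
    which may be scalar or per-band).
    """
    lo, hi = _band_arrays(band)
    edges = np.unique(np.concatenate([lo, hi]))
    curve = compute_hazard(spec, edges, rtol=rtol, atol=atol)
    H = dict(zip(edges, curve.cumulative))
    avg = np.array([(H[b] - H[a]) / (b - a) for a, b in zip(lo, hi)])
    mu = np.asarray(person_years, dtype=float) * avg
    return float(mu[0]) if np.ndim(person_years) == 0 and len(mu) == 1 \
        else mu


def loglik(spec: ModelSpec, table: IncidenceTable, rtol: float = 1e-8,
           atol: float = 1e-60) -> float:
    """Poisson log-likelihood of the table under the model hazard.

    Returns -inf when a band has observed cases but zero expected count
    (the model assigns the data probability zero).
    """
    mu = expected_cases(spec, table, table.person_years, rtol=rtol,
                        atol=atol)
    mu = np.atleast_1d(mu)
    cases = table.cases
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(cases > 0, cases * np.log(mu), 0.0)
    if np.any((mu == 0) & (cases > 0)):
        return -math.inf
    return float(np.sum(terms - mu - gammaln(cases + 1.0)))


def overdispersion_scale(spec: ModelSpec, table: IncidenceTable,
                         n_fitted: int = 0, rtol: float = 1e-8,
                         atol: float = 1e-60) -> float:
    """Pearson chi-square per degree of freedom: a descriptive
    quasi-likelihood scale factor.  Values well above 1 indicate extra-
    Poisson variation in the table; the factor is reported only, never
    used to reweight the likelihood."""
    mu = np.atleast_1d(expected_cases(spec, table, table.person_years,
                                      rtol=rtol, atol=atol))
    if np.any(mu <= 0):
        raise ValueError("overdispersion scale needs positive expected "
                         "counts in every band")
    dof = table.n_bands - n_fitted
    if dof < 1:
        raise ValueError("no residual degrees of freedom")
    return float(np.sum((table.cases - mu) ** 2 / mu) / dof)


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting over log-transformed schedule constants

def _constant_value(spec, handle) -> float:
    sched = parameter_schedule(spec, handle)
    if not sched.is_constant:
        raise ValueError(
            f"free parameter {handle!r} must be a constant schedule")
    return sched.values[0]


def _apply(spec, free, theta):
    for handle, val in zip(free, theta):
        spec = with_parameter(spec, handle, float(val))
    return spec


def fit(spec: ModelSpec, table: IncidenceTable, free, bounds=None,
        n_starts: int = 8, seed: int = 0, rtol: float = 1e-8,
        atol: float = 1e-60) -> FitResult:
    """Maximize the Poisson likelihood over the named free parameters.

    Optimization runs in log-parameter space (the likelihood ridges implied
    by parameter redundancy are axis-oblique but gentle there), from the
    supplied spec's values plus Latin-hypercube multistarts across the
    bounds.  ``bounds`` maps handle -> (lo, hi); the default spans four
    decades around each current value.
    """
    spec = validate_model(spec)
    free = list(free)
    if not free:
        ll = loglik(spec, table, rtol=rtol, atol=atol)
        return FitResult(estimates={}, loglik=ll, n_params=0,
                         singular_values=np.empty(0), n_estimable=0,
                         spec=spec)

    theta0 = np.array([_constant_value(spec, h) for h in free])
    bounds = dict(bounds or {})
    lo = np.empty(len(free))
    hi = np.empty(len(free))
    for j, h in enumerate(free):
        if h in bounds:
            lo[j], hi[j] = bounds[h]
        else:
            base = theta0[j] if theta0[j] > 0 else 1e-8
            lo[j], hi[j] = base * 1e-2, base * 1e2
        if lo[j] <= 0 or hi[j] <= lo[j]:
            raise ValueError(f"bounds for {h!r} must be 0 < lo < hi")
    zlo, zhi = np.log(lo), np.log(hi)

    def nll(z):
        val = loglik(_apply(spec, free, np.exp(z)), table, rtol=rtol,
                     atol=atol)
        return math.inf if not math.isfinite(val) else -val

    starts = [np.clip(np.log(np.where(theta0 > 0, theta0,
                                      np.sqrt(lo * hi))), zlo, zhi)]
    if n_starts > 1:
        sampler = qmc.LatinHypercube(d=len(free), seed=seed)
        unit = sampler.random(n_starts - 1)
        starts.extend(zlo + u * (zhi - zlo) for u in unit)

    best = None
    messages = []
    for z0 in starts:
        res = minimize(nll, z0, method="L-BFGS-B",
                       bounds=list(zip(zlo, zhi)))
        messages.append(str(res.message))
        if math.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise InferenceError(
            "no start converged to a finite likelihood; solver messages: "
            + "; ".join(messages))

    theta_hat = np.exp(best.x)
    fitted = _apply(spec, free, theta_hat)
    mids = 0.5 * (table.age_low + table.age_high)
    try:
        S = sensitivity_matrix(fitted, free, mids, rtol=min(rtol, 1e-10),
                               atol=atol)
        sv = np.linalg.svd(S, compute_uv=False)
        rank = numerical_rank(S)
    except Exception:            # hazard may vanish on part of the grid
        sv, rank = np.empty(0), len(free)
    return FitResult(estimates=dict(zip(free, theta_hat)),
                     loglik=-float(best.fun), n_params=len(free),
                     singular_values=sv, n_estimable=rank,
                     converged=bool(best.success), spec=fitted)


# ---------------------------------------------------------------------------
# Identifiability

def sensitivity_matrix(spec: ModelSpec, params, t_grid, rel_step: float = 1e-4,
                       rtol: float = 1e-12, atol: float = 1e-60) -> np.ndarray:
    """Matrix of dh(t)/d log(theta): rows are grid ages, columns the named
    parameters, by central finite differences in log-parameter space.

    The default tolerance is very tight because exact parameter
    redundancies must show up as singular values orders of magnitude below
    the estimable ones; with rel_step 1e-4 and rtol 1e-12 the numerical
    floor of a true null direction sits near 1e-9 relative.
    """
    spec = validate_model(spec)
    t_grid = np.asarray(t_grid, dtype=float)
    params = list(params)
    S = np.empty((len(t_grid), len(params)))
    for j, handle in enumerate(params):
        theta = _constant_value(spec, handle)
        if theta <= 0:
            raise ValueError(
                f"sensitivity in log({handle}) needs a positive value")
        up = compute_hazard(with_parameter(spec, handle,
                                           theta * math.exp(rel_step)),
                            t_grid, rtol=rtol, atol=atol).hazard
        dn = compute_hazard(with_parameter(spec, handle,
                                           theta * math.exp(-rel_step)),
                            t_grid, rtol=rtol, atol=atol).hazard
        S[:, j] = (up - dn) / (2.0 * rel_step)
    if not np.all(np.isfinite(S)):
        raise ValueError("sensitivity matrix has non-finite entries")
    return S


def numerical_rank(S: np.ndarray, tol_ratio: float = 1e-6) -> int:
    """Count of singular values exceeding ``tol_ratio`` times the largest:
    the number of locally estimable parameter combinations."""
    sv = np.linalg.svd(np.asarray(S, dtype=float), compute_uv=False)
    if len(sv) == 0 or sv[0] == 0.0:
        return 0
    return int(np.sum(sv / sv[0] > tol_ratio))


# ---------------------------------------------------------------------------
# Synthetic SEER-like tables

def generate_synthetic_incidence(spec: ModelSpec, bands=None,
                                 person_years=1e8, seed: int = 0,
                                 rtol: float = 1e-8,
                                 atol: float = 1e-60) -> IncidenceTable:
    """Draw a Poisson incidence table from the model's own hazard.

    ``bands`` is an array of band edges (default: 5-year bands 0-90);
    ``person_years`` is scalar or per-band.  Counts are reproducible given
    ``seed``.
    """
    edges = default_bands() if bands is None else np.asarray(bands,
                                                             dtype=float)
    lo, hi = edges[:-1], edges[1:]
    py = np.broadcast_to(np.asarray(person_years, dtype=float),
                         lo.shape).copy()
    mu = expected_cases(spec, (lo, hi), py, rtol=rtol, atol=atol)
    rng = np.random.default_rng(seed)
    cases = rng.poisson(np.atleast_1d(mu))
    return IncidenceTable(age_low=lo, age_high=hi, cases=cases,
                          person_years=py)
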