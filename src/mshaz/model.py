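"""Compartment-lattice specification of multistage carcinogenesis models.

The model family is the genomic-instability (GI) multistage model: a cell
lineage becomes malignant after accumulating ``k`` irreversible cancer-stage
mutations, and may additionally commit to one of ``r`` mutually exclusive
destabilization (GI) types, acquiring up to ``m_d`` destabilizing mutations
of its type.  Non-malignant cells live on a lattice of compartments
``I_(alpha, beta, d)``:

* ``alpha`` — cancer-stage mutations accumulated so far (0..k-1),
* ``d``     — destabilization type (0 = uncommitted, 1..r),
* ``beta``  — destabilizing mutations of type ``d`` (0 iff d == 0,
  else 1..m_d).

Per-compartment rates (all piecewise-constant in age):

* ``G`` symmetric division, ``D`` death/differentiation,
* ``M`` asymmetric division producing a daughter plus a cell with one more
  cancer-stage mutation (``alpha -> alpha+1``; at ``alpha = k-1`` the new
  cell is malignant),
* ``A`` asymmetric division producing a daughter plus a cell with one more
  destabilizing mutation; from the uncommitted plane this commits the new
  cell to a type ``d`` at level ``beta = 1``, within a committed plane it
  raises ``beta`` by one, and ``A = 0`` once ``beta = m_d``.

The susceptible stem-cell pool ``X(t)`` is deterministic; it seeds the
lattice through ``M(0,0,0)`` and ``A(0,0,0 -> d)``.  The classical models
are special cases: ``r = 0`` with ``G = D = 0`` is the Armitage-Doll
multistage model, ``k = 2, r = 0`` is the two-mutation (MVK / two-stage
clonal expansion) model, and ``r = 0`` in general is the generalized MVK
model.
"""

from __future__ import annotations

import dataclasses
import math
import re
from dataclasses import dataclass, field
from typing import NamedTuple

from .schedules import RateSchedule

__all__ = [
    "CompartmentIndex",
    "ModelSpec",
    "ModelError",
    "validate_model",
    "enumerate_compartments",
    "model_family",
    "mutation_target",
    "destabilization_targets",
    "armitage_doll_model",
    "two_mutation_model",
    "generalized_mvk_model",
    "gi_model",
    "parameter_schedule",
    "with_parameter",
    "scale_parameter",
    "parameter_handles",
]


class ModelError(ValueError):
    """A model specification violates a structural constraint."""


class CompartmentIndex(NamedTuple):
    """Lattice index (alpha, beta, d) of a non-malignant compartment."""

    alpha: int
    beta: int
    d: int

    def __str__(self) -> str:  # config-file key form
        return f"a{self.alpha}b{self.beta}d{self.d}"


ROOT = CompartmentIndex(0, 0, 0)


def _as_schedule(x) -> RateSchedule:
    if isinstance(x, RateSchedule):
        return x
    return RateSchedule.constant(float(x))


def _as_comp(c) -> CompartmentIndex:
    if isinstance(c, CompartmentIndex):
        return c
    return CompartmentIndex(*map(int, c))


@dataclass(frozen=True)
class ModelSpec:
    """Full parameterization of the GI compartment-lattice model.

    Rate maps may be sparse; :func:`validate_model` completes them with
    zero schedules.  ``A`` is keyed ``(compartment, target type d)``; from
    the uncommitted plane each target type has its own schedule, within a
    committed plane the target type must equal the compartment's own.
    ``initial_fractions`` places stem cells at age 0 (mass outside the root
    compartment expresses the two-populations-at-birth feature); ``latency``
    is a fixed lag (years) between the first malignant cell and detection.
    """

    k: int
    r: int = 0
    m: tuple[int, ...] = ()
    X: RateSchedule = field(default_factory=lambda: RateSchedule.constant(1e7))
    M: dict = field(default_factory=dict)
    A: dict = field(default_factory=dict)
    G: dict = field(default_factory=dict)
    D: dict = field(default_factory=dict)
    initial_fractions: dict = field(default_factory=lambda: {ROOT: 1.0})
    latency: float = 0.0

    def validated(self) -> "ModelSpec":
        return validate_model(self)


def enumerate_compartments(spec: ModelSpec) -> list[CompartmentIndex]:
    """Deterministically ordered non-malignant compartments.

    The uncommitted plane comes first (alpha ascending), then each
    destabilization plane d = 1..r (beta ascending, alpha ascending within
    beta).  The malignant class (alpha = k) is excluded.
    """
    comps = [CompartmentIndex(a, 0, 0) for a in range(spec.k)]
    for d in range(1, spec.r + 1):
        for beta in range(1, spec.m[d - 1] + 1):
            comps.extend(CompartmentIndex(a, beta, d) for a in range(spec.k))
    return comps


def mutation_target(spec: ModelSpec, c: CompartmentIndex):
    """Destination of a cancer-stage mutation; ``None`` means malignant."""
    if c.alpha + 1 == spec.k:
        return None
    return CompartmentIndex(c.alpha + 1, c.beta, c.d)


def destabilization_targets(spec: ModelSpec, c: CompartmentIndex):
    """(target type d, destination compartment) pairs reachable from ``c``."""
    if c.d == 0:
        return [(d, CompartmentIndex(c.alpha, 1, d))
                for d in range(1, spec.r + 1)]
    if c.beta < spec.m[c.d - 1]:
        return [(c.d, CompartmentIndex(c.alpha, c.beta + 1, c.d))]
    return []  # beta == m_d: no further destabilization (A == 0 convention)


def _check_fraction_keys(spec, comp_set):
    for c, f in spec.initial_fractions.items():
        if _as_comp(c) not in comp_set:
            raise ModelError(f"initial fraction on invalid compartment {c}")
        if f < 0.0:
            raise ModelError("initial fractions must be >= 0")
    total = sum(spec.initial_fractions.values())
    if abs(total - 1.0) > 1e-12:
        raise ModelError(f"initial fractions sum to {total!r}, not 1")


def validate_model(spec: ModelSpec) -> ModelSpec:
    """Check all structural invariants; complete sparse rate maps.

    Returns a new :class:`ModelSpec` whose M/G/D/A maps carry an explicit
    (possibly zero) schedule for every admissible transition.  Raises
    :class:`ModelError` on any violation: negative ``m_d``, rates on
    inadmissible transitions (e.g. nonzero ``A`` at ``beta = m_d``, or
    division/death on the stem-cell root, whose dynamics are governed
    solely by ``X(t)``), or initial fractions not summing to 1.
    """
    if spec.k < 1:
        raise ModelError("k must be >= 1")
    if spec.r < 0:
        raise ModelError("r must be >= 0")
    if len(spec.m) != spec.r:
        raise ModelError(f"m must list one level count per type: "
                         f"got {len(spec.m)} for r={spec.r}")
    if any(md < 1 for md in spec.m):
        raise ModelError("each m_d must be >= 1 (express 'no destabilization'"
                         " as r=0, not m_d=0)")
    if spec.latency < 0.0:
        raise ModelError("latency must be >= 0")

    comps = enumerate_compartments(spec)
    comp_set = set(comps)

    M = {}
    for c in comps:
        M[c] = _as_schedule(spec.M.get(c, RateSchedule.zero()))
    for c in spec.M:
        if _as_comp(c) not in comp_set:
            raise ModelError(f"M specified on invalid compartment {c}")

    G, D = {}, {}
    for name, src, out in (("G", spec.G, G), ("D", spec.D, D)):
        for c in src:
            cc = _as_comp(c)
            if cc not in comp_set:
                raise ModelError(f"{name} specified on invalid "
                                 f"compartment {c}")
            if cc == ROOT and not _as_schedule(src[c]).is_zero:
                raise ModelError(
                    f"{name}(0,0,0) is not used: the stem-cell pool is "
                    "governed solely by X(t)")
        for c in comps:
            if c == ROOT:
                continue
            out[c] = _as_schedule(src.get(c, RateSchedule.zero()))

    A = {}
    admissible = {(c, d): tgt for c in comps
                  for d, tgt in destabilization_targets(spec, c)}
    for key, sched in spec.A.items():
        c, d = _as_comp(key[0]), int(key[1])
        sched = _as_schedule(sched)
        if (c, d) not in admissible:
            if sched.is_zero:
                continue
            if c in comp_set and c.d >= 1 and d != c.d:
                raise ModelError(
                    f"A({c}; type {d}) would change the destabilization "
                    "type, but types are mutually exclusive")
            if c in comp_set and c.d >= 1 and c.beta >= spec.m[c.d - 1]:
                raise ModelError(
                    f"A({c}; type {d}) must be 0 at beta = m_d "
                    f"(= {spec.m[c.d - 1]})")
            raise ModelError(f"A({c}; type {d}) is not an admissible "
                             "destabilization")
    for key in admissible:
        A[key] = _as_schedule(spec.A.get(key, RateSchedule.zero()))

    _check_fraction_keys(spec, comp_set)
    fractions = {_as_comp(c): float(f)
                 for c, f in spec.initial_fractions.items()}

    return dataclasses.replace(
        spec, m=tuple(int(md) for md in spec.m), X=_as_schedule(spec.X),
        M=M, A=A, G=G, D=D, initial_fractions=fractions,
        latency=float(spec.latency))


def model_family(spec: ModelSpec) -> str:
    """Classify a spec into the model family it reduces to.

    Returns ``"armitage-doll"`` (no destabilization, no intermediate-cell
    proliferation or death), ``"two-mutation"`` (k=2 MVK), then
    ``"generalized-mvk"`` (any k, r=0), else ``"gi-multipath"``.
    """
    spec = validate_model(spec)
    if spec.r == 0:
        no_growth = all(s.is_zero for s in spec.G.values()) and \
            all(s.is_zero for s in spec.D.values())
        if no_growth:
            return "armitage-doll"
        if spec.k == 2:
            return "two-mutation"
        return "generalized-mvk"
    return "gi-multipath"


# ---------------------------------------------------------------------------
# Convenience builders for the classical special cases

def armitage_doll_model(k: int, X, M, latency: float = 0.0) -> ModelSpec:
    """k-stage Armitage-Doll model: mutation only, no clonal expansion."""
    M = list(M)
    if len(M) != k:
        raise ModelError(f"need {k} mutation rates, got {len(M)}")
    return validate_model(ModelSpec(
        k=k, X=_as_schedule(X),
        M={CompartmentIndex(i, 0, 0): _as_schedule(M[i]) for i in range(k)},
        latency=latency))


def two_mutation_model(X, M0, M1, G1, D1, latency: float = 0.0,
                       initial_fractions=None) -> ModelSpec:
    """Two-mutation (MVK / two-stage clonal expansion) model."""
    return generalized_mvk_model(2, X, [M0, M1], [G1], [D1],
                                 latency=latency,
                                 initial_fractions=initial_fractions)


def generalized_mvk_model(k: int, X, M, G, D, latency: float = 0.0,
                          initial_fractions=None) -> ModelSpec:
    """Generalized MVK model: k stages with per-stage birth/death rates.

    ``M`` lists k mutation rates M(0)..M(k-1); ``G`` and ``D`` list k-1
    division and death/differentiation rates for stages 1..k-1.
    """
    M, G, D = list(M), list(G), list(D)
    if len(M) != k or len(G) != k - 1 or len(D) != k - 1:
        raise ModelError("need k mutation and k-1 division/death rates")
    kwargs = {}
    if initial_fractions is not None:
        kwargs["initial_fractions"] = initial_fractions
    return validate_model(ModelSpec(
        k=k, X=_as_schedule(X),
        M={CompartmentIndex(i, 0, 0): _as_schedule(M[i]) for i in range(k)},
        G={CompartmentIndex(i, 0, 0): _as_schedule(G[i - 1])
           for i in range(1, k)},
        D={CompartmentIndex(i, 0, 0): _as_schedule(D[i - 1])
           for i in range(1, k)},
        latency=latency, **kwargs))


def gi_model(k: int, r: int, m, X, M=None, A=None, G=None, D=None,
             latency: float = 0.0, initial_fractions=None) -> ModelSpec:
    """General GI compartment model from sparse rate maps.

    ``M``/``G``/``D`` map (alpha, beta, d) tuples to rates; ``A`` maps
    ((alpha, beta, d), target type) pairs.
    """
    def comp_map(src):
        return {_as_comp(c): _as_schedule(v) for c, v in (src or {}).items()}

    kwargs = {}
    if initial_fractions is not None:
        kwargs["initial_fractions"] = {_as_comp(c): float(f)
                                       for c, f in initial_fractions.items()}
    return validate_model(ModelSpec(
        k=k, r=r, m=tuple(int(x) for x in m), X=_as_schedule(X),
        M=comp_map(M),
        A={(_as_comp(c), int(d)): _as_schedule(v)
           for (c, d), v in (A or {}).items()},
        G=comp_map(G), D=comp_map(D), latency=latency, **kwargs))


# ---------------------------------------------------------------------------
# Parameter handles — stable string names for individual rate schedules,
# used by perturbation studies, sensitivity analysis and fitting.

_HANDLE_RE = re.compile(
    r"^([MGDA])\((\d+),(\d+),(\d+)(?:->(\d+))?\)$")
_SHORT_RE = re.compile(r"^([MGD])(\d+)$")


def _resolve_handle(spec: ModelSpec, handle: str):
    """Return (map name, key) for a handle, or ("X", None)."""
    handle = handle.strip().replace(" ", "")
    if handle == "X":
        return "X", None
    match = _SHORT_RE.match(handle)
    if match:  # Mi / Gi / Di shorthand for r=0 models
        name, i = match.group(1), int(match.group(2))
        handle = f"{name}({i},0,0)"
    match = _HANDLE_RE.match(handle)
    if not match:
        raise ModelError(f"cannot parse parameter handle {handle!r}")
    name = match.group(1)
    c = CompartmentIndex(int(match.group(2)), int(match.group(3)),
                         int(match.group(4)))
    if name == "A":
        if match.group(5) is None:
            if c.d == 0:
                raise ModelError(
                    f"A handle from the uncommitted plane needs a target "
                    f"type, e.g. 'A({c.alpha},{c.beta},{c.d}->1)'")
            key = (c, c.d)
        else:
            key = (c, int(match.group(5)))
        if key not in spec.A:
            raise ModelError(f"no destabilization schedule for handle "
                             f"{handle!r}")
        return "A", key
    if match.group(5) is not None:
        raise ModelError(f"'->' target only applies to A handles: {handle!r}")
    if c not in getattr(spec, name):
        raise ModelError(f"no {name} schedule for compartment {c}")
    return name, c


def parameter_schedule(spec: ModelSpec, handle: str) -> RateSchedule:
    """The schedule a handle refers to (``"X"``, ``"M(0,0,0)"``,
    ``"G(1,0,0)"``, ``"A(0,0,0->1)"``; ``"M0"``-style shorthand for r=0)."""
    spec = validate_model(spec)
    name, key = _resolve_handle(spec, handle)
    return spec.X if name == "X" else getattr(spec, name)[key]


def with_parameter(spec: ModelSpec, handle: str,
                   schedule) -> ModelSpec:
    """New validated spec with one schedule replaced."""
    spec = validate_model(spec)
    name, key = _resolve_handle(spec, handle)
    schedule = _as_schedule(schedule)
    if name == "X":
        return validate_model(dataclasses.replace(spec, X=schedule))
    new_map = dict(getattr(spec, name))
    new_map[key] = schedule
    return validate_model(dataclasses.replace(spec, **{name: new_map}))


def scale_parameter(spec: ModelSpec, handle: str, factor: float,
                    from_age: float = 0.0,
                    to_age: float = math.inf) -> ModelSpec:
    """Multiply one parameter schedule by ``factor`` on ``[from_age, to_age)``."""
    sched = parameter_schedule(spec, handle)
    return with_parameter(spec, handle, sched.scaled(factor, from_age, to_age))


def parameter_handles(spec: ModelSpec,
                      include_zero: bool = False) -> list[str]:
    """Handles for X and every biological rate of the model, in the
    deterministic compartment order (zero schedules skipped by default —
    perturbing or fitting an identically-zero rate is vacuous)."""
    spec = validate_model(spec)
    handles = ["X"]
    for c in enumerate_compartments(spec):
        for name in ("M", "G", "D"):
            sched = getattr(spec, name).get(c)
            if sched is not None and (include_zero or not sched.is_zero):
                handles.append(f"{name}({c.alpha},{c.beta},{c.d})")
        for d, _tgt in destabilization_targets(spec, c):
            sched = spec.A[(c, d)]
            if include_zero or not sched.is_zero:
                handles.append(f"A({c.alpha},{c.beta},{c.d}->{d})")
    return handles
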