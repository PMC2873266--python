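"""Config-file and CSV readers/writers.

Model configs are YAML (or JSON, by file extension) with keys ``k``,
``r``, ``m``, ``X``, ``latency``, ``initial_fractions`` and rate tables
``M``/``G``/``D``/``A``.  Compartments are keyed ``"a<alpha>b<beta>d<d>"``;
destabilization schedules append the target type, ``"a0b0d0->1"``.  A
schedule is either a scalar (constant rate) or ``{breaks: [...],
values: [...]}``.  Unknown keys are rejected by name.

Incidence tables are CSV with the exact header
``age_low,age_high,cases,person_years``.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import pandas as pd
import yaml

from .inference import IncidenceTable
from .model import CompartmentIndex, ModelSpec, validate_model
from .schedules import RateSchedule

__all__ = ["ConfigError", "FormatError", "read_model_config",
           "write_model_config", "spec_to_dict", "spec_from_dict",
           "read_incidence_csv", "write_incidence_csv"]

_TOP_KEYS = {"k", "r", "m", "X", "latency", "initial_fractions",
             "M", "G", "D", "A"}
_COMP_RE = re.compile(r"^a(\d+)b(\d+)d(\d+)$")
_A_RE = re.compile(r"^a(\d+)b(\d+)d(\d+)->(\d+)$")
INCIDENCE_HEADER = ["age_low", "age_high", "cases", "person_years"]


class ConfigError(ValueError):
    """A model config violates the schema."""


class FormatError(ValueError):
    """A CSV file violates the incidence-table format."""


def _schedule_from(obj, where: str) -> RateSchedule:
    if isinstance(obj, (int, float)):
        return RateSchedule.constant(float(obj))
    if isinstance(obj, dict):
        unknown = set(obj) - {"breaks", "values"}
        if unknown:
            raise ConfigError(
                f"unknown schedule key(s) {sorted(unknown)} under {where}")
        try:
            return RateSchedule(tuple(obj.get("breaks", (0.0,))),
                                tuple(obj["values"]))
        except (KeyError, ValueError) as exc:
            raise ConfigError(f"bad schedule under {where}: {exc}") from exc
    raise ConfigError(f"schedule under {where} must be a number or "
                      "{breaks, values}")


def _schedule_to(sched: RateSchedule) -> dict:
    return {"breaks": list(sched.breakpoints), "values": list(sched.values)}


def _comp_from(key: str, where: str) -> CompartmentIndex:
    match = _COMP_RE.match(str(key))
    if not match:
        raise ConfigError(f"bad compartment key {key!r} under {where} "
                          "(expected 'a<alpha>b<beta>d<d>')")
    return CompartmentIndex(*map(int, match.groups()))


def spec_from_dict(data: dict) -> ModelSpec:
    """Build and validate a ModelSpec from a config mapping."""
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    if "k" not in data:
        raise ConfigError("config key 'k' is required")

    def comp_map(name):
        out = {}
        for key, val in (data.get(name) or {}).items():
            out[_comp_from(key, name)] = _schedule_from(val, f"{name}.{key}")
        return out

    A = {}
    for key, val in (data.get("A") or {}).items():
        match = _A_RE.match(str(key))
        if not match:
            raise ConfigError(f"bad A key {key!r} (expected "
                              "'a<alpha>b<beta>d<d>-><type>')")
        comp = CompartmentIndex(*map(int, match.groups()[:3]))
        A[(comp, int(match.group(4)))] = _schedule_from(val, f"A.{key}")

    fractions = {}
    for key, val in (data.get("initial_fractions")
                     or {"a0b0d0": 1.0}).items():
        fractions[_comp_from(key, "initial_fractions")] = float(val)

    try:
        return validate_model(ModelSpec(
            k=int(data["k"]), r=int(data.get("r", 0)),
            m=tuple(int(x) for x in data.get("m", ())),
            X=_schedule_from(data.get("X", 1e7), "X"),
            M=comp_map("M"), G=comp_map("G"), D=comp_map("D"), A=A,
            initial_fractions=fractions,
            latency=float(data.get("latency", 0.0))))
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def spec_to_dict(spec: ModelSpec) -> dict:
    """Canonical config mapping of a validated spec (identically-zero
    schedules omitted; keys sorted on write)."""
    spec = validate_model(spec)
    out = {
        "k": spec.k, "r": spec.r, "m": list(spec.m),
        "X": _schedule_to(spec.X), "latency": spec.latency,
        "initial_fractions": {str(c): f
                              for c, f in sorted(spec.initial_fractions
                                                 .items())},
    }
    for name in ("M", "G", "D"):
        table = {str(c): _schedule_to(s)
                 for c, s in sorted(getattr(spec, name).items())
                 if not s.is_zero}
        if table:
            out[name] = table
    A = {f"{c}->{d}": _schedule_to(s)
         for (c, d), s in sorted(spec.A.items()) if not s.is_zero}
    if A:
        out["A"] = A
    return out


def read_model_config(path) -> ModelSpec:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    return spec_from_dict(data)


def write_model_config(spec: ModelSpec, path) -> None:
    path = Path(path)
    data = spec_to_dict(spec)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))


# ---------------------------------------------------------------------------
# Incidence CSV

def read_incidence_csv(path) -> IncidenceTable:
    frame = pd.read_csv(path)
    if list(frame.columns) != INCIDENCE_HEADER:
        raise FormatError(
            f"expected header {','.join(INCIDENCE_HEADER)}; "
            f"got {','.join(map(str, frame.columns))}")
    try:
        return IncidenceTable(
            age_low=frame["age_low"].to_numpy(dtype=float),
            age_high=frame["age_high"].to_numpy(dtype=float),
            cases=frame["cases"].to_numpy(),
            person_years=frame["person_years"].to_numpy(dtype=float))
    except ValueError as exc:
        raise FormatError(str(exc)) from exc


def write_incidence_csv(table: IncidenceTable, path) -> None:
    frame = pd.DataFrame({
        "age_low": table.age_low, "age_high": table.age_high,
        "cases": table.cases, "person_years": table.person_years})
    frame.to_csv(path, index=False)
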