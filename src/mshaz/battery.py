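"""The fixture battery: named study specs covering every model family.

Eight specs, all with constant rates, exercising the four families
(armitage-doll, two-mutation, generalized-mvk, gi-multipath) plus the
two-populations-at-birth feature.  Rates are per cell per year; stem-cell
counts in cells.  They are chosen for biological plausibility at desk
scale: initiation fluxes X*M(0) of order 0.01-1 per year, intermediate-cell
net growth of order +/-0.01-0.05 per year, and lifetime cumulative
incidence between ~1% and ~30% so the Monte-Carlo/engine comparison has
statistical power without runaway clone sizes.

Separate helper constructors provide the perturbation-response and
excess-risk-decay study models, which need specific regimes (a
conversion-dominant two-stage model for identifiability; net cell
inactivation for decay-to-zero within a human lifetime).
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import (ModelSpec, armitage_doll_model, generalized_mvk_model,
                    gi_model, two_mutation_model)

__all__ = ["BatterySpec", "battery", "battery_by_name",
           "perturbation_study_model", "silent_perturbation_study",
           "decay_study_models", "PURPOSES"]

PURPOSES = ("oracle", "limit", "perturbation", "identifiability")


@dataclass(frozen=True)
class BatterySpec:
    name: str
    spec: ModelSpec
    purpose: str

    def __post_init__(self):
        if self.purpose not in PURPOSES:
            raise ValueError(f"unknown purpose {self.purpose!r}")


def battery() -> list[BatterySpec]:
    """The eight named study specs (every family label appears)."""
    specs = [
        BatterySpec(
            "ad-1", armitage_doll_model(1, 1e7, [1e-9]), "limit"),
        BatterySpec(
            "ad-3", armitage_doll_model(3, 1e7, [1e-9, 6.7e-3, 6.7e-3]),
            "limit"),
        BatterySpec(
            "tsce", two_mutation_model(1e7, 1e-7, 1e-6, 0.1, 0.09),
            "oracle"),
        BatterySpec(
            "tsce-ident", two_mutation_model(1e7, 1e-9, 1e-2, 0.1, 0.05),
            "identifiability"),
        BatterySpec(
            "gmvk-3", generalized_mvk_model(
                3, 1e7, [1e-7, 1e-5, 1e-3], [0.06, 0.06], [0.05, 0.05]),
            "perturbation"),
        BatterySpec(
            "gi-1", gi_model(
                k=2, r=1, m=(1,), X=1e7,
                M={(0, 0, 0): 5e-8, (1, 0, 0): 1e-6,
                   (0, 1, 1): 5e-6, (1, 1, 1): 1e-3},
                A={((0, 0, 0), 1): 5e-8, ((1, 0, 0), 1): 5e-8},
                G={(1, 0, 0): 0.05, (0, 1, 1): 0.02, (1, 1, 1): 0.05},
                D={(1, 0, 0): 0.04, (0, 1, 1): 0.01, (1, 1, 1): 0.04}),
            "oracle"),
        BatterySpec(
            "gi-2", gi_model(
                k=2, r=2, m=(1, 2), X=1e7,
                M={(0, 0, 0): 3e-8, (1, 0, 0): 1e-6,
                   (0, 1, 1): 2e-6, (1, 1, 1): 1e-3,
                   (0, 1, 2): 1e-6, (1, 1, 2): 1e-4,
                   (0, 2, 2): 1e-5, (1, 2, 2): 1e-3},
                A={((0, 0, 0), 1): 2e-8, ((0, 0, 0), 2): 2e-8,
                   ((1, 0, 0), 1): 2e-8, ((1, 0, 0), 2): 2e-8,
                   ((0, 1, 2), 2): 1e-2, ((1, 1, 2), 2): 1e-2},
                G={(1, 0, 0): 0.05, (0, 1, 1): 0.02, (1, 1, 1): 0.04,
                   (0, 1, 2): 0.03, (1, 1, 2): 0.03,
                   (0, 2, 2): 0.03, (1, 2, 2): 0.03},
                D={(1, 0, 0): 0.04, (0, 1, 1): 0.01, (1, 1, 1): 0.03,
                   (0, 1, 2): 0.02, (1, 1, 2): 0.02,
                   (0, 2, 2): 0.02, (1, 2, 2): 0.02}),
            "identifiability"),
        BatterySpec(
            "twopop", two_mutation_model(
                1e7, 1e-7, 1e-5, 0.05, 0.06,
                initial_fractions={(0, 0, 0): 1.0 - 1e-5,
                                   (1, 0, 0): 1e-5}),
            "oracle"),
    ]
    return specs


def battery_by_name(name: str) -> BatterySpec:
    for b in battery():
        if b.name == name:
            return b
    raise KeyError(name)


def perturbation_study_model(k: int) -> ModelSpec:
    """Constant-rate generalized MVK model for the instantaneous-response
    study: which parameters can step at a given age without a step in h.

    For k = 2 every parameter acts within one stage of malignancy and any
    step propagates to the hazard at once; from k = 3 on, the early
    parameters (X, M(0), G(1), D(1)) act only through slowly accumulating
    intermediate populations.
    """
    if k < 2:
        raise ValueError("the study needs k >= 2")
    M = [1e-7] + [1e-5] * (k - 2) + [1e-6]
    return generalized_mvk_model(k, 1e7, M, [0.1] * (k - 1),
                                 [0.05] * (k - 1))


def silent_perturbation_study(ks=(2, 3), t0: float = 40.0,
                              factor: float = 10.0, eps: float = 1e-3,
                              threshold: float = 1e-6):
    """Step every parameter of k-stage study models and measure the jump.

    Returns ``(jumps, smallest_k)``: per stage count, the relative hazard
    jump at ``t0`` for each parameter handle, and the smallest k (among
    ``ks``, ascending) for which some parameter's jump falls below
    ``threshold`` — i.e. can be perturbed without an instantaneous change
    in the cancer hazard.
    """
    from .hazard import perturbation_jump
    from .model import parameter_handles

    jumps: dict[int, dict[str, float]] = {}
    smallest = None
    for k in sorted(ks):
        spec = perturbation_study_model(k)
        jumps[k] = {
            handle: perturbation_jump(spec, handle, t0, factor,
                                      eps=eps).relative
            for handle in parameter_handles(spec)}
        if smallest is None and any(v < threshold
                                    for v in jumps[k].values()):
            smallest = k
    return jumps, smallest


def decay_study_models() -> dict[str, ModelSpec]:
    """Two-mutation and three-stage models for the excess-risk-decay study.

    Intermediate cells have net inactivation (G = 0.05, D = 0.17 per year,
    net -0.12/year) so clones initiated during a transient exposure window
    are cleared on a ~decade time scale; with two intermediate stages the
    clearance acts as a cascade (the excess decays like t * exp(-0.12 t)),
    so this rate puts even the three-stage model's asymptotic regime
    within a human lifetime.
    """
    return {
        "two-mutation": two_mutation_model(1e7, 1e-7, 1e-6, 0.05, 0.17),
        "k3": generalized_mvk_model(3, 1e7, [1e-7, 1e-5, 1e-4],
                                    [0.05, 0.05], [0.17, 0.17]),
    }
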