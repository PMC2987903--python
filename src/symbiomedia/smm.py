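"""Search for Minimal Media (SMM).

A minimal medium is a set of environmental metabolites that sustains the
required growth rate(s) and loses that property when any single member is
removed.  The search is a MILP over binary utilization indicators: uptake
through exchange reaction ``i`` is allowed (``v_EX_i >= -L * theta_i``) only
when ``theta_i = 1``, secretion is never gated, and ``sum theta_i`` is
minimized subject to the growth floor(s) — both members' biomass reactions
for a joint model, the single biomass otherwise.

Optionally, candidates whose formula spans several essential elements
(amino-acid-like nutrients) can be discouraged through a soft objective
penalty, and a configurable allowlist of freely available co-factors
(minerals, water) is excluded from the indicator count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .core_model import Medium, MetabolicModel, supports_growth
from .joint_builder import JointModel
from .milp_common import (
    Gate,
    IndicatorAssignment,
    IndicatorProblem,
    MilpConfig,
    enumerate_alternates,
    solve_gated_milp,
)

__all__ = [
    "MinimalMediumResult",
    "find_minimal_medium",
    "enumerate_minimal_media",
    "verify_minimal",
    "growth_floors",
]


@dataclass
class MinimalMediumResult:
    status: str  # optimal | infeasible | error
    medium: Medium | None = None
    cardinality: int | None = None
    assignment: IndicatorAssignment | None = None
    alternates: list[Medium] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


def _unwrap(model_or_joint: MetabolicModel | JointModel) -> MetabolicModel:
    return model_or_joint.model if isinstance(model_or_joint, JointModel) else model_or_joint


def growth_floors(
    model_or_joint: MetabolicModel | JointModel, config: MilpConfig
) -> dict[str, float]:
    """Growth-rate floors: both members for a joint model, one otherwise."""
    if isinstance(model_or_joint, JointModel):
        return {rid: config.v_min for rid in model_or_joint.biomass_ids}
    if model_or_joint.biomass_reaction_id is None:
        raise ValueError(f"model {model_or_joint.id} lacks a biomass reaction")
    return {model_or_joint.biomass_reaction_id: config.v_min}


def _candidate_rates(
    candidates: Iterable[str] | Mapping[str, float] | Medium,
    config: MilpConfig,
) -> dict[str, float]:
    if isinstance(candidates, Medium):
        return dict(candidates.availability)
    if isinstance(candidates, Mapping):
        return dict(candidates)
    return {mid: config.default_availability for mid in candidates}


def _build_problem(
    model_or_joint: MetabolicModel | JointModel,
    candidates: Iterable[str] | Mapping[str, float] | Medium,
    config: MilpConfig,
    base_medium: Medium | None = None,
):
    """Assemble the indicator problem shared by search and enumeration."""
    model = _unwrap(model_or_joint)
    rates = _candidate_rates(candidates, config)
    floors = growth_floors(model_or_joint, config)

    gated: list[str] = []
    weights: dict[str, float] = {}
    extra_bounds: dict[str, tuple[float, float]] = {}
    medium_av: dict[str, float] = dict(base_medium.availability) if base_medium else {}
    gates: list[Gate] = []
    for mid in sorted(rates):
        ex = model.exchange_for(mid)
        if ex is None:
            raise ValueError(f"candidate {mid!r} has no exchange reaction")
        if mid in config.free_metabolites:
            # free co-factors: available, never counted
            medium_av[mid] = rates[mid]
            continue
        gated.append(mid)
        medium_av[mid] = rates[mid]
        gates.append(Gate(candidate=mid, reactions=(ex,), mode="lower"))
        weight = 1.0
        if config.multi_element_penalty and model.has_metabolite(mid):
            n_el = model.metabolite(mid).n_elements()
            if n_el > 1:
                weight += config.multi_element_penalty * (n_el - 1)
        weights[mid] = weight

    medium = Medium(medium_av) if medium_av else None

    def solve(excluded: frozenset[str]):
        return solve_gated_milp(
            model,
            gates,
            config,
            medium=medium,
            floors=floors,
            extra_bounds=extra_bounds,
            weights=weights,
            excluded=excluded,
        )

    return IndicatorProblem(solve), rates, floors, model


def _assignment_to_medium(
    assignment: IndicatorAssignment,
    rates: Mapping[str, float],
    base_medium: Medium | None,
) -> Medium:
    av = dict(base_medium.availability) if base_medium else {}
    for mid in assignment.members:
        av[mid] = rates[mid]
    return Medium(av)


def find_minimal_medium(
    model_or_joint: MetabolicModel | JointModel,
    candidates: Iterable[str] | Mapping[str, float] | Medium,
    config: MilpConfig | None = None,
    base_medium: Medium | None = None,
) -> MinimalMediumResult:
    """Minimal utilized-metabolite medium over ``candidates``.

    ``candidates`` maps metabolite ids to availabilities (an iterable uses
    the config default rate).  ``base_medium`` metabolites are supplied
    ungated and for free — used by the media search when part of the medium
    is held fixed.  An empty or unsatisfiable candidate set yields an
    explicit infeasible result, never an exception.
    """
    config = config or MilpConfig()
    rates = _candidate_rates(candidates, config)
    if not rates and base_medium is None:
        return MinimalMediumResult(status="infeasible")
    problem, rates, _, _ = _build_problem(
        model_or_joint, rates, config, base_medium
    )
    res = problem.solve(frozenset())
    if not res.ok:
        return MinimalMediumResult(status=res.status)
    medium = _assignment_to_medium(res.assignment, rates, base_medium)
    return MinimalMediumResult(
        status="optimal",
        medium=medium,
        cardinality=res.assignment.cardinality,
        assignment=res.assignment,
    )


def enumerate_minimal_media(
    model_or_joint: MetabolicModel | JointModel,
    candidates: Iterable[str] | Mapping[str, float] | Medium,
    config: MilpConfig | None = None,
    base_medium: Medium | None = None,
) -> MinimalMediumResult:
    """All (near-)minimal media reachable by enumeration-by-exclusion."""
    config = config or MilpConfig()
    rates = _candidate_rates(candidates, config)
    if not rates and base_medium is None:
        return MinimalMediumResult(status="infeasible")
    problem, rates, _, _ = _build_problem(model_or_joint, rates, config, base_medium)
    assignments, status = enumerate_alternates(problem, config)
    if status != "optimal":
        return MinimalMediumResult(status=status)
    media = [_assignment_to_medium(a, rates, base_medium) for a in assignments]
    return MinimalMediumResult(
        status="optimal",
        medium=media[0],
        cardinality=assignments[0].cardinality,
        assignment=assignments[0],
        alternates=media,
    )


def verify_minimal(
    model_or_joint: MetabolicModel | JointModel,
    medium: Medium,
    config: MilpConfig | None = None,
) -> bool:
    """True iff every single-metabolite removal breaks the growth floor(s).

    The medium itself must support growth (precondition); free co-factors on
    the config allowlist are not subjected to the removal test.
    """
    config = config or MilpConfig()
    model = _unwrap(model_or_joint)
    floors = growth_floors(model_or_joint, config)
    if not supports_growth(model, medium, floors):
        raise ValueError("medium does not support the growth floors")
    for mid in sorted(medium.metabolite_ids):
        if mid in config.free_metabolites:
            continue
        if supports_growth(model, medium.without(mid), floors):
            return False
    return True
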