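"""Search for Exchanged Metabolites (SEM).

Given a joint two-species model and a growth medium, SEM finds a minimal set
of metabolites cross-fed between the members such that both can grow.  A
binary ``theta_i`` per candidate metabolite (transportable by both species
and not supplied by the medium) gates *both* species' shuttle reactions with
symmetric big-M bounds ``|v_S| <= L * theta_i``; the environmental exchange
reactions of non-medium metabolites are closed to uptake, so any uptake of a
candidate must come from the partner.  Minimizing ``sum theta_i`` yields the
fewest exchanged metabolites; a small L1 penalty on the selected shuttle
fluxes is then applied with the indicators frozen to strip zero-benefit
bidirectional loops before directions are read off the shuttle signs
(provider negative, recipient positive).

For large models the exact MILP can be heavy; a two-step heuristic first
minimizes the sum of absolute shuttle fluxes of all non-medium metabolites
by plain LP (flux splitting), then runs the exact search restricted to the
metabolites active in that solution.  The result is still minimal in the
removal sense but may not have a globally minimal count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .core_model import Medium, _medium_bounds
from .joint_builder import JointModel
from .milp_common import (
    Gate,
    IndicatorProblem,
    MilpConfig,
    enumerate_alternates,
    solve_gated_milp,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ExchangeSet",
    "exchange_candidates",
    "find_min_exchange_set",
    "enumerate_exchange_sets",
    "heuristic_exchange_set",
]

_SIGN_TOL = 1e-7


@dataclass
class ExchangeSet:
    """A solved cross-feeding pattern: metabolite -> direction."""

    members: dict[str, str] = field(default_factory=dict)  # "1->2"|"2->1"|"bidirectional"
    status: str = "optimal"

    @property
    def ok(self) -> bool:
        return self.status == "optimal"

    @property
    def cardinality(self) -> int:
        return len(self.members)

    @property
    def metabolite_ids(self) -> frozenset[str]:
        return frozenset(self.members)


def exchange_candidates(
    joint: JointModel, medium: Medium, subset: frozenset[str] | None = None
) -> list[str]:
    """Gateable metabolites: transportable by both species, not in the medium."""
    cands = joint.exchangeable_both - medium.metabolite_ids
    if subset is not None:
        cands &= subset
    return sorted(cands)


def _gates_for(joint: JointModel, candidates: list[str]) -> list[Gate]:
    return [
        Gate(
            candidate=mid,
            reactions=(
                joint.shuttle_registry[(1, mid)],
                joint.shuttle_registry[(2, mid)],
            ),
            mode="abs",
        )
        for mid in candidates
    ]


def _floors(joint: JointModel, config: MilpConfig) -> dict[str, float]:
    return {rid: config.v_min for rid in joint.biomass_ids}


def _assign_directions(
    joint: JointModel,
    medium: Medium,
    members: frozenset[str],
    candidates: list[str],
    config: MilpConfig,
) -> dict[str, str]:
    """Freeze the indicator pattern and read exchange directions.

    With non-selected candidate shuttles closed, an LP minimizes the total
    absolute shuttle flux through the selected metabolites (standard
    splitting into non-negative parts) subject to both growth floors; the
    sign pattern of the optimum assigns provider and recipient.
    """
    model = joint.model
    n = len(model.reactions)
    lb, ub = _medium_bounds(model, medium)
    for rid, vmin in _floors(joint, config).items():
        j = model.reaction_index(rid)
        lb[j] = max(lb[j], vmin)
    for mid in candidates:
        if mid not in members:
            for k in (1, 2):
                j = model.reaction_index(joint.shuttle_registry[(k, mid)])
                lb[j] = max(lb[j], 0.0)
                ub[j] = min(ub[j], 0.0)

    tracked = [
        model.reaction_index(joint.shuttle_registry[(k, mid)])
        for mid in sorted(members)
        for k in (1, 2)
    ]
    t = len(tracked)
    S = model.stoichiometric_matrix()
    A_eq = sparse.hstack([S, sparse.csr_matrix((S.shape[0], t))], format="csr")
    # t_r >= v_j and t_r >= -v_j  <=>  t_r - v_j >= 0 and t_r + v_j >= 0
    data, ri, ci = [], [], []
    for r, j in enumerate(tracked):
        ri.extend([2 * r, 2 * r, 2 * r + 1, 2 * r + 1])
        ci.extend([n + r, j, n + r, j])
        data.extend([1.0, -1.0, 1.0, 1.0])
    A_ub = sparse.csr_matrix((data, (ri, ci)), shape=(2 * t, n + t))
    c = np.concatenate([np.zeros(n), np.ones(t)])
    res = linprog(
        c,
        A_eq=A_eq,
        b_eq=np.zeros(S.shape[0]),
        A_ub=-A_ub,
        b_ub=np.zeros(2 * t),
        bounds=np.column_stack(
            [np.concatenate([lb, np.zeros(t)]), np.concatenate([ub, np.full(t, np.inf)])]
        ),
        method="highs",
    )
    if res.status != 0:
        logger.warning("direction LP failed (%s); directions undetermined", res.status)
        return {mid: "bidirectional" for mid in members}
    directions: dict[str, str] = {}
    for mid in sorted(members):
        s1 = res.x[model.reaction_index(joint.shuttle_registry[(1, mid)])]
        s2 = res.x[model.reaction_index(joint.shuttle_registry[(2, mid)])]
        if s1 < -_SIGN_TOL and s2 > _SIGN_TOL:
            directions[mid] = "1->2"
        elif s2 < -_SIGN_TOL and s1 > _SIGN_TOL:
            directions[mid] = "2->1"
        else:
            directions[mid] = "bidirectional"
    return directions


def _problem(
    joint: JointModel,
    medium: Medium,
    config: MilpConfig,
    subset: frozenset[str] | None = None,
):
    all_candidates = exchange_candidates(joint, medium)
    candidates = exchange_candidates(joint, medium, subset)
    gates = _gates_for(joint, candidates)
    floors = _floors(joint, config)
    # candidates outside the restriction are closed outright: a restricted
    # search must not hand out free cross-feeding channels
    clamp = {
        joint.shuttle_registry[(k, mid)]: (0.0, 0.0)
        for mid in all_candidates
        if mid not in candidates
        for k in (1, 2)
    }

    def solve(excluded: frozenset[str]):
        return solve_gated_milp(
            joint.model,
            gates,
            config,
            medium=medium,
            floors=floors,
            extra_bounds=clamp,
            excluded=excluded,
        )

    return IndicatorProblem(solve), candidates


def find_min_exchange_set(
    joint: JointModel,
    medium: Medium,
    config: MilpConfig | None = None,
    subset: frozenset[str] | None = None,
) -> ExchangeSet:
    """Smallest cross-fed metabolite set sustaining both growth floors.

    Returns an :class:`ExchangeSet` whose ``status`` is ``"infeasible"`` when
    the pair cannot grow on the medium even with unlimited exchange.
    """
    config = config or MilpConfig()
    problem, _ = _problem(joint, medium, config, subset)
    res = problem.solve(frozenset())
    if not res.ok:
        return ExchangeSet(status=res.status)
    members = res.assignment.members
    all_candidates = exchange_candidates(joint, medium)
    directions = (
        _assign_directions(joint, medium, members, all_candidates, config)
        if members
        else {}
    )
    return ExchangeSet(members=directions)


def enumerate_exchange_sets(
    joint: JointModel,
    medium: Medium,
    config: MilpConfig | None = None,
    subset: frozenset[str] | None = None,
) -> list[ExchangeSet]:
    """Alternate minimal (or near-minimal, per slack) exchange sets."""
    config = config or MilpConfig()
    problem, _ = _problem(joint, medium, config, subset)
    assignments, status = enumerate_alternates(problem, config)
    if status != "optimal":
        return [ExchangeSet(status=status)]
    all_candidates = exchange_candidates(joint, medium)
    out = []
    for assignment in assignments:
        directions = (
            _assign_directions(
                joint, medium, assignment.members, all_candidates, config
            )
            if assignment.members
            else {}
        )
        out.append(ExchangeSet(members=directions))
    return out


def is_removal_minimal(
    joint: JointModel,
    medium: Medium,
    members: frozenset[str],
    config: MilpConfig | None = None,
) -> bool:
    """Check that dropping any member (with no substitute) kills dual growth."""
    config = config or MilpConfig()
    candidates = exchange_candidates(joint, medium)
    for out in sorted(members):
        allowed = members - {out}
        res = solve_gated_milp(
            joint.model,
            _gates_for(joint, candidates),
            config,
            medium=medium,
            floors=_floors(joint, config),
            excluded=frozenset(candidates) - allowed,
        )
        if res.ok:
            return False
    return True


def heuristic_exchange_set(
    joint: JointModel,
    medium: Medium,
    config: MilpConfig | None = None,
) -> ExchangeSet:
    """Two-step scalable alternative to the exact search.

    Step 1 minimizes, by LP, the summed absolute shuttle fluxes over all
    metabolites absent from the medium; step 2 reruns the exact search
    restricted to the metabolites left active.  The result is removal-minimal
    but its cardinality may exceed the global optimum.
    """
    config = config or MilpConfig()
    model = joint.model
    n = len(model.reactions)
    lb, ub = _medium_bounds(model, medium)
    for rid, vmin in _floors(joint, config).items():
        j = model.reaction_index(rid)
        lb[j] = max(lb[j], vmin)

    non_medium = sorted(joint.env_metabolites - medium.metabolite_ids)
    tracked = [
        (mid, model.reaction_index(joint.shuttle_registry[(k, mid)]))
        for mid in non_medium
        for k in (1, 2)
        if (k, mid) in joint.shuttle_registry
    ]
    t = len(tracked)
    S = model.stoichiometric_matrix()
    A_eq = sparse.hstack([S, sparse.csr_matrix((S.shape[0], t))], format="csr")
    data, ri, ci = [], [], []
    for r, (_, j) in enumerate(tracked):
        ri.extend([2 * r, 2 * r, 2 * r + 1, 2 * r + 1])
        ci.extend([n + r, j, n + r, j])
        data.extend([1.0, -1.0, 1.0, 1.0])
    A_ub = sparse.csr_matrix((data, (ri, ci)), shape=(2 * t, n + t))
    c = np.concatenate([np.zeros(n), np.ones(t)])
    res = linprog(
        c,
        A_eq=A_eq,
        b_eq=np.zeros(S.shape[0]),
        A_ub=-A_ub,
        b_ub=np.zeros(2 * t),
        bounds=np.column_stack(
            [np.concatenate([lb, np.zeros(t)]), np.concatenate([ub, np.full(t, np.inf)])]
        ),
        method="highs",
    )
    if res.status != 0:
        return ExchangeSet(status="infeasible" if res.status == 2 else "error")
    active = frozenset(
        mid for (mid, j) in tracked if abs(res.x[j]) > max(config.lp_tol, _SIGN_TOL)
    )
    return find_min_exchange_set(joint, medium, config, subset=active)
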