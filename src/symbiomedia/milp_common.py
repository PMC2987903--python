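"""Shared mixed-integer machinery for media and exchange searches.

Both the minimal-medium search and the exchanged-metabolite search are
cardinality minimizations over binary indicators: indicator ``theta_i = 1``
opens a gated flux channel (an environmental uptake, or a pair of shuttle
reactions) and the objective minimizes ``sum theta_i`` subject to the usual
steady-state constraints plus growth-rate floors.  Gating uses big-M rows of
the form ``|v| <= L * theta`` (or one-sided ``v >= -L * theta``), with ``L``
validated against the largest finite bound in the model so an undersized
constant can never silently corrupt the relaxation.

Alternate optima are enumerated by exclusion: after each solution, each of
its member indicators is forced to zero in turn and the problem re-solved,
depth first, keeping solutions within a configurable cardinality slack of
the optimum.  As with any such scheme, the enumeration is not guaranteed to
be exhaustive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .core_model import MetabolicModel, Medium, _medium_bounds

logger = logging.getLogger(__name__)

__all__ = [
    "MilpConfig",
    "IndicatorAssignment",
    "IndicatorSolveResult",
    "Gate",
    "solve_gated_milp",
    "enumerate_alternates",
    "validate_big_m",
]


@dataclass
class MilpConfig:
    """Tunables shared by every MILP search.

    ``v_min`` is the growth-rate floor imposed on each species inside a MILP
    (the boolean growth threshold ``eps`` used for interaction classification
    is deliberately smaller and separate).  ``big_M`` is the gating constant
    ``L``; it must dominate every finite flux bound.
    """

    v_min: float = 0.1
    big_M: float = 1000.0
    eps: float = 1e-6
    integrality_tol: float = 1e-6
    lp_tol: float = 1e-9
    max_solutions: int = 50
    slack: float = 0.0
    time_limit: float | None = None
    default_availability: float = 10.0
    free_metabolites: frozenset[str] = frozenset()
    multi_element_penalty: float = 0.0

    def __post_init__(self) -> None:
        if not self.v_min > 0:
            raise ValueError("v_min must be positive")
        if not self.eps > 0:
            raise ValueError("eps must be positive")


def validate_big_m(model: MetabolicModel, config: MilpConfig) -> None:
    """Reject a gating constant smaller than some finite model bound."""
    lb, ub = model.bounds_arrays()
    finite = np.concatenate([lb[np.isfinite(lb)], ub[np.isfinite(ub)]])
    worst = float(np.abs(finite).max()) if finite.size else 0.0
    if config.big_M < worst:
        raise ValueError(
            f"big_M={config.big_M} is smaller than the largest finite bound "
            f"{worst} in model {model.id}; gating would be corrupted"
        )


@dataclass(frozen=True)
class IndicatorAssignment:
    """A solved binary pattern over candidate metabolites."""

    theta: Mapping[str, int]

    @property
    def members(self) -> frozenset[str]:
        return frozenset(m for m, v in self.theta.items() if v == 1)

    @property
    def cardinality(self) -> int:
        return len(self.members)


@dataclass
class IndicatorSolveResult:
    status: str  # optimal | infeasible | error
    assignment: IndicatorAssignment | None = None
    objective: float | None = None
    fluxes: dict[str, float] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


@dataclass(frozen=True)
class Gate:
    """One indicator and the reactions it gates.

    ``mode='abs'`` adds ``-L*theta <= v <= L*theta`` for each reaction;
    ``mode='lower'`` adds only ``v >= -L*theta`` (secretion never gated).
    """

    candidate: str
    reactions: tuple[str, ...]
    mode: Literal["abs", "lower"] = "abs"


_MILP_STATUS = {0: "optimal", 1: "error", 2: "infeasible", 3: "error", 4: "error"}


def solve_gated_milp(
    model: MetabolicModel,
    gates: Sequence[Gate],
    config: MilpConfig,
    medium: Medium | None = None,
    floors: Mapping[str, float] | None = None,
    extra_bounds: Mapping[str, tuple[float, float]] | None = None,
    weights: Mapping[str, float] | None = None,
    excluded: frozenset[str] = frozenset(),
    forced: frozenset[str] = frozenset(),
) -> IndicatorSolveResult:
    """Minimize the (weighted) indicator count over a gated flux polytope.

    Variables are the ``n`` reaction fluxes followed by one binary per gate.
    ``excluded`` pins indicators to 0 (enumeration-by-exclusion), ``forced``
    pins them to 1 (minimality re-checks).
    """
    validate_big_m(model, config)
    n = len(model.reactions)
    k = len(gates)
    candidates = [g.candidate for g in gates]
    if len(set(candidates)) != k:
        raise ValueError("duplicate gate candidates")

    lb, ub = _medium_bounds(model, medium)
    if floors:
        for rid, vmin in floors.items():
            j = model.reaction_index(rid)
            lb[j] = max(lb[j], vmin)
    if extra_bounds:
        for rid, (lo, hi) in extra_bounds.items():
            j = model.reaction_index(rid)
            lb[j] = max(lb[j], lo)
            ub[j] = min(ub[j], hi)

    theta_lb = np.zeros(k)
    theta_ub = np.ones(k)
    for i, cand in enumerate(candidates):
        if cand in excluded:
            theta_ub[i] = 0.0
        if cand in forced:
            theta_lb[i] = 1.0
    if np.any(lb > ub) or np.any(theta_lb > theta_ub):
        return IndicatorSolveResult(status="infeasible")

    S = model.stoichiometric_matrix()
    constraints = [
        LinearConstraint(
            sparse.hstack([S, sparse.csr_matrix((S.shape[0], k))], format="csr"),
            0.0,
            0.0,
        )
    ]

    # gating rows: v - L*theta <= 0 and/or v + L*theta >= 0
    rows_up: list[tuple[int, int]] = []  # (reaction index, gate index), v <= L*theta
    rows_lo: list[tuple[int, int]] = []  # v >= -L*theta
    for i, gate in enumerate(gates):
        for rid in gate.reactions:
            j = model.reaction_index(rid)
            rows_lo.append((j, i))
            if gate.mode == "abs":
                rows_up.append((j, i))
    L = config.big_M

    def _gate_matrix(pairs: list[tuple[int, int]], sign: float) -> sparse.csr_matrix:
        data, ri, ci = [], [], []
        for r, (j, i) in enumerate(pairs):
            ri.extend([r, r])
            ci.extend([j, n + i])
            data.extend([1.0, sign * L])
        return sparse.csr_matrix((data, (ri, ci)), shape=(len(pairs), n + k))

    if rows_up:
        constraints.append(
            LinearConstraint(_gate_matrix(rows_up, -1.0), -np.inf, 0.0)
        )
    if rows_lo:
        constraints.append(LinearConstraint(_gate_matrix(rows_lo, 1.0), 0.0, np.inf))

    c = np.zeros(n + k)
    for i, cand in enumerate(candidates):
        c[n + i] = weights.get(cand, 1.0) if weights else 1.0
    integrality = np.concatenate([np.zeros(n), np.ones(k)])
    options: dict = {}
    if config.time_limit is not None:
        options["time_limit"] = config.time_limit

    res = milp(
        c,
        constraints=constraints,
        integrality=integrality,
        bounds=Bounds(np.concatenate([lb, theta_lb]), np.concatenate([ub, theta_ub])),
        options=options,
    )
    status = _MILP_STATUS.get(res.status, "error")
    if status != "optimal":
        if status == "error":
            logger.warning("MILP failure on %s: %s", model.id, res.message)
        return IndicatorSolveResult(status=status)
    theta = {
        cand: int(round(res.x[n + i])) for i, cand in enumerate(candidates)
    }
    for i, cand in enumerate(candidates):
        if abs(res.x[n + i] - theta[cand]) > config.integrality_tol:
            logger.warning("indicator %s fractional: %.3g", cand, res.x[n + i])
    fluxes = dict(zip(model.reaction_ids, res.x[:n]))
    return IndicatorSolveResult(
        status="optimal",
        assignment=IndicatorAssignment(theta),
        objective=float(res.fun),
        fluxes=fluxes,
    )


class IndicatorProblem:
    """A re-solvable indicator MILP bound to fixed data except exclusions."""

    def __init__(self, solve_fn):
        self._solve_fn = solve_fn

    def solve(self, excluded: frozenset[str]) -> IndicatorSolveResult:
        return self._solve_fn(excluded)


def enumerate_alternates(
    problem: IndicatorProblem,
    config: MilpConfig,
) -> tuple[list[IndicatorAssignment], str]:
    """Enumerate alternate (near-)minimal indicator assignments.

    Depth-first exclusion: from each found solution, each member metabolite
    is forbidden one at a time (lexicographic order) and the MILP re-solved;
    solutions whose cardinality stays within ``optimum + slack`` are kept,
    deduplicated, up to ``max_solutions``.  An infeasible base problem yields
    an empty list with status ``"infeasible"``.
    """
    base = problem.solve(frozenset())
    if not base.ok:
        return [], base.status
    best = base.assignment.cardinality
    found = [base.assignment]
    seen = {base.assignment.members}
    if not base.assignment.members:
        return found, "optimal"  # empty optimum: nothing to exclude
    stack: list[tuple[frozenset[str], frozenset[str]]] = [
        (base.assignment.members, frozenset())
    ]
    while stack and len(found) < config.max_solutions:
        members, excluded = stack.pop()
        for met in sorted(members):
            res = problem.solve(excluded | {met})
            if not res.ok:
                continue
            if res.assignment.cardinality > best + config.slack:
                continue
            if res.assignment.members in seen:
                continue
            seen.add(res.assignment.members)
            found.append(res.assignment)
            stack.append((res.assignment.members, excluded | {met}))
            if len(found) >= config.max_solutions:
                break
    return found, "optimal"
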