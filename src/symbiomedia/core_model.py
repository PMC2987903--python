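"""Single-species stoichiometric models and flux balance analysis.

A metabolic network is encoded as a stoichiometric matrix ``S`` (metabolites
by reactions); a steady-state flux vector ``v`` satisfies ``S v = 0`` with
per-reaction bounds ``LB <= v <= UB``.  Flux balance analysis (FBA) maximizes
a linear objective ``c . v`` — typically biomass production — over that
polytope.  Fluxes carry units of mM per gram dry weight per hour.

Sign conventions
----------------
Exchange reactions are written ``metabolite -> (nothing)``: positive flux is
secretion out of the system, uptake is negative flux.  A :class:`Medium` is a
pure bounds overlay: a metabolite available at rate ``a`` sets the lower
bound of its exchange reaction to ``-a``; absent metabolites keep lower
bound 0, so secretion stays possible but uptake does not.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

logger = logging.getLogger(__name__)

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "Medium",
    "FluxSolution",
    "ModelError",
    "parse_formula",
    "formula_to_string",
    "apply_medium",
    "solve_fba",
    "grows",
    "supports_growth",
    "REACTION_KINDS",
]

REACTION_KINDS = ("internal", "transport", "shuttle", "exchange", "biomass")

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class ModelError(ValueError):
    """Raised when a model violates a structural invariant."""


def parse_formula(text: str) -> dict[str, int]:
    """Parse an elemental formula string such as ``C6H12O6`` into counts.

    Repeated element symbols accumulate (``CH3CH3`` -> ``{C: 2, H: 6}``).
    """
    if not text or text == "-":
        return {}
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(text):
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {text!r} at position {pos}")
        pos = match.end()
        symbol, digits = match.groups()
        counts[symbol] = counts.get(symbol, 0) + (int(digits) if digits else 1)
    if pos != len(text):
        raise ValueError(f"cannot parse formula {text!r} at position {pos}")
    return counts


def formula_to_string(formula: Mapping[str, int] | None) -> str:
    if not formula:
        return "-"
    return "".join(
        f"{el}{n if n != 1 else ''}" for el, n in sorted(formula.items()) if n > 0
    )


@dataclass
class Metabolite:
    """A chemical species located in one compartment of a model."""

    id: str
    compartment: str
    name: str = ""
    formula: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if self.formula is not None:
            bad = {el: n for el, n in self.formula.items() if n < 0}
            if bad:
                raise ModelError(f"negative element counts in {self.id}: {bad}")

    def has_element(self, symbol: str) -> bool:
        return bool(self.formula) and self.formula.get(symbol, 0) > 0

    def n_elements(self) -> int:
        """Number of distinct non-hydrogen elements in the formula."""
        if not self.formula:
            return 0
        return sum(1 for el, n in self.formula.items() if n > 0 and el != "H")


@dataclass
class Reaction:
    """A stoichiometric column: metabolite-id -> signed coefficient.

    ``kind`` distinguishes internal biochemistry, membrane transport, the
    joint-model shuttle layer, environmental exchange sinks, and the biomass
    reaction.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -1000.0
    upper_bound: float = 1000.0
    kind: str = "internal"
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in REACTION_KINDS:
            raise ModelError(f"reaction {self.id}: unknown kind {self.kind!r}")
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if self.kind == "exchange":
            if len(self.stoichiometry) != 1:
                raise ModelError(
                    f"exchange reaction {self.id} must touch exactly one metabolite"
                )
        elif not self.stoichiometry:
            raise ModelError(f"reaction {self.id} has empty stoichiometry")

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))


@dataclass
class Medium:
    """Environmentally available metabolites with maximal uptake rates."""

    availability: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {m: r for m, r in self.availability.items() if not r > 0}
        if bad:
            raise ModelError(f"medium rates must be positive: {bad}")

    def __contains__(self, metabolite_id: str) -> bool:
        return metabolite_id in self.availability

    def __len__(self) -> int:
        return len(self.availability)

    def __iter__(self) -> Iterator[str]:
        return iter(self.availability)

    @property
    def metabolite_ids(self) -> frozenset[str]:
        return frozenset(self.availability)

    def items(self):
        return self.availability.items()

    def without(self, metabolite_id: str) -> "Medium":
        av = {m: r for m, r in self.availability.items() if m != metabolite_id}
        return Medium(av)

    def adding(self, metabolite_id: str, rate: float) -> "Medium":
        av = dict(self.availability)
        av[metabolite_id] = rate
        return Medium(av)

    def union(self, other: "Medium") -> "Medium":
        av = dict(self.availability)
        av.update(other.availability)
        return Medium(av)

    def copy(self) -> "Medium":
        return Medium(dict(self.availability))


@dataclass
class FluxSolution:
    """Outcome of one LP solve: status, flux vector, objective value."""

    status: str  # optimal | infeasible | unbounded | error
    fluxes: dict[str, float] = field(default_factory=dict)
    objective_value: float | None = None

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


class MetabolicModel:
    """A stoichiometric model: metabolites, reactions, bounds, objective."""

    def __init__(
        self,
        id: str,
        metabolites: Iterable[Metabolite],
        reactions: Iterable[Reaction],
        biomass_reaction_id: str | None = None,
        objective: Mapping[str, float] | None = None,
    ) -> None:
        self.id = id
        self.metabolites = list(metabolites)
        self.reactions = list(reactions)
        self.biomass_reaction_id = biomass_reaction_id
        self.objective = dict(objective) if objective else None
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}
        self._matrix: sparse.csr_matrix | None = None
        self._exchange_for: dict[str, str] | None = None
        self.validate()

    # -- structure ---------------------------------------------------------

    def validate(self) -> None:
        if len(self._met_index) != len(self.metabolites):
            raise ModelError(f"model {self.id}: duplicate metabolite ids")
        if len(self._rxn_index) != len(self.reactions):
            raise ModelError(f"model {self.id}: duplicate reaction ids")
        for rxn in self.reactions:
            for mid in rxn.stoichiometry:
                if mid not in self._met_index:
                    raise ModelError(
                        f"model {self.id}: reaction {rxn.id} references "
                        f"undeclared metabolite {mid}"
                    )
        if (
            self.biomass_reaction_id is not None
            and self.biomass_reaction_id not in self._rxn_index
        ):
            raise ModelError(
                f"model {self.id}: biomass reaction "
                f"{self.biomass_reaction_id} not found"
            )

    @property
    def compartments(self) -> set[str]:
        return {m.compartment for m in self.metabolites}

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, metabolite_id: str) -> Metabolite:
        return self.metabolites[self._met_index[metabolite_id]]

    def reaction(self, reaction_id: str) -> Reaction:
        return self.reactions[self._rxn_index[reaction_id]]

    def reaction_index(self, reaction_id: str) -> int:
        return self._rxn_index[reaction_id]

    def has_metabolite(self, metabolite_id: str) -> bool:
        return metabolite_id in self._met_index

    def exchange_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.kind == "exchange"]

    def exchange_for(self, metabolite_id: str) -> str | None:
        """Id of the exchange reaction draining ``metabolite_id``, if any."""
        if self._exchange_for is None:
            self._exchange_for = {
                next(iter(r.stoichiometry)): r.id for r in self.exchange_reactions()
            }
        return self._exchange_for.get(metabolite_id)

    def stoichiometric_matrix(self) -> sparse.csr_matrix:
        if self._matrix is None:
            rows, cols, vals = [], [], []
            for j, rxn in enumerate(self.reactions):
                for mid, coeff in rxn.stoichiometry.items():
                    rows.append(self._met_index[mid])
                    cols.append(j)
                    vals.append(float(coeff))
            self._matrix = sparse.csr_matrix(
                (vals, (rows, cols)),
                shape=(len(self.metabolites), len(self.reactions)),
            )
        return self._matrix

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions], dtype=float)
        ub = np.array([r.upper_bound for r in self.reactions], dtype=float)
        return lb, ub

    def copy(self, id: str | None = None) -> "MetabolicModel":
        return MetabolicModel(
            id=id or self.id,
            metabolites=[replace(m, formula=dict(m.formula) if m.formula else None)
                         for m in self.metabolites],
            reactions=[r.copy() for r in self.reactions],
            biomass_reaction_id=self.biomass_reaction_id,
            objective=self.objective,
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<MetabolicModel {self.id}: {len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions>"
        )


# -- medium handling -------------------------------------------------------


def _medium_bounds(
    model: MetabolicModel, medium: Medium | None
) -> tuple[np.ndarray, np.ndarray]:
    """Bounds arrays with the medium overlaid on exchange lower bounds.

    Every exchange reaction's lower bound becomes ``-availability`` for
    metabolites in the medium and 0 otherwise; upper bounds (secretion) are
    untouched.
    """
    lb, ub = model.bounds_arrays()
    if medium is None:
        return lb, ub
    for mid in medium:
        if model.exchange_for(mid) is None:
            raise ModelError(f"unknown medium metabolite {mid}")
    for rxn in model.exchange_reactions():
        j = model.reaction_index(rxn.id)
        mid = next(iter(rxn.stoichiometry))
        lb[j] = -medium.availability[mid] if mid in medium else 0.0
    return lb, ub


def apply_medium(model: MetabolicModel, medium: Medium) -> MetabolicModel:
    """Return a copy of ``model`` with the medium written into its bounds."""
    lb, ub = _medium_bounds(model, medium)
    new = model.copy()
    for j, rxn in enumerate(new.reactions):
        rxn.lower_bound = lb[j]
        rxn.upper_bound = ub[j]
    return new


# -- LP solving ------------------------------------------------------------

_LP_STATUS = {0: "optimal", 1: "error", 2: "infeasible", 3: "unbounded", 4: "error"}


def _objective_vector(
    model: MetabolicModel, objective: Mapping[str, float] | None
) -> np.ndarray:
    if objective is None:
        objective = model.objective
    if objective is None:
        if model.biomass_reaction_id is None:
            raise ModelError(f"model {model.id}: no objective and no biomass reaction")
        objective = {model.biomass_reaction_id: 1.0}
    c = np.zeros(len(model.reactions))
    for rid, weight in objective.items():
        c[model.reaction_index(rid)] = weight
    return c


def solve_fba(
    model: MetabolicModel,
    medium: Medium | None = None,
    objective: Mapping[str, float] | None = None,
    floors: Mapping[str, float] | None = None,
    extra_bounds: Mapping[str, tuple[float, float]] | None = None,
) -> FluxSolution:
    """Maximize ``objective . v`` subject to ``S v = 0`` and bounds.

    ``floors`` raises lower bounds of named reactions (growth-rate floors);
    ``extra_bounds`` clamps named reactions to an intersection with the given
    interval.  Solver failures are reported through ``status``, never as
    silent zeros.
    """
    lb, ub = _medium_bounds(model, medium)
    if floors:
        for rid, vmin in floors.items():
            lb[model.reaction_index(rid)] = max(lb[model.reaction_index(rid)], vmin)
    if extra_bounds:
        for rid, (lo, hi) in extra_bounds.items():
            j = model.reaction_index(rid)
            lb[j] = max(lb[j], lo)
            ub[j] = min(ub[j], hi)
    if np.any(lb > ub):
        return FluxSolution(status="infeasible")
    c = _objective_vector(model, objective)
    S = model.stoichiometric_matrix()
    res = linprog(
        -c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=np.column_stack([lb, ub]),
        method="highs",
    )
    status = _LP_STATUS.get(res.status, "error")
    if status != "optimal":
        if status == "error":
            logger.warning("LP solver failure on %s: %s", model.id, res.message)
        return FluxSolution(status=status)
    fluxes = dict(zip(model.reaction_ids, res.x))
    return FluxSolution(status="optimal", fluxes=fluxes, objective_value=-res.fun)


def grows(
    model: MetabolicModel,
    medium: Medium | None = None,
    eps: float = 1e-6,
    objective: Mapping[str, float] | None = None,
) -> bool:
    """True iff maximal biomass flux reaches the growth threshold ``eps``.

    An infeasible LP counts as no growth (and is logged).
    """
    if not eps > 0:
        raise ValueError("growth threshold eps must be positive")
    sol = solve_fba(model, medium=medium, objective=objective)
    if not sol.ok:
        logger.info("grows(%s): LP status %s treated as no growth", model.id, sol.status)
        return False
    return sol.objective_value >= eps


def supports_growth(
    model: MetabolicModel,
    medium: Medium | None,
    floors: Mapping[str, float],
    extra_bounds: Mapping[str, tuple[float, float]] | None = None,
) -> bool:
    """Feasibility check: can all growth floors be met simultaneously?"""
    sol = solve_fba(
        model,
        medium=medium,
        objective={rid: 1.0 for rid in floors},
        floors=floors,
        extra_bounds=extra_bounds,
    )
    return sol.ok


def check_steady_state(
    model: MetabolicModel, solution: FluxSolution, tol: float = 1e-6
) -> float:
    """Maximal absolute mass-balance residual ``|S v|`` of a solution."""
    if not solution.ok:
        raise ValueError("steady-state check requires an optimal solution")
    v = np.array([solution.fluxes[rid] for rid in model.reaction_ids])
    residual = np.abs(model.stoichiometric_matrix() @ v)
    worst = float(residual.max()) if residual.size else 0.0
    if worst > tol:
        logger.warning("steady-state residual %.3g exceeds %.3g", worst, tol)
    return worst
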