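"""Built-in model pairs: the didactic toy pair and a seeded random generator.

The toy pair consists of two organisms that transport three metabolites X, Y
and Z, run one internal conversion each (``X -> Y`` in organism 1,
``X -> Z`` in organism 2) and build biomass from one unit of each of X, Y
and Z.  Organism 1 therefore grows alone on {X, Z}, organism 2 on {X, Y},
and a co-culture sharing an environment needs only X — each partner secretes
the precursor the other cannot make.

The random generator emulates such pairs at slightly larger scale with a
*planted* dependency structure: two species assimilate a configurable number
of carbon and nitrogen sources into two biomass precursors, and a dependency
plan deletes one species' assimilation route for one element while wiring a
one-way carrier metabolite from the partner.  The planted interaction class,
exchanged metabolites and viable element sources are certified by direct LP
at generation time and returned as ground truth for tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .core_model import Medium, MetabolicModel, Metabolite, Reaction
from .joint_builder import JointModel, MetaboliteMap, build_joint
from .milp_common import MilpConfig

__all__ = [
    "make_toy_pair",
    "make_toy_joint",
    "make_random_pair",
    "PlantedTruth",
    "DEPENDENCY_PLANS",
    "GenerationError",
]

DEPENDENCY_PLANS = ("neutral", "commensal_1to2", "commensal_2to1", "mutual")

DependencyPlan = Literal["neutral", "commensal_1to2", "commensal_2to1", "mutual"]


class GenerationError(RuntimeError):
    """Raised when a generated pair repeatedly fails its certification."""


# ---------------------------------------------------------------------------
# toy pair
# ---------------------------------------------------------------------------


def _toy_organism(index: int) -> MetabolicModel:
    internal_product = "Y_c" if index == 1 else "Z_c"
    mets = [
        Metabolite("X_c", "CYT", "X", {"C": 1, "H": 2, "O": 1}),
        Metabolite("Y_c", "CYT", "Y", {"N": 1, "H": 3}),
        Metabolite("Z_c", "CYT", "Z", {"S": 1, "H": 2}),
        Metabolite("X_e", "EX", "X", {"C": 1, "H": 2, "O": 1}),
        Metabolite("Y_e", "EX", "Y", {"N": 1, "H": 3}),
        Metabolite("Z_e", "EX", "Z", {"S": 1, "H": 2}),
    ]
    rxns = [
        Reaction("TX", {"X_e": -1.0, "X_c": 1.0}, -1000, 1000, "transport"),
        Reaction("TY", {"Y_e": -1.0, "Y_c": 1.0}, -1000, 1000, "transport"),
        Reaction("TZ", {"Z_e": -1.0, "Z_c": 1.0}, -1000, 1000, "transport"),
        Reaction("R1", {"X_c": -1.0, internal_product: 1.0}, 0, 1000, "internal"),
        Reaction(
            "BIO",
            {"X_c": -1.0, "Y_c": -1.0, "Z_c": -1.0},
            0,
            1000,
            "biomass",
        ),
        Reaction("EX_X", {"X_e": -1.0}, -1000, 1000, "exchange"),
        Reaction("EX_Y", {"Y_e": -1.0}, -1000, 1000, "exchange"),
        Reaction("EX_Z", {"Z_e": -1.0}, -1000, 1000, "exchange"),
    ]
    return MetabolicModel(
        id=f"toy{index}",
        metabolites=mets,
        reactions=rxns,
        biomass_reaction_id="BIO",
    )


def make_toy_pair() -> tuple[MetabolicModel, MetabolicModel, MetaboliteMap]:
    """The two toy organisms and the map identifying X, Y, Z across them."""
    m1 = _toy_organism(1)
    m2 = _toy_organism(2)
    met_map = MetaboliteMap(
        [("X_e", "X_e", "X"), ("Y_e", "Y_e", "Y"), ("Z_e", "Z_e", "Z")]
    )
    return m1, m2, met_map


def make_toy_joint() -> JointModel:
    m1, m2, met_map = make_toy_pair()
    return build_joint(m1, m2, met_map)


# ---------------------------------------------------------------------------
# random pair generator
# ---------------------------------------------------------------------------


@dataclass
class PlantedTruth:
    """Certified ground truth shipped with a generated pair."""

    plan: str
    seed: int
    designed_medium: Medium
    expected_class: str
    expected_exchange: dict[str, str]  # env metabolite -> "1->2" | "2->1"
    viable_carbon_sources: list[str]
    viable_nitrogen_sources: list[str]
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "plan": self.plan,
            "seed": self.seed,
            "designed_medium": dict(self.designed_medium.availability),
            "expected_class": self.expected_class,
            "expected_exchange": dict(self.expected_exchange),
            "viable_carbon_sources": list(self.viable_carbon_sources),
            "viable_nitrogen_sources": list(self.viable_nitrogen_sources),
            "params": dict(self.params),
        }


def _source_formula(element: str, j: int) -> dict[str, int]:
    return {element: j + 1, "H": 2 * (j + 1)}


def _species_model(
    index: int,
    n_sources: int,
    chain_len: int,
    assimilates_c: bool,
    assimilates_n: bool,
    carrier_roles: dict[str, str],  # carrier name -> "provider" | "recipient"
    carrier_element: dict[str, str],
) -> MetabolicModel:
    """One species of a generated pair.

    All species transport every environmental metabolite (so the candidate
    exchange sets of the two members coincide); the dependency plan only
    removes assimilation chemistry.
    """
    mets: list[Metabolite] = [
        Metabolite("precA_c", "CYT", "carbon precursor", {"C": 1, "H": 2}),
        Metabolite("precB_c", "CYT", "nitrogen precursor", {"N": 1, "H": 3}),
    ]
    rxns: list[Reaction] = [
        Reaction(
            "BIO", {"precA_c": -1.0, "precB_c": -1.0}, 0, 1000, "biomass"
        )
    ]

    def add_env_met(name: str, formula: dict[str, int], ex_lb: float, ex_ub: float):
        mets.append(Metabolite(f"{name}_e", "EX", name, dict(formula)))
        rxns.append(
            Reaction(f"EX_{name}", {f"{name}_e": -1.0}, ex_lb, ex_ub, "exchange")
        )

    # element sources
    for element, prefix, assimilates, prec in (
        ("C", "cs", assimilates_c, "precA_c"),
        ("N", "ns", assimilates_n, "precB_c"),
    ):
        for j in range(1, n_sources + 1):
            name = f"{prefix}{j}"
            formula = _source_formula(element, j)
            add_env_met(name, formula, -1000, 1000)
            mets.append(Metabolite(f"{name}_c", "CYT", name, dict(formula)))
            rxns.append(
                Reaction(
                    f"T_{name}",
                    {f"{name}_e": -1.0, f"{name}_c": 1.0},
                    -1000,
                    1000,
                    "transport",
                )
            )
            if assimilates:
                if j == 1 and chain_len > 0:
                    # a linear assimilation pathway for the first source
                    prev = f"{name}_c"
                    for step in range(1, chain_len + 1):
                        inter = f"{prefix}1_i{step}_c"
                        mets.append(
                            Metabolite(inter, "CYT", inter, {element: 1, "H": 1})
                        )
                        rxns.append(
                            Reaction(
                                f"A_{name}_{step}",
                                {prev: -1.0, inter: 1.0},
                                0,
                                1000,
                                "internal",
                            )
                        )
                        prev = inter
                    rxns.append(
                        Reaction(
                            f"A_{name}_final", {prev: -1.0, prec: 1.0}, 0, 1000, "internal"
                        )
                    )
                else:
                    rxns.append(
                        Reaction(
                            f"A_{name}", {f"{name}_c": -1.0, prec: 1.0}, 0, 1000, "internal"
                        )
                    )

    # decoy metabolites: transportable, never assimilated
    for name, formula in (("dc1", {"C": 2, "H": 2}), ("dn1", {"N": 2, "H": 2})):
        add_env_met(name, formula, -1000, 1000)
        mets.append(Metabolite(f"{name}_c", "CYT", name, dict(formula)))
        rxns.append(
            Reaction(
                f"T_{name}",
                {f"{name}_e": -1.0, f"{name}_c": 1.0},
                -1000,
                1000,
                "transport",
            )
        )

    # carrier metabolites: one-way conduits for a biomass precursor
    for carrier, role in carrier_roles.items():
        element = carrier_element[carrier]
        prec = "precA_c" if element == "C" else "precB_c"
        formula = {element: 2, "H": 3}
        mets.append(Metabolite(f"{carrier}_c", "CYT", carrier, dict(formula)))
        if role == "provider":
            # synthesis + export only; exchange is secretion-only so the
            # provider cannot take its own carrier back from the environment
            add_env_met(carrier, formula, 0, 1000)
            rxns.append(
                Reaction(
                    f"S_{carrier}", {prec: -1.0, f"{carrier}_c": 1.0}, 0, 1000, "internal"
                )
            )
            rxns.append(
                Reaction(
                    f"T_{carrier}",
                    {f"{carrier}_c": -1.0, f"{carrier}_e": 1.0},
                    0,
                    1000,
                    "transport",
                )
            )
        else:  # recipient: import + conversion only
            add_env_met(carrier, formula, -1000, 0)
            rxns.append(
                Reaction(
                    f"T_{carrier}",
                    {f"{carrier}_e": -1.0, f"{carrier}_c": 1.0},
                    0,
                    1000,
                    "transport",
                )
            )
            rxns.append(
                Reaction(
                    f"U_{carrier}", {f"{carrier}_c": -1.0, prec: 1.0}, 0, 1000, "internal"
                )
            )

    return MetabolicModel(
        id=f"synth{index}",
        metabolites=mets,
        reactions=rxns,
        biomass_reaction_id="BIO",
    )


def _plan_wiring(plan: str, alt_carriers: int):
    """Carrier roles per species and the expected exchange pattern."""
    roles1: dict[str, str] = {}
    roles2: dict[str, str] = {}
    element: dict[str, str] = {}
    exchange: dict[str, str] = {}
    c_carriers = ["xc"] + [f"xc{i}" for i in range(2, alt_carriers + 2)]
    if plan == "mutual":
        # species 1 lacks nitrogen assimilation, species 2 lacks carbon
        for name in c_carriers:
            roles1[name] = "provider"
            roles2[name] = "recipient"
            element[name] = "C"
        exchange[c_carriers[0]] = "1->2"
        roles1["xn"] = "recipient"
        roles2["xn"] = "provider"
        element["xn"] = "N"
        exchange["xn"] = "2->1"
        assim = {"c": (True, False), "n": (False, True)}  # (species1, species2)
    elif plan == "commensal_1to2":
        roles1["xn"] = "provider"
        roles2["xn"] = "recipient"
        element["xn"] = "N"
        exchange["xn"] = "1->2"
        assim = {"c": (True, True), "n": (True, False)}
    elif plan == "commensal_2to1":
        roles1["xn"] = "recipient"
        roles2["xn"] = "provider"
        element["xn"] = "N"
        exchange["xn"] = "2->1"
        assim = {"c": (True, True), "n": (False, True)}
    elif plan == "neutral":
        assim = {"c": (True, True), "n": (True, True)}
    else:
        raise ValueError(f"unknown dependency plan {plan!r}")
    return roles1, roles2, element, exchange, assim


_PLAN_CLASS = {
    "neutral": "neutralism",
    "commensal_1to2": "commensal_1_provider",
    "commensal_2to1": "commensal_2_provider",
    "mutual": "mutualism",
}


def make_random_pair(
    n_core_mets: int = 2,
    n_sources_per_element: int = 3,
    dependency_plan: DependencyPlan = "mutual",
    seed: int = 0,
    alt_carriers: int = 0,
    availability: float = 10.0,
    max_retries: int = 5,
) -> tuple[MetabolicModel, MetabolicModel, MetaboliteMap, PlantedTruth]:
    """Generate a certified two-species pair with a planted dependency.

    ``n_core_mets`` bounds the length of the linear assimilation pathway for
    each species' first carbon/nitrogen source; ``n_sources_per_element``
    sets how many alternative carbon and nitrogen sources exist (all usable
    by both species, directly or through the planted carrier);
    ``alt_carriers`` adds interchangeable copies of the carbon carrier so the
    minimal exchanged-metabolite set is degenerate.  The returned
    :class:`PlantedTruth` is certified by LP before return; certification
    failure triggers a bounded retry with a derived seed.
    """
    from .sim_search import classify_interaction  # local import: no cycle at load

    if dependency_plan not in DEPENDENCY_PLANS:
        raise ValueError(f"unknown dependency plan {dependency_plan!r}")
    last_error: str | None = None
    for attempt in range(max_retries):
        attempt_seed = (seed + attempt * 1_000_003) % (2**31)
        rng = np.random.default_rng(attempt_seed)
        roles1, roles2, element, exchange, assim = _plan_wiring(
            dependency_plan, alt_carriers
        )
        chain1 = int(rng.integers(0, n_core_mets + 1))
        chain2 = int(rng.integers(0, n_core_mets + 1))
        m1 = _species_model(
            1, n_sources_per_element, chain1, assim["c"][0], assim["n"][0],
            roles1, element,
        )
        m2 = _species_model(
            2, n_sources_per_element, chain2, assim["c"][1], assim["n"][1],
            roles2, element,
        )
        # shared ENV namespace: strip the _e suffix for the environment ids
        ext1 = [next(iter(r.stoichiometry)) for r in m1.exchange_reactions()]
        ext2 = {next(iter(r.stoichiometry)) for r in m2.exchange_reactions()}
        pairs = []
        for mid in sorted(set(ext1) | ext2):
            env_id = mid[:-2] if mid.endswith("_e") else mid
            pairs.append(
                (mid if mid in ext1 else None, mid if mid in ext2 else None, env_id)
            )
        met_map = MetaboliteMap(pairs)

        c_pick = int(rng.integers(1, n_sources_per_element + 1))
        n_pick = int(rng.integers(1, n_sources_per_element + 1))
        designed = Medium({f"cs{c_pick}": availability, f"ns{n_pick}": availability})
        truth = PlantedTruth(
            plan=dependency_plan,
            seed=attempt_seed,
            designed_medium=designed,
            expected_class=_PLAN_CLASS[dependency_plan],
            expected_exchange=exchange,
            viable_carbon_sources=[f"cs{j}" for j in range(1, n_sources_per_element + 1)],
            viable_nitrogen_sources=[f"ns{j}" for j in range(1, n_sources_per_element + 1)],
            params={
                "n_core_mets": n_core_mets,
                "n_sources_per_element": n_sources_per_element,
                "alt_carriers": alt_carriers,
                "chain_lengths": [chain1, chain2],
                "availability": availability,
            },
        )
        joint = build_joint(m1, m2, met_map)
        record = classify_interaction(joint, designed, MilpConfig())
        if record.interaction_class == truth.expected_class:
            return m1, m2, met_map, truth
        last_error = (
            f"plan {dependency_plan} seed {attempt_seed}: classified as "
            f"{record.interaction_class}"
        )
    raise GenerationError(f"certification failed after {max_retries} attempts: {last_error}")
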