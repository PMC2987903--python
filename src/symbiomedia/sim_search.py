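"""Search for Interaction-Inducing Media (SIM).

Starting from a seed medium that supports growth of both members of a joint
model, the pipeline (i) finds, element by element (C, N, P, S by default),
all metabolites — or minimal metabolite sets — that can substitute the
medium's sources of that element, (ii) assembles candidate media as the
Cartesian product of replacement choices across elements, and (iii)
classifies the interaction each candidate medium induces by comparing
growth of each species inside the joint model with growth of each species
alone:

===============  ===============  =========================
joint growth     solo growth      interaction class
===============  ===============  =========================
both             both             neutralism
both             species 1 only   commensalism, 1 provides
both             species 2 only   commensalism, 2 provides
both             neither          mutualism
not both         (any)            no growth
===============  ===============  =========================

Element membership comes from metabolite formulas; metabolites without a
formula are excluded from stripping and pools with a logged warning.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

from .core_model import Medium, grows, supports_growth
from .joint_builder import JointModel
from .milp_common import MilpConfig
from .smm import find_minimal_medium

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_ELEMENTS",
    "INTERACTION_CLASSES",
    "InteractionRecord",
    "interaction_class_from_growth",
    "classify_interaction",
    "joint_dual_growth",
    "find_replacements",
    "assemble_media",
    "run_sim",
    "InfeasibleSeedError",
]

DEFAULT_ELEMENTS = ("C", "N", "P", "S")

INTERACTION_CLASSES = (
    "neutralism",
    "commensal_1_provider",
    "commensal_2_provider",
    "mutualism",
    "no_growth",
)


class InfeasibleSeedError(ValueError):
    """The seed medium does not support joint growth of both species."""


@dataclass
class InteractionRecord:
    medium: Medium
    grows_joint: tuple[bool, bool]
    grows_alone: tuple[bool, bool]
    interaction_class: str


def interaction_class_from_growth(
    grows_joint: tuple[bool, bool], grows_alone: tuple[bool, bool]
) -> str:
    """Pure truth table mapping the four growth booleans to a class."""
    if not (grows_joint[0] and grows_joint[1]):
        return "no_growth"
    alone1, alone2 = grows_alone
    if alone1 and alone2:
        return "neutralism"
    if alone1:
        return "commensal_1_provider"
    if alone2:
        return "commensal_2_provider"
    return "mutualism"


def classify_interaction(
    joint: JointModel,
    medium: Medium,
    config: MilpConfig | None = None,
) -> InteractionRecord:
    """Classify the interaction a medium induces.

    Growth of each species inside the joint model is tested with its own
    biomass as the objective (the partner's network is free to run without
    growing); growth alone uses each member model with the medium translated
    into its namespace, dropping metabolites it cannot transport.
    """
    config = config or MilpConfig()
    eps = config.eps
    gj = tuple(
        grows(joint.model, medium, eps=eps, objective={bid: 1.0})
        for bid in joint.biomass_ids
    )
    ga = tuple(
        grows(member, joint.medium_for_member(medium, k), eps=eps)
        for k, member in enumerate(joint.member_models, start=1)
    )
    return InteractionRecord(
        medium=medium,
        grows_joint=gj,
        grows_alone=ga,
        interaction_class=interaction_class_from_growth(gj, ga),
    )


def joint_dual_growth(
    joint: JointModel, medium: Medium, config: MilpConfig | None = None
) -> bool:
    """Can both members meet the growth floor simultaneously?"""
    config = config or MilpConfig()
    floors = {rid: config.v_min for rid in joint.biomass_ids}
    return supports_growth(joint.model, medium, floors)


def _element_metabolites(joint: JointModel, ids, element: str) -> set[str]:
    """ENV metabolites among ``ids`` containing ``element``; no-formula ids skipped."""
    out = set()
    skipped = []
    for mid in ids:
        met = joint.model.metabolite(mid)
        if met.formula is None:
            skipped.append(mid)
            continue
        if met.has_element(element):
            out.add(mid)
    if skipped:
        logger.warning(
            "%d metabolite(s) without formula excluded from %s tagging: %s",
            len(skipped), element, ", ".join(sorted(skipped)[:5]),
        )
    return out


def strip_element(joint: JointModel, medium: Medium, element: str) -> Medium:
    """The medium with every metabolite containing ``element`` removed."""
    tagged = _element_metabolites(joint, medium.metabolite_ids, element)
    return Medium(
        {m: r for m, r in medium.items() if m not in tagged}
    )


def default_pool(joint: JointModel, exclude: Medium) -> list[str]:
    """All formula-bearing ENV metabolites outside ``exclude``, sorted."""
    pool = []
    for mid in sorted(joint.env_metabolites - exclude.metabolite_ids):
        if joint.model.metabolite(mid).formula is None:
            logger.warning("pool metabolite %s has no formula; excluded", mid)
            continue
        pool.append(mid)
    return pool


def find_replacements(
    element: str,
    joint: JointModel,
    medium: Medium,
    pool: list[str] | None = None,
    config: MilpConfig | None = None,
) -> list[frozenset[str]]:
    """Metabolite sets able to replace the medium's sources of ``element``.

    The element's sources are stripped from the medium; single metabolites
    from the pool (lexicographic order) that restore joint growth are
    collected first, each being removed from the pool as it is found.  When
    no single metabolite suffices, a minimal multi-metabolite set is found
    by the minimal-medium MILP restricted to the pool, and the search
    bifurcates on the removal of each of its members.  Exhausted pools and
    branches without replacements terminate silently with what was found.
    """
    config = config or MilpConfig()
    stripped = strip_element(joint, medium, element)
    if pool is None:
        pool = default_pool(joint, stripped)
    else:
        pool = [m for m in sorted(pool) if m not in stripped.metabolite_ids]
    rate = config.default_availability

    found: list[frozenset[str]] = []
    seen: set[frozenset[str]] = set()

    def record(s: frozenset[str]) -> None:
        if s not in seen:
            seen.add(s)
            found.append(s)

    def search(pool: tuple[str, ...]) -> None:
        remaining = list(pool)
        while remaining and len(found) < config.max_solutions:
            hit = next(
                (
                    x
                    for x in remaining
                    if joint_dual_growth(joint, stripped.adding(x, rate), config)
                ),
                None,
            )
            if hit is not None:
                record(frozenset([hit]))
                remaining.remove(hit)
                continue
            # no single metabolite restores growth: minimal multi-set
            res = find_minimal_medium(
                joint,
                {m: rate for m in remaining},
                config,
                base_medium=stripped,
            )
            if not res.ok or res.medium is None:
                return
            multi = frozenset(res.medium.metabolite_ids - stripped.metabolite_ids)
            if not multi:
                return
            record(multi)
            for member in sorted(multi):
                if len(found) >= config.max_solutions:
                    break
                search(tuple(m for m in remaining if m != member))
            return
        return

    search(tuple(pool))
    return found


def assemble_media(
    replacements_per_element: dict[str, list[frozenset[str]]],
    base: Medium,
    joint: JointModel,
    config: MilpConfig | None = None,
) -> list[Medium]:
    """Cartesian assembly of candidate media across elements.

    Each candidate medium is the base stripped of every searched element's
    sources, plus one replacement set per element (union; metabolites shared
    across sets count once).  Duplicate metabolite sets are emitted once.
    An element with no replacement set yields no candidates.
    """
    config = config or MilpConfig()
    elements = sorted(replacements_per_element)
    if not elements:
        return [base.copy()]
    stripped_av = dict(base.availability)
    for element in elements:
        for mid in _element_metabolites(joint, list(stripped_av), element):
            stripped_av.pop(mid, None)

    def rate_for(mid: str) -> float:
        return base.availability.get(mid, config.default_availability)

    media: list[Medium] = []
    seen: set[frozenset[str]] = set()
    for combo in itertools.product(
        *(replacements_per_element[e] for e in elements)
    ):
        av = dict(stripped_av)
        for repl_set in combo:
            for mid in repl_set:
                av[mid] = rate_for(mid)
        key = frozenset(av)
        if key not in seen:
            seen.add(key)
            media.append(Medium(av))
    return media


def run_sim(
    joint: JointModel,
    initial_medium: Medium,
    elements: tuple[str, ...] = DEFAULT_ELEMENTS,
    config: MilpConfig | None = None,
    pool: list[str] | None = None,
) -> list[InteractionRecord]:
    """Full media search: per-element replacement, assembly, classification.

    Elements with no source in the seed medium have nothing to vary and
    contribute the seed composition unchanged.  The seed must support joint
    growth of both members; otherwise the caller is directed to the
    minimal-medium search.  Deterministic given the pool ordering, and
    insensitive to pool permutations (pools are sorted internally).
    """
    config = config or MilpConfig()
    if not elements:
        return [classify_interaction(joint, initial_medium, config)]
    if not joint_dual_growth(joint, initial_medium, config):
        raise InfeasibleSeedError(
            "initial medium does not support joint growth of both species; "
            "derive a seed with find_minimal_medium first"
        )
    replacements: dict[str, list[frozenset[str]]] = {}
    for element in elements:
        stripped = strip_element(joint, initial_medium, element)
        if stripped.metabolite_ids == initial_medium.metabolite_ids:
            # no source of this element in the medium: nothing to substitute
            replacements[element] = [frozenset()]
            continue
        replacements[element] = find_replacements(
            element, joint, initial_medium, pool, config
        )
    media = assemble_media(replacements, initial_medium, joint, config)
    return [classify_interaction(joint, medium, config) for medium in media]
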