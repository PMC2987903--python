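"""Independent brute-force oracles used to validate the MILP searches.

These deliberately avoid the package's MILP code paths: they enumerate
candidate subsets in ascending cardinality and test plain-LP feasibility of
each subset, so the minimal cardinality they report is exhaustive up to the
optimum.  Only usable on small instances.
"""

from __future__ import annotations

import itertools

from symbiomedia.core_model import Medium, supports_growth
from symbiomedia.joint_builder import JointModel
from symbiomedia.milp_common import MilpConfig
from symbiomedia.sem import exchange_candidates
from symbiomedia.sim_search import joint_dual_growth, strip_element
from symbiomedia.smm import growth_floors


def smm_bruteforce(model_or_joint, candidates: dict[str, float], config: MilpConfig):
    """(min cardinality, all minimum-size feasible subsets) for uptake sets."""
    model = model_or_joint.model if isinstance(model_or_joint, JointModel) else model_or_joint
    floors = growth_floors(model_or_joint, config)
    ids = sorted(candidates)
    for size in range(len(ids) + 1):
        feasible = [
            frozenset(subset)
            for subset in itertools.combinations(ids, size)
            if supports_growth(
                model, Medium({m: candidates[m] for m in subset}), floors
            )
        ]
        if feasible:
            return size, feasible
    return None, []


def sem_bruteforce(joint: JointModel, medium: Medium, config: MilpConfig):
    """(min cardinality, all minimum-size exchangeable subsets).

    A subset S is feasible when both growth floors can be met with the
    shuttle reactions of every candidate outside S clamped to zero (for both
    species) and no external uptake of non-medium metabolites.
    """
    candidates = exchange_candidates(joint, medium)
    floors = growth_floors(joint, config)

    def feasible(subset: frozenset[str]) -> bool:
        clamp = {
            joint.shuttle_registry[(k, mid)]: (0.0, 0.0)
            for mid in candidates
            if mid not in subset
            for k in (1, 2)
        }
        return supports_growth(joint.model, medium, floors, extra_bounds=clamp)

    for size in range(len(candidates) + 1):
        hits = [
            frozenset(subset)
            for subset in itertools.combinations(candidates, size)
            if feasible(frozenset(subset))
        ]
        if hits:
            return size, hits
    return None, []


def sim_bruteforce_media(
    joint: JointModel,
    base: Medium,
    elements: tuple[str, ...],
    config: MilpConfig,
) -> set[frozenset[str]]:
    """All media reachable by single-source substitution per element.

    Mirrors the replacement search under the assumption (true for the
    planted generator instances) that single metabolites suffice as
    substitutes; every combination is re-checked for joint dual growth.
    """
    rate = config.default_availability
    stripped_all = base
    per_element: dict[str, list[str]] = {}
    for element in elements:
        stripped = strip_element(joint, base, element)
        pool = [
            m
            for m in sorted(joint.env_metabolites - stripped.metabolite_ids)
            if joint.model.metabolite(m).formula is not None
        ]
        per_element[element] = [
            m for m in pool if joint_dual_growth(joint, stripped.adding(m, rate), config)
        ]
        stripped_all = strip_element(joint, stripped_all, element)
    media: set[frozenset[str]] = set()
    for combo in itertools.product(*(per_element[e] for e in elements)):
        av = dict(stripped_all.availability)
        for mid in combo:
            av[mid] = base.availability.get(mid, rate)
        if joint_dual_growth(joint, Medium(av), config):
            media.add(frozenset(av))
    return media
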