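"""Two-species ecosystem models with a shared environmental compartment.

Each member model keeps its cytosolic and extracellular compartments; a new
``ENV`` compartment is layered on top.  For every extracellular metabolite a
1:1 *shuttle* reaction connects ``ENV`` to that species' extracellular space
(replacing the member's former exchange reaction), and a single *exchange*
reaction per ENV metabolite connects the shared environment to the outside
world.  Shuttle fluxes therefore read out each species' net uptake or
secretion of a metabolite regardless of how many transporters move it across
the membrane, which is what the exchanged-metabolite search gates on.

Sign conventions: a shuttle is written ``met[ENV] <=> met[EXk]``, so positive
flux is flow *into* species ``k``; an exchange is ``met[ENV] -> (nothing)``,
so positive flux is secretion out of the whole system and uptake from the
outside is negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .core_model import (
    FluxSolution,
    Medium,
    MetabolicModel,
    Metabolite,
    ModelError,
    Reaction,
)

__all__ = [
    "MetaboliteMap",
    "JointModel",
    "derive_metabolite_map",
    "build_joint",
    "net_secretion_profile",
    "MEMBER_PREFIXES",
]

MEMBER_PREFIXES = ("S1:", "S2:")
ENV_COMPARTMENT = "ENV"


@dataclass
class MetaboliteMap:
    """Correspondence between the two species' extracellular metabolites.

    Each entry is ``(ext-id in species 1, ext-id in species 2, shared ENV
    id)``; ``None`` in a species column means that species cannot reach the
    metabolite (it still receives a private ENV entry so the other species
    can dump or take it from the environment).
    """

    pairs: list[tuple[str | None, str | None, str]]

    def __post_init__(self) -> None:
        for col in range(3):
            seen: set[str] = set()
            for pair in self.pairs:
                val = pair[col]
                if val is None:
                    continue
                if val in seen:
                    raise ModelError(
                        f"metabolite map column {col} not injective: {val!r} repeated"
                    )
                seen.add(val)


@dataclass
class JointModel:
    """A merged two-species model plus its wiring registries."""

    model: MetabolicModel
    member_models: tuple[MetabolicModel, MetabolicModel]
    env_metabolites: frozenset[str]
    exchange_registry: dict[str, str]  # env met id -> exchange reaction id
    shuttle_registry: dict[tuple[int, str], str]  # (species 1|2, env id) -> rxn id
    biomass_ids: tuple[str, str]
    met_map: dict[str, tuple[str | None, str | None]] = field(default_factory=dict)

    @property
    def exchangeable(self) -> tuple[frozenset[str], frozenset[str]]:
        """Per-species transportable ENV metabolite sets TM(1), TM(2)."""
        tm1 = frozenset(m for (k, m) in self.shuttle_registry if k == 1)
        tm2 = frozenset(m for (k, m) in self.shuttle_registry if k == 2)
        return tm1, tm2

    @property
    def exchangeable_both(self) -> frozenset[str]:
        tm1, tm2 = self.exchangeable
        return tm1 & tm2

    def medium_for_member(self, medium: Medium, species: int) -> Medium:
        """Translate an ENV medium into one species' extracellular namespace.

        Metabolites the species cannot transport are dropped: they are
        invisible to it whether or not they sit in the environment.
        """
        col = species - 1
        availability: dict[str, float] = {}
        for env_id, rate in medium.items():
            ext = self.met_map.get(env_id, (None, None))[col]
            if ext is not None:
                availability[ext] = rate
        return Medium(availability)

    def copy_with_model(self, model: MetabolicModel) -> "JointModel":
        return replace(self, model=model)


def _extracellular_metabolites(model: MetabolicModel) -> list[str]:
    """Metabolites drained by exchange reactions, in declaration order."""
    return [next(iter(r.stoichiometry)) for r in model.exchange_reactions()]


def derive_metabolite_map(
    model1: MetabolicModel,
    model2: MetabolicModel,
    overrides: list[tuple[str | None, str | None, str]] | None = None,
) -> MetaboliteMap:
    """Pair extracellular metabolites by exact id match.

    ``overrides`` entries (same shape as :class:`MetaboliteMap` pairs) replace
    or extend the automatic matches and record manual curation reproducibly.
    """
    ext1 = _extracellular_metabolites(model1)
    ext2 = set(_extracellular_metabolites(model2))
    taken = {o[2] for o in overrides or []}

    def env_name(mid: str) -> str:
        # conventional "_e" suffix of extracellular ids is dropped in ENV
        base = mid[:-2] if mid.endswith("_e") else mid
        if base in taken:
            base = mid
        taken.add(base)
        return base

    pairs: list[tuple[str | None, str | None, str]] = []
    overridden1 = {o[0] for o in overrides or [] if o[0] is not None}
    overridden2 = {o[1] for o in overrides or [] if o[1] is not None}
    for mid in ext1:
        if mid in overridden1:
            continue
        pairs.append((mid, mid if mid in ext2 else None, env_name(mid)))
    mapped2 = {p[1] for p in pairs} | overridden2
    for mid in _extracellular_metabolites(model2):
        if mid not in mapped2:
            pairs.append((None, mid, env_name(mid)))
            mapped2.add(mid)
    pairs.extend(overrides or [])
    return MetaboliteMap(pairs)


def build_joint(
    model1: MetabolicModel,
    model2: MetabolicModel,
    met_map: MetaboliteMap | None = None,
    exchange_secretion_cap: float = 1000.0,
) -> JointModel:
    """Embed two models under a shared ENV compartment.

    Internal blocks are copied verbatim (namespaced ``S1:``/``S2:``); each
    member's former exchange reactions are relabeled as shuttle reactions
    against a new ENV metabolite, preserving their directionality; one fresh
    exchange reaction per ENV metabolite controls environmental availability.
    New exchange reactions start closed to uptake (lower bound 0) until a
    medium is applied.
    """
    if met_map is None:
        met_map = derive_metabolite_map(model1, model2)
    members = (model1, model2)

    for ext1, ext2, env_id in met_map.pairs:
        if ext1 is not None and model1.exchange_for(ext1) is None:
            raise ModelError(f"map entry {ext1!r} has no exchange reaction in model 1")
        if ext2 is not None and model2.exchange_for(ext2) is None:
            raise ModelError(f"map entry {ext2!r} has no exchange reaction in model 2")

    metabolites: list[Metabolite] = []
    reactions: list[Reaction] = []
    env_ids: list[str] = []
    exchange_registry: dict[str, str] = {}
    shuttle_registry: dict[tuple[int, str], str] = {}
    env_lookup: dict[str, tuple[str | None, str | None]] = {}

    # ENV layer
    for ext1, ext2, env_id in met_map.pairs:
        if env_id in env_lookup:
            raise ModelError(f"duplicate ENV metabolite id {env_id!r}")
        source = model1.metabolite(ext1) if ext1 else model2.metabolite(ext2)
        metabolites.append(
            Metabolite(
                id=env_id,
                compartment=ENV_COMPARTMENT,
                name=source.name,
                formula=dict(source.formula) if source.formula else None,
            )
        )
        env_ids.append(env_id)
        env_lookup[env_id] = (ext1, ext2)
        ex_id = f"EX_{env_id}"
        reactions.append(
            Reaction(
                id=ex_id,
                stoichiometry={env_id: -1.0},
                lower_bound=0.0,
                upper_bound=exchange_secretion_cap,
                kind="exchange",
                name=f"exchange of {env_id} with the outside",
            )
        )
        exchange_registry[env_id] = ex_id

    ext_to_env = [
        {ext1: env for ext1, _, env in met_map.pairs if ext1 is not None},
        {ext2: env for _, ext2, env in met_map.pairs if ext2 is not None},
    ]

    # member blocks
    for k, member in enumerate(members, start=1):
        prefix = MEMBER_PREFIXES[k - 1]
        for met in member.metabolites:
            metabolites.append(
                Metabolite(
                    id=prefix + met.id,
                    compartment=f"{met.compartment}{k}",
                    name=met.name,
                    formula=dict(met.formula) if met.formula else None,
                )
            )
        for rxn in member.reactions:
            if rxn.kind == "exchange":
                ext_id = next(iter(rxn.stoichiometry))
                env_id = ext_to_env[k - 1].get(ext_id)
                if env_id is None:
                    raise ModelError(
                        f"extracellular metabolite {ext_id!r} of species {k} "
                        f"missing from the metabolite map"
                    )
                # former exchange (positive = secretion) becomes a shuttle
                # (positive = uptake into the species): bounds flip sign.
                sh_id = f"{prefix}SH_{env_id}"
                reactions.append(
                    Reaction(
                        id=sh_id,
                        stoichiometry={env_id: -1.0, prefix + ext_id: 1.0},
                        lower_bound=-rxn.upper_bound,
                        upper_bound=-rxn.lower_bound,
                        kind="shuttle",
                        name=f"shuttle of {env_id} into species {k}",
                    )
                )
                shuttle_registry[(k, env_id)] = sh_id
            else:
                reactions.append(
                    Reaction(
                        id=prefix + rxn.id,
                        stoichiometry={
                            prefix + mid: coeff for mid, coeff in rxn.stoichiometry.items()
                        },
                        lower_bound=rxn.lower_bound,
                        upper_bound=rxn.upper_bound,
                        kind=rxn.kind,
                        name=rxn.name,
                    )
                )

    biomass_ids = []
    for k, member in enumerate(members, start=1):
        if member.biomass_reaction_id is None:
            raise ModelError(f"member model {member.id} lacks a biomass reaction")
        biomass_ids.append(MEMBER_PREFIXES[k - 1] + member.biomass_reaction_id)

    joint = MetabolicModel(
        id=f"{model1.id}+{model2.id}",
        metabolites=metabolites,
        reactions=reactions,
        biomass_reaction_id=biomass_ids[0],
    )
    return JointModel(
        model=joint,
        member_models=(model1, model2),
        env_metabolites=frozenset(env_ids),
        exchange_registry=exchange_registry,
        shuttle_registry=shuttle_registry,
        biomass_ids=(biomass_ids[0], biomass_ids[1]),
        met_map=env_lookup,
    )


def net_secretion_profile(
    joint: JointModel,
    solution: FluxSolution,
    drop_zero: bool = True,
    tol: float = 1e-9,
) -> dict[str, tuple[float, float]]:
    """Per-species shuttle flux for every ENV metabolite.

    Positive values are uptake into the species, negative values secretion
    into the shared environment.  With ``drop_zero`` metabolites untouched by
    both species are omitted.
    """
    if not solution.ok:
        raise ValueError("net secretion profile requires an optimal solution")
    profile: dict[str, tuple[float, float]] = {}
    for env_id in sorted(joint.env_metabolites):
        fluxes = []
        for k in (1, 2):
            rid = joint.shuttle_registry.get((k, env_id))
            fluxes.append(solution.fluxes.get(rid, 0.0) if rid else 0.0)
        if drop_zero and all(abs(f) <= tol for f in fluxes):
            continue
        profile[env_id] = (fluxes[0], fluxes[1])
    return profile
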