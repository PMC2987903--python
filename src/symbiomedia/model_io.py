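"""Readers and writers: tabular models, SBML L3+fbc, media, result tables.

The plain-text tabular model format is one reaction per line::

    # model <id>
    # biomass <reaction id>
    # metabolite <id> <compartment> <formula|->
    <rxn id>\t<kind>\t<lb>\t<ub>\t2 A[CYT] + B[CYT] -> C[CYT]

Metabolites are written as ``id[compartment]`` inside reaction strings and
declared (with elemental formulas) on ``# metabolite`` comment lines.
Exchange reactions are single-metabolite sinks written ``X[ENV] ->``.

SBML round-trips go through python-libsbml with the fbc package (flux
bounds, objectives, chemical formulas).  Media are TSV files with columns
``metabolite_id`` and ``max_uptake``.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path
from typing import Sequence

import pandas as pd

from .core_model import (
    Medium,
    MetabolicModel,
    Metabolite,
    ModelError,
    Reaction,
    formula_to_string,
    parse_formula,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_model",
    "write_model",
    "read_tabular_model",
    "write_tabular_model",
    "read_sbml_model",
    "write_sbml_model",
    "read_medium_tsv",
    "write_medium_tsv",
    "read_formula_table",
    "write_interactions_tsv",
    "write_usage_matrix",
    "write_transition_tsv",
    "write_provenance",
]

_MET_REF = re.compile(r"^(?:(\d+(?:\.\d+)?)\s+)?(\S+)\[([^\]]+)\]$")

DEFAULT_IRREVERSIBLE_BOUNDS = (0.0, 1000.0)
DEFAULT_REVERSIBLE_BOUNDS = (-1000.0, 1000.0)


# ---------------------------------------------------------------------------
# tabular model format
# ---------------------------------------------------------------------------


def _parse_side(text: str, sign: float, stoich: dict[str, float], line_no: int) -> None:
    text = text.strip()
    if not text:
        return
    for term in text.split(" + "):
        term = term.strip()
        match = _MET_REF.match(term)
        if not match:
            raise ModelError(f"line {line_no}: cannot parse metabolite term {term!r}")
        coeff, mid, _comp = match.groups()
        stoich[mid] = stoich.get(mid, 0.0) + sign * (float(coeff) if coeff else 1.0)


def read_tabular_model(path: str | Path) -> MetabolicModel:
    """Read a model from the one-reaction-per-line tabular format."""
    path = Path(path)
    model_id = path.stem
    biomass_id: str | None = None
    metabolites: dict[str, Metabolite] = {}
    compartment_of: dict[str, str] = {}
    reactions: list[Reaction] = []
    for line_no, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            fields = line[1:].split()
            if not fields:
                continue
            if fields[0] == "model" and len(fields) > 1:
                model_id = fields[1]
            elif fields[0] == "biomass" and len(fields) > 1:
                biomass_id = fields[1]
            elif fields[0] == "metabolite" and len(fields) >= 3:
                mid, comp = fields[1], fields[2]
                formula = parse_formula(fields[3]) if len(fields) > 3 else {}
                metabolites[mid] = Metabolite(
                    id=mid, compartment=comp, formula=formula or None
                )
            continue
        parts = raw.split("\t")
        if len(parts) != 5:
            raise ModelError(
                f"line {line_no}: expected 5 tab-separated fields, got {len(parts)}"
            )
        rid, kind, lb_s, ub_s, eqn = (p.strip() for p in parts)
        if "->" not in eqn:
            raise ModelError(f"line {line_no}: reaction {rid} lacks '->'")
        left, right = eqn.split("->", 1)
        stoich: dict[str, float] = {}
        _parse_side(left, -1.0, stoich, line_no)
        _parse_side(right, 1.0, stoich, line_no)
        # record compartments seen in the equation for undeclared metabolites
        for side in (left, right):
            for term in side.split(" + "):
                term = term.strip()
                match = _MET_REF.match(term) if term else None
                if match:
                    compartment_of.setdefault(match.group(2), match.group(3))
        reactions.append(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                lower_bound=float(lb_s),
                upper_bound=float(ub_s),
                kind=kind,
            )
        )
    for rxn in reactions:
        for mid in rxn.stoichiometry:
            if mid not in metabolites:
                if mid not in compartment_of:
                    raise ModelError(
                        f"reaction {rxn.id} references undeclared metabolite {mid}"
                    )
                metabolites[mid] = Metabolite(id=mid, compartment=compartment_of[mid])
    model = MetabolicModel(
        id=model_id,
        metabolites=list(metabolites.values()),
        reactions=reactions,
        biomass_reaction_id=biomass_id,
    )
    missing = sum(1 for m in model.metabolites if not m.formula)
    if missing:
        logger.info("%s: %d metabolite(s) without formula", model_id, missing)
    return model


def _format_side(terms: list[tuple[float, str, str]]) -> str:
    parts = []
    for coeff, mid, comp in terms:
        prefix = "" if coeff == 1 else f"{coeff:g} "
        parts.append(f"{prefix}{mid}[{comp}]")
    return " + ".join(parts)


def write_tabular_model(model: MetabolicModel, path: str | Path) -> None:
    path = Path(path)
    lines = [f"# model {model.id}"]
    if model.biomass_reaction_id:
        lines.append(f"# biomass {model.biomass_reaction_id}")
    for met in model.metabolites:
        lines.append(
            f"# metabolite {met.id} {met.compartment} {formula_to_string(met.formula)}"
        )
    for rxn in model.reactions:
        left = [
            (-c, mid, model.metabolite(mid).compartment)
            for mid, c in sorted(rxn.stoichiometry.items())
            if c < 0
        ]
        right = [
            (c, mid, model.metabolite(mid).compartment)
            for mid, c in sorted(rxn.stoichiometry.items())
            if c > 0
        ]
        eqn = f"{_format_side(left)} -> {_format_side(right)}".strip()
        lines.append(
            f"{rxn.id}\t{rxn.kind}\t{rxn.lower_bound:g}\t{rxn.upper_bound:g}\t{eqn}"
        )
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# SBML L3 + fbc
# ---------------------------------------------------------------------------


def _sbml_safe(sid: str) -> str:
    return re.sub(r"[^A-Za-z0-9_]", "__", sid)


def write_sbml_model(model: MetabolicModel, path: str | Path) -> None:
    """Write the model as SBML Level 3 Version 1 with the fbc package."""
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(_sbml_safe(model.id))
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(True)

    for comp in sorted(model.compartments):
        compartment = sbml_model.createCompartment()
        compartment.setId(_sbml_safe(comp))
        compartment.setConstant(True)

    id_map: dict[str, str] = {}
    for met in model.metabolites:
        species = sbml_model.createSpecies()
        sid = "M_" + _sbml_safe(met.id)
        id_map[met.id] = sid
        species.setId(sid)
        species.setName(met.name or met.id)
        species.setCompartment(_sbml_safe(met.compartment))
        species.setHasOnlySubstanceUnits(False)
        species.setBoundaryCondition(False)
        species.setConstant(False)
        if met.formula:
            splug = species.getPlugin("fbc")
            splug.setChemicalFormula(formula_to_string(met.formula))

    bound_ids: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_ids:
            param = sbml_model.createParameter()
            pid = f"bnd_{len(bound_ids)}"
            param.setId(pid)
            param.setValue(value)
            param.setConstant(True)
            bound_ids[value] = pid
        return bound_ids[value]

    for rxn in model.reactions:
        reaction = sbml_model.createReaction()
        rid = "R_" + _sbml_safe(rxn.id)
        reaction.setId(rid)
        reaction.setName(rxn.name or rxn.id)
        reaction.setFast(False)
        reaction.setReversible(rxn.lower_bound < 0)
        # reaction kind survives the round-trip in an annotation-free way:
        # encoded in the SBO-like notes field
        reaction.setNotes(f"<body xmlns='http://www.w3.org/1999/xhtml'><p>kind: {rxn.kind}</p></body>")
        for mid, coeff in sorted(rxn.stoichiometry.items()):
            if coeff < 0:
                ref = reaction.createReactant()
                ref.setStoichiometry(-coeff)
            else:
                ref = reaction.createProduct()
                ref.setStoichiometry(coeff)
            ref.setSpecies(id_map[mid])
            ref.setConstant(True)
        rplug = reaction.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(rxn.lower_bound))
        rplug.setUpperFluxBound(bound_param(rxn.upper_bound))

    if model.biomass_reaction_id:
        objective = mplug.createObjective()
        objective.setId("obj")
        objective.setType("maximize")
        mplug.setActiveObjectiveId("obj")
        flux_obj = objective.createFluxObjective()
        flux_obj.setReaction("R_" + _sbml_safe(model.biomass_reaction_id))
        flux_obj.setCoefficient(1.0)

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"failed to write SBML to {path}")


_KIND_NOTE = re.compile(r"kind:\s*(\w+)")


def read_sbml_model(path: str | Path) -> MetabolicModel:
    """Read an SBML L3 (+fbc) model.

    Reactions lacking fbc bounds fall back to documented defaults
    (irreversible 0..1000, reversible -1000..1000) with a warning.
    """
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelError(
            f"SBML parse error in {path}: {err.getMessage() if err else 'unknown'}"
        )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelError(f"no model element in {path}")

    def strip_prefix(sid: str, prefix: str) -> str:
        return sid[len(prefix):] if sid.startswith(prefix) else sid

    metabolites = []
    for i in range(sbml_model.getNumSpecies()):
        species = sbml_model.getSpecies(i)
        splug = species.getPlugin("fbc")
        formula = None
        if splug is not None and splug.isSetChemicalFormula():
            formula = parse_formula(splug.getChemicalFormula())
        metabolites.append(
            Metabolite(
                id=strip_prefix(species.getId(), "M_"),
                compartment=species.getCompartment(),
                name=species.getName() or "",
                formula=formula,
            )
        )

    def param_value(pid: str) -> float | None:
        param = sbml_model.getParameter(pid)
        return param.getValue() if param is not None else None

    reactions = []
    defaulted = 0
    for i in range(sbml_model.getNumReactions()):
        reaction = sbml_model.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(reaction.getNumReactants()):
            ref = reaction.getReactant(j)
            mid = strip_prefix(ref.getSpecies(), "M_")
            stoich[mid] = stoich.get(mid, 0.0) - ref.getStoichiometry()
        for j in range(reaction.getNumProducts()):
            ref = reaction.getProduct(j)
            mid = strip_prefix(ref.getSpecies(), "M_")
            stoich[mid] = stoich.get(mid, 0.0) + ref.getStoichiometry()
        rplug = reaction.getPlugin("fbc")
        lb = ub = None
        if rplug is not None:
            if rplug.isSetLowerFluxBound():
                lb = param_value(rplug.getLowerFluxBound())
            if rplug.isSetUpperFluxBound():
                ub = param_value(rplug.getUpperFluxBound())
        if lb is None or ub is None:
            defaults = (
                DEFAULT_REVERSIBLE_BOUNDS
                if reaction.getReversible()
                else DEFAULT_IRREVERSIBLE_BOUNDS
            )
            lb = defaults[0] if lb is None else lb
            ub = defaults[1] if ub is None else ub
            defaulted += 1
        kind = "internal"
        if reaction.isSetNotes():
            match = _KIND_NOTE.search(reaction.getNotesString())
            if match and match.group(1) in (
                "internal", "transport", "shuttle", "exchange", "biomass",
            ):
                kind = match.group(1)
        elif len(stoich) == 1:
            kind = "exchange"
        reactions.append(
            Reaction(
                id=strip_prefix(reaction.getId(), "R_"),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                kind=kind,
                name=reaction.getName() or "",
            )
        )
    if defaulted:
        logger.warning(
            "%s: %d reaction(s) lacked fbc bounds; defaults applied", path, defaulted
        )

    biomass_id = None
    mplug = sbml_model.getPlugin("fbc")
    if mplug is not None and mplug.getNumObjectives() > 0:
        objective = mplug.getActiveObjective() or mplug.getObjective(0)
        if objective is not None and objective.getNumFluxObjectives() > 0:
            biomass_id = strip_prefix(
                objective.getFluxObjective(0).getReaction(), "R_"
            )
    if biomass_id is None:
        for rxn in reactions:
            if rxn.kind == "biomass":
                biomass_id = rxn.id
                break
    return MetabolicModel(
        id=sbml_model.getId() or Path(path).stem,
        metabolites=metabolites,
        reactions=reactions,
        biomass_reaction_id=biomass_id,
    )


def read_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Read a model, auto-detecting SBML (.xml/.sbml) vs tabular."""
    path = Path(path)
    if format is None:
        format = "sbml" if path.suffix.lower() in (".xml", ".sbml") else "tabular"
    if format == "sbml":
        return read_sbml_model(path)
    if format == "tabular":
        return read_tabular_model(path)
    raise ValueError(f"unknown model format {format!r}")


def write_model(model: MetabolicModel, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "sbml" if path.suffix.lower() in (".xml", ".sbml") else "tabular"
    if format == "sbml":
        write_sbml_model(model, path)
    elif format == "tabular":
        write_tabular_model(model, path)
    else:
        raise ValueError(f"unknown model format {format!r}")


# ---------------------------------------------------------------------------
# media, formula tables, result tables
# ---------------------------------------------------------------------------


def read_medium_tsv(path: str | Path) -> Medium:
    frame = pd.read_csv(path, sep="\t")
    required = {"metabolite_id", "max_uptake"}
    if not required <= set(frame.columns):
        raise ModelError(f"medium TSV {path} must have columns {sorted(required)}")
    return Medium(dict(zip(frame["metabolite_id"], frame["max_uptake"].astype(float))))


def write_medium_tsv(medium: Medium, path: str | Path) -> None:
    frame = pd.DataFrame(
        sorted(medium.items()), columns=["metabolite_id", "max_uptake"]
    )
    frame.to_csv(path, sep="\t", index=False)


def read_formula_table(path: str | Path) -> dict[str, dict[str, int]]:
    """Read a metabolite -> elemental formula TSV (columns metabolite_id, formula)."""
    frame = pd.read_csv(path, sep="\t")
    required = {"metabolite_id", "formula"}
    if not required <= set(frame.columns):
        raise ModelError(f"formula table {path} must have columns {sorted(required)}")
    return {
        row.metabolite_id: parse_formula(str(row.formula))
        for row in frame.itertuples()
    }


def write_interactions_tsv(records: Sequence, path: str | Path) -> None:
    rows = []
    for i, rec in enumerate(records):
        rows.append(
            {
                "medium_id": f"medium_{i}",
                "metabolites": ";".join(sorted(rec.medium.metabolite_ids)),
                "interaction_class": rec.interaction_class,
                "grows_joint_1": rec.grows_joint[0],
                "grows_joint_2": rec.grows_joint[1],
                "grows_alone_1": rec.grows_alone[0],
                "grows_alone_2": rec.grows_alone[1],
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_usage_matrix(matrix, prefix: str | Path) -> None:
    """Write a usage matrix as MatrixMarket plus row/column label TSVs."""
    from scipy import io as scipy_io
    from scipy import sparse

    prefix = Path(prefix)
    scipy_io.mmwrite(str(prefix.with_suffix(".mtx")), sparse.csr_matrix(matrix.data))
    pd.DataFrame(
        {"medium_id": matrix.media_ids, "interaction_class": matrix.classes}
    ).to_csv(prefix.with_suffix(".rows.tsv"), sep="\t", index=False)
    pd.DataFrame({"metabolite_id": matrix.metabolite_ids}).to_csv(
        prefix.with_suffix(".cols.tsv"), sep="\t", index=False
    )


def write_transition_tsv(matrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t")


def write_provenance(path: str | Path, **fields) -> None:
    Path(path).write_text(json.dumps(fields, indent=2, sort_keys=True, default=str) + "\n")
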