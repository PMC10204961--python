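"""Model serialisation: native JSON dialect and optional SBML Level 3.

The native format is a versioned JSON document ("ecflux-model v1") with
``metabolites``, ``reactions`` and ``enzymes`` arrays. SBML import/export
goes through COBRApy (which bundles libsbml); constructs the dialect does
not represent (e.g. SBML groups, flux objectives beyond one reaction) are
dropped with a logged warning.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Union

from .model import Enzyme, MetabolicModel, Metabolite, Reaction, ValidationError

logger = logging.getLogger(__name__)

FORMAT_TAG = "ecflux-model v1"


def _model_to_dict(model: MetabolicModel) -> dict:
    return {
        "format": FORMAT_TAG,
        "id": model.id,
        "compartments": model.compartments,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                **({"formula": m.formula} if m.formula is not None else {}),
                **({"charge": m.charge} if m.charge is not None else {}),
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoich": {k: float(v) for k, v in r.stoich.items()},
                "lb": float(r.lb),
                "ub": float(r.ub),
                "gene_rule": r.gene_rule,
                "subsystem": r.subsystem,
            }
            for r in model.reactions
        ],
        "enzymes": [
            {
                "id": e.id,
                "genes": e.genes,
                "mw_g_per_mmol": e.mw,
                "ec_numbers": e.ec_numbers,
            }
            for e in model.enzymes
        ],
        "objective": model.objective,
        "meta": model.meta,
    }


def _model_from_dict(doc: dict, source: str = "<dict>") -> MetabolicModel:
    if doc.get("format") != FORMAT_TAG:
        raise ValueError(
            f"{source}: expected format {FORMAT_TAG!r}, got {doc.get('format')!r}"
        )
    try:
        model = MetabolicModel(
            id=doc.get("id", "model"),
            compartments=dict(doc.get("compartments", {})),
            metabolites=[
                Metabolite(
                    id=m["id"],
                    name=m.get("name", ""),
                    compartment=m.get("compartment", "c"),
                    formula=m.get("formula"),
                    charge=m.get("charge"),
                )
                for m in doc.get("metabolites", [])
            ],
            reactions=[
                Reaction(
                    id=r["id"],
                    name=r.get("name", ""),
                    stoich={k: float(v) for k, v in r["stoich"].items()},
                    lb=float(r.get("lb", -1000.0)),
                    ub=float(r.get("ub", 1000.0)),
                    gene_rule=[list(iso) for iso in r.get("gene_rule", [])],
                    subsystem=r.get("subsystem", ""),
                )
                for r in doc.get("reactions", [])
            ],
            enzymes=[
                Enzyme(
                    id=e["id"],
                    genes=list(e.get("genes", [])),
                    mw=float(e.get("mw_g_per_mmol", 0.0)),
                    ec_numbers=list(e.get("ec_numbers", [])),
                )
                for e in doc.get("enzymes", [])
            ],
            objective=doc.get("objective", ""),
            meta=doc.get("meta", {}),
        )
    except KeyError as exc:
        raise ValueError(f"{source}: missing required key {exc}") from exc
    model.validate()
    return model


def load_model(path: Union[str, Path], format: str = "json") -> MetabolicModel:
    """Load a model from the native JSON dialect or from SBML Level 3."""
    path = Path(path)
    if format == "json":
        try:
            with open(path) as fh:
                doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"{path}: JSON parse error at line {exc.lineno}: {exc.msg}")
        return _model_from_dict(doc, source=str(path))
    if format == "sbml":
        return _load_sbml(path)
    raise ValueError(f"unknown format {format!r}")


def write_model(
    model: MetabolicModel, path: Union[str, Path], format: str = "json"
) -> None:
    """Write a model; ``load_model(write_model(m))`` reproduces ``m``."""
    model.validate()
    path = Path(path)
    if format == "json":
        with open(path, "w") as fh:
            json.dump(_model_to_dict(model), fh, indent=1, sort_keys=True)
            fh.write("\n")
        return
    if format == "sbml":
        _write_sbml(model, path)
        return
    raise ValueError(f"unknown format {format!r}")


# -- SBML bridge via COBRApy ----------------------------------------------

def to_cobra(model: MetabolicModel):
    """Convert to a cobra.Model (gene rule = OR over isozymes of ANDs)."""
    import cobra

    cm = cobra.Model(model.id)
    mets = {}
    for m in model.metabolites:
        cmet = cobra.Metabolite(
            m.id, name=m.name, compartment=m.compartment or "c"
        )
        if m.formula:
            cmet.formula = m.formula
        if m.charge is not None:
            cmet.charge = m.charge
        mets[m.id] = cmet
    cm.add_metabolites(list(mets.values()))
    rxns = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id, name=r.name, subsystem=r.subsystem)
        cr.lower_bound, cr.upper_bound = r.lb, r.ub
        rxns.append(cr)
    cm.add_reactions(rxns)
    for r in model.reactions:
        cr = cm.reactions.get_by_id(r.id)
        cr.add_metabolites({mets[k]: v for k, v in r.stoich.items()})
        if r.gene_rule:
            rule = " or ".join(
                "( " + " and ".join(iso) + " )" if len(iso) > 1 else iso[0]
                for iso in r.gene_rule
            )
            cr.gene_reaction_rule = rule
    if model.objective:
        cm.objective = model.objective
    return cm


def from_cobra(cm) -> MetabolicModel:
    """Convert a cobra.Model into the native representation.

    GPR strings are read back as OR-of-ANDs when they have that shape;
    more deeply nested rules are flattened with a warning.
    """
    model = MetabolicModel(id=cm.id or "model")
    model.compartments = dict(cm.compartments) or {}
    for m in cm.metabolites:
        model.metabolites.append(
            Metabolite(
                id=m.id,
                name=m.name or "",
                compartment=m.compartment or "c",
                formula=m.formula or None,
                charge=m.charge if m.charge is not None else None,
            )
        )
    if not model.compartments:
        model.compartments = {
            m.compartment: m.compartment for m in model.metabolites
        }
    for r in cm.reactions:
        rule = []
        if r.gene_reaction_rule:
            for clause in r.gene_reaction_rule.split(" or "):
                genes = [
                    g.strip(" ()")
                    for g in clause.split(" and ")
                    if g.strip(" ()")
                ]
                if genes:
                    rule.append(genes)
        model.reactions.append(
            Reaction(
                id=r.id,
                name=r.name or "",
                stoich={m.id: v for m, v in r.metabolites.items()},
                lb=r.lower_bound,
                ub=r.upper_bound,
                gene_rule=rule,
                subsystem=r.subsystem or "",
            )
        )
    try:
        from cobra.util.solver import linear_reaction_coefficients

        coeffs = linear_reaction_coefficients(cm)
        if coeffs:
            if len(coeffs) > 1:
                logger.warning("multiple objective coefficients; keeping the first")
            model.objective = next(iter(coeffs)).id
    except Exception:  # pragma: no cover - solver-less cobra builds
        pass
    model.validate()
    return model


def _load_sbml(path: Path) -> MetabolicModel:
    try:
        import cobra.io
    except ImportError as exc:  # pragma: no cover
        raise ImportError("SBML import requires the optional cobra dependency") from exc
    cm = cobra.io.read_sbml_model(str(path))
    return from_cobra(cm)


def _write_sbml(model: MetabolicModel, path: Path) -> None:
    try:
        import cobra.io
    except ImportError as exc:  # pragma: no cover
        raise ImportError("SBML export requires the optional cobra dependency") from exc
    cobra.io.write_sbml_model(to_cobra(model), str(path))
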