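"""Readers and writers: model TSV dialect, SBML L3 (FBC), chemostat CSV,
pKa tables, run configuration and manifests.

Model TSV dialect (bit-exact round trip):

* reactions file, tab-separated columns
  ``id, name, equation, lower_bound, upper_bound, subsystem, gpr, is_transport``
  with equations like ``2 A[c] + B[c] -> C[e]`` (``<=>`` for reversible);
* metabolites file, columns
  ``id, name, formula, charge_pH6, charge_pH7, charge_pH8, compartment``
  plus optional ``base_charge, pka_list`` (semicolon-separated).

Exchange reactions are recognized structurally (single metabolite).
Numbers are serialized with 12 significant digits.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, Optional, Tuple

import pandas as pd
import yaml

from .core import (
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    format_equation,
    format_formula,
    parse_equation,
    parse_formula,
)
from .synthetic import ChemostatDataset

_NUM = "{:.12g}".format


# ---------------------------------------------------------------------------
# Model TSV dialect
# ---------------------------------------------------------------------------

def write_model_tsv(model: MetabolicModel, reactions_path, metabolites_path) -> None:
    rx_rows = []
    for r in model.reactions.values():
        rx_rows.append({
            "id": r.id,
            "name": r.name,
            "equation": format_equation(r, model),
            "lower_bound": _NUM(r.lower_bound),
            "upper_bound": _NUM(r.upper_bound),
            "subsystem": r.subsystem,
            "gpr": r.gpr,
            "is_transport": int(r.is_transport),
        })
    pd.DataFrame(rx_rows).to_csv(reactions_path, sep="\t", index=False)
    met_rows = []
    for m in model.metabolites.values():
        met_rows.append({
            "id": m.id,
            "name": m.name,
            "formula": format_formula(m.formula),
            "charge_pH6": _NUM(m.charge_by_ph.get("6", 0.0)),
            "charge_pH7": _NUM(m.charge_by_ph.get("7", 0.0)),
            "charge_pH8": _NUM(m.charge_by_ph.get("8", 0.0)),
            "compartment": m.compartment,
            "base_charge": "" if m.base_charge is None else int(m.base_charge),
            "pka_list": ";".join(_NUM(p) for p in (m.pka_list or [])),
        })
    pd.DataFrame(met_rows).to_csv(metabolites_path, sep="\t", index=False)


def read_model_tsv(
    reactions_path,
    metabolites_path,
    objective_id: Optional[str] = "BIOMASS",
    ph_condition: str = "7",
) -> MetabolicModel:
    model = MetabolicModel(ph_condition=ph_condition,
                           id=Path(str(reactions_path)).stem)
    mets = pd.read_csv(metabolites_path, sep="\t", dtype=str).fillna("")
    for _, row in mets.iterrows():
        pka = [float(p) for p in row.get("pka_list", "").split(";") if p]
        base = row.get("base_charge", "")
        model.add_metabolite(Metabolite(
            id=row["id"],
            name=row["name"],
            formula=parse_formula(row["formula"]),
            charge_by_ph={
                "6": float(row["charge_pH6"]),
                "7": float(row["charge_pH7"]),
                "8": float(row["charge_pH8"]),
            },
            compartment=row["compartment"],
            pka_list=pka if (pka or base != "") else None,
            base_charge=int(float(base)) if base != "" else None,
        ))
    rxns = pd.read_csv(reactions_path, sep="\t", dtype=str).fillna("")
    for i, row in rxns.iterrows():
        try:
            stoich, reversible = parse_equation(row["equation"])
        except ValueError as exc:
            raise ModelValidationError(
                f"{reactions_path}, line {i + 2}: {exc}"
            ) from exc
        unknown = [m for m in stoich if m not in model.metabolites]
        if unknown:
            raise ModelValidationError(
                f"{reactions_path}, line {i + 2}: unknown metabolite(s) {unknown}"
            )
        lb, ub = float(row["lower_bound"]), float(row["upper_bound"])
        model.add_reaction(Reaction(
            id=row["id"],
            name=row["name"],
            stoichiometry=stoich,
            lower_bound=lb,
            upper_bound=ub,
            subsystem=row["subsystem"],
            gpr=row["gpr"],
            is_transport=bool(int(row["is_transport"] or 0)),
            is_exchange=len(stoich) == 1,
        ))
    if objective_id and objective_id in model.reactions:
        model.objective_id = objective_id
    model.validate()
    return model


# ---------------------------------------------------------------------------
# SBML L3 + FBC
# ---------------------------------------------------------------------------

def write_sbml(model: MetabolicModel, path) -> None:
    import libsbml

    doc = libsbml.SBMLDocument(libsbml.SBMLNamespaces(3, 1, "fbc", 2))
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(model.id.replace("-", "_"))
    fbc_model = sm.getPlugin("fbc")
    fbc_model.setStrict(True)
    for comp_id in sorted({m.compartment for m in model.metabolites.values()}):
        comp = sm.createCompartment()
        comp.setId(comp_id)
        comp.setConstant(True)
    # flux-bound parameters (deduplicated)
    bound_params: Dict[float, str] = {}

    def param_for(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = sm.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for met in model.metabolites.values():
        s = sm.createSpecies()
        s.setId(f"M_{met.id}")
        s.setName(met.name)
        s.setCompartment(met.compartment)
        s.setHasOnlySubstanceUnits(False)
        s.setBoundaryCondition(False)
        s.setConstant(False)
        fbc_s = s.getPlugin("fbc")
        # FBC chemical formulas must have integer counts; macromolecular
        # pseudo-species (fractional composition) are left without one
        if met.formula and all(
            abs(n - round(n)) < 1e-9 for n in met.formula.values()
        ):
            fbc_s.setChemicalFormula(format_formula(met.formula))
        charge = met.charge_by_ph.get(model.ph_condition, 0.0)
        if charge == int(charge):
            fbc_s.setCharge(int(charge))
    genes = sorted(model.genes)
    for g in genes:
        gp = fbc_model.createGeneProduct()
        gp.setId(f"G_{g}")
        gp.setLabel(g)
    for rxn in model.reactions.values():
        r = sm.createReaction()
        r.setId(f"R_{rxn.id}")
        r.setName(rxn.name)
        r.setReversible(rxn.reversible)
        r.setFast(False)
        for mid, coeff in rxn.stoichiometry.items():
            ref = r.createReactant() if coeff < 0 else r.createProduct()
            ref.setSpecies(f"M_{mid}")
            ref.setStoichiometry(abs(coeff))
            ref.setConstant(True)
        fbc_r = r.getPlugin("fbc")
        fbc_r.setLowerFluxBound(param_for(rxn.lower_bound))
        fbc_r.setUpperFluxBound(param_for(rxn.upper_bound))
        if rxn.gpr:
            from .core import parse_gpr

            ga = fbc_r.createGeneProductAssociation()
            _build_association(ga, parse_gpr(rxn.gpr))
    if model.objective_id:
        obj = fbc_model.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction(f"R_{model.objective_id}")
        fo.setCoefficient(1.0)
        fbc_model.setActiveObjectiveId("obj")
    if doc.checkConsistency():
        errors = [
            doc.getError(i).getMessage()
            for i in range(doc.getNumErrors())
            if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
        ]
        if errors:
            raise ModelValidationError(f"SBML consistency errors: {errors[:3]}")
    libsbml.writeSBMLToFile(doc, str(path))


def read_sbml(path, ph_condition: str = "7") -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors() and any(
        doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
        for i in range(doc.getNumErrors())
    ):
        msgs = [doc.getError(i).getMessage() for i in range(doc.getNumErrors())]
        raise ModelValidationError(f"SBML parse errors: {msgs[:3]}")
    sm = doc.getModel()
    model = MetabolicModel(id=sm.getId() or "sbml_model", ph_condition=ph_condition)
    for i in range(sm.getNumSpecies()):
        s = sm.getSpecies(i)
        fbc_s = s.getPlugin("fbc")
        mid = s.getId()[2:] if s.getId().startswith("M_") else s.getId()
        charge = float(fbc_s.getCharge()) if fbc_s.isSetCharge() else 0.0
        formula = (
            parse_formula(fbc_s.getChemicalFormula())
            if fbc_s.isSetChemicalFormula() and fbc_s.getChemicalFormula()
            else {}
        )
        model.add_metabolite(Metabolite(
            id=mid, name=s.getName(), formula=formula,
            charge_by_ph={"6": charge, "7": charge, "8": charge},
            compartment=s.getCompartment(),
        ))
    params = {
        sm.getParameter(i).getId(): sm.getParameter(i).getValue()
        for i in range(sm.getNumParameters())
    }
    for i in range(sm.getNumReactions()):
        r = sm.getReaction(i)
        rid = r.getId()[2:] if r.getId().startswith("R_") else r.getId()
        stoich: Dict[str, float] = {}
        for j in range(r.getNumReactants()):
            ref = r.getReactant(j)
            mid = ref.getSpecies()[2:]
            stoich[mid] = stoich.get(mid, 0.0) - ref.getStoichiometry()
        for j in range(r.getNumProducts()):
            ref = r.getProduct(j)
            mid = ref.getSpecies()[2:]
            stoich[mid] = stoich.get(mid, 0.0) + ref.getStoichiometry()
        fbc_r = r.getPlugin("fbc")
        lb = params.get(fbc_r.getLowerFluxBound(), -1000.0)
        ub = params.get(fbc_r.getUpperFluxBound(), 1000.0)
        gpr = ""
        ga = fbc_r.getGeneProductAssociation()
        if ga is not None and ga.getAssociation() is not None:
            gpr = _association_to_gpr(ga.getAssociation())
        model.add_reaction(Reaction(
            id=rid, name=r.getName(), stoichiometry=stoich,
            lower_bound=lb, upper_bound=ub, gpr=gpr,
            is_exchange=len(stoich) == 1,
        ))
    fbc_model = sm.getPlugin("fbc")
    if fbc_model is not None and fbc_model.getActiveObjective() is not None:
        obj = fbc_model.getActiveObjective()
        if obj.getNumFluxObjectives():
            rid = obj.getFluxObjective(0).getReaction()
            model.objective_id = rid[2:] if rid.startswith("R_") else rid
    model.validate()
    return model


def _build_association(parent, node) -> None:
    """Materialize a GPR AST as nested FBC And/Or/GeneProductRef objects."""
    kind = node[0]
    if kind == "gene":
        ref = parent.createGeneProductRef()
        ref.setGeneProduct(f"G_{node[1]}")
        return
    container = parent.createAnd() if kind == "and" else parent.createOr()
    _build_association(container, node[1])
    _build_association(container, node[2])


def _association_to_gpr(assoc) -> str:
    """Render an FBC association tree in the dialect's AND/OR grammar."""
    import libsbml

    if isinstance(assoc, libsbml.GeneProductRef):
        label = assoc.getGeneProduct()
        return label[2:] if label.startswith("G_") else label
    if isinstance(assoc, libsbml.FbcAnd):
        parts = [
            _association_to_gpr(assoc.getAssociation(i))
            for i in range(assoc.getNumAssociations())
        ]
        return "(" + " AND ".join(parts) + ")"
    if isinstance(assoc, libsbml.FbcOr):
        parts = [
            _association_to_gpr(assoc.getAssociation(i))
            for i in range(assoc.getNumAssociations())
        ]
        return "(" + " OR ".join(parts) + ")"
    raise ModelValidationError(f"unsupported FBC association {type(assoc)}")


# ---------------------------------------------------------------------------
# Chemostat CSV and pKa TSV
# ---------------------------------------------------------------------------

def write_chemostat_csv(data: ChemostatDataset, path) -> None:
    pd.DataFrame(
        data.records, columns=["dilution_rate", "substrate_uptake_mmol_gDCW_h"]
    ).to_csv(path, index=False)


def read_chemostat_csv(path, substrate_id: str = "EX_fru") -> ChemostatDataset:
    df = pd.read_csv(path)
    required = {"dilution_rate", "substrate_uptake_mmol_gDCW_h"}
    if not required <= set(df.columns):
        raise ValueError(f"chemostat CSV needs columns {sorted(required)}")
    records = list(
        zip(df["dilution_rate"].astype(float),
            df["substrate_uptake_mmol_gDCW_h"].astype(float))
    )
    ds = ChemostatDataset(records=records, substrate_id=substrate_id)
    ds.validate()
    return ds


def read_pka_tsv(path) -> Dict[str, Tuple[int, list]]:
    """pKa table: ``metabolite_id, base_charge, pka1;pka2;...`` ->
    id -> (base_charge, sorted pKa list)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = {}
    for _, row in df.iterrows():
        pkas = sorted(float(p) for p in row.get("pkas", "").split(";") if p)
        out[row["metabolite_id"]] = (int(float(row["base_charge"] or 0)), pkas)
    return out


def write_pka_tsv(table: Dict[str, Tuple[int, list]], path) -> None:
    rows = [
        {"metabolite_id": mid, "base_charge": base,
         "pkas": ";".join(_NUM(p) for p in pkas)}
        for mid, (base, pkas) in table.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Run configuration and manifest
# ---------------------------------------------------------------------------

_CONFIG_KEYS = {
    "model", "metabolites", "scenario", "constraints", "energetics",
    "solver", "outdir", "seed", "condition", "ph", "include_pfk",
}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    unknown = set(cfg) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return cfg


def config_hash(cfg: dict) -> str:
    payload = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_manifest(cfg: dict, outdir, extra: Optional[dict] = None) -> Path:
    from .fba import FEASIBILITY_TOL, OPTIMALITY_TOL

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": cfg,
        "config_hash": config_hash(cfg),
        "solver": {
            "lp": "scipy-highs",
            "qp": "scipy-trust-constr",
            "feasibility_tolerance": FEASIBILITY_TOL,
            "optimality_tolerance": OPTIMALITY_TOL,
        },
    }
    if extra:
        manifest.update(extra)
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return path
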