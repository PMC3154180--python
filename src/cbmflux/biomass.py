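"""Condition-specific biomass reactions and maintenance energetics.

The biomass reaction drains monomeric precursors in proportion to the
measured macromolecular composition (g gDCW^-1), converted to mmol gDCW^-1
through monomer molecular weights, and couples growth to ATP hydrolysis
through the growth-associated maintenance energy (GAME).  Non-growth
associated maintenance (NGAME) is a separate ATP-hydrolysis reaction whose
flux is fixed.

GAME is specified in g gDCW^-1 (the units the chemostat calibration
produces); as a stoichiometric ATP coefficient it is converted to
mmol gDCW^-1 via GAME * 1000 / MW(ATP), with the molecular-weight basis
configurable and a raw-mmol mode available (``game_units="mmol"``), since
both conventions circulate in the genome-scale-modeling literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional

from .core import MetabolicModel, Metabolite, ModelValidationError, Reaction

# IUPAC 2021 standard atomic weights, rounded
ATOMIC_WEIGHTS = {
    "C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999, "P": 30.974, "S": 32.06,
}

WATER_MW = 2 * ATOMIC_WEIGHTS["H"] + ATOMIC_WEIGHTS["O"]

MACRO_CLASSES = ("protein", "carbohydrate", "lipid", "RNA", "DNA", "cofactors")

#: classes whose monomers condense with loss of water when polymerized
_POLYMER_CLASSES = {"protein", "carbohydrate"}


def molecular_weight(formula: Mapping[str, float]) -> float:
    try:
        return sum(ATOMIC_WEIGHTS[e] * n for e, n in formula.items())
    except KeyError as exc:  # pragma: no cover - formula audit
        raise ModelValidationError(f"no atomic weight for element {exc}") from exc


@dataclass
class BiomassComposition:
    """Macromolecular composition for one growth condition.

    ``macromolecule_fractions``: class -> g gDCW^-1, summing to 1.
    ``monomer_fractions``: class -> monomer metabolite id -> mole fraction.
    ``fatty_acid_profile``: acyl chain -> weight fraction within the lipid
    class (the nitrogen-limited condition differs from the normal one chiefly
    here: palmitoleate drops while heptadecanoate rises from 0.6% to 11.2%).
    """

    condition: str = "normal"
    macromolecule_fractions: Dict[str, float] = field(default_factory=dict)
    monomer_fractions: Dict[str, Dict[str, float]] = field(default_factory=dict)
    fatty_acid_profile: Dict[str, float] = field(default_factory=dict)

    def validate(self, tol: float = 1e-6) -> None:
        total = sum(self.macromolecule_fractions.values())
        if abs(total - 1.0) > tol:
            raise ModelValidationError(
                f"macromolecule fractions sum to {total:.8f}, expected 1 g/gDCW"
            )
        for cls, monomers in self.monomer_fractions.items():
            s = sum(monomers.values())
            if monomers and abs(s - 1.0) > tol:
                raise ModelValidationError(
                    f"monomer fractions of class {cls!r} sum to {s:.8f}"
                )
        if self.fatty_acid_profile:
            s = sum(self.fatty_acid_profile.values())
            if abs(s - 1.0) > tol:
                raise ModelValidationError(
                    f"fatty-acid profile sums to {s:.8f}"
                )


@dataclass
class EnergeticParameters:
    """GAME (g gDCW^-1, ATP term of the biomass equation) and NGAME
    (mmol gDCW^-1 h^-1, fixed maintenance flux)."""

    game: float
    ngame: float
    game_units: str = "g_per_gdcw"  # or "mmol"

    def __post_init__(self) -> None:
        if self.game < 0 or self.ngame < 0:
            raise ValueError("maintenance energies must be non-negative")


def game_atp_coefficient(
    energetics: EnergeticParameters, atp_mw: float
) -> float:
    """ATP coefficient (mmol gDCW^-1) implied by the GAME setting."""
    if energetics.game_units == "mmol":
        return energetics.game
    return energetics.game * 1000.0 / atp_mw


_ATP_SPECIES = ("atp_c", "adp_c", "pi_c", "h_c", "h2o_c")


def _require_cofactors(model: MetabolicModel) -> None:
    missing = [m for m in _ATP_SPECIES if m not in model.metabolites]
    if missing:
        raise ModelValidationError(
            f"ATP-hydrolysis cofactors missing from model: {missing}"
        )


def build_biomass_reaction(
    composition: BiomassComposition,
    energetics: EnergeticParameters,
    model: MetabolicModel,
    reaction_id: str = "BIOMASS",
    biomass_metabolite: str = "biomass_c",
    weight_basis: str = "free",
) -> Reaction:
    """Assemble the biomass formation reaction for one condition.

    Monomer drains are fraction * 1000 / MW mmol gDCW^-1.  ``weight_basis``
    chooses the molecular weight used: "free" takes the monomer metabolite's
    own formula weight; "residue" subtracts one water per condensation for
    protein/carbohydrate monomers and releases that water explicitly.  The
    ATP term is the GAME coefficient driving ATP + H2O -> ADP + Pi + H+.

    Protons are added to close the net charge, and the biomass metabolite's
    formula/charge are (re)defined as the exact net elemental content, so the
    reaction is element- and charge-balanced by construction.
    """
    composition.validate()
    _require_cofactors(model)
    ph = model.ph_condition
    stoich: Dict[str, float] = {}
    water_released = 0.0
    missing = []
    for cls, fraction in composition.macromolecule_fractions.items():
        if fraction == 0:
            continue
        if cls == "lipid" and composition.fatty_acid_profile:
            monomers = composition.fatty_acid_profile
            by_weight = True
        else:
            monomers = composition.monomer_fractions.get(cls, {})
            by_weight = False
        if not monomers:
            raise ModelValidationError(
                f"macromolecule class {cls!r} has weight {fraction} but no monomers"
            )
        if by_weight:
            # weight fractions within the class: mmol = f_cls*f_mono*1000/MW
            for mid, wfrac in monomers.items():
                if mid not in model.metabolites:
                    missing.append(mid)
                    continue
                mw = molecular_weight(model.metabolites[mid].formula)
                stoich[mid] = stoich.get(mid, 0.0) - fraction * wfrac * 1000.0 / mw
        else:
            # mole fractions within the class: convert through the mean MW
            mws = {}
            for mid in monomers:
                if mid not in model.metabolites:
                    missing.append(mid)
                    continue
                mw = molecular_weight(model.metabolites[mid].formula)
                if weight_basis == "residue" and cls in _POLYMER_CLASSES:
                    mw -= WATER_MW
                mws[mid] = mw
            if missing:
                continue
            mean_mw = sum(monomers[m] * mws[m] for m in monomers)
            total_mmol = fraction * 1000.0 / mean_mw
            for mid, mfrac in monomers.items():
                stoich[mid] = stoich.get(mid, 0.0) - total_mmol * mfrac
                if weight_basis == "residue" and cls in _POLYMER_CLASSES:
                    water_released += total_mmol * mfrac
    if missing:
        raise ModelValidationError(
            f"biomass monomers missing from model: {sorted(set(missing))}"
        )

    atp_mw = molecular_weight(model.metabolites["atp_c"].formula)
    atp = game_atp_coefficient(energetics, atp_mw)
    stoich["atp_c"] = stoich.get("atp_c", 0.0) - atp
    stoich["h2o_c"] = stoich.get("h2o_c", 0.0) - atp + water_released
    stoich["adp_c"] = stoich.get("adp_c", 0.0) + atp
    stoich["pi_c"] = stoich.get("pi_c", 0.0) + atp
    stoich["h_c"] = stoich.get("h_c", 0.0) + atp

    # close charge with protons; define biomass formula as the exact net
    net_charge = sum(
        c * model.metabolites[m].charge_by_ph.get(ph, 0.0)
        for m, c in stoich.items()
    )
    stoich["h_c"] = stoich.get("h_c", 0.0) - net_charge
    net_elements: Dict[str, float] = {}
    for m, c in stoich.items():
        for e, n in model.metabolites[m].formula.items():
            net_elements[e] = net_elements.get(e, 0.0) + (-c) * n
    biomass_formula = {e: round(v, 9) for e, v in net_elements.items() if abs(v) > 1e-9}
    if any(v < 0 for v in biomass_formula.values()):
        raise ModelValidationError(
            f"biomass composition implies negative element content: {biomass_formula}"
        )
    if biomass_metabolite not in model.metabolites:
        model.add_metabolite(
            Metabolite(
                id=biomass_metabolite,
                name="biomass (1 gDCW)",
                compartment="c",
            )
        )
    bm = model.metabolites[biomass_metabolite]
    bm.formula = biomass_formula
    bm.charge_by_ph = {p: 0.0 for p in ("6", "7", "8")}
    stoich[biomass_metabolite] = stoich.get(biomass_metabolite, 0.0) + 1.0
    stoich = {k: v for k, v in stoich.items() if v != 0}
    return Reaction(
        id=reaction_id,
        name=f"biomass formation ({composition.condition})",
        stoichiometry=stoich,
        lower_bound=0.0,
        upper_bound=1000.0,
        subsystem="Biomass and maintenance",
    )


def install_ngame_reaction(
    model: MetabolicModel,
    energetics: EnergeticParameters,
    reaction_id: str = "ATPM",
) -> MetabolicModel:
    """Add (or reset) the fixed ATP-hydrolysis maintenance reaction.

    ATP + H2O -> ADP + Pi + H+ with lower = upper = NGAME, so every feasible
    flux distribution pays the maintenance cost.
    """
    _require_cofactors(model)
    out = model.copy()
    rxn = Reaction(
        id=reaction_id,
        name="non-growth associated maintenance (ATP hydrolysis)",
        stoichiometry={
            "atp_c": -1.0, "h2o_c": -1.0,
            "adp_c": 1.0, "pi_c": 1.0, "h_c": 1.0,
        },
        lower_bound=energetics.ngame,
        upper_bound=energetics.ngame,
        subsystem="Biomass and maintenance",
    )
    if reaction_id in out.reactions:
        out.reactions[reaction_id] = rxn
    else:
        out.add_reaction(rxn)
    return out


def set_game(
    model: MetabolicModel,
    energetics: EnergeticParameters,
    reaction_id: str = "BIOMASS",
) -> MetabolicModel:
    """Copy of the model with the biomass ATP term set to the given GAME.

    Rewrites the ATP/ADP/Pi/H+/H2O coefficients of the biomass reaction by
    the difference between the new and the currently embedded ATP drain.
    """
    out = model.copy()
    rxn = out.reactions[reaction_id]
    atp_mw = molecular_weight(out.metabolites["atp_c"].formula)
    new_atp = game_atp_coefficient(energetics, atp_mw)
    old_atp = -rxn.stoichiometry.get("atp_c", 0.0)
    delta = new_atp - old_atp
    for mid, sign in (
        ("atp_c", -1), ("h2o_c", -1), ("adp_c", 1), ("pi_c", 1), ("h_c", 1)
    ):
        rxn.stoichiometry[mid] = rxn.stoichiometry.get(mid, 0.0) + sign * delta
    return out
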