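"""Metabolite charge estimation from pKa values and proton rebalancing.

The average charge of a species with acid dissociation constants pKa_k and a
fully-protonated charge z0 follows from Henderson-Hasselbalch: each
dissociable group is deprotonated with probability 1 / (1 + 10^(pKa_k - pH)),
so

    <z>(pH) = z0 - sum_k 1 / (1 + 10^(pKa_k - pH))

which is continuous and non-increasing in pH.  For model building the average
is rounded to the nearest integer (stoichiometric H+ coefficients must close
exactly); half-integer ties round toward the reference pH-7 charge.  The
real-valued average remains available for audits.

``adjust_model_to_ph`` emits a pH-variant model: metabolite charges and
hydrogen counts are moved to the new protonation state and every non-exchange
reaction's proton coefficient is readjusted so that charge (and hence
elemental) balance closes at the new pH.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

from .core import (
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    check_charge_balance,
    check_element_balance,
)

PH_VALUES = {"6": 6.0, "7": 7.0, "8": 8.0}
REFERENCE_PH = "7"


@dataclass
class ProtonationProfile:
    """Sorted pKa list plus the charge of the fully protonated species."""

    pka_list: List[float] = field(default_factory=list)
    base_charge: int = 0

    def __post_init__(self) -> None:
        self.pka_list = sorted(float(p) for p in self.pka_list)


def average_charge(profile: ProtonationProfile, ph: float) -> float:
    """Henderson-Hasselbalch average charge at a given pH (real-valued)."""
    z = float(profile.base_charge)
    for pka in profile.pka_list:
        z -= 1.0 / (1.0 + 10.0 ** (pka - ph))
    return z


def rounded_charge(
    profile: ProtonationProfile, ph: float, reference_charge: Optional[int] = None
) -> int:
    """Integer model-building charge; half-integer ties round toward the
    reference (pH-7) charge when one is supplied."""
    import math

    z = average_charge(profile, ph)
    lo, hi = math.floor(z), math.ceil(z)
    if lo == hi:
        return lo
    frac = z - lo
    if abs(frac - 0.5) < 1e-9 and reference_charge is not None:
        return lo if abs(lo - reference_charge) <= abs(hi - reference_charge) else hi
    return lo if frac < 0.5 else hi


def profile_of(met: Metabolite) -> Optional[ProtonationProfile]:
    if met.pka_list is None:
        return None
    return ProtonationProfile(
        pka_list=list(met.pka_list), base_charge=int(met.base_charge or 0)
    )


def charge_table(met: Metabolite) -> Dict[str, int]:
    """Rounded charges at pH 6/7/8 from a metabolite's protonation profile."""
    prof = profile_of(met)
    if prof is None:
        raise ModelValidationError(f"metabolite {met.id!r} has no pKa profile")
    ref = rounded_charge(prof, PH_VALUES[REFERENCE_PH])
    return {
        label: rounded_charge(prof, value, reference_charge=ref)
        for label, value in PH_VALUES.items()
    }


# ---------------------------------------------------------------------------
# Proton rebalancing
# ---------------------------------------------------------------------------

def _proton_id(model: MetabolicModel, compartment: str) -> str:
    for met in model.metabolites.values():
        if met.compartment == compartment and met.formula == {"H": 1.0}:
            if all(v == 1 for v in met.charge_by_ph.values()):
                return met.id
    raise ModelValidationError(
        f"no proton metabolite found in compartment {compartment!r}"
    )


def rebalance_protons(
    reaction: Reaction, model: MetabolicModel, ph: str
) -> Reaction:
    """Return a copy with the H+ coefficient adjusted to zero the net charge.

    Adding n protons to the product side raises the right-hand charge and H
    count by n simultaneously, so a charge-balanced reaction whose only
    imbalance is protonation is automatically element-balanced afterwards.
    A residual non-hydrogen element imbalance cannot be fixed by protons and
    raises, pointing at :func:`cbmflux.core.check_element_balance`.
    """
    if reaction.is_exchange:
        return reaction
    net = check_charge_balance(reaction, model, ph)
    out = Reaction(**{**reaction.__dict__})
    out.stoichiometry = dict(reaction.stoichiometry)
    if abs(net) > 1e-9:
        compartment = "c"
        for mid in reaction.stoichiometry:
            compartment = model.metabolites[mid].compartment
            if compartment == "c":
                break
        hid = _proton_id(model, compartment)
        out.stoichiometry[hid] = out.stoichiometry.get(hid, 0.0) - net
        if out.stoichiometry[hid] == 0:
            del out.stoichiometry[hid]
    residual = check_element_balance(out, model)
    non_h = {e: v for e, v in residual.items() if e != "H"}
    if non_h:
        raise ModelValidationError(
            f"reaction {reaction.id!r} has a non-hydrogen element imbalance "
            f"{non_h}; protons alone cannot fix it - run check_element_balance"
        )
    return out


def adjust_model_to_ph(model: MetabolicModel, ph: str) -> MetabolicModel:
    """Emit the pH-variant of a model.

    For every metabolite with a pKa profile the charge is re-derived at the
    target pH; the hydrogen count of its formula moves with the charge (one H
    gained per unit of charge gained).  Every non-exchange reaction is then
    proton-rebalanced.  The result satisfies charge balance = 0 and element
    balance = 0 at its own pH.
    """
    ph = str(ph)
    if ph not in PH_VALUES:
        raise ValueError(f"pH label must be one of {sorted(PH_VALUES)}, got {ph!r}")
    out = model.copy()
    out.ph_condition = ph
    old_ph = str(model.ph_condition)
    for met in out.metabolites.values():
        old_charge = met.charge_by_ph.get(old_ph)
        new_charge = met.charge_by_ph.get(ph)
        if old_charge is None or new_charge is None:
            continue
        delta = new_charge - old_charge
        if delta and met.formula:
            h = met.formula.get("H", 0.0) + delta
            if h < -1e-9:
                raise ModelValidationError(
                    f"metabolite {met.id!r}: protonation change to pH {ph} "
                    f"implies a negative hydrogen count"
                )
            met.formula = dict(met.formula)
            if h:
                met.formula["H"] = h
            else:
                met.formula.pop("H", None)
    for rid in out.reaction_ids:
        out.reactions[rid] = rebalance_protons(out.reactions[rid], out, ph)
    return out
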