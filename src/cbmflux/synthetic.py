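"""Synthetic inputs: a hand-curated R. eutropha H16 core model and chemostat data.

The core network (~90 reactions, two compartments) captures every pathway the
flux studies need, with real elemental formulas and pKa-derived charges so
that each reaction is element- and charge-balanced at its pH:

* fructose uptake and the Entner-Doudoroff (ED) route — the organism lacks
  phosphofructokinase, so hexoses pass through 6-phosphogluconate and KDPG
  aldolase (eda); a pfk reaction can be inserted to complete the EMP pathway;
* lower glycolysis, an (incomplete) TCA arm, PEP carboxylase anaplerosis;
* the PHB pathway phaA/phaB/phaC with a PHB sink;
* the 2-methylcitrate cycle (prpC/prpD/acnM/prpB) with a 2-MCA exchange and
  a propionyl-CoA supply (propionate activation, methylmalonyl-CoA route);
* a lumped Calvin (CBB) reaction, soluble NiFe hydrogenases and formate
  dehydrogenases for litho-/organoautotrophic growth;
* lumped respiration (P/O = 2 for NADH), denitrification steps (NO3-/NO2- as
  alternative electron acceptors), nitrogen assimilation, serine/glycine/THF
  one-carbon metabolism, fatty-acid synthesis (odd chains primed with
  propionyl-CoA), and a composition-derived biomass reaction with GAME/NGAME.

Deliberate design devices (see docs/methods.md for the full rationale):
the NADP-reducing enzymes are confined to the one-carbon/formate couple and
the hydrogenase (isocitrate dehydrogenase and glutamate dehydrogenase are
NAD(H)-linked), which makes NADPH supply on fructose growth-coupled and
produces the interior C/N optimum for PHB; oxidative-phosphorylation
stoichiometries are chosen so the fermentative ATP yield per fructose is
exactly 1 via the ED route and 2 via the EMP route.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .biomass import (
    BiomassComposition,
    EnergeticParameters,
    build_biomass_reaction,
    install_ngame_reaction,
)
from .core import MetabolicModel, Metabolite, Reaction, parse_equation
from .ph import ProtonationProfile, adjust_model_to_ph, charge_table

#: the organism's maintenance energetics in minimal fructose medium
DEFAULT_GAME = 15.30   # g gDCW^-1
DEFAULT_NGAME = 3.00   # mmol gDCW^-1 h^-1

#: default fructose cap, mmol gDCW^-1 h^-1
DEFAULT_FRUCTOSE_UPTAKE = 2.6


@dataclass
class CoreModelSpec:
    condition: str = "normal"          # normal | nitrogen_limited
    include_pfk: bool = False
    ph: str = "7"
    game: float = DEFAULT_GAME
    ngame: float = DEFAULT_NGAME
    declared_sizes: Optional[Dict[str, int]] = None


# ---------------------------------------------------------------------------
# Metabolite table: id-base, name, compartments, formula (pH-7 state),
# fully-protonated charge, pKa list.  Charges at pH 6/7/8 are derived from
# the profile via Henderson-Hasselbalch rounding; formulas are the pH-7
# protonation state (the pH pipeline shifts H counts for variant models).
# ---------------------------------------------------------------------------

def _acidic(n: int) -> List[float]:
    """n synthetic pKa values well below the 6-8 window (charge -n there)."""
    return [1.5 + 0.5 * i for i in range(n)]

_PHOSPHO2 = [1.5, 5.2]            # phosphomonoester-like, -2 across 6..8
_PHOSPHO3 = [1.5, 3.5, 5.2]       # -3 across 6..8
_PHOSPHO4 = [1.0, 1.6, 5.0, 5.3]  # -4 across 6..8
_PHOSPHO5 = [1.0, 1.5, 2.0, 5.0, 5.3]
_DICARB = [2.5, 4.5]              # dicarboxylate, -2
_TRICARB = [3.1, 4.7, 5.4]        # citrate-like, -3

_METS: List[Tuple[str, str, str, str, int, List[float]]] = [
    # (id base, name, compartments, formula@pH7, base_charge, pKas)
    ("fru", "D-fructose", "ce", "C6H12O6", 0, []),
    ("f6p", "D-fructose 6-phosphate", "c", "C6H11O9P", 0, _PHOSPHO2),
    ("g6p", "D-glucose 6-phosphate", "c", "C6H11O9P", 0, _PHOSPHO2),
    ("fdp", "D-fructose 1,6-bisphosphate", "c", "C6H10O12P2", 0, _PHOSPHO4),
    ("dhap", "dihydroxyacetone phosphate", "c", "C3H5O6P", 0, _PHOSPHO2),
    ("g3p", "glyceraldehyde 3-phosphate", "c", "C3H5O6P", 0, _PHOSPHO2),
    ("13dpg", "1,3-bisphospho-D-glycerate", "c", "C3H4O10P2", 0, _PHOSPHO4),
    ("3pg", "3-phospho-D-glycerate", "c", "C3H4O7P", 0, _PHOSPHO3),
    ("2pg", "2-phospho-D-glycerate", "c", "C3H4O7P", 0, _PHOSPHO3),
    ("pep", "phosphoenolpyruvate", "c", "C3H2O6P", 0, _PHOSPHO3),
    ("pyr", "pyruvate", "ce", "C3H3O3", 0, [2.5]),
    ("6pgc", "6-phospho-D-gluconate", "c", "C6H10O10P", 0, _PHOSPHO3),
    ("2ddg6p", "2-dehydro-3-deoxy-6-phospho-D-gluconate", "c", "C6H8O9P", 0, _PHOSPHO3),
    ("accoa", "acetyl-CoA", "c", "C23H34N7O17P3S", 0, _PHOSPHO4),
    ("coa", "coenzyme A", "c", "C21H32N7O16P3S", 0, _PHOSPHO4),
    ("aacoa", "acetoacetyl-CoA", "c", "C25H36N7O18P3S", 0, _PHOSPHO4),
    ("3hbcoa", "(R)-3-hydroxybutyryl-CoA", "c", "C25H38N7O18P3S", 0, _PHOSPHO4),
    ("ppcoa", "propionyl-CoA", "c", "C24H36N7O17P3S", 0, _PHOSPHO4),
    ("succoa", "succinyl-CoA", "c", "C25H35N7O19P3S", 0, _PHOSPHO5),
    ("cit", "citrate", "c", "C6H5O7", 0, _TRICARB),
    ("icit", "isocitrate", "c", "C6H5O7", 0, _TRICARB),
    ("akg", "2-oxoglutarate", "c", "C5H4O5", 0, _DICARB),
    ("succ", "succinate", "c", "C4H4O4", 0, _DICARB),
    ("fum", "fumarate", "c", "C4H2O4", 0, _DICARB),
    ("mal", "(S)-malate", "c", "C4H4O5", 0, _DICARB),
    ("oaa", "oxaloacetate", "c", "C4H2O5", 0, _DICARB),
    ("glu", "L-glutamate", "c", "C5H8NO4", 1, [2.19, 4.25, 9.67]),
    ("asp", "L-aspartate", "c", "C4H6NO4", 1, [1.88, 3.65, 9.60]),
    ("gly", "glycine", "c", "C2H5NO2", 1, [2.35, 9.78]),
    ("ser", "L-serine", "c", "C3H7NO3", 1, [2.21, 9.15]),
    ("3php", "3-phosphohydroxypyruvate", "c", "C3H2O7P", 0, _PHOSPHO3),
    ("pser", "O-phospho-L-serine", "c", "C3H6NO6P", 0, _PHOSPHO2),
    ("thf", "tetrahydrofolate", "c", "C19H21N7O6", 0, _PHOSPHO2),
    ("mlthf", "5,10-methylenetetrahydrofolate", "c", "C20H21N7O6", 0, _PHOSPHO2),
    ("for", "formate", "ce", "CHO2", 0, [3.75]),
    ("atp", "ATP", "c", "C10H12N5O13P3", 0, _PHOSPHO4),
    ("adp", "ADP", "c", "C10H12N5O10P2", 0, _PHOSPHO3),
    ("pi", "orthophosphate", "ce", "HO4P", 0, [2.15, 6.8, 12.4]),
    ("nad", "NAD+", "c", "C21H26N7O14P2", 0, _acidic(1)),
    ("nadh", "NADH", "c", "C21H27N7O14P2", 0, _PHOSPHO2),
    ("nadp", "NADP+", "c", "C21H25N7O17P3", 0, _PHOSPHO3),
    ("nadph", "NADPH", "c", "C21H26N7O17P3", 0, _PHOSPHO4),
    ("h", "proton", "ce", "H", 1, []),
    ("h2o", "water", "ce", "H2O", 0, []),
    ("o2", "oxygen", "ce", "O2", 0, []),
    ("co2", "carbon dioxide", "ce", "CO2", 0, []),
    ("h2", "hydrogen", "ce", "H2", 0, []),
    ("nh4", "ammonium", "ce", "H4N", 1, [9.25]),
    ("no3", "nitrate", "ce", "NO3", 0, _acidic(1)),
    ("no2", "nitrite", "ce", "NO2", 0, [3.25]),
    ("n2", "dinitrogen", "ce", "N2", 0, []),
    ("lac", "D-lactate", "ce", "C3H5O3", 0, [3.86]),
    ("ac", "acetate", "ce", "C2H3O2", 0, [4.76]),
    ("etoh", "ethanol", "ce", "C2H6O", 0, []),
    ("prp", "propionate", "ce", "C3H5O2", 0, [4.87]),
    ("2mcit", "2-methylcitrate", "ce", "C7H7O7", 0, _TRICARB),
    ("2mcacn", "2-methyl-cis-aconitate", "c", "C7H5O6", 0, _acidic(3)),
    ("micit", "2-methylisocitrate", "c", "C7H7O7", 0, _TRICARB),
    ("glucan", "glucan (glycogen unit)", "c", "C6H10O5", 0, []),
    ("phb", "PHB (3-hydroxybutanoyl unit)", "ce", "C4H6O2", 0, []),
    ("ttdca", "myristate (C14:0)", "c", "C14H27O2", 0, [4.8]),
    ("hdca", "palmitate (C16:0)", "c", "C16H31O2", 0, [4.8]),
    ("hdcea", "palmitoleate (C16:1)", "c", "C16H29O2", 0, [4.8]),
    ("hpdca", "heptadecanoate (C17:0)", "c", "C17H33O2", 0, [4.8]),
    ("ttdcea", "myristoleate (C14:1)", "c", "C14H25O2", 0, [4.8]),
    ("ocdcea", "oleate (C18:1)", "c", "C18H33O2", 0, [4.8]),
    ("nndca", "nonadecanoate (C19:0)", "c", "C19H37O2", 0, [4.8]),
]


# ---------------------------------------------------------------------------
# Reaction table: id, name, equation (TSV dialect), lb, ub, subsystem, gpr,
# is_transport.  Every equation is element- and charge-balanced at pH 7.
# ---------------------------------------------------------------------------

_BIG = 1000.0

_EXCHANGES: List[Tuple[str, str, float, float]] = [
    ("EX_fru", "fru[e] <=>", -DEFAULT_FRUCTOSE_UPTAKE, _BIG),
    ("EX_o2", "o2[e] <=>", -_BIG, _BIG),
    ("EX_co2", "co2[e] <=>", 0.0, _BIG),
    ("EX_h2", "h2[e] <=>", 0.0, _BIG),
    ("EX_nh4", "nh4[e] <=>", -_BIG, _BIG),
    ("EX_no3", "no3[e] <=>", 0.0, _BIG),
    ("EX_no2", "no2[e] <=>", 0.0, _BIG),
    ("EX_n2", "n2[e] <=>", 0.0, _BIG),
    ("EX_pi", "pi[e] <=>", -_BIG, _BIG),
    ("EX_h", "h[e] <=>", -_BIG, _BIG),
    ("EX_h2o", "h2o[e] <=>", -_BIG, _BIG),
    ("EX_for", "for[e] <=>", 0.0, _BIG),
    ("EX_prp", "prp[e] <=>", 0.0, _BIG),
    ("EX_lac", "lac[e] <=>", 0.0, _BIG),
    ("EX_ac", "ac[e] <=>", 0.0, _BIG),
    ("EX_etoh", "etoh[e] <=>", 0.0, _BIG),
    ("EX_pyr", "pyr[e] <=>", 0.0, _BIG),
    ("EX_2mca", "2mcit[e] <=>", 0.0, _BIG),
    ("EX_phb", "phb[e] <=>", 0.0, _BIG),
]

_TRANSPORTERS: List[Tuple[str, str, str, str]] = [
    # id, name, equation, gpr
    ("FRUt", "fructose transport", "fru[e] -> fru[c]", "frcA"),
    ("O2t", "oxygen diffusion", "o2[e] <=> o2[c]", ""),
    ("CO2t", "CO2 diffusion", "co2[e] <=> co2[c]", ""),
    ("H2t", "hydrogen diffusion", "h2[e] -> h2[c]", ""),
    ("NH4t", "ammonium transport", "nh4[e] <=> nh4[c]", "amtB"),
    ("NO3t", "nitrate transport", "no3[e] <=> no3[c]", "narK"),
    ("NO2t", "nitrite transport", "no2[e] <=> no2[c]", "narK"),
    ("N2t", "dinitrogen release", "n2[c] -> n2[e]", ""),
    ("PIt", "phosphate transport", "pi[e] <=> pi[c]", "pitA"),
    ("Ht", "proton exchange", "h[e] <=> h[c]", ""),
    ("H2Ot", "water diffusion", "h2o[e] <=> h2o[c]", ""),
    ("FORt", "formate transport", "for[e] <=> for[c]", "focA"),
    ("PRPt", "propionate uptake", "prp[e] -> prp[c]", "prpP"),
    ("LACt", "lactate efflux", "lac[c] -> lac[e]", ""),
    ("ACt", "acetate efflux", "ac[c] -> ac[e]", ""),
    ("ETOHt", "ethanol efflux", "etoh[c] -> etoh[e]", ""),
    ("PYRt", "pyruvate efflux", "pyr[c] -> pyr[e]", ""),
    ("MCITt", "2-methylcitrate efflux", "2mcit[c] -> 2mcit[e]", ""),
    ("PHBt", "PHB granule export", "phb[c] -> phb[e]", ""),
]

_INTERNAL: List[Tuple[str, str, str, bool, str, str]] = [
    # id, name, equation, reversible, subsystem, gpr
    ("FRK", "fructokinase",
     "fru[c] + atp[c] -> f6p[c] + adp[c] + h[c]", False, "Glycolysis/ED", "frk"),
    ("PGI", "glucose-6-phosphate isomerase",
     "g6p[c] <=> f6p[c]", True, "Glycolysis/ED", "pgi"),
    ("G6PDH", "glucose-6-phosphate dehydrogenase (NAD, lumped with lactonase)",
     "g6p[c] + nad[c] + h2o[c] -> 6pgc[c] + nadh[c] + 2 h[c]",
     False, "Glycolysis/ED", "zwf"),
    ("EDD", "6-phosphogluconate dehydratase",
     "6pgc[c] -> 2ddg6p[c] + h2o[c]", False, "Glycolysis/ED", "edd"),
    ("EDA", "KDPG aldolase",
     "2ddg6p[c] -> pyr[c] + g3p[c]", False, "Glycolysis/ED", "eda"),
    ("FBA", "fructose-bisphosphate aldolase",
     "fdp[c] <=> dhap[c] + g3p[c]", True, "Glycolysis/ED", "fbaA"),
    ("TPI", "triose-phosphate isomerase",
     "dhap[c] <=> g3p[c]", True, "Glycolysis/ED", "tpiA"),
    ("FBP", "fructose-1,6-bisphosphatase (gluconeogenic, cbb operon)",
     "fdp[c] + h2o[c] -> f6p[c] + pi[c]", False, "Glycolysis/ED", "cbbF"),
    ("GAPD", "glyceraldehyde-3-phosphate dehydrogenase",
     "g3p[c] + nad[c] + pi[c] <=> 13dpg[c] + nadh[c] + h[c]",
     True, "Glycolysis/ED", "gap"),
    ("PGK", "phosphoglycerate kinase",
     "13dpg[c] + adp[c] <=> 3pg[c] + atp[c]", True, "Glycolysis/ED", "pgk"),
    ("PGM", "phosphoglycerate mutase",
     "3pg[c] <=> 2pg[c]", True, "Glycolysis/ED", "gpmA"),
    ("ENO", "enolase", "2pg[c] <=> pep[c] + h2o[c]", True, "Glycolysis/ED", "eno"),
    ("PYK", "pyruvate kinase",
     "pep[c] + adp[c] + h[c] -> pyr[c] + atp[c]", False, "Glycolysis/ED", "pyk"),
    ("PDH", "pyruvate dehydrogenase",
     "pyr[c] + coa[c] + nad[c] -> accoa[c] + co2[c] + nadh[c]",
     False, "Glycolysis/ED", "pdhA"),
    ("PPC", "PEP carboxylase",
     "pep[c] + co2[c] + h2o[c] -> oaa[c] + pi[c] + h[c]",
     False, "Anaplerosis", "ppc"),
    ("CS", "citrate synthase",
     "accoa[c] + oaa[c] + h2o[c] -> cit[c] + coa[c] + h[c]",
     False, "TCA cycle", "gltA"),
    ("ACONT", "aconitase", "cit[c] <=> icit[c]", True, "TCA cycle", "acnA"),
    ("ICDH", "isocitrate dehydrogenase (NAD)",
     "icit[c] + nad[c] -> akg[c] + co2[c] + nadh[c]",
     False, "TCA cycle", "icd"),
    ("AKGDH", "2-oxoglutarate dehydrogenase",
     "akg[c] + coa[c] + nad[c] -> succoa[c] + co2[c] + nadh[c]",
     False, "TCA cycle", "sucA"),
    ("SUCOAS", "succinyl-CoA synthetase",
     "succ[c] + atp[c] + coa[c] <=> succoa[c] + adp[c] + pi[c]",
     True, "TCA cycle", "(sucC AND sucD) OR (sucC2 AND sucD2)"),
    ("SUCDi", "succinate dehydrogenase (lumped, O2-coupled)",
     "succ[c] + 0.5 o2[c] + adp[c] + pi[c] + h[c] -> fum[c] + atp[c] + 2 h2o[c]",
     False, "TCA cycle", ""),
    ("FRD", "fumarate reductase (NADH)",
     "fum[c] + nadh[c] + h[c] -> succ[c] + nad[c]", False, "TCA cycle", "frdA"),
    ("FUM", "fumarase", "fum[c] + h2o[c] <=> mal[c]", True, "TCA cycle", "fumC1 OR fumC2"),
    ("MDH", "malate dehydrogenase",
     "mal[c] + nad[c] <=> oaa[c] + nadh[c] + h[c]", True, "TCA cycle", "mdh OR mqo"),
    ("GDH", "glutamate dehydrogenase (NADH)",
     "akg[c] + nh4[c] + nadh[c] + h[c] -> glu[c] + nad[c] + h2o[c]",
     False, "Nitrogen assimilation", "gdhA"),
    ("ASPTA", "aspartate transaminase",
     "oaa[c] + glu[c] <=> asp[c] + akg[c]", True, "Amino acids", "aspC"),
    ("PGCD", "phosphoglycerate dehydrogenase",
     "3pg[c] + nad[c] -> 3php[c] + nadh[c] + h[c]", False, "Amino acids", "serA"),
    ("PSERT", "phosphoserine transaminase",
     "3php[c] + glu[c] -> pser[c] + akg[c]", False, "Amino acids", "serC"),
    ("PSP", "phosphoserine phosphatase",
     "pser[c] + h2o[c] -> ser[c] + pi[c]", False, "Amino acids", "serB"),
    ("GHMT", "glycine hydroxymethyltransferase",
     "ser[c] + thf[c] <=> gly[c] + mlthf[c] + h2o[c]", True, "Amino acids", "glyA"),
    ("MTHFD", "methylene-THF oxidation to formate (lumped)",
     "mlthf[c] + nadp[c] + 2 h2o[c] -> thf[c] + for[c] + nadph[c] + 2 h[c]",
     False, "One-carbon metabolism", "folD"),
    ("FDH", "formate dehydrogenase (NAD)",
     "for[c] + nad[c] -> co2[c] + nadh[c]", False, "Energy metabolism", "fdhA"),
    ("FDHN", "formate dehydrogenase (NADP)",
     "for[c] + nadp[c] -> co2[c] + nadph[c]", False, "Energy metabolism", "fdsA"),
    ("HYDS", "soluble NiFe hydrogenase (NAD-reducing)",
     "h2[c] + nad[c] -> nadh[c] + h[c]", False, "Energy metabolism", "hoxF"),
    ("HYDN", "NADP-reducing hydrogenase (lumped reductant supply)",
     "h2[c] + nadp[c] -> nadph[c] + h[c]", False, "Energy metabolism", "hoxY"),
    ("THD", "transhydrogenase (NADPH -> NADH)",
     "nadph[c] + nad[c] -> nadp[c] + nadh[c]", False, "Energy metabolism", "sth"),
    ("NADHOX", "respiratory chain (lumped, P/O = 2)",
     "nadh[c] + 0.5 o2[c] + 3 h[c] + 2 adp[c] + 2 pi[c] -> "
     "nad[c] + 3 h2o[c] + 2 atp[c]",
     False, "Energy metabolism", ""),
    ("NO3R", "nitrate reductase (respiratory, lumped)",
     "no3[c] + nadh[c] + 2 h[c] + adp[c] + pi[c] -> "
     "no2[c] + nad[c] + 2 h2o[c] + atp[c]",
     False, "Denitrification", "narG OR napA"),
    ("NO2R", "nitrite reduction to N2 (lumped denitrification)",
     "2 no2[c] + 3 nadh[c] + 6 h[c] + adp[c] + pi[c] -> "
     "n2[c] + 3 nad[c] + 5 h2o[c] + atp[c]",
     False, "Denitrification", "nirS"),
    ("CBB", "Calvin-Benson-Bassham cycle (lumped, 3 CO2 -> G3P)",
     "3 co2[c] + 9 atp[c] + 6 nadph[c] + 5 h2o[c] -> "
     "g3p[c] + 9 adp[c] + 6 nadp[c] + 8 pi[c] + 3 h[c]",
     False, "CO2 fixation", "cbbL AND cbbS"),
    ("PRPCT", "propionate-CoA ligase (lumped activation)",
     "prp[c] + atp[c] + coa[c] -> ppcoa[c] + adp[c] + pi[c]",
     False, "Methylcitrate cycle", "prpE"),
    ("LDH", "D-lactate dehydrogenase",
     "pyr[c] + nadh[c] + h[c] -> lac[c] + nad[c]", False, "Fermentation", "ldhA"),
    ("PTACK", "acetate formation (phosphotransacetylase + acetate kinase)",
     "accoa[c] + adp[c] + pi[c] -> ac[c] + atp[c] + coa[c]",
     False, "Fermentation", "pta AND ackA"),
    ("ALCD", "ethanol formation (lumped)",
     "accoa[c] + 2 nadh[c] + 2 h[c] -> etoh[c] + coa[c] + 2 nad[c]",
     False, "Fermentation", "adhE"),
    ("PHAA", "beta-ketothiolase",
     "2 accoa[c] -> aacoa[c] + coa[c]", False, "PHB synthesis", "phaA"),
    ("PHAB", "acetoacetyl-CoA reductase",
     "aacoa[c] + nadph[c] + h[c] -> 3hbcoa[c] + nadp[c]",
     False, "PHB synthesis", "phaB"),
    ("PHAC", "PHA synthase",
     "3hbcoa[c] -> phb[c] + coa[c]", False, "PHB synthesis", "phaC"),
    ("MMM", "methylmalonyl-CoA route (mutase + decarboxylase, lumped)",
     "succoa[c] + h[c] -> ppcoa[c] + co2[c]", False, "Methylcitrate cycle", "mcm"),
    ("PRPC", "2-methylcitrate synthase",
     "ppcoa[c] + oaa[c] + h2o[c] -> 2mcit[c] + coa[c] + h[c]",
     False, "Methylcitrate cycle", "prpC"),
    ("PRPD", "2-methylcitrate dehydratase",
     "2mcit[c] <=> 2mcacn[c] + h2o[c]", True, "Methylcitrate cycle", "prpD"),
    ("ACNM", "2-methylisocitrate dehydratase",
     "2mcacn[c] + h2o[c] <=> micit[c]", True, "Methylcitrate cycle", "acnM"),
    ("PRPB", "methylisocitrate lyase",
     "micit[c] -> pyr[c] + succ[c]", False, "Methylcitrate cycle", "prpB"),
    ("GLGC", "glycogen synthesis (lumped from G6P)",
     "g6p[c] + atp[c] + h2o[c] -> glucan[c] + adp[c] + 2 pi[c] + h[c]",
     False, "Carbohydrate storage", "glgC"),
]

_PFK = ("PFK", "phosphofructokinase",
        "f6p[c] + atp[c] -> fdp[c] + adp[c] + h[c]",
        False, "Glycolysis/ED", "pfk")


def _fatty_acid_reactions() -> List[Tuple[str, str, str, bool, str, str]]:
    """Lumped FAS reactions (NADH-linked reductases, ACC+elongation+TE).

    Chains are (metabolite id, even-chain acetyl units, double bonds,
    odd-chain primer flag).  Odd chains are primed with propionyl-CoA.
    """
    chains = [
        ("ttdca", 7, 0, False), ("hdca", 8, 0, False), ("hdcea", 8, 1, False),
        ("ttdcea", 7, 1, False), ("ocdcea", 9, 1, False),
        ("hpdca", 8, 0, True), ("nndca", 9, 0, True),
    ]
    out = []
    for mid, units, dbonds, odd in chains:
        n_ac = units - 1 if odd else units
        m = units - 1                  # malonyl condensations
        nred = 2 * m - dbonds          # NADH-consuming reduction steps
        nh = m - 1 - dbonds            # protons consumed
        lhs = []
        if odd:
            lhs.append("ppcoa[c]")
        lhs += [f"{n_ac} accoa[c]", f"{m} atp[c]", f"{nred} nadh[c]"]
        if nh:
            lhs.append(f"{nh} h[c]")
        lhs.append("h2o[c]")
        rhs = [f"{mid}[c]", f"{units} coa[c]", f"{m} adp[c]", f"{m} pi[c]",
               f"{nred} nad[c]"]
        eq = " + ".join(lhs) + " -> " + " + ".join(rhs)
        out.append(
            (f"FAS_{mid}", f"fatty-acid synthesis ({mid}, lumped)", eq,
             False, "Lipid synthesis", "fabF")
        )
    return out


# ---------------------------------------------------------------------------
# Biomass compositions (g gDCW^-1 macromolecule fractions; mole fractions
# within protein; weight fractions within lipid)
# ---------------------------------------------------------------------------

_PROTEIN_MONOMERS = {"glu_c": 0.30, "asp_c": 0.25, "gly_c": 0.30, "ser_c": 0.15}

FATTY_ACID_PROFILES = {
    "normal": {
        "ttdca_c": 0.050, "hdca_c": 0.400, "hdcea_c": 0.320,
        "hpdca_c": 0.006, "ocdcea_c": 0.224,
    },
    "nitrogen_limited": {
        "ttdca_c": 0.050, "hdca_c": 0.380, "hdcea_c": 0.180,
        "hpdca_c": 0.112, "ttdcea_c": 0.040, "ocdcea_c": 0.198,
        "nndca_c": 0.040,
    },
}


def core_biomass_composition(condition: str = "normal") -> BiomassComposition:
    """Macromolecular composition of the core model.

    Protein/carbohydrate/lipid only; RNA, DNA and the cofactor pool are set
    to zero in this reduced network (their precursor pathways are not part of
    the core model).  The two conditions differ only in the fatty-acid
    profile, mirroring the measured lipid shift under nitrogen limitation.
    """
    if condition not in FATTY_ACID_PROFILES:
        raise ValueError(f"unknown condition {condition!r}")
    return BiomassComposition(
        condition=condition,
        macromolecule_fractions={
            "protein": 0.68, "carbohydrate": 0.17, "lipid": 0.15,
            "RNA": 0.0, "DNA": 0.0, "cofactors": 0.0,
        },
        monomer_fractions={
            "protein": dict(_PROTEIN_MONOMERS),
            "carbohydrate": {"glucan_c": 1.0},
        },
        fatty_acid_profile=dict(FATTY_ACID_PROFILES[condition]),
    )


# ---------------------------------------------------------------------------
# Model assembly
# ---------------------------------------------------------------------------

def _build_metabolites() -> List[Metabolite]:
    from .core import parse_formula

    out = []
    for base, name, comps, formula, base_charge, pkas in _METS:
        prof_met = Metabolite(
            id="tmp", name=name, formula=parse_formula(formula),
            pka_list=list(pkas), base_charge=base_charge,
        )
        charges = charge_table(prof_met)
        for comp in comps:
            out.append(
                Metabolite(
                    id=f"{base}_{comp}",
                    name=name,
                    formula=parse_formula(formula),
                    charge_by_ph={k: float(v) for k, v in charges.items()},
                    compartment=comp,
                    pka_list=list(pkas),
                    base_charge=base_charge,
                )
            )
    return out


def generate_core_model(spec: Optional[CoreModelSpec] = None) -> MetabolicModel:
    """Build the R. eutropha core model for a condition/pH/pfk variant."""
    spec = spec or CoreModelSpec()
    model = MetabolicModel(id=f"reh_core_{spec.condition}_ph{spec.ph}",
                           ph_condition="7")
    for met in _build_metabolites():
        model.add_metabolite(met)

    for rid, eq, lb, ub in _EXCHANGES:
        stoich, _ = parse_equation(eq)
        model.add_reaction(
            Reaction(
                id=rid, name=rid.replace("EX_", "") + " exchange",
                stoichiometry=stoich, lower_bound=lb, upper_bound=ub,
                subsystem="Exchange", is_exchange=True,
            )
        )
    for rid, name, eq, gpr in _TRANSPORTERS:
        stoich, rev = parse_equation(eq)
        model.add_reaction(
            Reaction(
                id=rid, name=name, stoichiometry=stoich,
                lower_bound=-_BIG if rev else 0.0, upper_bound=_BIG,
                subsystem="Transport", gpr=gpr, is_transport=True,
            )
        )
    internal = list(_INTERNAL) + _fatty_acid_reactions()
    if spec.include_pfk:
        internal.append(_PFK)
    for rid, name, eq, rev, subsystem, gpr in internal:
        stoich, rev_eq = parse_equation(eq)
        rev = rev or rev_eq
        model.add_reaction(
            Reaction(
                id=rid, name=name, stoichiometry=stoich,
                lower_bound=-_BIG if rev else 0.0, upper_bound=_BIG,
                subsystem=subsystem, gpr=gpr,
            )
        )

    energetics = EnergeticParameters(game=spec.game, ngame=spec.ngame)
    composition = core_biomass_composition(spec.condition)
    biomass = build_biomass_reaction(composition, energetics, model)
    model.add_reaction(biomass)
    model.add_reaction(
        Reaction(
            id="EX_biomass", name="biomass drain",
            stoichiometry={"biomass_c": -1.0},
            lower_bound=0.0, upper_bound=_BIG,
            subsystem="Exchange", is_exchange=True,
        )
    )
    model = install_ngame_reaction(model, energetics)
    model.objective_id = "BIOMASS"
    model.validate()
    if str(spec.ph) != "7":
        model = adjust_model_to_ph(model, str(spec.ph))
    if spec.declared_sizes:
        from .core import model_statistics

        stats = model_statistics(model).as_dict()
        for key, val in spec.declared_sizes.items():
            if stats.get(key) != val:
                raise ValueError(
                    f"declared size {key}={val} does not match generated "
                    f"model ({stats.get(key)})"
                )
    return model


def declared_core_sizes(spec: Optional[CoreModelSpec] = None) -> Dict[str, int]:
    """Bookkeeping sizes of the generated model (for statistics tests)."""
    spec = spec or CoreModelSpec()
    n_exchange = len(_EXCHANGES) + 1          # + biomass drain
    n_transport = len(_TRANSPORTERS)
    n_internal = (
        len(_INTERNAL) + 7 + (1 if spec.include_pfk else 0) + 2
    )  # + FAS chains + biomass + NGAME
    return {
        "n_reactions_redundant": n_exchange + n_transport + n_internal,
        "n_transport": n_exchange + n_transport,
        "n_biochemical": n_internal,
    }


# ---------------------------------------------------------------------------
# Chemostat data
# ---------------------------------------------------------------------------

@dataclass
class ChemostatDataset:
    """(dilution rate, substrate uptake) records for maintenance calibration."""

    records: List[Tuple[float, float]] = field(default_factory=list)
    substrate_id: str = "EX_fru"

    def validate(self) -> None:
        if any(d <= 0 for d, _ in self.records):
            raise ValueError("dilution rates must be positive")
        if len({d for d, _ in self.records}) < 2:
            raise ValueError("need at least 2 distinct dilution rates")

    @property
    def dilution_rates(self) -> List[float]:
        return [d for d, _ in self.records]

    @property
    def uptake_rates(self) -> List[float]:
        return [u for _, u in self.records]


DEFAULT_DILUTION_RATES = (0.05, 0.07, 0.10)


def generate_chemostat_dataset(
    game: float,
    ngame: float,
    dilution_rates: Sequence[float] = DEFAULT_DILUTION_RATES,
    replicates: int = 1,
    noise_sd_fraction: float = 0.0,
    seed: int = 0,
    model: Optional[MetabolicModel] = None,
) -> ChemostatDataset:
    """Simulate chemostat fructose-uptake data with known energetics.

    Uptake at each dilution rate D is the core model's minimal fructose
    uptake at growth fixed to D (the same inner objective the calibration
    uses), perturbed by multiplicative Gaussian noise of the given relative
    standard deviation.  Seed-deterministic.
    """
    from .calibration import predicted_uptake

    if noise_sd_fraction < 0:
        raise ValueError("noise_sd_fraction must be >= 0")
    if model is None:
        model = generate_core_model(CoreModelSpec(game=game, ngame=ngame))
    energetics = EnergeticParameters(game=game, ngame=ngame)
    rng = np.random.default_rng(seed)
    cap = _max_feasible_growth(model, energetics)
    records: List[Tuple[float, float]] = []
    for d in dilution_rates:
        uptake = predicted_uptake(model, energetics, d)
        if uptake is None or d > cap + 1e-9:
            raise ValueError(
                f"dilution rate {d} infeasible at the medium's substrate "
                f"cap; maximum feasible growth is {cap:.4f} h^-1"
            )
        for _ in range(replicates):
            noisy = uptake * (1.0 + noise_sd_fraction * rng.standard_normal())
            records.append((d, float(noisy)))
    return ChemostatDataset(records=records, substrate_id="EX_fru")


def _max_feasible_growth(model: MetabolicModel, energetics) -> float:
    from .biomass import install_ngame_reaction, set_game
    from .fba import FluxConstraintSet, fba

    m = set_game(model, energetics)
    m = install_ngame_reaction(m, energetics)
    res = fba(m, FluxConstraintSet())
    return res.objective_value if res.ok else 0.0
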