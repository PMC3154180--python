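"""The four in-silico studies as reproducible pipeline stages.

Each scenario takes a compatible model (the bundled core model or any model
exposing the same reaction ids for exchanges, biomass and maintenance), a
constraint set, and returns plain data structures.  All scenarios keep the
global organic-acid-secretion lockout unless a stage explicitly relaxes a
named valve (each such relaxation is part of that study's stated condition).

Studies
-------
* ``gas_sweep`` — lithoautotrophic growth over (H2, CO2) uptake grids at a
  fixed O2 supply, with fructose closed and the CBB route active.
* ``cn_sweep`` — PHB production vs nitrogen availability at capped fructose,
  on the nitrogen-limited biomass composition.
* ``ph_comparison`` — PHB yield across the pH 6/7/8 model variants under
  nitrogen limitation.
* ``pfk_variants`` — growth and glycolytic ATP capacity of the wild type,
  the eda-deficient strain, and the pfk-expressing strains.
* ``mca_screen`` — single-gene knockout screen (FBA and MOMA) for
  2-methylcitrate production under a propionate co-feed, with production
  envelopes for the wild type and each top-priority mutant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .core import MetabolicModel, ModelValidationError, Reaction, apply_knockout
from .fba import (
    FluxConstraintSet,
    fba,
    max_atp_yield,
    production_envelope,
    single_knockout_scan,
)

DEFAULT_O2_UPTAKE = 10.0
DEFAULT_FRUCTOSE_CAP = 2.6
DEFAULT_NITROGEN_CAP = 1.0
DEFAULT_PROPIONATE_FEED = 1.0

GAS_GRID_DEFAULT = tuple(np.linspace(0.0, 20.0, 21))
N_GRID_DEFAULT = tuple(np.linspace(0.0, 3.0, 21))


@dataclass
class SweepGrid:
    """Complete grid of scenario outputs.

    ``axes`` maps axis name -> value list; ``growth`` (and optionally
    ``product``) are arrays indexed by the axes in order.  Infeasible cells
    hold growth 0 and are flagged in ``feasible``.
    """

    axes: Dict[str, List[float]]
    growth: np.ndarray
    product: Optional[np.ndarray] = None
    feasible: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        shape = tuple(len(v) for v in self.axes.values())
        if self.growth.shape != shape:
            raise ValueError(f"growth grid shape {self.growth.shape} != {shape}")
        if not np.all(np.isfinite(self.growth)):
            raise ValueError("growth grid contains non-finite values")


def _require_reactions(model: MetabolicModel, ids: Iterable[str], what: str) -> None:
    missing = [rid for rid in ids if rid not in model.reactions]
    if missing:
        raise ModelValidationError(f"{what} requires reactions {missing}")


# ---------------------------------------------------------------------------
# 1. Lithoautotrophic gas sweep
# ---------------------------------------------------------------------------

def gas_sweep(
    model: MetabolicModel,
    h2_values: Sequence[float] = GAS_GRID_DEFAULT,
    co2_values: Sequence[float] = GAS_GRID_DEFAULT,
    o2_uptake: float = DEFAULT_O2_UPTAKE,
    constraints: Optional[FluxConstraintSet] = None,
) -> SweepGrid:
    """Growth over (H2, CO2) uptake bounds with organic carbon closed."""
    _require_reactions(model, ("CBB", "HYDS", "EX_h2", "EX_co2", "EX_o2", "EX_fru"),
                       "lithoautotrophic gas sweep")
    cs = constraints or FluxConstraintSet()
    growth = np.zeros((len(h2_values), len(co2_values)))
    feas = np.zeros_like(growth, dtype=bool)
    for i, h2 in enumerate(h2_values):
        for j, co2 in enumerate(co2_values):
            over = {
                "EX_fru": (0.0, 1000.0),
                "EX_h2": (-float(h2), 1000.0),
                "EX_co2": (-float(co2), 1000.0),
                "EX_o2": (-float(o2_uptake), 1000.0),
            }
            res = fba(model, cs.with_overrides(over))
            ok = res.ok and res.objective_value is not None
            growth[i, j] = max(res.objective_value, 0.0) if ok else 0.0
            feas[i, j] = ok
    return SweepGrid(
        axes={"h2_uptake": list(map(float, h2_values)),
              "co2_uptake": list(map(float, co2_values))},
        growth=growth, feasible=feas,
    )


def gas_sensitivities(grid: SweepGrid) -> Dict[str, float]:
    """Mean |dgrowth/dgas| along each axis, grid-wide and where limiting.

    ``*_mean`` averages finite differences over the whole grid (dominated by
    whichever gas binds over more grid area); ``*_limiting`` averages only
    over cells where the gas actually controls growth (nonzero response) —
    the marginal value of one mmol of that gas where it is scarce, which is
    the quantity the ratio-sensitivity statement concerns.
    """
    h2 = np.asarray(grid.axes["h2_uptake"])
    co2 = np.asarray(grid.axes["co2_uptake"])
    g = grid.growth
    d_h2 = np.diff(g, axis=0) / np.diff(h2)[:, None]
    d_co2 = np.diff(g, axis=1) / np.diff(co2)[None, :]

    def limiting_mean(d: np.ndarray) -> float:
        active = np.abs(d) > 1e-9
        return float(np.abs(d[active]).mean()) if active.any() else 0.0

    return {
        "dgrowth_dh2_mean": float(np.abs(d_h2).mean()),
        "dgrowth_dco2_mean": float(np.abs(d_co2).mean()),
        "dgrowth_dh2_limiting": limiting_mean(d_h2),
        "dgrowth_dco2_limiting": limiting_mean(d_co2),
    }


# ---------------------------------------------------------------------------
# 2. C/N sweep for PHB
# ---------------------------------------------------------------------------

def cn_sweep(
    model_nlimited: MetabolicModel,
    fructose_cap: float = DEFAULT_FRUCTOSE_CAP,
    n_values: Sequence[float] = N_GRID_DEFAULT,
    constraints: Optional[FluxConstraintSet] = None,
) -> Tuple[SweepGrid, List[Dict[str, float]]]:
    """Growth and PHB secretion vs nitrogen uptake at capped fructose.

    Per nitrogen level: maximize growth, then maximize PHB secretion at that
    optimum (deterministic tie-break across alternate optima).  Returns the
    grid plus per-point records including the realized C/N uptake ratio
    (mmol fructose per mmol nitrogen).
    """
    _require_reactions(model_nlimited, ("PHAA", "PHAB", "PHAC", "EX_phb", "EX_nh4"),
                       "C/N sweep")
    cs = constraints or FluxConstraintSet()
    growth = np.zeros(len(n_values))
    phb = np.zeros(len(n_values))
    feas = np.zeros(len(n_values), dtype=bool)
    records: List[Dict[str, float]] = []
    for k, n in enumerate(n_values):
        over = {
            "EX_fru": (-float(fructose_cap), 1000.0),
            "EX_nh4": (-float(n), 1000.0),
        }
        res = fba(model_nlimited, cs.with_overrides(over))
        if not res.ok:
            records.append({"nitrogen_uptake": float(n), "growth": 0.0,
                            "phb": 0.0, "fructose_uptake": 0.0,
                            "nitrogen_uptake_actual": 0.0,
                            "cn_ratio": float("nan"), "feasible": 0.0})
            continue
        g = max(res.objective_value, 0.0)
        tie = cs.with_overrides(
            {**over, model_nlimited.objective_id: (g, g)}
        )
        res2 = fba(model_nlimited, tie, objective="EX_phb", sense="max")
        p = max(res2.objective_value, 0.0) if res2.ok else 0.0
        fru_uptake = -res2.fluxes.get("EX_fru", 0.0) if res2.ok else 0.0
        n_uptake = -res2.fluxes.get("EX_nh4", 0.0) if res2.ok else 0.0
        growth[k], phb[k], feas[k] = g, p, True
        records.append({
            "nitrogen_uptake": float(n), "growth": g, "phb": p,
            "fructose_uptake": fru_uptake,
            "nitrogen_uptake_actual": n_uptake,
            "cn_ratio": fru_uptake / n_uptake if n_uptake > 1e-9 else float("inf"),
            "feasible": 1.0,
        })
    grid = SweepGrid(
        axes={"nitrogen_uptake": list(map(float, n_values))},
        growth=growth, product=phb, feasible=feas,
    )
    return grid, records


# ---------------------------------------------------------------------------
# 3. pH comparison
# ---------------------------------------------------------------------------

def ph_comparison(
    models: Mapping[str, MetabolicModel],
    nitrogen_cap: float = DEFAULT_NITROGEN_CAP,
    fructose_cap: float = DEFAULT_FRUCTOSE_CAP,
    constraints: Optional[FluxConstraintSet] = None,
) -> Dict[str, Dict[str, float]]:
    """Growth and PHB yield Y_PHB per pH-variant model.

    Y_PHB = PHB secretion / fructose uptake (mol/mol) at maximal growth with
    the PHB tie-break, under nitrogen limitation.  The model triple must
    share reaction ids.
    """
    ids = None
    for ph, m in models.items():
        rids = set(m.reactions)
        if ids is None:
            ids = rids
        elif rids != ids:
            raise ModelValidationError(
                f"pH-variant models do not share reaction ids (pH {ph} differs)"
            )
    cs = constraints or FluxConstraintSet()
    out: Dict[str, Dict[str, float]] = {}
    for ph, m in models.items():
        over = {
            "EX_fru": (-float(fructose_cap), 1000.0),
            "EX_nh4": (-float(nitrogen_cap), 1000.0),
        }
        res = fba(m, cs.with_overrides(over))
        if not res.ok:
            out[str(ph)] = {"growth": 0.0, "phb": 0.0, "y_phb": 0.0}
            continue
        g = res.objective_value
        res2 = fba(
            m, cs.with_overrides({**over, m.objective_id: (g, g)}),
            objective="EX_phb", sense="max",
        )
        phb = max(res2.objective_value, 0.0) if res2.ok else 0.0
        fru = -res2.fluxes.get("EX_fru", 0.0) if res2.ok else 0.0
        out[str(ph)] = {
            "growth": g, "phb": phb,
            "y_phb": phb / fru if fru > 1e-9 else 0.0,
        }
    return out


# ---------------------------------------------------------------------------
# 4. pfk expression variants
# ---------------------------------------------------------------------------

#: fermentative-capacity conditions for the glycolytic ATP yield: no O2 or
#: alternative acceptors, lactate valve open as the redox sink, maintenance
#: freed — isolates substrate-level phosphorylation, where the EMP route
#: yields exactly twice the ED route per fructose.
def _fermentative_constraints(base: Optional[FluxConstraintSet]) -> FluxConstraintSet:
    zeroed = set((base or FluxConstraintSet()).zeroed_secretions) - {"EX_lac"}
    cs = FluxConstraintSet(dict((base or FluxConstraintSet()).overrides), zeroed)
    return cs.with_overrides(
        {"EX_o2": (0.0, 1000.0), "EX_no3": (0.0, 0.0), "EX_no2": (0.0, 0.0)}
    )


def pfk_variants(
    model: MetabolicModel,
    pfk_reaction: Optional[Reaction] = None,
    constraints: Optional[FluxConstraintSet] = None,
    fructose_cap: float = DEFAULT_FRUCTOSE_CAP,
) -> List[Dict[str, float]]:
    """Growth and maximal ATP yield for the four glycolytic variants.

    I wild type (ED only), II eda-deficient, III eda-deficient + pfk,
    IV wild type + pfk.  Growth is aerobic FBA at the fructose cap; the ATP
    yield is the fermentative (substrate-level) capacity per mol fructose.
    """
    if not any("eda" in r.gpr.lower().split() or r.gpr.lower() == "eda"
               for r in model.reactions.values()):
        raise ModelValidationError("model has no eda-associated reaction")
    if pfk_reaction is None:
        pfk_reaction = _default_pfk_template()
    if any(
        r.gpr.lower() == pfk_reaction.gpr.lower() and r.gpr
        for r in model.reactions.values()
    ):
        raise ModelValidationError("model already contains a pfk reaction")

    def with_pfk(m: MetabolicModel) -> MetabolicModel:
        out = m.copy()
        rxn = Reaction(**{**pfk_reaction.__dict__})
        rxn.stoichiometry = dict(pfk_reaction.stoichiometry)
        out.add_reaction(rxn)
        return out

    variants = {
        "I": model,
        "II": apply_knockout(model, {"eda"}),
        "III": apply_knockout(with_pfk(model), {"eda"}),
        "IV": with_pfk(model),
    }
    cs = constraints or FluxConstraintSet()
    aerobic = cs.with_overrides({"EX_fru": (-float(fructose_cap), 1000.0)})
    ferm = _fermentative_constraints(constraints)
    rows = []
    for label, m in variants.items():
        res = fba(m, aerobic)
        g = max(res.objective_value, 0.0) if res.ok else 0.0
        atp = max_atp_yield(m, ferm, substrate_exchange="EX_fru", uptake=1.0)
        rows.append({"variant": label, "growth": g, "max_atp_yield": atp})
    return rows


def _default_pfk_template() -> Reaction:
    from .synthetic import _PFK  # the core model's insertion template
    from .core import parse_equation

    rid, name, eq, _rev, subsystem, gpr = _PFK
    stoich, _ = parse_equation(eq)
    return Reaction(id=rid, name=name, stoichiometry=stoich,
                    lower_bound=0.0, upper_bound=1000.0,
                    subsystem=subsystem, gpr=gpr)


# ---------------------------------------------------------------------------
# 5. 2-methylcitrate knockout screen
# ---------------------------------------------------------------------------

@dataclass
class McaScreenResult:
    fba_ranking: List[Tuple[str, float, float, int]]
    moma_ranking: List[Tuple[str, float, float, int]]
    top_class: List[str]
    wildtype_growth: float
    mutant_growth_percent: Dict[str, float]
    envelopes: Dict[str, List[Tuple[float, float, float]]]


def mca_screen(
    model: MetabolicModel,
    propionate_feed: float = DEFAULT_PROPIONATE_FEED,
    constraints: Optional[FluxConstraintSet] = None,
    genes: Optional[Iterable[str]] = None,
    envelope_points: int = 11,
) -> McaScreenResult:
    """Knockout targets for 2-methylcitrate production, FBA and MOMA.

    A fixed propionate co-uptake (the experimental co-feeding strategy for
    methylcitrate production) supplies propionyl-CoA; knockouts of the
    cycle's consumption steps then force 2-MCA secretion.  The scan ranks
    every gene by maximal production at the knockout's growth; envelopes are
    reported for the wild type and each top-class mutant, with mutant
    optimal growth as percent of the wild-type optimum.
    """
    _require_reactions(
        model, ("PRPC", "PRPD", "ACNM", "PRPB", "EX_2mca", "EX_prp"),
        "2-methylcitrate screen",
    )
    for rid, gene in (("PRPB", "prpb"), ("PRPD", "prpd"), ("ACNM", "acnm"),
                      ("PRPC", "prpc")):
        if model.reactions[rid].gpr.lower() != gene:
            raise ModelValidationError(
                f"reaction {rid} lacks its {gene} gene association"
            )
    cs = (constraints or FluxConstraintSet()).with_overrides(
        {"EX_prp": (-float(propionate_feed), -float(propionate_feed))}
    )
    fba_rank = single_knockout_scan(model, cs, genes=genes,
                                    target="EX_2mca", method="fba")
    moma_rank = single_knockout_scan(model, cs, genes=genes,
                                     target="EX_2mca", method="moma")
    top = sorted(g for g, _, prod, c in fba_rank if c == 1 and prod > 1e-6)
    wt = fba(model, cs)
    wt_growth = wt.objective_value if wt.ok else 0.0
    envelopes = {"wild_type": production_envelope(
        model, cs, target="EX_2mca", n_points=envelope_points)}
    growth_pct = {}
    for gene in top:
        mutant = apply_knockout(model, {gene})
        res = fba(mutant, cs)
        g = res.objective_value if res.ok else 0.0
        growth_pct[gene] = 100.0 * g / wt_growth if wt_growth > 0 else 0.0
        envelopes[gene] = production_envelope(
            mutant, cs, target="EX_2mca", n_points=envelope_points)
    return McaScreenResult(
        fba_ranking=fba_rank,
        moma_ranking=moma_rank,
        top_class=top,
        wildtype_growth=wt_growth,
        mutant_growth_percent=growth_pct,
        envelopes=envelopes,
    )
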