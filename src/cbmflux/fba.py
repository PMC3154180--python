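"""LP/QP core: FBA, FVA, MOMA, knockout scans, envelopes, ATP yields.

All linear programs are solved with scipy's HiGHS backend at fixed tolerances
(feasibility/optimality 1e-9), which makes every run deterministic.  The LP
contract is the objective value; flux vectors at degenerate optima are one of
possibly many alternate solutions — FVA is the tool that quantifies the
alternate-optimum space, exactly as it is used in the underlying study.

The MOMA quadratic program min ||v - v_wt||^2 s.t. S.v = 0, l <= v <= u is a
strictly convex QP — the Euclidean projection of the wild-type flux vector
onto the mutant's flux polytope — solved by operator splitting (ADMM over
the affine subspace S.v = 0 and the bound box, with the affine projection
precomputed from a pseudo-inverse).  The minimizer is unique, so the result
is deterministic and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import optimize, sparse

from .core import (
    MetabolicModel,
    ModelValidationError,
    Reaction,
    apply_knockout,
    build_stoichiometric_matrix,
)

FEASIBILITY_TOL = 1e-9
OPTIMALITY_TOL = 1e-9
TIE_TOL = 1e-6

#: exchange reactions closed by default: the organism secretes no organic
#: acids or ethanol during batch growth, so these valves are constrained to 0
DEFAULT_ZEROED_SECRETIONS = ("EX_ac", "EX_lac", "EX_pyr", "EX_etoh")


@dataclass
class FluxConstraintSet:
    """Named bound overrides plus the organic-acid secretion lockout."""

    overrides: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    zeroed_secretions: Set[str] = field(
        default_factory=lambda: set(DEFAULT_ZEROED_SECRETIONS)
    )

    def with_overrides(self, more: Mapping[str, Tuple[float, float]]) -> "FluxConstraintSet":
        merged = dict(self.overrides)
        merged.update(more)
        return FluxConstraintSet(merged, set(self.zeroed_secretions))

    def bounds_for(self, model: MetabolicModel) -> List[Tuple[float, float]]:
        for rid, (lo, hi) in self.overrides.items():
            if rid not in model.reactions:
                raise ModelValidationError(
                    f"constraint override references unknown reaction {rid!r}"
                )
            if lo > hi:
                raise ModelValidationError(
                    f"constraint override for {rid!r} has lower {lo} > upper {hi}"
                )
        out = []
        for rid, rxn in model.reactions.items():
            lo, hi = rxn.lower_bound, rxn.upper_bound
            if rid in self.zeroed_secretions:
                lo, hi = 0.0, 0.0
            if rid in self.overrides:
                lo, hi = self.overrides[rid]
            out.append((lo, hi))
        return out


@dataclass
class FluxResult:
    status: str  # optimal | infeasible | unbounded
    objective_value: Optional[float]
    fluxes: Dict[str, float] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


@dataclass
class FluxRange:
    reaction_id: str
    min_flux: float
    max_flux: float


def _empty_constraints() -> FluxConstraintSet:
    return FluxConstraintSet(zeroed_secretions=set())


def _solve_lp(
    S: np.ndarray,
    bounds: Sequence[Tuple[float, float]],
    c: np.ndarray,
    extra_A_ub: Optional[np.ndarray] = None,
    extra_b_ub: Optional[np.ndarray] = None,
) -> optimize.OptimizeResult:
    return optimize.linprog(
        c,
        A_ub=extra_A_ub,
        b_ub=extra_b_ub,
        A_eq=sparse.csr_matrix(S),
        b_eq=np.zeros(S.shape[0]),
        bounds=list(bounds),
        method="highs",
        options={
            "presolve": True,
            "primal_feasibility_tolerance": FEASIBILITY_TOL,
            "dual_feasibility_tolerance": OPTIMALITY_TOL,
        },
    )


_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


def fba(
    model: MetabolicModel,
    constraints: Optional[FluxConstraintSet] = None,
    objective: Optional[str] = None,
    sense: str = "max",
) -> FluxResult:
    """Flux balance analysis: optimize one reaction's flux s.t. S.v = 0.

    Only the reactions named in ``constraints.zeroed_secretions`` that exist
    in the model are closed; overrides must reference existing reactions.
    """
    if constraints is None:
        constraints = FluxConstraintSet()
    objective = objective or model.objective_id
    if objective not in model.reactions:
        raise ModelValidationError(f"objective reaction {objective!r} not in model")
    S = build_stoichiometric_matrix(model)
    rids = model.reaction_ids
    cs = FluxConstraintSet(
        dict(constraints.overrides),
        {z for z in constraints.zeroed_secretions if z in model.reactions},
    )
    bounds = cs.bounds_for(model)
    c = np.zeros(len(rids))
    c[rids.index(objective)] = -1.0 if sense == "max" else 1.0
    res = _solve_lp(S, bounds, c)
    status = _STATUS.get(res.status, "infeasible")
    if status != "optimal":
        return FluxResult(status=status, objective_value=None)
    obj = float(res.x[rids.index(objective)])
    return FluxResult(
        status="optimal",
        objective_value=obj,
        fluxes={rid: float(v) for rid, v in zip(rids, res.x)},
    )


def parsimonious_fluxes(
    model: MetabolicModel,
    constraints: Optional[FluxConstraintSet] = None,
    objective: Optional[str] = None,
) -> FluxResult:
    """FBA followed by minimization of total |v| at the fixed optimum.

    Used as the deterministic, seed-free wild-type reference for MOMA: the
    plain FBA flux vector is one of many alternate optima, while the minimal
    total-flux solution of the optimum face is reproducible.
    """
    base = fba(model, constraints, objective)
    if not base.ok:
        return base
    objective = objective or model.objective_id
    S = build_stoichiometric_matrix(model)
    rids = model.reaction_ids
    n = len(rids)
    cs = constraints or FluxConstraintSet()
    cs = FluxConstraintSet(
        dict(cs.overrides), {z for z in cs.zeroed_secretions if z in model.reactions}
    )
    bounds = cs.bounds_for(model)
    j = rids.index(objective)
    lo, hi = bounds[j]
    bounds = list(bounds)
    bounds[j] = (base.objective_value - 1e-9, min(hi, base.objective_value + 1e-9))
    # split v = p - q, p,q >= 0 to minimize sum(p + q)
    S2 = np.hstack([S, -S])
    b2 = [(max(l, 0.0), max(u, 0.0)) for l, u in bounds]
    b2 += [(max(-u, 0.0), max(-l, 0.0)) for l, u in bounds]
    c2 = np.ones(2 * n)
    res = _solve_lp(S2, b2, c2)
    if _STATUS.get(res.status) != "optimal":
        return base
    v = res.x[:n] - res.x[n:]
    return FluxResult(
        status="optimal",
        objective_value=float(v[j]),
        fluxes={rid: float(x) for rid, x in zip(rids, v)},
    )


def fva(
    model: MetabolicModel,
    constraints: Optional[FluxConstraintSet] = None,
    objective: Optional[str] = None,
    objective_fraction: float = 1.0,
    reactions: Optional[Iterable[str]] = None,
) -> List[FluxRange]:
    """Flux variability analysis at a fixed objective level.

    For each reaction the minimal and maximal flux is computed subject to
    objective >= objective_fraction * optimum (default: the full optimum, as
    in the study's use of FVA at maximum growth).
    """
    objective = objective or model.objective_id
    base = fba(model, constraints, objective)
    if not base.ok:
        raise ModelValidationError(
            f"FVA requires an optimal base FBA solution (status {base.status})"
        )
    S = build_stoichiometric_matrix(model)
    rids = model.reaction_ids
    cs = constraints or FluxConstraintSet()
    cs = FluxConstraintSet(
        dict(cs.overrides), {z for z in cs.zeroed_secretions if z in model.reactions}
    )
    bounds = list(cs.bounds_for(model))
    j = rids.index(objective)
    target = objective_fraction * base.objective_value
    # objective >= target, with a tiny slack against round-off at fraction 1.0
    A_ub = np.zeros((1, len(rids)))
    A_ub[0, j] = -1.0
    b_ub = np.array([-(target - 1e-9 * max(1.0, abs(target)))])
    wanted = list(reactions) if reactions is not None else rids
    out: List[FluxRange] = []
    for rid in wanted:
        k = rids.index(rid)
        lo_hi = []
        for sense in (1.0, -1.0):
            c = np.zeros(len(rids))
            c[k] = sense
            res = _solve_lp(S, bounds, c, A_ub, b_ub)
            if _STATUS.get(res.status) != "optimal":
                raise ModelValidationError(
                    f"FVA subproblem for reaction {rid!r} failed "
                    f"(status {_STATUS.get(res.status, res.status)})"
                )
            lo_hi.append(float(res.x[k]))
        out.append(FluxRange(rid, min_flux=lo_hi[0], max_flux=lo_hi[1]))
    return out


# ---------------------------------------------------------------------------
# MOMA
# ---------------------------------------------------------------------------

def moma(
    model_mutant: MetabolicModel,
    constraints: Optional[FluxConstraintSet] = None,
    wildtype_fluxes: Optional[Mapping[str, float]] = None,
) -> FluxResult:
    """Minimization of metabolic adjustment.

    Finds the mutant-feasible flux vector closest (squared Euclidean
    distance) to the wild-type distribution and reports the growth flux it
    implies.  The objective_value is the flux of the model's objective
    reaction in the minimizing vector, not the distance; the distance is
    reported in ``fluxes`` space implicitly.
    """
    if wildtype_fluxes is None:
        raise ValueError("moma requires wild-type reference fluxes")
    S = build_stoichiometric_matrix(model_mutant)
    rids = model_mutant.reaction_ids
    cs = constraints or FluxConstraintSet()
    cs = FluxConstraintSet(
        dict(cs.overrides),
        {z for z in cs.zeroed_secretions if z in model_mutant.reactions},
    )
    bounds = cs.bounds_for(model_mutant)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    w = np.array([wildtype_fluxes.get(rid, 0.0) for rid in rids])

    # feasibility check + starting point: LP minimizing nothing
    feas = _solve_lp(S, bounds, np.zeros(len(rids)))
    if _STATUS.get(feas.status) != "optimal":
        return FluxResult(status="infeasible", objective_value=None)
    x0 = np.clip(feas.x, lo, hi)

    # if the wild type itself is feasible in the mutant, distance is 0
    w_clipped = np.clip(w, lo, hi)
    if np.allclose(w_clipped, w, atol=1e-12) and np.max(np.abs(S @ w)) < 1e-6:
        obj = None
        if model_mutant.objective_id:
            obj = float(w[rids.index(model_mutant.objective_id)])
        return FluxResult(
            status="optimal", objective_value=obj,
            fluxes={rid: float(v) for rid, v in zip(rids, w)},
        )

    v = _project_onto_polytope(S, lo, hi, w, x0)
    if v is None or np.max(np.abs(S @ v)) > 1e-5:
        return FluxResult(status="infeasible", objective_value=None)
    obj = None
    if model_mutant.objective_id:
        obj = float(v[rids.index(model_mutant.objective_id)])
    return FluxResult(
        status="optimal",
        objective_value=obj,
        fluxes={rid: float(x) for rid, x in zip(rids, v)},
    )


def _project_onto_polytope(
    S: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    w: np.ndarray,
    x0: np.ndarray,
    rho: float = 2.0,
    max_iter: int = 20000,
    tol: float = 1e-10,
) -> Optional[np.ndarray]:
    """Euclidean projection of w onto {v : S v = 0, lo <= v <= hi} by ADMM.

    The x-step minimizes ||x - w||^2 + (rho/2)||x - z + u||^2 on the null
    space of S (closed form through the orthogonal projector P = I - S^+ S);
    the z-step clips to the box.  Strict convexity gives a unique limit.
    """
    n = S.shape[1]
    P = np.eye(n) - np.linalg.pinv(S, rcond=1e-10) @ S
    z = np.clip(x0, lo, hi)
    u = np.zeros(n)
    x = z.copy()
    for it in range(max_iter):
        x = P @ ((2.0 * w + rho * (z - u)) / (2.0 + rho))
        z_new = np.clip(x + u, lo, hi)
        du = x - z_new
        u += du
        r_dual = rho * np.max(np.abs(z_new - z))
        z = z_new
        if np.max(np.abs(du)) < tol and r_dual < tol:
            break
    v = np.clip(x, lo, hi)
    if np.max(np.abs(v - x)) > 1e-6:
        return None
    return v


# ---------------------------------------------------------------------------
# Knockout scanning and envelopes
# ---------------------------------------------------------------------------

def _max_production_at_growth(
    model: MetabolicModel,
    constraints: FluxConstraintSet,
    target: str,
    growth_rxn: str,
    growth: float,
) -> float:
    cs = constraints.with_overrides({growth_rxn: (growth, growth)})
    res = fba(model, cs, objective=target, sense="max")
    return res.objective_value if res.ok else 0.0


def single_knockout_scan(
    model: MetabolicModel,
    constraints: Optional[FluxConstraintSet] = None,
    genes: Optional[Iterable[str]] = None,
    target: Optional[str] = None,
    method: str = "fba",
) -> List[Tuple[str, float, float, int]]:
    """Single-gene knockout scan ranked by maximal target production.

    For each gene: apply the knockout, evaluate growth (FBA or MOMA against
    the parsimonious wild-type reference), then the maximal target flux at
    that growth.  Returns (gene, growth, max_production, priority_class)
    sorted by production (descending); productions equal within 1e-6 share a
    priority class, the top class being 1.  Infeasible knockouts are reported
    with growth 0 and production 0.
    """
    if target is None or target not in model.reactions:
        raise ModelValidationError(f"knockout-scan target {target!r} not in model")
    constraints = constraints or FluxConstraintSet()
    gene_list = sorted(genes) if genes is not None else sorted(model.genes)
    growth_rxn = model.objective_id
    wt = None
    if method == "moma":
        wt = parsimonious_fluxes(model, constraints)
        if not wt.ok:
            raise ModelValidationError("wild-type model infeasible; cannot run MOMA")
    rows: List[Tuple[str, float, float]] = []
    for gene in gene_list:
        mutant = apply_knockout(model, {gene})
        if method == "moma":
            res = moma(mutant, constraints, wt.fluxes)
        else:
            res = fba(mutant, constraints, growth_rxn)
        if not res.ok or res.objective_value is None:
            rows.append((gene, 0.0, 0.0))
            continue
        growth = max(res.objective_value, 0.0)
        prod = _max_production_at_growth(mutant, constraints, target, growth_rxn, growth)
        rows.append((gene, growth, prod))
    rows.sort(key=lambda r: (-r[2], r[0]))
    ranked: List[Tuple[str, float, float, int]] = []
    cls, prev = 0, None
    for gene, growth, prod in rows:
        if prev is None or prev - prod > TIE_TOL:
            cls += 1
            prev = prod
        ranked.append((gene, growth, prod, cls))
    return ranked


def production_envelope(
    model: MetabolicModel,
    constraints: Optional[FluxConstraintSet] = None,
    target: Optional[str] = None,
    objective: Optional[str] = None,
    n_points: int = 21,
) -> List[Tuple[float, float, float]]:
    """(growth fraction %, target min, target max) along the growth axis.

    Growth is fixed at k/(n_points-1) of this model's own optimum for
    k = 0..n_points-1; callers normalize across strains where needed.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    objective = objective or model.objective_id
    constraints = constraints or FluxConstraintSet()
    base = fba(model, constraints, objective)
    if not base.ok:
        raise ModelValidationError("envelope requires a feasible model")
    gmax = base.objective_value
    out = []
    for k in range(n_points):
        g = gmax * k / (n_points - 1)
        cs = constraints.with_overrides({objective: (g, g)})
        lo = fba(model, cs, objective=target, sense="min")
        hi = fba(model, cs, objective=target, sense="max")
        out.append(
            (
                100.0 * k / (n_points - 1),
                lo.objective_value if lo.ok else float("nan"),
                hi.objective_value if hi.ok else float("nan"),
            )
        )
    return out


def max_atp_yield(
    model: MetabolicModel,
    constraints: Optional[FluxConstraintSet] = None,
    substrate_exchange: str = "EX_fru",
    uptake: float = 1.0,
    atp_drain: str = "ATPM",
) -> float:
    """Maximal ATP-drain flux per unit substrate uptake, growth fixed at 0.

    The maintenance reaction doubles as the drain: its bounds are freed and
    maximized while the substrate exchange is fixed at the requested uptake
    (negative flux = uptake) and the growth reaction is closed.  The result
    is mol ATP per mol substrate.
    """
    if atp_drain not in model.reactions:
        raise ModelValidationError(f"ATP drain reaction {atp_drain!r} not in model")
    if uptake < 0:
        raise ValueError("uptake must be non-negative")
    constraints = constraints or FluxConstraintSet()
    over = {
        atp_drain: (0.0, 1e6),
        substrate_exchange: (-uptake, -uptake),
    }
    if model.objective_id:
        over[model.objective_id] = (0.0, 0.0)
    res = fba(model, constraints.with_overrides(over), objective=atp_drain)
    if not res.ok:
        return 0.0
    # at zero uptake the raw drain flux is reported (no mole basis to scale)
    return res.objective_value / uptake if uptake > 0 else res.objective_value


def normalize_fluxes(result: FluxResult, reference: str) -> Dict[str, float]:
    """Fluxes as percent of |reference flux| (the carbon-uptake convention)."""
    if reference not in result.fluxes:
        raise KeyError(f"reference reaction {reference!r} not in flux result")
    ref = abs(result.fluxes[reference])
    if ref == 0:
        raise ZeroDivisionError(
            f"reference flux {reference!r} is zero; cannot normalize"
        )
    return {rid: 100.0 * v / ref for rid, v in result.fluxes.items()}


def audit_solution(model: MetabolicModel, result: FluxResult,
                   constraints: Optional[FluxConstraintSet] = None,
                   tol_mass: float = 1e-6, tol_bounds: float = 1e-6) -> None:
    """Post-solve audit: |S.v| <= tol componentwise and bounds respected."""
    if not result.ok:
        return
    S = build_stoichiometric_matrix(model)
    rids = model.reaction_ids
    v = np.array([result.fluxes[rid] for rid in rids])
    resid = np.max(np.abs(S @ v))
    if resid > tol_mass:
        raise AssertionError(f"mass balance violated: max |S.v| = {resid:g}")
    cs = constraints or _empty_constraints()
    cs = FluxConstraintSet(
        dict(cs.overrides), {z for z in cs.zeroed_secretions if z in model.reactions}
    )
    for (lo, hi), rid, x in zip(cs.bounds_for(model), rids, v):
        if x < lo - tol_bounds or x > hi + tol_bounds:
            raise AssertionError(
                f"flux {rid}={x:g} outside bounds [{lo:g}, {hi:g}]"
            )
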