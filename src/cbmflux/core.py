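"""Domain model for constraint-based metabolic networks.

Metabolites carry elemental formulas and pH-resolved charges; reactions carry
stoichiometry, flux bounds (mmol gDCW^-1 h^-1) and boolean gene-protein-reaction
(GPR) rules.  A :class:`MetabolicModel` is the container from which the
stoichiometric matrix S (metabolites x reactions) is built; the pseudo-steady
state assumption S.v = 0 is what every flux analysis downstream solves against.

The model is two-compartment (cytosol ``c`` / external ``e``); exchange
reactions touch exactly one (external) metabolite, with a negative lower bound
meaning uptake is allowed.
"""

from __future__ import annotations

import copy as _copy
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

PH_LABELS = ("6", "7", "8")

#: elements tracked by the balance checker, in reporting order
ELEMENTS = ("C", "H", "N", "O", "P", "S")

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")


class ModelValidationError(ValueError):
    """Structural problem in a model (dangling reference, bad bounds, ...)."""


class GPRSyntaxError(ValueError):
    """Raised when a gene-protein-reaction rule fails to parse."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at token position {position})")
        self.position = position


def parse_formula(text: str) -> Dict[str, float]:
    """Parse ``C6H12O6``-style formulas into an element -> count map.

    Fractional counts are allowed (macromolecular pseudo-species such as the
    biomass metabolite have non-integer compositions).
    """
    if not text or text in ("-", "X"):
        return {}
    out: Dict[str, float] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {text!r} at offset {pos}")
        pos = m.end()
        elem, num = m.group(1), m.group(2)
        n = float(num) if num else 1.0
        if n < 0:
            raise ValueError(f"negative count for {elem} in {text!r}")
        out[elem] = out.get(elem, 0.0) + n
    if pos != len(text):
        raise ValueError(f"cannot parse formula {text!r} at offset {pos}")
    return {k: v for k, v in out.items() if v != 0}


def format_formula(formula: Mapping[str, float]) -> str:
    """Inverse of :func:`parse_formula` (Hill-ish ordering, C, H, then rest)."""
    if not formula:
        return "-"

    def fmt(n: float) -> str:
        if abs(n - round(n)) < 1e-9:
            return "" if round(n) == 1 else str(int(round(n)))
        return format(n, ".6g")

    keys = sorted(formula, key=lambda e: (e != "C", e != "H", e))
    return "".join(f"{k}{fmt(formula[k])}" for k in keys if formula[k] != 0)


@dataclass
class Metabolite:
    """A chemical species in one compartment.

    ``charge_by_ph`` maps the pH label ("6" | "7" | "8") to the (integer,
    model-building) charge of the species at that pH; ``formula`` is the
    elemental composition of the charge state at the *model's own* pH.
    ``pka_list``/``base_charge`` optionally record the protonation profile the
    charges were derived from (see :mod:`cbmflux.ph`).
    """

    id: str
    name: str = ""
    formula: Dict[str, float] = field(default_factory=dict)
    charge_by_ph: Dict[str, float] = field(default_factory=dict)
    compartment: str = "c"
    pka_list: Optional[List[float]] = None
    base_charge: Optional[int] = None

    def charge(self, ph: str) -> float:
        try:
            return self.charge_by_ph[str(ph)]
        except KeyError:
            raise KeyError(
                f"metabolite {self.id!r} has no charge entry for pH {ph}"
            ) from None


@dataclass
class Reaction:
    """A stoichiometric conversion with flux bounds and an optional GPR.

    Stoichiometry maps metabolite id -> coefficient, negative = consumed.
    ``reversible`` is *derived*: a reaction is reversible iff its lower bound
    is negative.
    """

    id: str
    name: str = ""
    stoichiometry: Dict[str, float] = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    subsystem: str = ""
    gpr: str = ""
    is_transport: bool = False
    is_exchange: bool = False

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    def validate(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id!r} has empty stoichiometry")
        if self.is_exchange and len(self.stoichiometry) != 1:
            raise ModelValidationError(
                f"exchange reaction {self.id!r} must touch exactly one metabolite"
            )


@dataclass
class ModelStatistics:
    n_reactions_redundant: int
    n_biochemical: int
    n_transport: int
    n_reactions_unique: int
    n_metabolites: int
    n_genes: int

    def as_dict(self) -> Dict[str, int]:
        return dict(self.__dict__)


class MetabolicModel:
    """Ordered collection of metabolites and reactions plus an objective."""

    def __init__(
        self,
        metabolites: Iterable[Metabolite] = (),
        reactions: Iterable[Reaction] = (),
        objective_id: Optional[str] = None,
        ph_condition: str = "7",
        id: str = "model",
    ):
        self.id = id
        self.metabolites: Dict[str, Metabolite] = {}
        self.reactions: Dict[str, Reaction] = {}
        self.objective_id = objective_id
        self.ph_condition = str(ph_condition)
        for m in metabolites:
            self.add_metabolite(m)
        for r in reactions:
            self.add_reaction(r)

    # -- construction -----------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ModelValidationError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ModelValidationError(f"duplicate reaction id {rxn.id!r}")
        self.reactions[rxn.id] = rxn

    def remove_reaction(self, rxn_id: str) -> None:
        del self.reactions[rxn_id]

    def copy(self) -> "MetabolicModel":
        return _copy.deepcopy(self)

    # -- views ------------------------------------------------------------
    @property
    def reaction_ids(self) -> List[str]:
        return list(self.reactions)

    @property
    def metabolite_ids(self) -> List[str]:
        return list(self.metabolites)

    @property
    def genes(self) -> Set[str]:
        out: Set[str] = set()
        for r in self.reactions.values():
            out |= gpr_genes(r.gpr)
        return out

    def validate(self) -> None:
        for r in self.reactions.values():
            r.validate()
            for mid in r.stoichiometry:
                if mid not in self.metabolites:
                    raise ModelValidationError(
                        f"reaction {r.id!r} references unknown metabolite {mid!r}"
                    )
        if self.objective_id is not None and self.objective_id not in self.reactions:
            raise ModelValidationError(
                f"objective reaction {self.objective_id!r} not in model"
            )

    def __repr__(self) -> str:  # pragma: no cover - debugging nicety
        return (
            f"<MetabolicModel {self.id}: {len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions, pH {self.ph_condition}>"
        )


# ---------------------------------------------------------------------------
# Stoichiometric matrix
# ---------------------------------------------------------------------------

def build_stoichiometric_matrix(model: MetabolicModel) -> np.ndarray:
    """S matrix, metabolites (rows, model order) x reactions (columns).

    Entry (i, j) is the coefficient of metabolite i in reaction j; the sign
    convention is negative = consumed.  Raises
    :class:`ModelValidationError` on dangling metabolite references.
    """
    model.validate()
    met_index = {mid: i for i, mid in enumerate(model.metabolite_ids)}
    S = np.zeros((len(met_index), len(model.reactions)))
    for j, rxn in enumerate(model.reactions.values()):
        for mid, coeff in rxn.stoichiometry.items():
            S[met_index[mid], j] = coeff
    return S


# ---------------------------------------------------------------------------
# Balance checks
# ---------------------------------------------------------------------------

def check_element_balance(
    reaction: Reaction, model: MetabolicModel, tol: float = 1e-9
) -> Dict[str, float]:
    """Net elemental change of a reaction (all-zero map <=> balanced).

    Exchange reactions are boundary conditions, not conversions: they return
    an empty map (balanced by convention).
    """
    if reaction.is_exchange:
        return {}
    net: Dict[str, float] = {}
    for mid, coeff in reaction.stoichiometry.items():
        met = model.metabolites[mid]
        if not met.formula:
            raise ModelValidationError(
                f"metabolite {mid!r} in reaction {reaction.id!r} has no formula"
            )
        for elem, cnt in met.formula.items():
            net[elem] = net.get(elem, 0.0) + coeff * cnt
    return {e: v for e, v in net.items() if abs(v) > tol}


def check_charge_balance(
    reaction: Reaction, model: MetabolicModel, ph: str
) -> float:
    """Net charge of a reaction at the given pH label (0 <=> balanced)."""
    if reaction.is_exchange:
        return 0.0
    net = 0.0
    for mid, coeff in reaction.stoichiometry.items():
        met = model.metabolites[mid]
        if str(ph) not in met.charge_by_ph:
            raise ModelValidationError(
                f"metabolite {mid!r} has no charge at pH {ph} "
                f"(needed by reaction {reaction.id!r})"
            )
        net += coeff * met.charge_by_ph[str(ph)]
    return net


# ---------------------------------------------------------------------------
# GPR rules
# ---------------------------------------------------------------------------

_GPR_TOKEN = re.compile(r"\(|\)|[^\s()]+")


def _tokenize_gpr(expression: str) -> List[str]:
    return _GPR_TOKEN.findall(expression)


def _parse_gpr(tokens: List[str], pos: int) -> Tuple[tuple, int]:
    """Recursive-descent parser.  Grammar: or_expr; OR binds weaker than AND."""

    def parse_atom(p: int) -> Tuple[tuple, int]:
        if p >= len(tokens):
            raise GPRSyntaxError("unexpected end of expression", p)
        tok = tokens[p]
        if tok == "(":
            node, p = parse_or(p + 1)
            if p >= len(tokens) or tokens[p] != ")":
                raise GPRSyntaxError("missing closing parenthesis", p)
            return node, p + 1
        if tok == ")" or tok.upper() in ("AND", "OR"):
            raise GPRSyntaxError(f"unexpected token {tok!r}", p)
        return ("gene", tok.lower()), p + 1

    def parse_and(p: int) -> Tuple[tuple, int]:
        node, p = parse_atom(p)
        while p < len(tokens) and tokens[p].upper() == "AND":
            rhs, p = parse_atom(p + 1)
            node = ("and", node, rhs)
        return node, p

    def parse_or(p: int) -> Tuple[tuple, int]:
        node, p = parse_and(p)
        while p < len(tokens) and tokens[p].upper() == "OR":
            rhs, p = parse_and(p + 1)
            node = ("or", node, rhs)
        return node, p

    return parse_or(pos)


def parse_gpr(expression: str) -> Optional[tuple]:
    """Parse a GPR rule into an AST; empty/blank expressions give ``None``."""
    tokens = _tokenize_gpr(expression or "")
    if not tokens:
        return None
    node, pos = _parse_gpr(tokens, 0)
    if pos != len(tokens):
        raise GPRSyntaxError(f"trailing tokens {tokens[pos:]}", pos)
    return node


def gpr_genes(expression: str) -> Set[str]:
    """Gene ids (lower-cased) referenced by a GPR rule."""
    ast = parse_gpr(expression)
    out: Set[str] = set()

    def walk(node):
        if node is None:
            return
        if node[0] == "gene":
            out.add(node[1])
        else:
            walk(node[1])
            walk(node[2])

    walk(ast)
    return out


def evaluate_gpr(expression: str, knocked_out: Iterable[str]) -> bool:
    """Evaluate a GPR rule with the given genes set to False, others True.

    An empty expression is always active (reactions without gene annotations
    cannot be knocked out).
    """
    ko = {g.lower() for g in knocked_out}
    ast = parse_gpr(expression)
    if ast is None:
        return True

    def ev(node) -> bool:
        kind = node[0]
        if kind == "gene":
            return node[1] not in ko
        if kind == "and":
            return ev(node[1]) and ev(node[2])
        return ev(node[1]) or ev(node[2])

    return ev(ast)


# ---------------------------------------------------------------------------
# Knockouts
# ---------------------------------------------------------------------------

def apply_knockout(
    model: MetabolicModel,
    genes: Iterable[str],
    on_unknown: str = "error",
) -> MetabolicModel:
    """Copy of the model with every GPR-inactivated reaction closed to [0, 0].

    Reactions with empty GPRs are untouched.  ``on_unknown`` is "error" or
    "warn" for genes absent from the model.
    """
    genes = {g.lower() for g in genes}
    unknown = genes - model.genes
    if unknown:
        msg = f"unknown gene(s) in knockout set: {sorted(unknown)}"
        if on_unknown == "error":
            raise ModelValidationError(msg)
        import warnings

        warnings.warn(msg, stacklevel=2)
    mutant = model.copy()
    for rxn in mutant.reactions.values():
        if rxn.gpr and not evaluate_gpr(rxn.gpr, genes):
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    return mutant


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def _canonical_stoichiometry(rxn: Reaction) -> tuple:
    """Direction-normalized, sorted stoichiometry key for deduplication."""
    items = sorted(rxn.stoichiometry.items())
    if items:
        # normalize direction: first (by id) metabolite coefficient negative
        sign = -1.0 if items[0][1] > 0 else 1.0
        items = [(mid, round(sign * c, 9)) for mid, c in items]
    return tuple(items)


def model_statistics(model: MetabolicModel) -> ModelStatistics:
    """Counts for the model feature table.

    Redundant count = all reactions; biochemical excludes transport and
    exchange boundary conditions are counted as transport; unique reactions
    deduplicate identical stoichiometry after sorting metabolite ids and
    normalizing direction.
    """
    n_total = len(model.reactions)
    n_transport = sum(
        1 for r in model.reactions.values() if r.is_transport or r.is_exchange
    )
    n_biochemical = n_total - n_transport
    unique = {_canonical_stoichiometry(r) for r in model.reactions.values()}
    return ModelStatistics(
        n_reactions_redundant=n_total,
        n_biochemical=n_biochemical,
        n_transport=n_transport,
        n_reactions_unique=len(unique),
        n_metabolites=len(model.metabolites),
        n_genes=len(model.genes),
    )


def orf_coverage_percent(n_assigned: int, n_total: int) -> float:
    """Percent of a genome's ORFs assigned to the metabolic network."""
    if n_total <= 0:
        raise ValueError("total ORF count must be positive")
    return 100.0 * n_assigned / n_total


# ---------------------------------------------------------------------------
# Equation-string round trip (the TSV dialect's reaction grammar)
# ---------------------------------------------------------------------------

_ARROWS = ("<=>", "->")


def parse_equation(equation: str) -> Tuple[Dict[str, float], bool]:
    """Parse ``2 A[c] + B[c] -> C[e]`` into (stoichiometry, reversible).

    Metabolite tokens are ``id[compartment]``; the stored metabolite id is
    ``id_compartment``.  ``<=>`` marks reversible reactions.  One side may be
    empty (exchange / sink notation).
    """
    arrow = None
    for a in _ARROWS:
        if a in equation:
            arrow = a
            break
    if arrow is None:
        raise ValueError(f"no arrow ('->' or '<=>') in equation {equation!r}")
    lhs_text, rhs_text = equation.split(arrow, 1)
    stoich: Dict[str, float] = {}

    def add_side(text: str, sign: float) -> None:
        text = text.strip()
        if not text:
            return
        for term in text.split(" + "):
            term = term.strip()
            if not term:
                continue
            parts = term.split()
            if len(parts) == 2:
                coeff = float(parts[0])
                token = parts[1]
            elif len(parts) == 1:
                coeff = 1.0
                token = parts[0]
            else:
                raise ValueError(f"cannot parse term {term!r} in {equation!r}")
            m = re.fullmatch(r"(.+)\[(\w+)\]", token)
            if not m:
                raise ValueError(
                    f"metabolite token {token!r} lacks [compartment] in {equation!r}"
                )
            mid = f"{m.group(1)}_{m.group(2)}"
            stoich[mid] = stoich.get(mid, 0.0) + sign * coeff
    add_side(lhs_text, -1.0)
    add_side(rhs_text, +1.0)
    stoich = {k: v for k, v in stoich.items() if v != 0}
    return stoich, arrow == "<=>"


def format_equation(rxn: Reaction, model: MetabolicModel) -> str:
    """Render a reaction in the TSV dialect's equation grammar."""

    def token(mid: str) -> str:
        comp = model.metabolites[mid].compartment if mid in model.metabolites else "c"
        comp_code = {"cytosol": "c", "external": "e"}.get(comp, comp)
        base = mid[: -(len(comp_code) + 1)] if mid.endswith(f"_{comp_code}") else mid
        return f"{base}[{comp_code}]"

    def fmt(coeff: float) -> str:
        if abs(coeff - 1.0) < 1e-12:
            return ""
        if abs(coeff - round(coeff)) < 1e-12:
            return f"{int(round(coeff))} "
        return f"{format(coeff, '.12g')} "

    lhs = [f"{fmt(-c)}{token(m)}" for m, c in rxn.stoichiometry.items() if c < 0]
    rhs = [f"{fmt(c)}{token(m)}" for m, c in rxn.stoichiometry.items() if c > 0]
    arrow = "<=>" if rxn.reversible else "->"
    return f"{' + '.join(lhs)} {arrow} {' + '.join(rhs)}".strip()
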