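"""Shared fixtures: core-model variants and small hand-built models."""

import numpy as np
import pytest

from cbmflux.core import MetabolicModel, Metabolite, Reaction
from cbmflux.fba import FluxConstraintSet
from cbmflux.synthetic import CoreModelSpec, generate_core_model


@pytest.fixture(scope="session")
def core_model():
    return generate_core_model()


@pytest.fixture(scope="session")
def core_model_pfk():
    return generate_core_model(CoreModelSpec(include_pfk=True))


@pytest.fixture(scope="session")
def nlim_model():
    return generate_core_model(CoreModelSpec(condition="nitrogen_limited"))


@pytest.fixture()
def constraints():
    return FluxConstraintSet()


def tiny_model(reactions, charges=None, objective=None):
    """Build a model from {rid: (stoich, lb, ub)} with uncharged, formula-free
    metabolites (for pure LP-structure tests)."""
    mets = set()
    for stoich, _, _ in reactions.values():
        mets |= set(stoich)
    model = MetabolicModel(
        metabolites=[
            Metabolite(id=m, name=m, formula={"C": 1},
                       charge_by_ph={"6": 0.0, "7": 0.0, "8": 0.0})
            for m in sorted(mets)
        ],
        reactions=[
            Reaction(id=rid, name=rid, stoichiometry=dict(stoich),
                     lower_bound=lb, upper_bound=ub,
                     is_exchange=len(stoich) == 1)
            for rid, (stoich, lb, ub) in reactions.items()
        ],
        objective_id=objective,
    )
    return model


@pytest.fixture()
def chain_model():
    """uptake(<=10) -> A -> B -> sink, unique flux distribution."""
    return tiny_model(
        {
            "UP": ({"A": 1}, 0, 10),
            "AB": ({"A": -1, "B": 1}, 0, 1000),
            "SINK": ({"B": -1}, 0, 1000),
        },
        objective="SINK",
    )


def enumerate_vertices(S, bounds):
    """Brute-force vertex enumeration of {v : S v = 0, l <= v <= u}.

    Fixes (n - rank S) variables at a bound in all combinations, solves for
    the rest, and keeps feasible solutions.  Independent oracle for FBA on
    tiny models.
    """
    import itertools

    S = np.asarray(S, dtype=float)
    n = S.shape[1]
    r = np.linalg.matrix_rank(S) if S.size else 0
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    vertices = []
    for fixed_idx in itertools.combinations(range(n), n - r):
        free_idx = [j for j in range(n) if j not in fixed_idx]
        S_free = S[:, free_idx]
        if free_idx and np.linalg.matrix_rank(S_free) < len(free_idx):
            continue
        for levels in itertools.product(*[(lo[j], hi[j]) for j in fixed_idx]):
            v = np.zeros(n)
            for j, val in zip(fixed_idx, levels):
                v[j] = val
            rhs = -S @ v
            if free_idx:
                sol, *_ = np.linalg.lstsq(S_free, rhs, rcond=None)
                v[free_idx] = sol
            if np.max(np.abs(S @ v)) > 1e-8:
                continue
            if np.all(v >= lo - 1e-9) and np.all(v <= hi + 1e-9):
                vertices.append(np.clip(v, lo, hi))
    return vertices
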