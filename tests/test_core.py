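"""Model domain layer: S matrix, balance checks, GPR logic, knockouts."""

import itertools

import numpy as np
import pytest

from cbmflux.core import (
    GPRSyntaxError,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    apply_knockout,
    build_stoichiometric_matrix,
    check_charge_balance,
    check_element_balance,
    evaluate_gpr,
    model_statistics,
    orf_coverage_percent,
    parse_equation,
    parse_formula,
)
from cbmflux.synthetic import CoreModelSpec, declared_core_sizes, generate_core_model

from conftest import tiny_model


class TestStoichiometricMatrix:
    def test_single_reaction_column(self):
        m = tiny_model({"R": ({"A": -1, "B": 1}, 0, 10)})
        S = build_stoichiometric_matrix(m)
        mets = m.metabolite_ids
        assert S.shape == (2, 1)
        assert S[mets.index("A"), 0] == -1 and S[mets.index("B"), 0] == 1

    def test_toy_model_matches_hand_written_table(self):
        # A branched 6-reaction toy: uptake, split to B/C, rejoin, sink
        m = tiny_model({
            "UP": ({"A": 1}, 0, 5),
            "AB": ({"A": -1, "B": 1}, 0, 10),
            "AC": ({"A": -1, "C": 1}, 0, 10),
            "BD": ({"B": -1, "D": 1}, 0, 10),
            "CD": ({"C": -1, "D": 2}, 0, 10),
            "OUT": ({"D": -1}, 0, 100),
        })
        S = build_stoichiometric_matrix(m)
        hand = np.array([
            # UP  AB  AC  BD  CD  OUT      (metabolites sorted: A B C D)
            [1, -1, -1, 0, 0, 0],
            [0, 1, 0, -1, 0, 0],
            [0, 0, 1, 0, -1, 0],
            [0, 0, 0, 1, 2, -1],
        ], dtype=float)
        np.testing.assert_array_equal(S, hand)

    def test_empty_model_gives_0x0(self):
        assert build_stoichiometric_matrix(MetabolicModel()).shape == (0, 0)

    def test_dangling_metabolite_is_validation_error(self):
        m = tiny_model({"R": ({"A": -1, "B": 1}, 0, 10)})
        m.reactions["R"].stoichiometry["GHOST"] = 1.0
        with pytest.raises(ModelValidationError, match="GHOST"):
            build_stoichiometric_matrix(m)

    def test_reversed_reaction_column_is_negated(self, core_model):
        m = core_model.copy()
        fwd = m.reactions["PGI"]
        m.add_reaction(Reaction(
            id="PGI_rev", stoichiometry={k: -v for k, v in fwd.stoichiometry.items()},
            lower_bound=-1000, upper_bound=1000,
        ))
        S = build_stoichiometric_matrix(m)
        j_f = m.reaction_ids.index("PGI")
        j_r = m.reaction_ids.index("PGI_rev")
        np.testing.assert_allclose(S[:, j_f], -S[:, j_r])


def _met(mid, formula, charge=0.0, comp="c"):
    return Metabolite(id=mid, name=mid, formula=parse_formula(formula),
                      charge_by_ph={"6": charge, "7": charge, "8": charge},
                      compartment=comp)


class TestBalanceChecks:
    def test_glucose_to_pyruvate_without_cofactors_imbalanced(self):
        # C6H12O6 -> 2 C3H3O3(-): unbalanced in H and charge
        m = MetabolicModel(
            metabolites=[_met("glc", "C6H12O6"), _met("pyr", "C3H3O3", -1.0)],
            reactions=[Reaction(id="BAD", stoichiometry={"glc": -1, "pyr": 2})],
        )
        net = check_element_balance(m.reactions["BAD"], m)
        assert net["H"] == pytest.approx(-6)
        assert "C" not in net and "O" not in net
        assert check_charge_balance(m.reactions["BAD"], m, "7") == pytest.approx(-2)

    def test_identity_reaction_balanced(self):
        m = MetabolicModel(
            metabolites=[_met("a1", "C2H5NO2"), _met("a2", "C2H5NO2")],
            reactions=[Reaction(id="ID", stoichiometry={"a1": -1, "a2": 1})],
        )
        assert check_element_balance(m.reactions["ID"], m) == {}
        assert check_charge_balance(m.reactions["ID"], m, "7") == 0.0

    def test_pha_synthase_step_balanced(self, core_model):
        # (R)-3HB-CoA -> PHB monomer + CoA closes elements and charge
        rxn = core_model.reactions["PHAC"]
        assert check_element_balance(rxn, core_model) == {}
        assert check_charge_balance(rxn, core_model, "7") == pytest.approx(0.0)

    def test_missing_formula_names_the_metabolite(self):
        m = MetabolicModel(
            metabolites=[_met("a", "C2H5NO2"), Metabolite(id="b")],
            reactions=[Reaction(id="R", stoichiometry={"a": -1, "b": 1})],
        )
        with pytest.raises(ModelValidationError, match="'b'"):
            check_element_balance(m.reactions["R"], m)

    def test_missing_charge_names_metabolite_and_ph(self):
        m = MetabolicModel(
            metabolites=[_met("a", "C2H5NO2"),
                         Metabolite(id="b", formula={"C": 1},
                                    charge_by_ph={"7": 0.0})],
            reactions=[Reaction(id="R", stoichiometry={"a": -1, "b": 1})],
        )
        with pytest.raises(ModelValidationError, match="pH 6"):
            check_charge_balance(m.reactions["R"], m, "6")


class TestGPR:
    def test_single_gene_knockout(self):
        assert evaluate_gpr("prpB", {"prpB"}) is False
        assert evaluate_gpr("prpB", set()) is True

    def test_nested_and_or(self):
        assert evaluate_gpr("g1 AND (g2 OR g3)", {"g2"}) is True
        assert evaluate_gpr("g1 AND (g2 OR g3)", {"g2", "g3"}) is False
        assert evaluate_gpr("", {"anything"}) is True

    def test_truth_table_agreement_with_bruteforce(self):
        """All two-operator expressions over 3 genes agree with direct
        Python boolean evaluation on every knockout subset."""
        genes = ["g1", "g2", "g3"]
        ops = ["AND", "OR"]
        for o1, o2 in itertools.product(ops, repeat=2):
            expressions = [
                (f"g1 {o1} (g2 {o2} g3)", lambda a, b, c, o1=o1, o2=o2:
                 _op(o1)(a, _op(o2)(b, c))),
                (f"(g1 {o1} g2) {o2} g3", lambda a, b, c, o1=o1, o2=o2:
                 _op(o2)(_op(o1)(a, b), c)),
            ]
            for expr, ref in expressions:
                for ko in _powerset(genes):
                    vals = [g not in ko for g in genes]
                    assert evaluate_gpr(expr, ko) == ref(*vals), (expr, ko)

    def test_syntax_error_reports_position(self):
        with pytest.raises(GPRSyntaxError):
            evaluate_gpr("g1 AND", set())
        with pytest.raises(GPRSyntaxError):
            evaluate_gpr("(g1 OR g2", set())

    def test_case_insensitive_gene_tokens(self):
        assert evaluate_gpr("PrpB", {"prpb"}) is False


def _op(name):
    return (lambda a, b: a and b) if name == "AND" else (lambda a, b: a or b)


def _powerset(items):
    return itertools.chain.from_iterable(
        itertools.combinations(items, k) for k in range(len(items) + 1)
    )


class TestKnockout:
    def test_one_to_one_gene_closes_reaction(self, core_model):
        mutant = apply_knockout(core_model, {"eda"})
        assert mutant.reactions["EDA"].lower_bound == 0
        assert mutant.reactions["EDA"].upper_bound == 0
        # original untouched
        assert core_model.reactions["EDA"].upper_bound > 0

    def test_acnm_closes_methylisocitrate_dehydratase(self, core_model):
        mutant = apply_knockout(core_model, {"acnM"})
        assert mutant.reactions["ACNM"].upper_bound == 0
        assert mutant.reactions["ACNM"].lower_bound == 0
        # the rest of the cycle stays open
        assert mutant.reactions["PRPC"].upper_bound > 0

    def test_empty_knockout_is_identity(self, core_model):
        mutant = apply_knockout(core_model, set())
        for rid, rxn in core_model.reactions.items():
            assert mutant.reactions[rid].lower_bound == rxn.lower_bound
            assert mutant.reactions[rid].upper_bound == rxn.upper_bound

    def test_idempotent_and_commutative_on_disjoint_sets(self, core_model):
        a = apply_knockout(apply_knockout(core_model, {"eda"}), {"eda"})
        b = apply_knockout(core_model, {"eda"})
        ab = apply_knockout(apply_knockout(core_model, {"eda"}), {"phaC"})
        ba = apply_knockout(apply_knockout(core_model, {"phaC"}), {"eda"})
        for m1, m2 in ((a, b), (ab, ba)):
            for rid in m1.reactions:
                assert m1.reactions[rid].lower_bound == m2.reactions[rid].lower_bound
                assert m1.reactions[rid].upper_bound == m2.reactions[rid].upper_bound

    def test_isozyme_protected_reaction_survives_single_knockout(self, core_model):
        mutant = apply_knockout(core_model, {"fumC1"})
        assert mutant.reactions["FUM"].upper_bound > 0
        double = apply_knockout(core_model, {"fumC1", "fumC2"})
        assert double.reactions["FUM"].upper_bound == 0

    def test_unknown_gene_raises_or_warns(self, core_model):
        with pytest.raises(ModelValidationError, match="ghost"):
            apply_knockout(core_model, {"ghost"})
        with pytest.warns(UserWarning):
            apply_knockout(core_model, {"ghost"}, on_unknown="warn")


class TestStatistics:
    def test_core_model_counts_match_generator_bookkeeping(self, core_model):
        stats = model_statistics(core_model).as_dict()
        declared = declared_core_sizes()
        for key, val in declared.items():
            assert stats[key] == val, key
        assert stats["n_reactions_redundant"] == (
            stats["n_biochemical"] + stats["n_transport"]
        )
        assert stats["n_reactions_unique"] <= stats["n_reactions_redundant"]

    def test_empty_model_all_zero(self):
        stats = model_statistics(MetabolicModel())
        assert all(v == 0 for v in stats.as_dict().values())

    def test_duplicate_reactions_deduplicated(self):
        m = tiny_model({
            "R1": ({"A": -1, "B": 1}, 0, 10),
            "R2": ({"A": -1, "B": 1}, 0, 10),
            "R3": ({"A": -2, "B": 2}, 0, 10),
        })
        stats = model_statistics(m)
        assert stats.n_reactions_redundant == 3
        assert stats.n_reactions_unique == 2

    def test_redundant_equals_biochemical_plus_transport(self, nlim_model):
        s = model_statistics(nlim_model)
        assert s.n_reactions_redundant == s.n_biochemical + s.n_transport

    def test_orf_coverage(self):
        assert orf_coverage_percent(1256, 6626) == pytest.approx(18.96, abs=0.005)


class TestEquationGrammar:
    def test_parse_example(self):
        stoich, rev = parse_equation("2 A[c] + B[c] <=> C[e]")
        assert stoich == {"A_c": -2.0, "B_c": -1.0, "C_e": 1.0}
        assert rev is True

    def test_irreversible_arrow(self):
        stoich, rev = parse_equation("A[c] -> B[c]")
        assert rev is False

    def test_missing_arrow_raises(self):
        with pytest.raises(ValueError, match="arrow"):
            parse_equation("A[c] + B[c]")
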