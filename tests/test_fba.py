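"""LP/QP engine: FBA vs vertex-enumeration oracle, FVA, MOMA, envelopes."""

import numpy as np
import pytest

from cbmflux.core import apply_knockout, build_stoichiometric_matrix
from cbmflux.fba import (
    FluxConstraintSet,
    audit_solution,
    fba,
    fva,
    max_atp_yield,
    moma,
    normalize_fluxes,
    parsimonious_fluxes,
    production_envelope,
    single_knockout_scan,
)

from conftest import enumerate_vertices, tiny_model


class TestFba:
    def test_linear_chain_bottleneck(self, chain_model):
        res = fba(chain_model, FluxConstraintSet(zeroed_secretions=set()),
                  objective="SINK")
        assert res.status == "optimal"
        assert res.objective_value == pytest.approx(10.0)

    def test_branched_toy_matches_vertex_enumeration(self):
        m = tiny_model({
            "UP": ({"A": 1}, 0, 7),
            "AB": ({"A": -1, "B": 1}, 0, 4),
            "AC": ({"A": -1, "C": 2}, 0, 10),
            "OUT": ({"B": -1, "C": -1}, 0, 100),
        })
        S = build_stoichiometric_matrix(m)
        bounds = [(r.lower_bound, r.upper_bound) for r in m.reactions.values()]
        verts = enumerate_vertices(S, bounds)
        j = m.reaction_ids.index("OUT")
        oracle = max(v[j] for v in verts)
        res = fba(m, FluxConstraintSet(zeroed_secretions=set()), objective="OUT")
        assert res.objective_value == pytest.approx(oracle, abs=1e-8)

    def test_random_small_models_match_oracle(self):
        """FBA equals brute-force vertex enumeration on random models with
        <= 8 reactions (bounded polytopes containing 0)."""
        rng = np.random.default_rng(42)
        for trial in range(25):
            n_m = rng.integers(2, 5)
            n_r = rng.integers(int(n_m) + 1, 9)
            S = np.round(rng.integers(-2, 3, size=(n_m, n_r)).astype(float))
            lo = -np.round(rng.uniform(0, 10, n_r), 2)
            hi = np.round(rng.uniform(0, 10, n_r), 2)
            rxns = {
                f"R{j}": (
                    {f"M{i}": S[i, j] for i in range(n_m) if S[i, j] != 0}
                    or {f"M0": 0.0},
                    lo[j], hi[j],
                )
                for j in range(n_r)
            }
            rxns = {k: v for k, v in rxns.items() if v[0]}
            if not rxns:
                continue
            m = tiny_model(rxns)
            S2 = build_stoichiometric_matrix(m)
            bounds = [(r.lower_bound, r.upper_bound)
                      for r in m.reactions.values()]
            verts = enumerate_vertices(S2, bounds)
            if not verts:
                continue
            obj = m.reaction_ids[0]
            j = 0
            oracle = max(v[j] for v in verts)
            res = fba(m, FluxConstraintSet(zeroed_secretions=set()),
                      objective=obj)
            assert res.status == "optimal", trial
            assert res.objective_value == pytest.approx(oracle, abs=1e-7), trial

    def test_infeasible_status_has_no_fluxes(self, chain_model):
        cs = FluxConstraintSet(
            {"UP": (5.0, 5.0), "SINK": (0.0, 1.0)}, set()
        )
        res = fba(chain_model, cs, objective="SINK")
        assert res.status == "infeasible"
        assert res.objective_value is None and res.fluxes == {}

    def test_optimal_solution_passes_audit(self, core_model, constraints):
        res = fba(core_model, constraints)
        audit_solution(core_model, res, constraints)


class TestFva:
    def test_unique_chain_min_equals_max(self, chain_model):
        cs = FluxConstraintSet(zeroed_secretions=set())
        res = fba(chain_model, cs, objective="SINK")
        for fr in fva(chain_model, cs, objective="SINK"):
            assert fr.min_flux == pytest.approx(fr.max_flux, abs=1e-7)
            assert fr.min_flux == pytest.approx(res.fluxes[fr.reaction_id],
                                                abs=1e-7)

    def test_parallel_equivalent_paths_have_complementary_ranges(self):
        m = tiny_model({
            "UP": ({"A": 1}, 0, 6),
            "P1": ({"A": -1, "B": 1}, 0, 1000),
            "P2": ({"A": -1, "B": 1}, 0, 1000),
            "OUT": ({"B": -1}, 0, 1000),
        })
        cs = FluxConstraintSet(zeroed_secretions=set())
        ranges = {fr.reaction_id: fr for fr in fva(m, cs, objective="OUT")}
        for rid in ("P1", "P2"):
            assert ranges[rid].min_flux == pytest.approx(0.0, abs=1e-7)
            assert ranges[rid].max_flux == pytest.approx(6.0, abs=1e-7)

    def test_eda_knockout_narrows_ed_pathway_to_zero(self, core_model_pfk,
                                                     constraints):
        mutant = apply_knockout(core_model_pfk, {"eda"})
        ranges = {
            fr.reaction_id: fr
            for fr in fva(mutant, constraints, reactions=["EDA", "EDD"])
        }
        for rid in ("EDA", "EDD"):
            assert ranges[rid].min_flux == pytest.approx(0.0, abs=1e-7)
            assert ranges[rid].max_flux == pytest.approx(0.0, abs=1e-7)

    def test_ranges_contain_fba_flux_and_tighten_monotonically(self, core_model,
                                                               constraints):
        wanted = ["EX_fru", "EDA", "NADHOX", "EX_o2", "GAPD"]
        base = fba(core_model, constraints)
        ranges = {r.reaction_id: r
                  for r in fva(core_model, constraints, reactions=wanted)}
        for rid in wanted:
            assert ranges[rid].min_flux - 1e-6 <= base.fluxes[rid] <= (
                ranges[rid].max_flux + 1e-6
            )
        tighter = constraints.with_overrides({"EX_o2": (-6.0, 1000.0)})
        shrunk = {r.reaction_id: r
                  for r in fva(core_model, tighter, reactions=wanted)}
        for rid in wanted:
            assert shrunk[rid].min_flux >= ranges[rid].min_flux - 1e-6
            assert shrunk[rid].max_flux <= ranges[rid].max_flux + 1e-6


class TestMoma:
    def test_wildtype_projection_is_identity(self, core_model, constraints):
        wt = parsimonious_fluxes(core_model, constraints)
        res = moma(core_model, constraints, wt.fluxes)
        assert res.status == "optimal"
        dist = sum(
            (res.fluxes[r] - wt.fluxes[r]) ** 2 for r in core_model.reactions
        )
        assert dist == pytest.approx(0.0, abs=1e-8)
        assert res.objective_value == pytest.approx(wt.objective_value, abs=1e-6)

    def test_two_reaction_toy_matches_analytic_projection(self):
        # feasible set: v_UP = v_OUT in [0, 10]; projecting (5, 1) onto the
        # diagonal gives (3, 3)
        m = tiny_model({
            "UP": ({"A": 1}, 0, 10),
            "OUT": ({"A": -1}, 0, 10),
        }, objective="OUT")
        res = moma(m, FluxConstraintSet(zeroed_secretions=set()),
                   {"UP": 5.0, "OUT": 1.0})
        assert res.fluxes["UP"] == pytest.approx(3.0, abs=1e-6)
        assert res.fluxes["OUT"] == pytest.approx(3.0, abs=1e-6)

    def test_projection_clips_at_bounds(self):
        # projecting (12, 8) onto the diagonal hits the box corner (10, 10)
        m = tiny_model({
            "UP": ({"A": 1}, 0, 10),
            "OUT": ({"A": -1}, 0, 10),
        }, objective="OUT")
        res = moma(m, FluxConstraintSet(zeroed_secretions=set()),
                   {"UP": 12.0, "OUT": 8.0})
        assert res.fluxes["UP"] == pytest.approx(10.0, abs=1e-6)
        assert res.fluxes["OUT"] == pytest.approx(10.0, abs=1e-6)

    def test_three_reaction_closed_path_least_squares(self):
        # A made by UP, drained by two routes; closing route 2 forces its
        # flux to 0 and the projection of (6, 3, 3) onto {v1=v2, v3=0} is
        # (4.5, 4.5, 0)
        m = tiny_model({
            "UP": ({"A": 1}, 0, 20),
            "OUT1": ({"A": -1}, 0, 20),
            "OUT2": ({"A": -1}, 0, 0),
        }, objective="OUT1")
        res = moma(m, FluxConstraintSet(zeroed_secretions=set()),
                   {"UP": 6.0, "OUT1": 3.0, "OUT2": 3.0})
        assert res.fluxes["UP"] == pytest.approx(4.5, abs=1e-6)
        assert res.fluxes["OUT1"] == pytest.approx(4.5, abs=1e-6)
        assert res.fluxes["OUT2"] == pytest.approx(0.0, abs=1e-9)

    def test_acnm_knockout_moma_growth_not_above_fba(self, core_model):
        cs = FluxConstraintSet().with_overrides({"EX_prp": (-1.0, -1.0)})
        wt = parsimonious_fluxes(core_model, cs)
        mutant = apply_knockout(core_model, {"acnM"})
        fba_res = fba(mutant, cs)
        moma_res = moma(mutant, cs, wt.fluxes)
        assert moma_res.status == "optimal"
        assert moma_res.objective_value <= fba_res.objective_value + 1e-6
        assert moma_res.fluxes["EX_2mca"] > 1e-3

    def test_infeasible_mutant_reported(self, chain_model):
        cs = FluxConstraintSet({"UP": (5.0, 5.0), "SINK": (0.0, 1.0)}, set())
        res = moma(chain_model, cs, {"UP": 5.0, "AB": 5.0, "SINK": 5.0})
        assert res.status == "infeasible"


class TestKnockoutScanAndEnvelope:
    def test_blocked_gene_knockout_leaves_growth_unchanged(self, core_model,
                                                           constraints):
        # ldhA carries no flux aerobically with the lactate valve closed
        base = fba(core_model, constraints).objective_value
        rank = single_knockout_scan(core_model, constraints,
                                    genes={"ldhA"}, target="EX_2mca")
        gene, growth, prod, cls = rank[0]
        assert growth == pytest.approx(base, rel=1e-6)

    def test_envelope_min_le_max_and_nesting(self, core_model, constraints):
        cs = constraints.with_overrides({"EX_prp": (-1.0, -1.0)})
        env = production_envelope(core_model, cs, target="EX_2mca", n_points=6)
        finite = [(f, lo, hi) for f, lo, hi in env
                  if np.isfinite(lo) and np.isfinite(hi)]
        assert finite
        for _, lo, hi in finite:
            assert lo <= hi + 1e-8
        tighter = cs.with_overrides({"EX_o2": (-5.0, 1000.0)})
        env2 = production_envelope(core_model, tighter, target="EX_2mca",
                                   n_points=6)
        # envelopes are reported on each model's own optimum; absolute
        # maxima shrink when constraints tighten
        hmax = max(h for _, _, h in env if np.isfinite(h))
        hmax2 = max(h for _, _, h in env2 if np.isfinite(h))
        assert hmax2 <= hmax + 1e-6

    def test_envelope_requires_two_points(self, core_model, constraints):
        with pytest.raises(ValueError):
            production_envelope(core_model, constraints, target="EX_2mca",
                                n_points=1)


class TestAtpYieldAndNormalization:
    def test_zero_substrate_gives_zero_yield(self, core_model):
        cs = FluxConstraintSet().with_overrides({"ATPM": (0.0, 1000.0)})
        y = max_atp_yield(core_model, cs, substrate_exchange="EX_fru",
                          uptake=0.0)
        assert y == pytest.approx(0.0, abs=1e-6)

    def test_yield_matches_hand_traced_pathway(self, core_model):
        """Fermentative ED catabolism: fructokinase -1, PGK +1, PYK +1 ATP
        per fructose, NADH disposed via lactate -> net 1."""
        cs = FluxConstraintSet(zeroed_secretions={"EX_ac", "EX_pyr", "EX_etoh"})
        cs = cs.with_overrides({"EX_o2": (0.0, 1000.0), "EX_no3": (0.0, 0.0),
                                "EX_no2": (0.0, 0.0)})
        assert max_atp_yield(core_model, cs, "EX_fru", 1.0) == pytest.approx(1.0)

    def test_normalize_fluxes(self, core_model, constraints):
        res = fba(core_model, constraints)
        norm = normalize_fluxes(res, "EX_fru")
        assert abs(norm["EX_fru"]) == pytest.approx(100.0)
        # ratios preserved
        a, b = "GAPD", "PYK"
        assert norm[a] / norm[b] == pytest.approx(
            res.fluxes[a] / res.fluxes[b], rel=1e-9
        )

    def test_zero_reference_rejected(self, core_model, constraints):
        res = fba(core_model, constraints)
        with pytest.raises(ZeroDivisionError):
            normalize_fluxes(res, "EX_lac")


class TestAnaerobicProperty:
    def test_strictly_respiratory_growth(self, core_model):
        """No growth without O2/NO3-/NO2- (even with overflow valves open,
        fermentative ATP cannot cover maintenance); growth resumes with
        nitrate or nitrite as alternative electron acceptors."""
        closed = FluxConstraintSet(zeroed_secretions=set()).with_overrides(
            {"EX_o2": (0.0, 1000.0), "EX_no3": (0.0, 0.0),
             "EX_no2": (0.0, 0.0)}
        )
        res = fba(core_model, closed)
        assert not res.ok or res.objective_value <= 1e-9
        for acceptor in ("EX_no3", "EX_no2"):
            cs = FluxConstraintSet(
                zeroed_secretions={"EX_lac", "EX_pyr", "EX_etoh"}
            ).with_overrides(
                {"EX_o2": (0.0, 1000.0), "EX_no3": (0.0, 0.0),
                 "EX_no2": (0.0, 0.0), acceptor: (-10.0, 1000.0)}
            )
            res = fba(core_model, cs)
            assert res.ok and res.objective_value > 0.05, acceptor
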