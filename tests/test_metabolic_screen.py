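"""FBA/FVA, GPR semantics, inhibition and the selective combo screen."""

import itertools

import numpy as np
import pytest

from polypharm.metabolic_screen import (
    MetabolicModel,
    Reaction,
    apply_inhibition,
    combo_screen,
    fba,
    fva,
    gpr_active,
    hallmark_classify,
)
from polypharm.synthetic_data import PLANTED_GENE_PAIR, gen_toy_models


def chain_model(uptake_ub=10.0):
    """uptake(<=ub) -> A -> biomass: the optimum equals the binding bound."""
    return MetabolicModel(
        metabolites=["A"],
        reactions=[
            Reaction("uptake", {"A": 1.0}, 0.0, uptake_ub),
            Reaction("BIOMASS", {"A": -1.0}, 0.0, 1000.0),
        ],
        genes=[],
        biomass_rxn="BIOMASS",
    )


def branch_model():
    """uptake(<=10) -> A; A -> biomass; A -> side(<=4): FVA solvable by hand."""
    return MetabolicModel(
        metabolites=["A"],
        reactions=[
            Reaction("uptake", {"A": 1.0}, 0.0, 10.0),
            Reaction("BIOMASS", {"A": -1.0}, 0.0, 1000.0),
            Reaction("side", {"A": -1.0}, 0.0, 4.0),
            Reaction("dead", {}, 0.0, 0.0),
        ],
        genes=[],
        biomass_rxn="BIOMASS",
    )


class TestFba:
    def test_chain_optimum_equals_binding_bound(self):
        res = fba(chain_model())
        assert res.ok
        assert res.objective == pytest.approx(10.0, abs=1e-9)

    def test_all_zero_bounds_give_zero(self):
        m = chain_model(uptake_ub=0.0)
        assert fba(m).objective == pytest.approx(0.0, abs=1e-12)

    def test_lp_homogeneity(self):
        m = chain_model()
        m2 = chain_model()
        for r in m2.reactions:
            r.lb *= 2
            r.ub *= 2
        assert fba(m2).objective == pytest.approx(2 * fba(m).objective, rel=1e-9)

    def test_matches_cobrapy_on_toy_cancer_model(self, toy_models):
        cobra = pytest.importorskip("cobra")
        cancer, _ = toy_models
        cm = cobra.Model("toy")
        mets = {m: cobra.Metabolite(m) for m in cancer.metabolites}
        for r in cancer.reactions:
            rx = cobra.Reaction(r.id)
            rx.lower_bound, rx.upper_bound = r.lb, r.ub
            cm.add_reactions([rx])
            rx.add_metabolites({mets[m]: c for m, c in r.stoich.items()})
        cm.objective = cancer.biomass_rxn
        sol = cm.optimize()
        assert fba(cancer).objective == pytest.approx(sol.objective_value, rel=1e-6)


class TestFva:
    def test_objective_reaction_reaches_wild_type_optimum(self):
        m = branch_model()
        lo, hi = fva(m, "BIOMASS", biomass_fraction=0.8)
        assert hi == pytest.approx(10.0, abs=1e-9)
        assert lo == pytest.approx(8.0, abs=1e-9)

    def test_dead_end_reaction_is_pinned_to_zero(self):
        lo, hi = fva(branch_model(), "dead")
        assert (lo, hi) == (0.0, 0.0)

    def test_hand_solved_branch_interval(self):
        # at >= 80% of the optimum (8), spare uptake capacity is 2,
        # further capped by the side reaction's own bound of 4
        lo, hi = fva(branch_model(), "side", biomass_fraction=0.8)
        assert lo == pytest.approx(0.0, abs=1e-9)
        assert hi == pytest.approx(2.0, abs=1e-9)


class TestGpr:
    @pytest.mark.parametrize(
        "expr,inactive,expected",
        [
            ("g1 AND g2", {"g1"}, False),
            ("g1 AND g2", set(), True),
            ("g1 OR g2", {"g1"}, True),
            ("g1 OR g2", {"g1", "g2"}, False),
            ("(g1 OR g2) AND g3", {"g1"}, True),
            ("(g1 OR g2) AND g3", {"g3"}, False),
            ("", {"g1"}, True),
            ("g1 and g2", {"g2"}, False),  # case-insensitive operators
        ],
    )
    def test_semantics(self, expr, inactive, expected):
        assert gpr_active(expr, inactive) is expected

    @pytest.mark.parametrize("expr", ["g1 AND", "(g1 OR g2", "AND g1", "g1 g2"])
    def test_malformed_raises(self, expr):
        with pytest.raises(ValueError):
            gpr_active(expr, set())


class TestApplyInhibition:
    def test_conjunction_falsified_scales_bounds(self, toy_models):
        cancer, _ = toy_models
        inh = apply_inhibition(cancer, {"g1"})
        assert inh.reaction("PATH1").ub == pytest.approx(0.01 * cancer.reaction("PATH1").ub)
        assert inh.reaction("PATH2").ub == cancer.reaction("PATH2").ub

    def test_isozyme_needs_both(self):
        m = MetabolicModel(
            metabolites=["A"],
            reactions=[
                Reaction("uptake", {"A": 1.0}, 0.0, 10.0, gpr="g1 OR g2"),
                Reaction("BIOMASS", {"A": -1.0}, 0.0, 1000.0),
            ],
            genes=["g1", "g2"],
            biomass_rxn="BIOMASS",
        )
        assert apply_inhibition(m, {"g1"}).reaction("uptake").ub == 10.0
        assert apply_inhibition(m, {"g1", "g2"}).reaction("uptake").ub == pytest.approx(0.1)

    def test_empty_set_is_identity(self, toy_models):
        cancer, _ = toy_models
        inh = apply_inhibition(cancer, set())
        assert [(r.lb, r.ub) for r in inh.reactions] == [(r.lb, r.ub) for r in cancer.reactions]

    def test_idempotent(self, toy_models):
        cancer, _ = toy_models
        once = apply_inhibition(cancer, {"g1", "g2"})
        twice = apply_inhibition(once, {"g1", "g2"})
        assert [(r.lb, r.ub) for r in twice.reactions] == [(r.lb, r.ub) for r in once.reactions]

    def test_original_model_untouched(self, toy_models):
        cancer, _ = toy_models
        before = [(r.lb, r.ub) for r in cancer.reactions]
        apply_inhibition(cancer, {"g1"})
        assert [(r.lb, r.ub) for r in cancer.reactions] == before

    def test_unknown_gene_raises(self, toy_models):
        with pytest.raises(KeyError):
            apply_inhibition(toy_models[0], {"gX"})

    def test_inhibition_monotone_in_gene_set(self, toy_models):
        cancer, _ = toy_models
        prev = fba(cancer).objective
        genes = []
        for g in ["g1", "g2", "g3", "g4"]:
            genes.append(g)
            cur = fba(apply_inhibition(cancer, set(genes))).objective
            assert cur <= prev + 1e-9
            prev = cur


class TestComboScreen:
    def test_planted_pair_is_unique_genuine(self, toy_models):
        cancer, healthy = toy_models
        groups = [set(c) for r in (1, 2) for c in itertools.combinations(cancer.genes, r)]
        outcomes = combo_screen(cancer, healthy, groups, classify_hallmarks=False)
        genuine = {o.genes for o in outcomes if o.genuine_flag}
        assert genuine == {PLANTED_GENE_PAIR}

    def test_untouched_group_keeps_full_biomass(self, toy_models):
        cancer, healthy = toy_models
        (out,) = combo_screen(cancer, healthy, [{"g3", "g4"}], classify_hallmarks=False)
        assert out.biomass_cancer_frac == pytest.approx(1.0, abs=1e-9)
        assert not out.genuine_flag

    def test_singleton_never_genuine(self, toy_models):
        cancer, healthy = toy_models
        (out,) = combo_screen(cancer, healthy, [{"g1"}], classify_hallmarks=False)
        assert not out.genuine_flag

    def test_unknown_gene_raises(self, toy_models):
        cancer, healthy = toy_models
        with pytest.raises(KeyError):
            combo_screen(cancer, healthy, [{"gX"}])


class TestHallmarkClassify:
    def test_inhibited_reaching_healthy_is_strong_reversal(self, toy_models):
        cancer, healthy = toy_models
        # bound-only surrogate whose hallmark maxima equal the healthy ones
        shifted = cancer.copy()
        for r, h in zip(shifted.reactions, healthy.reactions):
            r.lb, r.ub = h.lb, h.ub
        call = hallmark_classify(cancer, shifted, healthy, "EX_glc")
        assert call.call == "strong reversal"
        assert call.ratio == pytest.approx(1.0, abs=1e-9)

    def test_unchanged_model_is_no_effect(self, toy_models):
        cancer, healthy = toy_models
        call = hallmark_classify(cancer, cancer.copy(), healthy, "EX_glc")
        assert call.call == "no effect"

    def test_divergence_is_strong_worsening(self):
        # healthy max = 5, cancer max = 10, inhibited max = 16: moves away
        cancer = chain_model(10.0)
        cancer.hallmark_rxns = {"Glu": "uptake"}
        healthy = chain_model(5.0)
        worse = chain_model(16.0)
        call = hallmark_classify(cancer, worse, healthy, "uptake")
        assert call.call == "strong worsening"

    def test_zero_gap_flagged_degenerate(self):
        m = chain_model(10.0)
        call = hallmark_classify(m, m.copy(), m.copy(), "uptake")
        assert call.call == "no effect"
        assert call.degenerate


def test_model_json_round_trip(tmp_path, toy_models):
    cancer, _ = toy_models
    cancer.to_json(tmp_path / "m.json")
    back = MetabolicModel.from_json(tmp_path / "m.json")
    assert [r.id for r in back.reactions] == [r.id for r in cancer.reactions]
    assert np.array_equal(back.stoichiometric_matrix(), cancer.stoichiometric_matrix())
    assert back.hallmark_rxns == cancer.hallmark_rxns
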