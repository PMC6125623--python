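"""Unit tests for the core data model, GPR parsing and matrix assembly."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gemcarve.core import (
    GPRExpression,
    GPRParseError,
    Medium,
    MediumWarning,
    Metabolite,
    Model,
    ModelValidationError,
    Reaction,
    ReactionKind,
    apply_medium,
    build_stoichiometric_matrix,
    complete_medium,
    formula_to_string,
    parse_formula,
    parse_gpr,
)

from _oracles import truth_table_eval


def cpx(*groups):
    return frozenset(frozenset(g) for g in groups)


class TestParseGPR:
    def test_single_complex(self):
        assert parse_gpr("g1 and g2").complexes == cpx({"g1", "g2"})

    def test_dnf_identity(self):
        assert parse_gpr("(g1 and g2) or g3").complexes == cpx(
            {"g1", "g2"}, {"g3"}
        )

    def test_distributes_and_over_or(self):
        # derived: check against truth-table enumeration over 3 genes
        text = "g1 and (g2 or g3)"
        expr = parse_gpr(text)
        assert expr.complexes == cpx({"g1", "g2"}, {"g1", "g3"})
        genes = ["g1", "g2", "g3"]
        for bits in itertools.product([False, True], repeat=3):
            present = {g for g, b in zip(genes, bits) if b}
            assert expr.evaluate(present) == truth_table_eval(text, present, genes)

    def test_empty_text(self):
        assert parse_gpr("").is_empty
        assert parse_gpr("   ").is_empty
        assert parse_gpr(None).is_empty

    def test_case_insensitive_operators(self):
        assert parse_gpr("g1 AND g2").complexes == parse_gpr("g1 and g2").complexes
        assert parse_gpr("g1 Or g2").complexes == cpx({"g1"}, {"g2"})

    @pytest.mark.parametrize(
        "bad", ["g1 and", "and g1", "(g1 or g2", "g1 )", "g1 or or g2"]
    )
    def test_malformed_reports_position(self, bad):
        with pytest.raises(GPRParseError) as exc:
            parse_gpr(bad)
        assert "position" in str(exc.value)

    def test_nested_parentheses(self):
        expr = parse_gpr("((g1 or g2) and (g3 or g4))")
        assert expr.complexes == cpx(
            {"g1", "g3"}, {"g1", "g4"}, {"g2", "g3"}, {"g2", "g4"}
        )


@st.composite
def gpr_expressions(draw):
    genes = [f"g{i}" for i in range(draw(st.integers(2, 8)))]
    depth = draw(st.integers(0, 2))

    def build(d):
        if d == 0:
            return draw(st.sampled_from(genes))
        op = draw(st.sampled_from(["and", "or"]))
        return f"({build(d - 1)} {op} {build(d - 1)})"

    return build(depth), genes


class TestGPRProperties:
    @settings(max_examples=60, deadline=None)
    @given(gpr_expressions())
    def test_dnf_matches_truth_table(self, expr_genes):
        text, genes = expr_genes
        expr = parse_gpr(text)
        for bits in itertools.product([False, True], repeat=len(genes)):
            present = {g for g, b in zip(genes, bits) if b}
            assert expr.evaluate(present) == truth_table_eval(
                text, present, genes
            )

    @settings(max_examples=60, deadline=None)
    @given(gpr_expressions())
    def test_serialize_roundtrip(self, expr_genes):
        text, _ = expr_genes
        expr = parse_gpr(text)
        assert parse_gpr(expr.to_string()).complexes == expr.complexes


class TestFormula:
    def test_parse(self):
        assert parse_formula("C6H12O6") == {"C": 6, "H": 12, "O": 6}
        assert parse_formula("H2O") == {"H": 2, "O": 1}
        assert parse_formula("") == {}

    def test_two_letter_elements(self):
        assert parse_formula("Fe2S2") == {"Fe": 2, "S": 2}

    def test_roundtrip(self):
        for text in ("C6H12O6", "CH4", "Fe2S2"):
            assert parse_formula(formula_to_string(parse_formula(text))) == parse_formula(text)

    def test_malformed(self):
        with pytest.raises(ValueError):
            parse_formula("c6h12")


class TestStoichiometricMatrix:
    def test_simple_column(self):
        model = Model("m", compartments={"c": "c"})
        model.add_metabolite(Metabolite("A", compartment="c"))
        model.add_metabolite(Metabolite("B", compartment="c"))
        model.add_reaction(Reaction("R", {"A": -1.0, "B": 1.0}))
        mat = build_stoichiometric_matrix(model).toarray()
        assert mat.shape == (2, 1)
        assert mat[0, 0] == -1.0 and mat[1, 0] == 1.0

    def test_empty_model(self):
        assert build_stoichiometric_matrix(Model("empty")).shape == (0, 0)

    def test_toy6_nonzeros(self, toy6_model):
        # derived by counting participants in the fixture definition:
        # EX_A(1) + EX_D(1) + T_A(2) + R1(2) + R2(2) + R3(2) + GROWTH(1)
        mat = build_stoichiometric_matrix(toy6_model)
        assert mat.nnz == 11

    def test_columns_reconstruct_reactions(self, toy6_model):
        mat = build_stoichiometric_matrix(toy6_model).toarray()
        met_ids = toy6_model.metabolite_ids()
        for j, rxn in enumerate(toy6_model.reactions.values()):
            recon = {
                met_ids[i]: mat[i, j] for i in range(len(met_ids)) if mat[i, j]
            }
            assert recon == rxn.stoichiometry


class TestMedium:
    def test_apply(self, toy6_model):
        out = apply_medium(toy6_model, Medium({"A": 10.0}))
        assert out.reactions["EX_A"].lb == -10.0
        assert out.reactions["EX_D"].lb == 0.0
        # secretion stays open
        assert out.reactions["EX_A"].ub == toy6_model.reactions["EX_A"].ub

    def test_empty_medium_closes_uptake(self, toy6_model):
        from gemcarve.phenotyping import fba

        out = apply_medium(toy6_model, Medium({}))
        assert all(r.lb == 0.0 for r in out.exchanges)
        assert fba(out).growth == pytest.approx(0.0, abs=1e-9)

    def test_complete_medium(self, toy6_model):
        out = apply_medium(toy6_model, complete_medium(toy6_model, 100.0))
        assert all(r.lb == -100.0 for r in out.exchanges)

    def test_unknown_compound_warns_and_skips(self, toy6_model):
        with pytest.warns(MediumWarning, match="notacompound"):
            out = apply_medium(toy6_model, Medium({"A": 5.0, "notacompound": 1.0}))
        assert out.reactions["EX_A"].lb == -5.0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            Medium({"A": -1.0})


class TestModelInvariants:
    def test_bounds_ordering(self):
        with pytest.raises(ModelValidationError):
            Reaction("R", {}, lb=1.0, ub=-1.0)

    def test_duplicate_metabolite(self):
        model = Model("m", compartments={"c": "c"})
        model.add_metabolite(Metabolite("A", compartment="c"))
        with pytest.raises(ModelValidationError):
            model.add_metabolite(Metabolite("A", compartment="c"))

    def test_unknown_metabolite_in_reaction(self):
        model = Model("m", compartments={"c": "c"})
        with pytest.raises(ModelValidationError):
            model.add_reaction(Reaction("R", {"ghost": -1.0}))

    def test_exchange_must_be_extracellular(self):
        model = Model("m", compartments={"c": "c", "e": "e"}, extracellular="e")
        model.add_metabolite(Metabolite("A_c", compartment="c"))
        model.add_reaction(
            Reaction("EX_A", {"A_c": -1.0}, kind=ReactionKind.EXCHANGE)
        )
        with pytest.raises(ModelValidationError):
            model.validate()

    def test_single_biomass(self, toy6_model):
        toy6_model.add_reaction(
            Reaction("GROWTH2", {"C_c": -1.0}, lb=0, kind=ReactionKind.BIOMASS)
        )
        with pytest.raises(ModelValidationError):
            toy6_model.validate()

    def test_toy6_is_valid(self, toy6_model):
        toy6_model.validate()
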