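"""Curation tests: balance, thermodynamics, pruning, cycles, templates."""

import math

import numpy as np
import pytest

from gemcarve.core import (
    Metabolite,
    Model,
    Reaction,
    ReactionKind,
    parse_formula,
)
from gemcarve.curation import (
    GAS_CONSTANT_KJ,
    DEFAULT_TEMPERATURE,
    BiomassComponent,
    MissingFormulaError,
    assign_reversibility,
    build_template,
    check_mass_balance,
    detect_energy_cycles,
    estimate_dg_bounds,
    find_blocked,
    prune_blocked,
    screen_mass_balance,
)
from gemcarve.fixtures import make_energy_cycle_toy
from gemcarve.phenotyping import fba

RT_LN_1000 = GAS_CONSTANT_KJ * DEFAULT_TEMPERATURE * math.log(1000.0)


class TestMassBalance:
    def test_balanced_glycolysis_stub(self):
        formulas = {
            "glc": parse_formula("C6H12O6"),
            "lac": parse_formula("C3H6O3"),
        }
        rxn = Reaction("R", {"glc": -1.0, "lac": 2.0})
        assert check_mass_balance(rxn, formulas) == {}

    def test_hydrogen_imbalance(self):
        formulas = {"A": parse_formula("H2O"), "B": parse_formula("HO")}
        rxn = Reaction("R", {"A": -1.0, "B": 1.0})
        assert check_mass_balance(rxn, formulas) == {"H": -1.0}

    def test_exchange_exempt(self):
        rxn = Reaction("EX_A", {"A_e": -1.0}, kind=ReactionKind.EXCHANGE)
        assert check_mass_balance(rxn, {}) == {}

    def test_biomass_exempt(self):
        rxn = Reaction("GROWTH", {"C_c": -1.0}, lb=0, kind=ReactionKind.BIOMASS)
        assert check_mass_balance(rxn, {}) == {}

    def test_missing_formula_flagged_not_removed(self):
        rxn = Reaction("R", {"A": -1.0, "B": 1.0})
        with pytest.raises(MissingFormulaError):
            check_mass_balance(rxn, {"A": parse_formula("CH4")})

    def test_screen_toy6_all_balanced(self, toy6_model):
        report = screen_mass_balance(toy6_model)
        assert not report.unbalanced
        assert not report.unverifiable


class TestDgBounds:
    """Oracle: for A -> B with shared bounds 0.01-10 mM the log-quotient
    spread is exactly RT ln(1000) = 17.12 kJ/mol."""

    @pytest.mark.parametrize(
        "dg0, expect_lo, expect_hi",
        [(-10.0, -27.12, 7.12), (-30.0, -47.12, -12.88), (20.0, 2.88, 37.12)],
    )
    def test_unit_conversion_examples(self, dg0, expect_lo, expect_hi):
        rxn = Reaction("R", {"A": -1.0, "B": 1.0})
        lo, hi = estimate_dg_bounds(rxn, dg0, {})
        assert lo == pytest.approx(dg0 - RT_LN_1000, abs=1e-9)
        assert hi == pytest.approx(dg0 + RT_LN_1000, abs=1e-9)
        assert round(lo, 2) == expect_lo
        assert round(hi, 2) == expect_hi

    def test_stoichiometric_exponents(self):
        rxn = Reaction("R", {"A": -2.0, "B": 1.0})
        lo, hi = estimate_dg_bounds(rxn, 0.0, {})
        rt = GAS_CONSTANT_KJ * DEFAULT_TEMPERATURE
        # max ln Q = ln(cmax) - 2 ln(cmin); concentrations in M
        expect_hi = rt * (math.log(10e-3) - 2 * math.log(0.01e-3))
        assert hi == pytest.approx(expect_hi, abs=1e-9)

    def test_water_and_protons_ignored(self):
        with_water = Reaction("R", {"A": -1.0, "h2o_c": -1.0, "B": 1.0})
        without = Reaction("R", {"A": -1.0, "B": 1.0})
        assert estimate_dg_bounds(with_water, -5.0, {}) == estimate_dg_bounds(
            without, -5.0, {}
        )

    def test_measured_bounds_override_default(self):
        rxn = Reaction("R", {"A": -1.0, "B": 1.0})
        conc = {"A": (1.0, 1.0), "B": (1.0, 1.0)}  # pinned: Q == 1
        lo, hi = estimate_dg_bounds(rxn, -10.0, conc)
        assert lo == pytest.approx(-10.0) and hi == pytest.approx(-10.0)


def two_reaction_model():
    model = Model("m", compartments={"c": "c", "e": "e"}, extracellular="e")
    for mid, comp in [("A_c", "c"), ("B_c", "c"), ("atp_c", "c"), ("adp_c", "c")]:
        model.add_metabolite(Metabolite(mid, compartment=comp))
    model.add_reaction(Reaction("R_AB", {"A_c": -1.0, "B_c": 1.0}, lb=-100, ub=100))
    model.add_reaction(
        Reaction(
            "R_ATP",
            {"atp_c": -1.0, "A_c": -1.0, "adp_c": 1.0, "B_c": 1.0},
            lb=-100,
            ub=100,
        )
    )
    return model


class TestAssignReversibility:
    def test_strictly_negative_forward_only(self):
        model = two_reaction_model()
        out = assign_reversibility(model, {"R_AB": -30.0})
        assert out.reactions["R_AB"].lb == 0.0
        assert out.reactions["R_AB"].ub == 100.0

    def test_strictly_positive_reverse_only(self):
        model = two_reaction_model()
        out = assign_reversibility(model, {"R_AB": 30.0})
        assert out.reactions["R_AB"].ub == 0.0

    def test_atp_heuristic_when_undetermined(self):
        model = two_reaction_model()
        out = assign_reversibility(model, {}, atp_consumers={"R_ATP"})
        assert out.reactions["R_ATP"].lb == 0.0
        # no dG, not curated, not an ATP consumer: untouched
        assert out.reactions["R_AB"].lb == -100.0

    def test_curated_direction_beats_atp_heuristic(self):
        model = two_reaction_model()
        out = assign_reversibility(
            model, {}, curated_directions={"R_ATP": "rev_ok"},
            atp_consumers={"R_ATP"},
        )
        assert out.reactions["R_ATP"].lb == -100.0

    def test_dg_beats_curated(self, caplog):
        model = two_reaction_model()
        with caplog.at_level("WARNING"):
            out = assign_reversibility(
                model, {"R_AB": -30.0}, curated_directions={"R_AB": "rev"}
            )
        assert out.reactions["R_AB"].lb == 0.0
        assert "conflict" in caplog.text.lower()

    def test_never_widens_bounds(self):
        model = two_reaction_model()
        model.reactions["R_AB"].lb = 0.0  # already irreversible
        out = assign_reversibility(
            model, {}, curated_directions={"R_AB": "rev_ok"}
        )
        assert out.reactions["R_AB"].lb >= 0.0


class TestBlockedAndDeadEnds:
    def test_producer_only_metabolite(self):
        model = Model("m", compartments={"c": "c", "e": "e"}, extracellular="e")
        model.add_metabolite(Metabolite("A_e", compartment="e"))
        model.add_metabolite(Metabolite("A_c", compartment="c"))
        model.add_metabolite(Metabolite("X_c", compartment="c"))
        model.add_reaction(
            Reaction("EX_A", {"A_e": -1.0}, kind=ReactionKind.EXCHANGE)
        )
        model.add_reaction(Reaction("T_A", {"A_e": -1.0, "A_c": 1.0}, lb=-100))
        model.add_reaction(Reaction("R_AX", {"A_c": -1.0, "X_c": 1.0}, lb=0))
        blocked, dead = find_blocked(model)
        assert "R_AX" in blocked
        assert "X_c" in dead

    def test_toy6_exd_blocked(self, toy6_model):
        # D_e touches only its exchange: no steady-state flux possible
        blocked, dead = find_blocked(toy6_model)
        assert blocked == {"EX_D"}
        assert dead == {"D_e"}

    def test_chain_blocked_after_deletion(self, toy6_model):
        # without R3 and R2 the B branch cannot reach the biomass drain...
        model = toy6_model.copy()
        model.remove_reactions(["R2", "R3"])
        blocked, dead = find_blocked(model)
        assert "R1" in blocked  # B_c has no consumer left
        assert "B_c" in dead
        assert "C_c" in dead

    def test_prune_reaches_fixpoint_and_preserves_growth(self, toy6_model, toy6_media):
        from gemcarve.core import apply_medium, complete_medium

        before = fba(
            toy6_model, medium=complete_medium(toy6_model)
        ).growth
        pruned, removed_rxns, removed_mets = prune_blocked(toy6_model)
        assert removed_rxns == {"EX_D"}
        assert removed_mets == {"D_e"}
        again, rxns2, mets2 = prune_blocked(pruned)
        assert not rxns2 and not mets2
        after = fba(pruned, medium=complete_medium(pruned)).growth
        assert after == pytest.approx(before, abs=1e-9)


class TestEnergyCycles:
    def test_cycle_detected_with_support(self, energy_cycle_toy):
        cycles = detect_energy_cycles(energy_cycle_toy, "ATPM")
        assert len(cycles) == 1
        assert cycles[0] == {"R_AB", "R_BC", "R_CA", "ATPM"}

    def test_no_cycle_in_toy6(self, toy6_model):
        model = toy6_model.copy()
        model.add_metabolite(Metabolite("atp_c", compartment="c"))
        model.add_metabolite(Metabolite("adp_c", compartment="c"))
        model.add_reaction(
            Reaction("ATPM", {"atp_c": -1.0, "adp_c": 1.0}, lb=0.0)
        )
        assert detect_energy_cycles(model, "ATPM") == []

    def test_fix_removes_cycle(self):
        assert detect_energy_cycles(make_energy_cycle_toy(fixed=True), "ATPM") == []

    def test_requires_maintenance_id(self, energy_cycle_toy):
        with pytest.raises(ValueError, match="maintenance"):
            detect_energy_cycles(energy_cycle_toy, None)


class TestBuildTemplate:
    def test_single_component(self, toy6_model):
        out = build_template(
            toy6_model, [BiomassComponent("C_c", 1.0, 100.0)], "t"
        )
        assert out.reactions["GROWTH"].stoichiometry == {"C_c": -10.0}

    def test_two_components(self, toy6_model):
        out = build_template(
            toy6_model,
            [
                BiomassComponent("B_c", 0.5, 100.0),
                BiomassComponent("C_c", 0.5, 200.0),
            ],
            "t",
        )
        stoich = out.reactions["GROWTH"].stoichiometry
        assert stoich["B_c"] == pytest.approx(-5.0)
        assert stoich["C_c"] == pytest.approx(-2.5)

    def test_uneven_fractions(self, toy6_model):
        out = build_template(
            toy6_model,
            [
                BiomassComponent("B_c", 0.6, 100.0),
                BiomassComponent("C_c", 0.4, 100.0),
            ],
            "t",
        )
        stoich = out.reactions["GROWTH"].stoichiometry
        assert stoich["B_c"] == pytest.approx(-6.0)
        assert stoich["C_c"] == pytest.approx(-4.0)

    def test_unknown_metabolite_listed(self, toy6_model):
        with pytest.raises(ValueError, match="ghost_c"):
            build_template(
                toy6_model, [BiomassComponent("ghost_c", 1.0, 100.0)], "t"
            )

    @pytest.mark.parametrize("seed", range(5))
    def test_mass_normalization_random(self, toy6_model, seed):
        rng = np.random.default_rng(seed)
        mets = ["A_c", "B_c", "C_c"]
        comps = [
            BiomassComponent(m, float(rng.uniform(0.1, 5.0)), float(rng.uniform(10, 1000)))
            for m in mets
        ]
        out = build_template(toy6_model, comps, "t")
        total = sum(
            -coeff * next(c.mw for c in comps if c.metabolite_id == met) / 1000.0
            for met, coeff in out.reactions["GROWTH"].stoichiometry.items()
        )
        assert total == pytest.approx(1.0, abs=1e-9)
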