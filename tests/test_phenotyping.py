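"""FBA/FVA, phenotype arrays, free diffusion, essentiality and metrics."""

import math

import pytest

from gemcarve.core import (
    Medium,
    Metabolite,
    Reaction,
    ReactionKind,
)
from gemcarve.phenotyping import (
    confusion_metrics,
    enable_free_diffusion,
    fba,
    fva,
    gene_essentiality,
    simulate_phenotype_array,
)


class TestFBA:
    def test_toy6_unit_yield(self, toy6_model, toy6_media):
        # hand LP: uptake 10 -> chain at 10 -> growth 10
        assert fba(toy6_model, medium=toy6_media["A10"]).growth == pytest.approx(10.0)

    def test_closed_medium_zero_growth(self, toy6_model, toy6_media):
        assert fba(toy6_model, medium=toy6_media["empty"]).growth == pytest.approx(
            0.0, abs=1e-9
        )

    def test_flux_vector_returned(self, toy6_model, toy6_media):
        result = fba(toy6_model, medium=toy6_media["A10"])
        assert result.fluxes["EX_A"] == pytest.approx(-10.0)
        assert result.fluxes["T_A"] == pytest.approx(10.0)

    def test_missing_objective(self, toy6_model):
        toy6_model.objective = None
        with pytest.raises(ValueError, match="objective"):
            fba(toy6_model)


class TestFVA:
    def test_blocked_reaction_is_zero_zero(self, toy6_model, toy6_media):
        opened = toy6_model.copy()
        ranges = fva(opened, reactions=["EX_D"], medium=Medium({"A": 10, "D": 10}))
        lo, hi = ranges["EX_D"]
        assert lo == pytest.approx(0.0, abs=1e-9)
        assert hi == pytest.approx(0.0, abs=1e-9)

    def test_chain_range(self, toy6_model, toy6_media):
        ranges = fva(toy6_model, reactions=["GROWTH"], medium=toy6_media["A10"])
        assert ranges["GROWTH"] == (pytest.approx(0.0, abs=1e-9), pytest.approx(10.0))


class TestPhenotypeArray:
    def test_toy6_carbon_array(self, toy6_model, toy6_media):
        calls = simulate_phenotype_array(
            toy6_model,
            base_medium=toy6_media["A10"],
            element="C",
            default_source="A",
            sources=["A", "D"],
        )
        assert calls == {"A": True, "D": False}

    def test_growth_exactly_at_threshold_is_viable(self, toy6_model):
        # uptake 0.01 -> growth exactly 0.01 (unit yields); "at least" rule
        calls = simulate_phenotype_array(
            toy6_model,
            base_medium=Medium({"A": 10.0}),
            element="C",
            default_source="A",
            sources=["A"],
            uptake_rate=0.01,
        )
        assert calls["A"] is True

    def test_empty_source_list(self, toy6_model, toy6_media):
        assert (
            simulate_phenotype_array(
                toy6_model, toy6_media["A10"], "C", "A", []
            )
            == {}
        )

    def test_source_without_exchange_warned_nonviable(self, toy6_model, toy6_media):
        with pytest.warns(UserWarning, match="ghost"):
            calls = simulate_phenotype_array(
                toy6_model, toy6_media["A10"], "C", "A", ["ghost"]
            )
        assert calls["ghost"] is False

    def test_missing_default_source(self, toy6_model):
        with pytest.raises(ValueError, match="default"):
            simulate_phenotype_array(
                toy6_model, Medium({"D": 10.0}), "C", "A", ["A"]
            )


class TestFreeDiffusion:
    def add_untransported_b(self, model):
        model.add_metabolite(Metabolite("B_e", compartment="e"))
        model.add_reaction(
            Reaction("EX_B", {"B_e": -1.0}, kind=ReactionKind.EXCHANGE)
        )
        return model

    def test_unlocks_untransported_compound(self, toy6_model, toy6_media):
        model = self.add_untransported_b(toy6_model.copy())
        before = simulate_phenotype_array(
            model, toy6_media["A10"], "C", "A", ["B"]
        )
        assert before["B"] is False
        patched = enable_free_diffusion(model, toy6_model)
        after = simulate_phenotype_array(
            patched, toy6_media["A10"], "C", "A", ["B"]
        )
        assert after["B"] is True  # B_e now diffuses to B_c, feeding R2

    def test_fully_transported_model_unchanged(self, toy6_model):
        model = toy6_model.copy()
        model.remove_reactions(["EX_D"])
        model.remove_orphan_metabolites()
        patched = enable_free_diffusion(model, toy6_model)
        assert list(patched.reactions) == list(model.reactions)

    def test_added_reactions_are_spontaneous_geneless(self, toy6_model):
        model = self.add_untransported_b(toy6_model.copy())
        patched = enable_free_diffusion(model, toy6_model)
        diff = patched.reactions["DIFF_B"]
        assert diff.kind is ReactionKind.SPONTANEOUS
        assert diff.gpr.is_empty
        assert diff.lb < 0 < diff.ub

    def test_never_decreases_viable_calls(self, toy6_model, toy6_media):
        model = self.add_untransported_b(toy6_model.copy())
        sources = ["A", "B", "D"]
        before = simulate_phenotype_array(model, toy6_media["A10"], "C", "A", sources)
        patched = enable_free_diffusion(model, toy6_model)
        after = simulate_phenotype_array(patched, toy6_media["A10"], "C", "A", sources)
        assert sum(after.values()) >= sum(before.values())


class TestEssentiality:
    def test_single_path_gene_essential(self, toy6_model, toy6_media):
        model = toy6_model.copy()
        model.remove_reactions(["R3"])
        essential = gene_essentiality(model, medium=toy6_media["A10"])
        assert "g2" in essential  # sole gene of R1
        assert "g1" in essential  # sole transporter gene

    def test_isozyme_not_essential(self, toy6_model, toy6_media):
        model = toy6_model.copy()
        model.remove_reactions(["R3"])
        essential = gene_essentiality(model, medium=toy6_media["A10"])
        assert "g3" not in essential and "g4" not in essential

    def test_reroute_rescues_deletion(self, toy6_model, toy6_media):
        essential = gene_essentiality(toy6_model, medium=toy6_media["A10"])
        assert "g2" not in essential  # R3 bypasses R1/R2

    def test_unknown_gene_skipped_with_warning(self, toy6_model, toy6_media):
        with pytest.warns(UserWarning, match="g99"):
            essential = gene_essentiality(
                toy6_model, medium=toy6_media["A10"], genes=["g99", "g1"]
            )
        assert "g99" not in essential

    def test_monotone_under_medium_restriction(self, toy6_model):
        model = toy6_model.copy()
        model.remove_reactions(["R3"])
        rich = gene_essentiality(model, medium=Medium({"A": 10.0, "D": 10.0}))
        poor = gene_essentiality(model, medium=Medium({"A": 5.0}))
        assert rich <= poor


class TestConfusionMetrics:
    def test_worked_example(self):
        # TP=2 FP=1 TN=3 FN=0
        predicted = [1, 1, 1, 0, 0, 0]
        observed = [1, 1, 0, 0, 0, 0]
        metrics = confusion_metrics(predicted, observed)
        assert metrics["precision"] == pytest.approx(2 / 3)
        assert metrics["sensitivity"] == pytest.approx(1.0)
        assert metrics["specificity"] == pytest.approx(0.75)
        assert metrics["accuracy"] == pytest.approx(5 / 6)
        assert metrics["f1"] == pytest.approx(0.8)

    def test_perfect_prediction(self):
        metrics = confusion_metrics([1, 0, 1], [1, 0, 1])
        for value in metrics.values():
            assert value == pytest.approx(1.0)

    def test_undefined_ratios_are_nan_not_zero(self):
        metrics = confusion_metrics([0, 0], [0, 0])
        assert math.isnan(metrics["precision"])
        assert math.isnan(metrics["sensitivity"])
        assert metrics["specificity"] == pytest.approx(1.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion_metrics([1], [1, 0])

    def test_f1_is_harmonic_mean(self):
        predicted = [1, 1, 0, 0, 1]
        observed = [1, 0, 1, 0, 1]
        metrics = confusion_metrics(predicted, observed)
        p, s = metrics["precision"], metrics["sensitivity"]
        assert metrics["f1"] == pytest.approx(2 * p * s / (p + s))

    def test_bounded_in_unit_interval(self):
        import itertools

        for bits in itertools.product([0, 1], repeat=6):
            predicted, observed = bits[:3], bits[3:]
            for value in confusion_metrics(predicted, observed).values():
                assert math.isnan(value) or 0.0 <= value <= 1.0
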