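"""Simulation engines and phenotype prediction.

Flux balance analysis (FBA), flux variability analysis (FVA),
Biolog-style phenotype-array simulation, free-diffusion augmentation,
single-gene essentiality, and binary confusion metrics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .core import (
    DEFAULT_MAX_FLUX,
    GPRExpression,
    Medium,
    Metabolite,
    Model,
    Reaction,
    ReactionKind,
    apply_medium,
)
from .solver import LinearProblem

__all__ = [
    "FBAResult",
    "fba",
    "fva",
    "simulate_phenotype_array",
    "enable_free_diffusion",
    "gene_essentiality",
    "confusion_metrics",
]

VIABILITY_THRESHOLD = 0.01  # growth rate (1/h) calling a phenotype viable
ESSENTIALITY_THRESHOLD = 1e-6  # growth below this after deletion => essential
PHENOTYPE_UPTAKE_RATE = 10.0  # mmol/gDW/h per array compound


@dataclass
class FBAResult:
    status: str
    objective_value: float | None = None
    fluxes: dict[str, float] = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    @property
    def growth(self) -> float:
        """Objective optimum, or 0 for an infeasible problem."""
        if self.status == "infeasible" or self.objective_value is None:
            return 0.0
        return self.objective_value


def _base_problem(model: Model) -> LinearProblem:
    problem = LinearProblem(model.id)
    for rxn in model.reactions.values():
        problem.add_variable(rxn.id, rxn.lb, rxn.ub)
    balance: dict[str, dict[str, float]] = {m: {} for m in model.metabolites}
    for rxn in model.reactions.values():
        for met_id, coeff in rxn.stoichiometry.items():
            balance[met_id][rxn.id] = coeff
    for met_id, row in balance.items():
        if row:
            problem.add_constraint(row, 0.0, 0.0)
    return problem


def fba(
    model: Model,
    medium: Medium | None = None,
    objective: str | None = None,
    maximize: bool = True,
) -> FBAResult:
    """Flux balance analysis: optimize one reaction flux at steady state."""
    if medium is not None:
        model = apply_medium(model, medium)
    objective = objective or model.objective
    if objective is None or objective not in model.reactions:
        raise ValueError(f"objective reaction {objective!r} not in model")
    problem = _base_problem(model)
    problem.set_objective({objective: 1.0}, "max" if maximize else "min")
    sol = problem.solve()
    if sol.status == "unbounded":
        # diagnostic for energy cycles / missing bounds
        return FBAResult("unbounded")
    if not sol.optimal:
        return FBAResult(sol.status)
    return FBAResult("optimal", sol.objective, sol.values)


def fva(
    model: Model,
    reactions: Iterable[str] | None = None,
    medium: Medium | None = None,
) -> dict[str, tuple[float, float]]:
    """Per-reaction feasible flux range (two LPs per reaction)."""
    if medium is not None:
        model = apply_medium(model, medium)
    rxn_ids = list(reactions) if reactions is not None else list(model.reactions)
    problem = _base_problem(model)
    out: dict[str, tuple[float, float]] = {}
    for rid in rxn_ids:
        bounds = []
        for sense in ("min", "max"):
            problem.set_objective({rid: 1.0}, sense)
            sol = problem.solve()
            if sol.status == "infeasible":
                raise ValueError("FVA on infeasible model")
            if sol.status == "unbounded":
                bounds.append(-math.inf if sense == "min" else math.inf)
            else:
                bounds.append(sol.objective)
        out[rid] = (bounds[0], bounds[1])
    return out


# ---------------------------------------------------------------------------
# phenotype arrays
# ---------------------------------------------------------------------------


def simulate_phenotype_array(
    model: Model,
    base_medium: Medium,
    element: str,
    default_source: str,
    sources: Sequence[str],
    uptake_rate: float = PHENOTYPE_UPTAKE_RATE,
    viability_threshold: float = VIABILITY_THRESHOLD,
) -> dict[str, bool]:
    """Substrate-utilization calls for one element array.

    The default source of the element in the base medium is swapped for
    each candidate compound at ``uptake_rate``; a source is viable iff FBA
    growth is at least ``viability_threshold``. Compounds without an
    exchange reaction in the model are called non-viable (transporter-gap
    semantics) with a warning.
    """
    if default_source not in base_medium:
        raise ValueError(
            f"base medium lacks the declared default {element} source "
            f"{default_source!r}"
        )
    compounds = model.exchanges_by_compound()
    calls: dict[str, bool] = {}
    for source in sources:
        if source not in compounds:
            warnings.warn(
                f"array compound {source!r} has no exchange reaction; "
                "called non-viable",
                stacklevel=2,
            )
            calls[source] = False
            continue
        medium = base_medium.replace_source(default_source, source, uptake_rate)
        growth = fba(model, medium=medium).growth
        calls[source] = growth >= viability_threshold
    return calls


def enable_free_diffusion(model: Model, universe: Model) -> Model:
    """Add passive transport for extracellular metabolites lacking one.

    For every extracellular metabolite of the model with no associated
    transport reaction, a reversible diffusion reaction into the cytosol
    (and an exchange reaction, if absent) is added. Added reactions carry
    no genes and are marked spontaneous. The universe supplies formulas
    for newly created cytosolic partners.
    """
    out = model.copy()
    ext = out.extracellular
    transported: set[str] = set()
    exchanged: set[str] = set()
    for rxn in out.reactions.values():
        ext_mets = [
            m for m in rxn.stoichiometry if out.metabolites[m].compartment == ext
        ]
        if rxn.kind is ReactionKind.EXCHANGE:
            exchanged.update(ext_mets)
        elif ext_mets and len(ext_mets) < len(rxn.stoichiometry):
            transported.update(ext_mets)

    cytosol = next(
        (c for c in out.compartments if c != ext), "c"
    )
    out.add_compartment(cytosol)

    for met_id in list(out.metabolites):
        met = out.metabolites[met_id]
        if met.compartment != ext or met_id in transported:
            continue
        base = met_id[: -len(f"_{ext}")] if met_id.endswith(f"_{ext}") else met_id
        partner = f"{base}_{cytosol}"
        if partner not in out.metabolites:
            template = universe.metabolites.get(partner)
            out.add_metabolite(
                Metabolite(
                    id=partner,
                    name=template.name if template else base,
                    compartment=cytosol,
                    formula=dict(template.formula)
                    if template and template.formula
                    else (dict(met.formula) if met.formula else None),
                    charge=template.charge if template else met.charge,
                )
            )
        diff_id = f"DIFF_{base}"
        if diff_id not in out.reactions:
            out.add_reaction(
                Reaction(
                    id=diff_id,
                    stoichiometry={met_id: -1.0, partner: 1.0},
                    lb=-DEFAULT_MAX_FLUX,
                    ub=DEFAULT_MAX_FLUX,
                    gpr=GPRExpression(),
                    kind=ReactionKind.SPONTANEOUS,
                )
            )
        if met_id not in exchanged:
            ex_id = f"EX_{base}"
            if ex_id not in out.reactions:
                out.add_reaction(
                    Reaction(
                        id=ex_id,
                        stoichiometry={met_id: -1.0},
                        lb=0.0,
                        ub=DEFAULT_MAX_FLUX,
                        kind=ReactionKind.EXCHANGE,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# gene essentiality
# ---------------------------------------------------------------------------


def knockout_reactions(model: Model, gene: str) -> list[str]:
    """Reactions disabled by deleting one gene (no surviving DNF complex).

    Reactions with empty GPRs (spontaneous, exchanges) are immune.
    """
    disabled = []
    for rxn in model.reactions.values():
        if rxn.gpr.is_empty or gene not in rxn.gpr.genes:
            continue
        remaining = rxn.gpr.genes - {gene}
        if not rxn.gpr.evaluate(remaining):
            disabled.append(rxn.id)
    return disabled


def gene_essentiality(
    model: Model,
    medium: Medium | None = None,
    genes: Iterable[str] | None = None,
    threshold: float = ESSENTIALITY_THRESHOLD,
) -> set[str]:
    """Single-gene deletion screen; returns the essential gene set."""
    if medium is not None:
        model = apply_medium(model, medium)
    model_genes = model.genes
    if genes is None:
        candidates = sorted(model_genes)
    else:
        candidates = []
        for gene in genes:
            if gene not in model_genes:
                warnings.warn(f"gene {gene!r} not in model GPRs; skipped", stacklevel=2)
                continue
            candidates.append(gene)
    essential: set[str] = set()
    for gene in candidates:
        disabled = knockout_reactions(model, gene)
        if not disabled:
            continue
        mutant = model.copy()
        for rid in disabled:
            mutant.reactions[rid].lb = 0.0
            mutant.reactions[rid].ub = 0.0
        if fba(mutant).growth < threshold:
            essential.add(gene)
    return essential


# ---------------------------------------------------------------------------
# confusion metrics
# ---------------------------------------------------------------------------


def confusion_metrics(
    predicted: Sequence[bool], observed: Sequence[bool]
) -> dict[str, float]:
    """Precision, sensitivity, specificity, accuracy and F1.

    Ratios with a zero denominator are reported as NaN, never as 0.
    """
    if len(predicted) != len(observed):
        raise ValueError(
            f"length mismatch: {len(predicted)} predictions vs "
            f"{len(observed)} observations"
        )
    tp = sum(1 for p, o in zip(predicted, observed) if p and o)
    fp = sum(1 for p, o in zip(predicted, observed) if p and not o)
    tn = sum(1 for p, o in zip(predicted, observed) if not p and not o)
    fn = sum(1 for p, o in zip(predicted, observed) if not p and o)

    def ratio(num: float, den: float) -> float:
        return num / den if den > 0 else math.nan

    return {
        "precision": ratio(tp, tp + fp),
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "accuracy": ratio(tp + tn, tp + fp + tn + fn),
        "f1": ratio(2 * tp, 2 * tp + fn + fp),
    }
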