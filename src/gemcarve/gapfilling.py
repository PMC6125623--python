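"""Score-weighted gap-filling against growth media.

For each medium where the model fails to grow, a MILP picks the
cheapest set of universe reactions to add:

    min  sum_{i in R} 1 / (1 + s_i) * y_i
    s.t. S v = 0
         lb <= v <= ub            (model reactions)
         y_i lb_i <= v_i <= y_i ub_i   (candidates R)
         v_growth >= min_growth

where R is the universe minus the current model and s_i is the
evidence-based score of candidate i (0 when it has none, negative values
clamped to 0 so the weight stays defined). Media are processed
sequentially in the given order and additions accumulate; with all
scores equal the objective degenerates to minimizing the number of added
reactions.
"""

from __future__ import annotations

import logging

from .carving import CarveParams
from .core import Medium, Model, apply_medium
from .phenotyping import fba
from .scoring import ReactionScoreTable
from .solver import LinearProblem

__all__ = ["GapfillError", "gapfill", "gapfill_weights"]

logger = logging.getLogger(__name__)


class GapfillError(RuntimeError):
    """No feasible extension enables growth on a medium."""


def gapfill_weights(
    universe: Model, scores: ReactionScoreTable | dict[str, float] | None
) -> dict[str, float]:
    """Objective weight 1/(1+s_i) per universe reaction, s clamped to >= 0."""
    if scores is None:
        evidence: dict[str, float] = {}
    elif isinstance(scores, ReactionScoreTable):
        evidence = scores.evidence_scores()
    else:
        evidence = scores
    weights = {}
    for rid in universe.reactions:
        s = evidence.get(rid, 0.0)
        if s < 0:
            logger.warning(
                "gapfill: negative score %.3g for %s clamped to 0", s, rid
            )
            s = 0.0
        weights[rid] = 1.0 / (1.0 + s)
    return weights


def _combined_model(model: Model, universe: Model) -> tuple[Model, list[str]]:
    """Model plus all universe reactions it lacks; returns candidate ids."""
    import copy

    combined = universe.copy()
    for rid, rxn in model.reactions.items():
        if rid not in combined.reactions:
            raise GapfillError(
                f"model reaction {rid!r} does not resolve in the universe"
            )
        combined.reactions[rid] = copy.deepcopy(rxn)
    candidates = [r for r in combined.reactions if r not in model.reactions]
    return combined, candidates


def _solve_gapfill_milp(
    combined: Model,
    candidates: list[str],
    weights: dict[str, float],
    params: CarveParams,
) -> set[str] | None:
    growth_id = combined.objective
    problem = LinearProblem("gapfill")
    candidate_set = set(candidates)
    for rxn in combined.reactions.values():
        problem.add_variable(f"v_{rxn.id}", min(rxn.lb, 0.0) if rxn.id in candidate_set else rxn.lb,
                             max(rxn.ub, 0.0) if rxn.id in candidate_set else rxn.ub)
    objective = {}
    for rid in candidates:
        rxn = combined.reactions[rid]
        problem.add_variable(f"y_{rid}", 0, 1, integer=True)
        # y lb <= v <= y ub
        problem.add_constraint({f"v_{rid}": 1.0, f"y_{rid}": -rxn.lb}, lb=0.0)
        problem.add_constraint({f"v_{rid}": 1.0, f"y_{rid}": -rxn.ub}, ub=0.0)
        objective[f"y_{rid}"] = weights[rid]
    balance: dict[str, dict[str, float]] = {m: {} for m in combined.metabolites}
    for rxn in combined.reactions.values():
        for met_id, coeff in rxn.stoichiometry.items():
            balance[met_id][f"v_{rxn.id}"] = coeff
    for row in balance.values():
        if row:
            problem.add_constraint(row, 0.0, 0.0)
    problem.add_constraint({f"v_{growth_id}": 1.0}, lb=params.min_growth)
    problem.set_objective(objective, "min")
    sol = problem.solve(mip_gap=params.mip_gap)
    if not sol.optimal:
        return None
    return {r for r in candidates if sol.values[f"y_{r}"] > 0.5}


def gapfill(
    model: Model,
    universe: Model,
    scores: ReactionScoreTable | dict[str, float] | None,
    media: list[Medium],
    params: CarveParams | None = None,
) -> tuple[Model, dict[str, list[str]]]:
    """Extend a model so it grows on every medium, in order.

    Returns the extended model and, per medium id, the reactions added
    for it. Media where the model already reaches ``params.min_growth``
    contribute nothing.
    """
    params = params or CarveParams()
    weights = gapfill_weights(universe, scores)
    current = model.copy()
    added_per_medium: dict[str, list[str]] = {}
    for idx, medium in enumerate(media):
        label = medium.id or f"medium_{idx}"
        if label in added_per_medium:  # same medium listed twice
            label = f"{label}#{idx}"
        if current.objective is None:
            raise GapfillError("model has no objective reaction")
        growth = fba(current, medium=medium).growth
        if growth >= params.min_growth:
            added_per_medium[label] = []
            continue
        combined, candidates = _combined_model(current, universe)
        combined = apply_medium(combined, medium)
        added = _solve_gapfill_milp(combined, candidates, weights, params)
        if added is None:
            raise GapfillError(
                f"no feasible gap-fill extension for medium {label!r}"
            )
        _graft_reactions(current, universe, added)
        added_per_medium[label] = sorted(added)
    return current, added_per_medium


def _graft_reactions(model: Model, universe: Model, rxn_ids: set[str]) -> None:
    """Copy reactions (and any missing metabolites) from the universe."""
    import copy

    for rid in sorted(rxn_ids):
        rxn = universe.reactions[rid]
        for met_id in rxn.stoichiometry:
            if met_id not in model.metabolites:
                model.add_metabolite(copy.deepcopy(universe.metabolites[met_id]))
        model.add_reaction(copy.deepcopy(rxn))
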