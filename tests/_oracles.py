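"""Independent brute-force oracles used to freeze expected values.

These deliberately avoid the package's solver layer: LPs are assembled
by hand and passed straight to scipy.optimize.linprog, and combinatorial
optima come from exhaustive enumeration over subnetworks / direction
assignments. They are only tractable on toy instances (<= ~10 reactions)
and exist so the MILP implementations can be checked against an
independent route.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.optimize import linprog

from gemcarve.core import Model, ReactionKind, apply_medium, complete_medium


def _lp_feasible(
    model: Model,
    var_bounds: dict[str, tuple[float, float]],
    growth_id: str,
    min_growth: float,
) -> bool:
    """Feasibility of S v = 0 under explicit per-reaction bounds."""
    rxn_ids = list(model.reactions)
    index = {r: i for i, r in enumerate(rxn_ids)}
    n = len(rxn_ids)
    met_rows: dict[str, np.ndarray] = {}
    for rid, rxn in model.reactions.items():
        for met, coeff in rxn.stoichiometry.items():
            row = met_rows.setdefault(met, np.zeros(n))
            row[index[rid]] = coeff
    a_eq = np.array(list(met_rows.values())) if met_rows else np.zeros((0, n))
    b_eq = np.zeros(a_eq.shape[0])
    bounds = []
    for rid in rxn_ids:
        lo, hi = var_bounds[rid]
        if rid == growth_id:
            lo = max(lo, min_growth)
            if lo > hi:
                return False
        bounds.append((lo, hi))
    res = linprog(
        c=np.zeros(n), A_eq=a_eq, b_eq=b_eq, bounds=bounds, method="highs"
    )
    return res.status == 0


def brute_force_carve(
    model: Model,
    scores: dict[str, float],
    epsilon: float = 1e-3,
    big_m: float = 100.0,
    min_growth: float = 0.1,
    soft: dict[str, int] | None = None,
    soft_weight: float = 1.0,
) -> tuple[float, set[str]] | None:
    """Exhaustive search over off/forward/reverse assignments.

    Returns (best objective, one best active set) or None if no
    assignment sustains growth.
    """
    soft = soft or {}
    opened = apply_medium(model, complete_medium(model, big_m))
    rxn_ids = list(opened.reactions)
    options = []
    for rid in rxn_ids:
        rxn = opened.reactions[rid]
        lb, ub = max(rxn.lb, -big_m), min(rxn.ub, big_m)
        states = [("off", (0.0, 0.0))]
        if ub > 0:
            states.append(("fwd", (epsilon, ub)))
        if lb < 0:
            states.append(("rev", (lb, -epsilon)))
        options.append(states)

    best: tuple[float, set[str]] | None = None
    growth_id = opened.objective
    for assignment in itertools.product(*options):
        states = dict(zip(rxn_ids, (s for s, _ in assignment)))
        if states[growth_id] != "fwd":
            continue
        var_bounds = dict(zip(rxn_ids, (b for _, b in assignment)))
        objective = 0.0
        for rid, state in states.items():
            if state == "off":
                continue
            objective += scores.get(rid, 0.0)
            pref = soft.get(rid)
            if pref == 1 and state == "fwd":
                objective += soft_weight
            elif pref == -1 and state == "rev":
                objective += soft_weight
            elif pref == 0:
                objective -= soft_weight
        if best is not None and objective <= best[0]:
            continue
        if _lp_feasible(opened, var_bounds, growth_id, min_growth):
            active = {r for r, s in states.items() if s != "off"}
            best = (objective, active)
    return best


def brute_force_gapfill(
    model: Model,
    universe: Model,
    weights: dict[str, float],
    min_growth: float = 0.1,
) -> tuple[float, set[str]] | None:
    """Cheapest candidate subset restoring growth, by enumeration.

    ``model`` must already have medium bounds applied; candidate
    reactions adopt the (medium-applied) universe bounds when included.
    """
    candidates = [r for r in universe.reactions if r not in model.reactions]
    best: tuple[float, set[str]] | None = None
    for k in range(len(candidates) + 1):
        for subset in itertools.combinations(candidates, k):
            cost = sum(weights[r] for r in subset)
            if best is not None and cost >= best[0]:
                continue
            trial = model.copy()
            for rid in subset:
                rxn = universe.reactions[rid]
                for met in rxn.stoichiometry:
                    if met not in trial.metabolites:
                        import copy

                        trial.add_metabolite(copy.deepcopy(universe.metabolites[met]))
                import copy

                trial.add_reaction(copy.deepcopy(rxn))
            var_bounds = {r.id: (r.lb, r.ub) for r in trial.reactions.values()}
            if _lp_feasible(trial, var_bounds, trial.objective, min_growth):
                best = (cost, set(subset))
    return best


def brute_force_minimal_medium(
    model: Model,
    compound_groups: dict[str, list[str]],
    growth_ids: list[str],
    min_growth: float = 0.1,
    big_m: float = 100.0,
) -> set[str] | None:
    """Smallest compound subset sustaining all growth reactions."""
    compounds = sorted(compound_groups)
    for k in range(len(compounds) + 1):
        for subset in itertools.combinations(compounds, k):
            allowed = {r for c in subset for r in compound_groups[c]}
            var_bounds = {}
            for rxn in model.reactions.values():
                lb, ub = rxn.lb, rxn.ub
                if rxn.id in {r for g in compound_groups.values() for r in g}:
                    lb = -big_m if rxn.id in allowed else 0.0
                var_bounds[rxn.id] = (lb, ub)
            if _lp_all_growing(model, var_bounds, growth_ids, min_growth):
                return set(subset)
    return None


def _lp_all_growing(
    model: Model,
    var_bounds: dict[str, tuple[float, float]],
    growth_ids: list[str],
    min_growth: float,
) -> bool:
    bounds = dict(var_bounds)
    for gid in growth_ids:
        lo, hi = bounds[gid]
        lo = max(lo, min_growth)
        if lo > hi:
            return False
        bounds[gid] = (lo, hi)
    return _lp_feasible(model, bounds, growth_ids[0], min_growth)


def truth_table_eval(text: str, present: set[str], genes: list[str]) -> bool:
    """Evaluate a GPR string directly with Python booleans."""
    expr = text
    for gene in sorted(genes, key=len, reverse=True):
        expr = expr.replace(gene, "True" if gene in present else "False")
    return bool(eval(expr))  # test-only oracle
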