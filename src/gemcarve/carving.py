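"""Model carving: MILP selection of an organism-specific subnetwork.

The carve MILP maximizes the total score of activated reactions while
requiring a steady-state flux certificate in which every activated
reaction carries at least epsilon flux and the biomass reaction at least
the minimum growth rate:

    max  s' (yf + yr)
    s.t. S v = 0
         v >= -M yr + eps yf      (per reaction)
         v <=  M yf - eps yr
         yf + yr <= 1,  yf, yr binary
         v_growth >= min_growth

Irreversibility is encoded by fixing the opposing binary to zero. The
MILP is solved with all exchanges open (complete medium), making carving
context-independent: connectivity comes from genetic evidence alone.
Strict inequalities of the formulation are implemented as closed ones
(epsilon already separates "on" from "off").
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import (
    DEFAULT_MAX_FLUX,
    GPRExpression,
    Model,
    apply_medium,
    complete_medium,
)
from .scoring import ReactionScoreTable
from .solver import LinearProblem

__all__ = [
    "CarveParams",
    "SoftConstraintSet",
    "HardConstraintSet",
    "CarveSolution",
    "CarveError",
    "HardConstraintInfeasibleError",
    "carve",
    "prune_to_model",
]


class CarveError(RuntimeError):
    """The carve MILP is infeasible on the given universe."""


class HardConstraintInfeasibleError(CarveError):
    """Infeasibility introduced by user-provided hard constraints."""


@dataclass
class CarveParams:
    epsilon: float = 1e-3  # minimum flux of an active reaction, mmol/gDW/h
    bigM: float = DEFAULT_MAX_FLUX  # flux cap, mmol/gDW/h
    min_growth: float = 0.1  # 1/h
    mip_gap: float = 1e-9
    seed: int | None = None  # recorded for provenance; the solver is deterministic

    def __post_init__(self) -> None:
        if not (0 < self.epsilon < self.bigM):
            raise ValueError("need 0 < epsilon < bigM")
        if self.min_growth <= 0:
            raise ValueError("min_growth must be positive")


@dataclass
class SoftConstraintSet:
    """Reaction preferences: +1 forward, -1 backward, 0 should not occur."""

    values: dict[str, int] = field(default_factory=dict)
    weight: float = 1.0

    def __post_init__(self) -> None:
        bad = {r: v for r, v in self.values.items() if v not in (-1, 0, 1)}
        if bad:
            raise ValueError(f"soft-constraint values must be -1/0/1: {bad}")


@dataclass
class HardConstraintSet:
    """Flux-bound overrides v_min <= v <= v_max per reaction."""

    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rid, (lo, hi) in self.bounds.items():
            if lo > hi:
                raise ValueError(f"hard constraint {rid}: v_min > v_max")


@dataclass
class CarveSolution:
    kept: set[str]
    y_forward: dict[str, int]
    y_reverse: dict[str, int]
    fluxes: dict[str, float]  # certificate flux vector
    objective: float
    model: Model | None = None


def _solve_carve_milp(
    universe: Model,
    scores: dict[str, float],
    params: CarveParams,
    soft: SoftConstraintSet | None,
    hard: HardConstraintSet | None,
) -> "tuple[str, CarveSolution | None]":
    eps, big_m = params.epsilon, params.bigM
    growth_id = universe.objective
    if growth_id is None:
        raise CarveError("universe has no biomass/objective reaction")

    opened = apply_medium(universe, complete_medium(universe, big_m))

    problem = LinearProblem("carve")
    objective: dict[str, float] = {}
    for rxn in opened.reactions.values():
        lb = max(rxn.lb, -big_m)
        ub = min(rxn.ub, big_m)
        problem.add_variable(f"v_{rxn.id}", lb, ub)
        fwd_allowed = ub > 0
        rev_allowed = lb < 0
        problem.add_variable(
            f"yf_{rxn.id}", 0, 1 if fwd_allowed else 0, integer=True
        )
        problem.add_variable(
            f"yr_{rxn.id}", 0, 1 if rev_allowed else 0, integer=True
        )
        # v >= -M yr + eps yf  and  v <= M yf - eps yr
        problem.add_constraint(
            {f"v_{rxn.id}": 1.0, f"yr_{rxn.id}": big_m, f"yf_{rxn.id}": -eps},
            lb=0.0,
        )
        problem.add_constraint(
            {f"v_{rxn.id}": 1.0, f"yf_{rxn.id}": -big_m, f"yr_{rxn.id}": eps},
            ub=0.0,
        )
        problem.add_constraint(
            {f"yf_{rxn.id}": 1.0, f"yr_{rxn.id}": 1.0}, ub=1.0
        )
        score = scores.get(rxn.id, 0.0)
        objective[f"yf_{rxn.id}"] = score
        objective[f"yr_{rxn.id}"] = score

    if soft is not None:
        for rid, value in soft.values.items():
            if rid not in opened.reactions:
                continue
            if value == 1:
                objective[f"yf_{rid}"] += soft.weight
            elif value == -1:
                objective[f"yr_{rid}"] += soft.weight
            else:  # reaction should not occur
                objective[f"yf_{rid}"] -= soft.weight
                objective[f"yr_{rid}"] -= soft.weight

    if hard is not None:
        for rid, (lo, hi) in hard.bounds.items():
            if rid in opened.reactions:
                problem.set_bounds(f"v_{rid}", lo, hi)

    # steady state
    balance: dict[str, dict[str, float]] = {m: {} for m in opened.metabolites}
    for rxn in opened.reactions.values():
        for met_id, coeff in rxn.stoichiometry.items():
            balance[met_id][f"v_{rxn.id}"] = coeff
    for row in balance.values():
        if row:
            problem.add_constraint(row, 0.0, 0.0)

    problem.add_constraint({f"v_{growth_id}": 1.0}, lb=params.min_growth)
    problem.set_objective(objective, "max")
    sol = problem.solve(mip_gap=params.mip_gap)
    if not sol.optimal:
        return sol.status, None

    y_f = {r: int(round(sol.values[f"yf_{r}"])) for r in opened.reactions}
    y_r = {r: int(round(sol.values[f"yr_{r}"])) for r in opened.reactions}
    fluxes = {r: sol.values[f"v_{r}"] for r in opened.reactions}
    kept = {r for r in opened.reactions if y_f[r] or y_r[r]}
    return "optimal", CarveSolution(kept, y_f, y_r, fluxes, sol.objective)


def carve(
    universe: Model,
    scores: ReactionScoreTable | dict[str, float],
    params: CarveParams | None = None,
    soft: SoftConstraintSet | None = None,
    hard: HardConstraintSet | None = None,
) -> CarveSolution:
    """Carve an organism model out of the universe.

    ``scores`` is either a full ReactionScoreTable or a plain
    reaction -> score map (missing reactions score 0). After the MILP,
    inactive reactions are removed along with orphaned metabolites and
    genes; organism GPRs are attached when a score table is given.
    """
    params = params or CarveParams()
    score_map = scores.scores if isinstance(scores, ReactionScoreTable) else scores
    status, solution = _solve_carve_milp(universe, score_map, params, soft, hard)
    if solution is None:
        if hard is not None and hard.bounds:
            retry_status, retry = _solve_carve_milp(
                universe, score_map, params, soft, None
            )
            if retry is not None:
                raise HardConstraintInfeasibleError(
                    f"carve MILP {status}: the hard constraints make the "
                    "problem infeasible (it is feasible without them)"
                )
        raise CarveError(
            f"carve MILP {status}: universe cannot sustain growth >= "
            f"{params.min_growth} under complete medium"
        )
    gprs = scores.gprs if isinstance(scores, ReactionScoreTable) else None
    solution.model = prune_to_model(universe, solution, gprs)
    return solution


def prune_to_model(
    universe: Model,
    solution: CarveSolution,
    organism_gprs: dict[str, GPRExpression] | None = None,
) -> Model:
    """Induced submodel on the kept reactions.

    Bounds are inherited from the universe, orphaned metabolites (and,
    through the per-reaction GPRs, orphaned genes) disappear. When
    organism GPRs are available they replace the universe rules;
    evidence-less reactions that were carved in for connectivity keep no
    genes.
    """
    model = universe.copy()
    model.remove_reactions(
        [r for r in universe.reactions if r not in solution.kept]
    )
    model.remove_orphan_metabolites()
    if organism_gprs is not None:
        for rxn in model.reactions.values():
            rxn.gpr = organism_gprs.get(rxn.id, GPRExpression())
    return model
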