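"""Microbial community models.

Single-species models are merged into one network in which every member
keeps its own namespaced compartments (``c__member``) while the
extracellular environment is a shared pool. Options cover isolated
per-member extracellular compartments bridged to the pool by shuttle
reactions, a common community biomass reaction (equal 1/n member
weights), and initialization with a growth medium.

The metabolic interaction potential (MIP) of a community is the
reduction in minimal-medium size allowed by metabolite exchange: the
minimal medium of the non-interacting community (isolated extracellular
compartments, no cross-feeding shuttles, per-member boundary exchanges)
minus that of the interacting community (shared pool).
"""

from __future__ import annotations

import copy
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
    "CommunityModel",
    "CommunityError",
    "merge_community",
    "minimal_medium",
    "mip_score",
]

SEP = "__"  # namespacing separator (kept SId-safe for SBML export)


class CommunityError(RuntimeError):
    pass


@dataclass
class CommunityModel:
    """A merged multi-species model plus its bookkeeping."""

    model: Model
    members: list[str]
    member_biomass: dict[str, str]  # member id -> biomass reaction id
    pool_compartment: str
    # compound -> exchange reaction ids feeding it (one entry per compound
    # even when several members exchange it independently)
    compound_groups: dict[str, list[str]] = field(default_factory=dict)
    interacting: bool = True


def _namespace(identifier: str, member: str) -> str:
    return f"{identifier}{SEP}{member}"


def _namespace_gpr(gpr: GPRExpression, member: str) -> GPRExpression:
    if gpr.is_empty:
        return gpr
    return GPRExpression.from_complexes(
        [{_namespace(g, member) for g in cplx} for cplx in gpr.complexes]
    )


def merge_community(
    models: Sequence[Model],
    isolated_extracellular: bool = False,
    community_biomass: bool = False,
    medium: Medium | None = None,
    interacting: bool = True,
) -> CommunityModel:
    """Merge single-species models into one community model.

    Extracellular metabolite ids must come from a shared vocabulary.
    With ``interacting=False`` the members keep fully isolated
    extracellular compartments with their own boundary exchanges and no
    shared pool (the non-interacting baseline of the MIP score);
    ``isolated_extracellular`` instead bridges isolated compartments to
    the pool with shuttle reactions.
    """
    if not models:
        raise CommunityError("need at least one member model")
    member_ids = [m.id for m in models]
    if len(set(member_ids)) != len(member_ids):
        raise CommunityError(f"duplicate member ids: {member_ids}")

    pool = models[0].extracellular
    merged = Model(
        "community_" + "_".join(member_ids),
        extracellular=pool,
        annotation={"COMMUNITY_MEMBERS": ",".join(member_ids)},
    )
    if interacting:
        merged.add_compartment(pool, "extracellular pool")

    member_biomass: dict[str, str] = {}
    compound_groups: dict[str, list[str]] = {}
    pool_exchanges: dict[str, str] = {}  # compound -> exchange id

    for member in models:
        mid = member.id
        ext = member.extracellular
        met_map: dict[str, str] = {}

        for comp_id, comp_name in member.compartments.items():
            if comp_id != ext or isolated_extracellular or not interacting:
                merged.add_compartment(_namespace(comp_id, mid), comp_name)

        for met in member.metabolites.values():
            if met.compartment == ext and interacting and not isolated_extracellular:
                new_id, new_comp = met.id, pool
            else:
                new_id = _namespace(met.id, mid)
                new_comp = _namespace(met.compartment, mid)
            met_map[met.id] = new_id
            if new_id not in merged.metabolites:
                clone = copy.deepcopy(met)
                clone.id, clone.compartment = new_id, new_comp
                merged.add_metabolite(clone)

        for rxn in member.reactions.values():
            if rxn.kind is ReactionKind.EXCHANGE:
                (met_id,) = rxn.stoichiometry
                compound = member.exchange_compound(rxn)
                if not interacting:
                    # per-member boundary exchange on the isolated compartment
                    new_id = _namespace(rxn.id, mid)
                    clone = copy.deepcopy(rxn)
                    clone.id = new_id
                    clone.stoichiometry = {met_map[met_id]: -1.0}
                    merged.add_reaction(clone)
                    compound_groups.setdefault(compound, []).append(new_id)
                    continue
                if isolated_extracellular:
                    # shuttle member compartment <-> pool, exchange on pool
                    pool_met = met_id
                    if pool_met not in merged.metabolites:
                        src = member.metabolites[met_id]
                        clone = copy.deepcopy(src)
                        clone.compartment = pool
                        merged.add_metabolite(clone)
                    shuttle_id = _namespace(f"SH_{compound}", mid)
                    merged.add_reaction(
                        Reaction(
                            id=shuttle_id,
                            stoichiometry={met_map[met_id]: -1.0, pool_met: 1.0},
                            lb=-DEFAULT_MAX_FLUX,
                            ub=DEFAULT_MAX_FLUX,
                            kind=ReactionKind.TRANSPORT,
                        )
                    )
                    target = pool_met
                else:
                    target = met_map[met_id]
                if compound not in pool_exchanges:
                    clone = copy.deepcopy(rxn)
                    clone.gpr = GPRExpression()
                    clone.stoichiometry = {target: -1.0}
                    merged.add_reaction(clone)
                    pool_exchanges[compound] = clone.id
                    compound_groups[compound] = [clone.id]
                continue

            clone = copy.deepcopy(rxn)
            clone.id = _namespace(rxn.id, mid)
            clone.stoichiometry = {
                met_map[m]: c for m, c in rxn.stoichiometry.items()
            }
            clone.gpr = _namespace_gpr(rxn.gpr, mid)
            if rxn.kind is ReactionKind.BIOMASS:
                clone.kind = ReactionKind.ENZYMATIC  # uniqueness restored below
                clone.annotation["MEMBER_BIOMASS"] = mid
                member_biomass[mid] = clone.id
            merged.add_reaction(clone)

        if mid not in member_biomass:
            raise CommunityError(f"member {mid!r} has no biomass reaction")

    if community_biomass:
        n = len(models)
        comm_stoich: dict[str, float] = {}
        for mid in member_ids:
            token = Metabolite(
                id=_namespace("biomass", mid),
                name=f"biomass token of {mid}",
                compartment=merged.metabolites[
                    next(iter(merged.reactions[member_biomass[mid]].stoichiometry))
                ].compartment,
            )
            merged.add_metabolite(token)
            merged.reactions[member_biomass[mid]].stoichiometry[token.id] = 1.0
            comm_stoich[token.id] = -1.0 / n
        merged.add_reaction(
            Reaction(
                id="community_biomass",
                stoichiometry=comm_stoich,
                lb=0.0,
                ub=DEFAULT_MAX_FLUX,
                kind=ReactionKind.BIOMASS,
            )
        )
        merged.objective = "community_biomass"
    else:
        first = member_biomass[member_ids[0]]
        merged.reactions[first].kind = ReactionKind.BIOMASS
        merged.objective = first

    if medium is not None:
        merged = apply_medium(merged, medium)

    return CommunityModel(
        model=merged,
        members=member_ids,
        member_biomass=member_biomass,
        pool_compartment=pool,
        compound_groups=compound_groups,
        interacting=interacting,
    )


# ---------------------------------------------------------------------------
# minimal medium and MIP
# ---------------------------------------------------------------------------


def minimal_medium(
    community: "CommunityModel | Model",
    candidates: Iterable[str] | None = None,
    min_growth: float = 0.1,
    big_m: float = DEFAULT_MAX_FLUX,
) -> set[str]:
    """Smallest compound set whose uptake sustains growth.

    One binary per candidate compound gates the uptake of every exchange
    reaction of that compound; the MILP minimizes the number of open
    compounds subject to growth of every community member (or of the
    model objective for a plain model) at ``min_growth``. Returns one
    optimal compound set.
    """
    if isinstance(community, CommunityModel):
        model = community.model
        groups = community.compound_groups
        growth_ids = list(community.member_biomass.values())
    else:
        model = community
        groups = {
            c: [r.id for r in rxns]
            for c, rxns in community.exchanges_by_compound().items()
        }
        if model.objective is None:
            raise CommunityError("model has no objective reaction")
        growth_ids = [model.objective]

    if candidates is not None:
        candidates = set(candidates)
        groups = {c: rxns for c, rxns in groups.items() if c in candidates}

    gated = {rid for rxns in groups.values() for rid in rxns}
    problem = LinearProblem("minimal_medium")
    for rxn in model.reactions.values():
        if rxn.id in gated:
            problem.add_variable(f"v_{rxn.id}", -big_m, max(rxn.ub, 0.0))
        else:
            lb = rxn.lb
            if rxn.kind is ReactionKind.EXCHANGE:
                lb = max(lb, 0.0)  # non-candidate compounds stay closed
            problem.add_variable(f"v_{rxn.id}", lb, rxn.ub)
    for compound, rxns in groups.items():
        problem.add_variable(f"y_{compound}", 0, 1, integer=True)
        for rid in rxns:
            # uptake only when the compound is in the medium: v >= -M y
            problem.add_constraint(
                {f"v_{rid}": 1.0, f"y_{compound}": big_m}, lb=0.0
            )
    balance: dict[str, dict[str, float]] = {m: {} for m in model.metabolites}
    for rxn in model.reactions.values():
        for met_id, coeff in rxn.stoichiometry.items():
            balance[met_id][f"v_{rxn.id}"] = coeff
    for row in balance.values():
        if row:
            problem.add_constraint(row, 0.0, 0.0)
    for rid in growth_ids:
        problem.add_constraint({f"v_{rid}": 1.0}, lb=min_growth)
    problem.set_objective({f"y_{c}": 1.0 for c in groups}, "min")
    sol = problem.solve()
    if not sol.optimal:
        raise CommunityError(
            "no growth on the full candidate pool: minimal medium undefined"
        )
    return {c for c in groups if sol.values[f"y_{c}"] > 0.5}


def mip_score(
    models: Sequence[Model],
    min_growth: float = 0.1,
    big_m: float = DEFAULT_MAX_FLUX,
) -> int:
    """Metabolic interaction potential of a community.

    Number of environmental compounds the community can stop requiring
    when its members may exchange metabolites through a shared pool.
    Always non-negative.
    """
    interacting = merge_community(models, interacting=True)
    isolated = merge_community(models, interacting=False)
    mm_isolated = minimal_medium(isolated, min_growth=min_growth, big_m=big_m)
    mm_interacting = minimal_medium(
        interacting, min_growth=min_growth, big_m=big_m
    )
    return len(mm_isolated) - len(mm_interacting)
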