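"""Universal-model curation.

Mass-balance screening, thermodynamics-based reversibility assignment,
blocked-reaction and dead-end pruning via flux variability analysis,
energy-generating-cycle detection, and biomass-template construction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from .core import (
    DEFAULT_MAX_FLUX,
    Model,
    Reaction,
    ReactionKind,
    apply_medium,
    complete_medium,
)
from .phenotyping import fba, fva

__all__ = [
    "BiomassComponent",
    "MassBalanceReport",
    "check_mass_balance",
    "screen_mass_balance",
    "estimate_dg_bounds",
    "assign_reversibility",
    "find_blocked",
    "prune_blocked",
    "detect_energy_cycles",
    "build_template",
    "GAS_CONSTANT_KJ",
    "DEFAULT_TEMPERATURE",
]

logger = logging.getLogger(__name__)

GAS_CONSTANT_KJ = 8.314e-3  # kJ / (mol K)
DEFAULT_TEMPERATURE = 298.15  # K
DEFAULT_CONC_BOUNDS = (0.01, 10.0)  # mM, applied to unmeasured metabolites
ENERGY_CYCLE_TOL = 1e-6  # mmol/gDW/h, above LP solver noise
BLOCKED_TOL = 1e-9

# transformed-energy convention: water and protons do not enter ln Q
LNQ_IGNORED_COMPOUNDS = {"h2o", "h"}


class MissingFormulaError(KeyError):
    """A participating metabolite has no elemental formula."""


class MissingThermoError(KeyError):
    """No standard Gibbs energy available for the reaction."""


# ---------------------------------------------------------------------------
# mass balance
# ---------------------------------------------------------------------------


def check_mass_balance(
    reaction: Reaction, formulas: Mapping[str, Mapping[str, int]]
) -> dict[str, float]:
    """Elemental imbalance of a reaction: element -> sum(coeff * count).

    Empty map means balanced. Exchange and biomass reactions are exempt by
    definition (they are boundary/pseudo reactions) and return an empty
    map. A participant without a formula raises MissingFormulaError.
    """
    if reaction.kind in (ReactionKind.EXCHANGE, ReactionKind.BIOMASS):
        return {}
    imbalance: dict[str, float] = {}
    for met_id, coeff in reaction.stoichiometry.items():
        formula = formulas.get(met_id)
        if formula is None:
            raise MissingFormulaError(met_id)
        for element, count in formula.items():
            imbalance[element] = imbalance.get(element, 0.0) + coeff * count
    return {el: v for el, v in imbalance.items() if abs(v) > 1e-9}


@dataclass
class MassBalanceReport:
    balanced: list[str]
    unbalanced: dict[str, dict[str, float]]
    unverifiable: list[str]  # flagged, never removed


def screen_mass_balance(model: Model) -> MassBalanceReport:
    """Classify every reaction as balanced / unbalanced / unverifiable."""
    formulas = {
        m.id: m.formula for m in model.metabolites.values() if m.formula is not None
    }
    report = MassBalanceReport([], {}, [])
    for rxn in model.reactions.values():
        try:
            imbalance = check_mass_balance(rxn, formulas)
        except MissingFormulaError:
            report.unverifiable.append(rxn.id)
            continue
        if imbalance:
            report.unbalanced[rxn.id] = imbalance
        else:
            report.balanced.append(rxn.id)
    return report


def remove_unbalanced(model: Model) -> tuple[Model, MassBalanceReport]:
    """Drop atomically unbalanced reactions; unverifiable ones stay."""
    report = screen_mass_balance(model)
    out = model.copy()
    out.remove_reactions(report.unbalanced)
    out.remove_orphan_metabolites()
    return out, report


# ---------------------------------------------------------------------------
# thermodynamic reversibility
# ---------------------------------------------------------------------------


def estimate_dg_bounds(
    reaction: Reaction,
    dg0: float,
    conc_bounds: Mapping[str, tuple[float, float]],
    temperature: float = DEFAULT_TEMPERATURE,
    default_bounds: tuple[float, float] = DEFAULT_CONC_BOUNDS,
    ignored: Iterable[str] = LNQ_IGNORED_COMPOUNDS,
) -> tuple[float, float]:
    """Range of dG_r = dG0 + RT ln Q over the concentration box (kJ/mol).

    Concentrations in mM are converted to M; ln Q is maximized with
    products at cmax and substrates at cmin (and vice versa for the
    minimum), with stoichiometric coefficients as exponents. Water and
    protons are excluded (transformed-energy convention).
    """
    if dg0 is None or not math.isfinite(dg0):
        raise MissingThermoError(reaction.id)
    ignored = set(ignored)
    rt = GAS_CONSTANT_KJ * temperature
    lnq_min = 0.0
    lnq_max = 0.0
    for met_id, coeff in reaction.stoichiometry.items():
        base = met_id.rsplit("_", 1)[0] if "_" in met_id else met_id
        if base in ignored or met_id in ignored:
            continue
        cmin_mm, cmax_mm = conc_bounds.get(met_id, default_bounds)
        if not (0 < cmin_mm <= cmax_mm):
            raise ValueError(
                f"invalid concentration bounds for {met_id}: "
                f"({cmin_mm}, {cmax_mm}) mM"
            )
        ln_cmin = math.log(cmin_mm / 1000.0)
        ln_cmax = math.log(cmax_mm / 1000.0)
        if coeff > 0:  # product: high concentration raises Q
            lnq_max += coeff * ln_cmax
            lnq_min += coeff * ln_cmin
        else:  # substrate: high concentration lowers Q
            lnq_max += coeff * ln_cmin
            lnq_min += coeff * ln_cmax
    return (dg0 + rt * lnq_min, dg0 + rt * lnq_max)


def assign_reversibility(
    model: Model,
    thermo: Mapping[str, float],
    conc_bounds: Mapping[str, tuple[float, float]] | None = None,
    curated_directions: Mapping[str, str] | None = None,
    atp_consumers: Iterable[str] | None = None,
    temperature: float = DEFAULT_TEMPERATURE,
) -> Model:
    """Constrain reaction directions from thermodynamic evidence.

    Precedence: strict dG sign > curated direction table > ATP-consumer
    heuristic. Bounds are only ever tightened, never widened. Conflicts
    between a curated direction and a strict dG sign are logged; dG wins.
    """
    conc_bounds = conc_bounds or {}
    curated_directions = curated_directions or {}
    atp_set = set(atp_consumers or ())
    out = model.copy()
    for rxn in out.reactions.values():
        if rxn.kind in (ReactionKind.EXCHANGE, ReactionKind.BIOMASS):
            continue
        dg_range: tuple[float, float] | None = None
        if rxn.id in thermo:
            dg_range = estimate_dg_bounds(
                rxn, thermo[rxn.id], conc_bounds, temperature
            )
        curated = curated_directions.get(rxn.id)
        if dg_range is not None and dg_range[1] < 0:
            if curated == "rev":
                logger.warning(
                    "reaction %s: curated direction 'rev' conflicts with "
                    "strictly negative dG range %s; dG evidence wins",
                    rxn.id,
                    dg_range,
                )
            rxn.lb = max(rxn.lb, 0.0)
        elif dg_range is not None and dg_range[0] > 0:
            if curated == "fwd":
                logger.warning(
                    "reaction %s: curated direction 'fwd' conflicts with "
                    "strictly positive dG range %s; dG evidence wins",
                    rxn.id,
                    dg_range,
                )
            rxn.ub = min(rxn.ub, 0.0)
        elif curated == "fwd":
            rxn.lb = max(rxn.lb, 0.0)
        elif curated == "rev":
            rxn.ub = min(rxn.ub, 0.0)
        elif curated == "rev_ok":
            pass
        elif rxn.id in atp_set:
            rxn.lb = max(rxn.lb, 0.0)
        if rxn.lb > rxn.ub:  # ub forced to 0 on a forward-only reaction
            rxn.lb = rxn.ub
    return out


def find_atp_consumers(
    model: Model, atp_id: str = "atp_c", adp_id: str = "adp_c"
) -> set[str]:
    """Reactions consuming ATP and releasing ADP in the written direction."""
    out = set()
    for rxn in model.reactions.values():
        if rxn.stoichiometry.get(atp_id, 0) < 0 and rxn.stoichiometry.get(adp_id, 0) > 0:
            out.add(rxn.id)
    return out


# ---------------------------------------------------------------------------
# blocked reactions and dead ends
# ---------------------------------------------------------------------------


def find_blocked(
    model: Model,
    open_exchanges: bool = True,
    tol: float = BLOCKED_TOL,
) -> tuple[set[str], set[str]]:
    """Blocked reactions and dead-end metabolites under complete medium.

    A reaction is blocked iff its FVA range is [0, 0]; a metabolite is a
    dead end iff every reaction touching it is blocked (no feasible flux
    can both produce and consume it). Runs without a growth constraint:
    this is pure connectivity screening.
    """
    if open_exchanges:
        model = apply_medium(model, complete_medium(model))
    ranges = fva(model)
    blocked = {
        rid
        for rid, (lo, hi) in ranges.items()
        if abs(lo) <= tol and abs(hi) <= tol
    }
    dead_ends: set[str] = set()
    for met_id in model.metabolites:
        touching = [
            r.id for r in model.reactions.values() if met_id in r.stoichiometry
        ]
        if touching and all(r in blocked for r in touching):
            dead_ends.add(met_id)
    return blocked, dead_ends


def prune_blocked(model: Model, tol: float = BLOCKED_TOL) -> tuple[Model, set[str], set[str]]:
    """Remove blocked reactions and dead-end metabolites to fixpoint."""
    out = model.copy()
    removed_rxns: set[str] = set()
    removed_mets: set[str] = set()
    while True:
        if not out.reactions:
            break
        blocked, dead = find_blocked(out, tol=tol)
        if not blocked and not dead:
            break
        out.remove_reactions(blocked)
        removed_rxns |= blocked
        for met_id in dead:
            out.metabolites.pop(met_id, None)
        removed_mets |= dead
        removed_mets |= set(out.remove_orphan_metabolites())
    return out, removed_rxns, removed_mets


# ---------------------------------------------------------------------------
# energy-generating cycles
# ---------------------------------------------------------------------------


def detect_energy_cycles(
    model: Model,
    maintenance_id: str | None = None,
    tol: float = ENERGY_CYCLE_TOL,
) -> list[set[str]]:
    """Detect unlimited ATP generation with all exchanges closed.

    Closes every exchange (lb = ub = 0) and maximizes flux through the
    ATP-maintenance reaction. An optimum above tolerance reveals an
    energy-generating cycle; the support of one optimal solution is
    returned as the offending reaction set.
    """
    if maintenance_id is None:
        raise ValueError(
            "no ATP-maintenance reaction declared; pass maintenance_id"
        )
    if maintenance_id not in model.reactions:
        raise ValueError(
            f"maintenance reaction {maintenance_id!r} not in model"
        )
    closed = model.copy()
    for rxn in closed.exchanges:
        rxn.lb = 0.0
        rxn.ub = 0.0
    result = fba(closed, objective=maintenance_id)
    if result.status == "unbounded" or (
        result.optimal and result.objective_value > tol
    ):
        if result.fluxes:
            support = {r for r, v in result.fluxes.items() if abs(v) > tol}
        else:  # unbounded: re-solve with the maintenance flux capped
            capped = closed.copy()
            capped.reactions[maintenance_id].ub = DEFAULT_MAX_FLUX
            result = fba(capped, objective=maintenance_id)
            support = {r for r, v in result.fluxes.items() if abs(v) > tol}
        return [support]
    return []


# ---------------------------------------------------------------------------
# biomass templates
# ---------------------------------------------------------------------------


@dataclass
class BiomassComponent:
    """One biomass constituent given as a mass fraction of dry weight."""

    metabolite_id: str
    mass_fraction: float  # g per gDW, renormalized to sum to 1
    mw: float  # g/mol

    def __post_init__(self) -> None:
        if self.mass_fraction <= 0:
            raise ValueError(f"{self.metabolite_id}: mass fraction must be > 0")
        if self.mw <= 0:
            raise ValueError(f"{self.metabolite_id}: molecular weight must be > 0")


def build_template(
    universe: Model,
    components: list[BiomassComponent],
    template_id: str,
) -> Model:
    """Replace the biomass reaction with a user-provided composition.

    Molar coefficients c_i (mmol/gDW) are chosen so that
    sum(c_i * MW_i) / 1000 = 1 g/gDW exactly; given mass fractions are
    rescaled to sum to 1 first.
    """
    if not components:
        raise ValueError("no biomass components given")
    missing = [
        c.metabolite_id
        for c in components
        if c.metabolite_id not in universe.metabolites
    ]
    if missing:
        raise ValueError(
            f"biomass components not in universe: {sorted(missing)}"
        )
    biomass = universe.biomass_reaction
    if biomass is None:
        raise ValueError("universe has no biomass reaction to specialize")
    total = sum(c.mass_fraction for c in components)
    out = universe.copy()
    out.id = template_id
    new_stoich = {
        c.metabolite_id: -1000.0 * (c.mass_fraction / total) / c.mw
        for c in components
    }
    out.reactions[biomass.id].stoichiometry = new_stoich
    return out
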