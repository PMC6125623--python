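"""Deterministic synthetic fixtures.

Everything here is a pure function of its arguments (including the
seed): toy universes with known ground truth, synthetic alignments whose
bitscores follow a log-normal law, and cross-feeding species pairs.
These power the test suite and the acceptance checks without any
downloads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import (
    DEFAULT_MAX_FLUX,
    GPRExpression,
    Medium,
    Metabolite,
    Model,
    Reaction,
    ReactionKind,
    parse_formula,
    parse_gpr,
)
from .phenotyping import fba
from .scoring import ReactionScoreTable, score_pipeline

__all__ = [
    "ToySpec",
    "RandomUniverse",
    "make_toy6",
    "make_energy_cycle_toy",
    "make_ambiguous_toy",
    "make_crossfeed_pair",
    "make_crossfeed_species",
    "make_random_universe",
    "write_alignment_tsv",
]

M = DEFAULT_MAX_FLUX
SUGAR = "C6H12O6"


def _met(mid: str, comp: str, formula: str | None = SUGAR) -> Metabolite:
    return Metabolite(
        id=mid,
        compartment=comp,
        formula=parse_formula(formula) if formula else None,
    )


def _exchange(met_id: str, lb: float = -M) -> Reaction:
    base = met_id.rsplit("_", 1)[0]
    return Reaction(
        id=f"EX_{base}",
        stoichiometry={met_id: -1.0},
        lb=lb,
        ub=M,
        kind=ReactionKind.EXCHANGE,
    )


# ---------------------------------------------------------------------------
# TOY6: the canonical linear-chain universe
# ---------------------------------------------------------------------------


def make_toy6() -> tuple[Model, ReactionScoreTable, dict[str, Medium]]:
    """Canonical toy universe.

    A is imported and converted to the growth precursor C either via B
    (two scored steps, one with isozymes) or directly via the unscored
    shortcut R3; D has an exchange but no pathway. Unit stoichiometry,
    all internal reactions elementally balanced by construction.
    """
    model = Model("toy6", compartments={"c": "cytosol", "e": "extracellular"})
    for met in (
        _met("A_e", "e"),
        _met("A_c", "c"),
        _met("B_c", "c"),
        _met("C_c", "c"),
        _met("D_e", "e", "C2H4O2"),
    ):
        model.add_metabolite(met)
    model.add_reaction(_exchange("A_e"))
    model.add_reaction(_exchange("D_e"))
    model.add_reaction(
        Reaction(
            id="T_A",
            stoichiometry={"A_e": -1.0, "A_c": 1.0},
            lb=0.0,
            ub=M,
            gpr=parse_gpr("g1"),
            kind=ReactionKind.TRANSPORT,
        )
    )
    model.add_reaction(
        Reaction(
            id="R1",
            stoichiometry={"A_c": -1.0, "B_c": 1.0},
            lb=0.0,
            ub=M,
            gpr=parse_gpr("g2"),
        )
    )
    model.add_reaction(
        Reaction(
            id="R2",
            stoichiometry={"B_c": -1.0, "C_c": 1.0},
            lb=0.0,
            ub=M,
            gpr=parse_gpr("g3 or g4"),
        )
    )
    model.add_reaction(
        Reaction(
            id="R3",
            stoichiometry={"A_c": -1.0, "C_c": 1.0},
            lb=0.0,
            ub=M,
            gpr=parse_gpr("g5"),
        )
    )
    model.add_reaction(
        Reaction(
            id="GROWTH",
            stoichiometry={"C_c": -1.0},
            lb=0.0,
            ub=M,
            kind=ReactionKind.BIOMASS,
        )
    )
    model.objective = "GROWTH"
    model.validate()

    # g5 has no evidence -> R3 carries the default negative score
    gene_scores = {"g1": 100.0, "g2": 100.0, "g3": 50.0, "g4": 50.0}
    scores = score_pipeline(model, gene_scores)
    media = {
        "A10": Medium({"A": 10.0}, id="A10"),
        "D10": Medium({"D": 10.0}, id="D10"),
        "empty": Medium({}, id="empty"),
    }
    return model, scores, media


# ---------------------------------------------------------------------------
# energy-generating cycle fixture
# ---------------------------------------------------------------------------


def make_energy_cycle_toy(fixed: bool = False) -> Model:
    """Three-reaction loop that regenerates ATP with all exchanges closed.

    With ``fixed=True`` the loop closure is made irreversible in the
    ATP-consuming (thermodynamically favorable) direction, which removes
    the cycle.
    """
    model = Model("energy_cycle_toy", compartments={"c": "cytosol", "e": "extracellular"})
    for met in (
        _met("A_c", "c"),
        _met("B_c", "c"),
        _met("C_c", "c"),
        _met("atp_c", "c", None),
        _met("adp_c", "c", None),
        _met("A_e", "e"),
    ):
        model.add_metabolite(met)
    model.add_reaction(_exchange("A_e"))
    model.add_reaction(
        Reaction(id="T_A", stoichiometry={"A_e": -1.0, "A_c": 1.0}, lb=-M, ub=M,
                 kind=ReactionKind.TRANSPORT)
    )
    model.add_reaction(
        Reaction(id="R_AB", stoichiometry={"A_c": -1.0, "B_c": 1.0}, lb=-M, ub=M)
    )
    model.add_reaction(
        Reaction(id="R_BC", stoichiometry={"B_c": -1.0, "C_c": 1.0}, lb=-M, ub=M)
    )
    # written direction generates ATP; the fix forbids it
    model.add_reaction(
        Reaction(
            id="R_CA",
            stoichiometry={"C_c": -1.0, "adp_c": -1.0, "A_c": 1.0, "atp_c": 1.0},
            lb=-M,
            ub=0.0 if fixed else M,
        )
    )
    model.add_reaction(
        Reaction(id="ATPM", stoichiometry={"atp_c": -1.0, "adp_c": 1.0}, lb=0.0, ub=M)
    )
    return model


# ---------------------------------------------------------------------------
# ambiguous two-pathway fixture (for ensembles)
# ---------------------------------------------------------------------------


def make_ambiguous_toy() -> tuple[Model, ReactionScoreTable]:
    """Two equal-evidence (unscored) alternative routes from A to growth."""
    model = Model("ambiguous_toy", compartments={"c": "cytosol", "e": "extracellular"})
    for met in (_met("A_e", "e"), _met("A_c", "c"), _met("P_c", "c")):
        model.add_metabolite(met)
    model.add_reaction(_exchange("A_e"))
    model.add_reaction(
        Reaction(id="T_A", stoichiometry={"A_e": -1.0, "A_c": 1.0}, lb=0.0, ub=M,
                 gpr=parse_gpr("g1"), kind=ReactionKind.TRANSPORT)
    )
    model.add_reaction(
        Reaction(id="Ra", stoichiometry={"A_c": -1.0, "P_c": 1.0}, lb=0.0, ub=M)
    )
    model.add_reaction(
        Reaction(id="Rb", stoichiometry={"A_c": -1.0, "P_c": 1.0}, lb=0.0, ub=M)
    )
    model.add_reaction(
        Reaction(id="GROWTH", stoichiometry={"P_c": -1.0}, lb=0.0, ub=M,
                 kind=ReactionKind.BIOMASS)
    )
    model.objective = "GROWTH"
    scores = score_pipeline(model, {"g1": 100.0})
    return model, scores


# ---------------------------------------------------------------------------
# cross-feeding pair (for community / MIP)
# ---------------------------------------------------------------------------


def make_crossfeed_species(
    species_id: str, makes: str, needs: str
) -> Model:
    """Species eating A, producing ``makes`` as byproduct, requiring ``needs``."""
    model = Model(species_id, compartments={"c": "cytosol", "e": "extracellular"})
    for met in (
        _met("A_e", "e"),
        _met(f"{makes}_e", "e"),
        _met(f"{needs}_e", "e"),
        _met("A_c", "c"),
        _met(f"{makes}_c", "c"),
        _met(f"{needs}_c", "c"),
        _met("P_c", "c"),
    ):
        model.add_metabolite(met)
    model.add_reaction(_exchange("A_e"))
    model.add_reaction(_exchange(f"{makes}_e"))
    model.add_reaction(_exchange(f"{needs}_e"))
    model.add_reaction(
        Reaction(id="T_A", stoichiometry={"A_e": -1.0, "A_c": 1.0}, lb=0.0, ub=M,
                 kind=ReactionKind.TRANSPORT)
    )
    model.add_reaction(
        Reaction(
            id="R_SPLIT",
            stoichiometry={"A_c": -1.0, f"{makes}_c": 1.0, "P_c": 1.0},
        )
    )
    model.add_reaction(
        Reaction(
            id=f"T_{makes}_out",
            stoichiometry={f"{makes}_c": -1.0, f"{makes}_e": 1.0},
            lb=0.0,
            ub=M,
            kind=ReactionKind.TRANSPORT,
        )
    )
    model.add_reaction(
        Reaction(
            id=f"T_{needs}_in",
            stoichiometry={f"{needs}_e": -1.0, f"{needs}_c": 1.0},
            lb=0.0,
            ub=M,
            kind=ReactionKind.TRANSPORT,
        )
    )
    model.add_reaction(
        Reaction(
            id="GROWTH",
            stoichiometry={"P_c": -1.0, f"{needs}_c": -1.0},
            lb=0.0,
            ub=M,
            kind=ReactionKind.BIOMASS,
        )
    )
    model.objective = "GROWTH"
    for rxn in model.reactions.values():
        if rxn.kind is ReactionKind.ENZYMATIC:
            rxn.lb, rxn.ub = 0.0, M
    return model


def make_crossfeed_pair() -> tuple[Model, Model]:
    """Obligate mutualists: sp1 secretes B and requires C, sp2 vice versa.

    On substrate A alone each secretes what the other needs; in isolation
    each needs its partner compound from the environment, so the pair's
    MIP score is 2.
    """
    return (
        make_crossfeed_species("sp1", makes="B", needs="C"),
        make_crossfeed_species("sp2", makes="C", needs="B"),
    )


# ---------------------------------------------------------------------------
# randomized universes with planted ground truth
# ---------------------------------------------------------------------------


@dataclass
class ToySpec:
    """Parameters for a random toy universe with a planted organism."""

    n_pathways: int = 3
    pathway_len: int = 3
    planted_pathways: int = 1
    isozyme_prob: float = 0.0
    complex_prob: float = 0.0
    n_dead_ends: int = 0
    n_unbalanced: int = 0
    energy_cycle: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.planted_pathways <= self.n_pathways):
            raise ValueError("need 1 <= planted_pathways <= n_pathways")
        if self.pathway_len < 1:
            raise ValueError("pathway_len must be >= 1")


@dataclass
class RandomUniverse:
    model: Model
    planted: set[str]  # ground-truth organism reaction set
    alignment: list[tuple] = field(default_factory=list)  # outfmt-6 rows
    gene_scores: dict[str, float] = field(default_factory=dict)
    media: dict[str, Medium] = field(default_factory=dict)
    spec: ToySpec | None = None


def make_random_universe(spec: ToySpec) -> RandomUniverse:
    """Random multi-pathway universe with a growth-capable planted subnet.

    All pathways run from the imported substrate A to the biomass
    precursor Z; the first ``planted_pathways`` of them belong to the
    organism and their genes receive synthetic alignment hits with
    log-normal bitscores (median ~100). Distractor pathway genes get no
    hits. Optional planted defects: dead-end branches, atomically
    unbalanced reactions, and an energy-generating cycle.
    """
    rng = np.random.default_rng(spec.seed)
    model = Model(
        f"random_universe_{spec.seed}",
        compartments={"c": "cytosol", "e": "extracellular"},
    )
    model.add_metabolite(_met("A_e", "e"))
    model.add_metabolite(_met("A_c", "c"))
    model.add_metabolite(_met("Z_c", "c"))
    model.add_reaction(_exchange("A_e"))
    model.add_reaction(
        Reaction(id="T_A", stoichiometry={"A_e": -1.0, "A_c": 1.0}, lb=0.0, ub=M,
                 gpr=parse_gpr("gT"), kind=ReactionKind.TRANSPORT)
    )
    model.add_reaction(
        Reaction(id="GROWTH", stoichiometry={"Z_c": -1.0}, lb=0.0, ub=M,
                 kind=ReactionKind.BIOMASS)
    )
    model.objective = "GROWTH"

    planted: set[str] = {"EX_A", "T_A", "GROWTH"}
    planted_genes: list[str] = ["gT"]

    for p in range(spec.n_pathways):
        is_planted = p < spec.planted_pathways
        chain = ["A_c"]
        for step in range(1, spec.pathway_len):
            mid = f"I_{p}_{step}_c"
            model.add_metabolite(_met(mid, "c"))
            chain.append(mid)
        chain.append("Z_c")
        for step in range(spec.pathway_len):
            rid = f"R_{p}_{step}"
            gene = f"g_{p}_{step}"
            gpr_text = gene
            extra_genes = [gene]
            roll = rng.random()
            if roll < spec.isozyme_prob:
                gpr_text = f"{gene} or {gene}_iso"
                extra_genes.append(f"{gene}_iso")
            elif roll < spec.isozyme_prob + spec.complex_prob:
                gpr_text = f"{gene} and {gene}_sub"
                extra_genes.append(f"{gene}_sub")
            model.add_reaction(
                Reaction(
                    id=rid,
                    stoichiometry={chain[step]: -1.0, chain[step + 1]: 1.0},
                    lb=0.0,
                    ub=M,
                    gpr=parse_gpr(gpr_text),
                )
            )
            if is_planted:
                planted.add(rid)
                planted_genes.extend(extra_genes)

    for d in range(spec.n_dead_ends):
        mid = f"DEAD_{d}_c"
        model.add_metabolite(_met(mid, "c"))
        model.add_reaction(
            Reaction(id=f"R_DEAD_{d}", stoichiometry={"A_c": -1.0, mid: 1.0},
                     lb=0.0, ub=M)
        )

    for u in range(spec.n_unbalanced):
        # 1 sugar -> 2 sugars: free mass
        model.add_reaction(
            Reaction(id=f"R_UNBAL_{u}", stoichiometry={"A_c": -1.0, "Z_c": 2.0},
                     lb=0.0, ub=M)
        )

    if spec.energy_cycle:
        for met in (_met("atp_c", "c", None), _met("adp_c", "c", None),
                    _met("E1_c", "c"), _met("E2_c", "c")):
            model.add_metabolite(met)
        model.add_reaction(
            Reaction(id="EGC_1", stoichiometry={"A_c": -1.0, "E1_c": 1.0}, lb=-M, ub=M)
        )
        model.add_reaction(
            Reaction(id="EGC_2", stoichiometry={"E1_c": -1.0, "E2_c": 1.0}, lb=-M, ub=M)
        )
        model.add_reaction(
            Reaction(
                id="EGC_3",
                stoichiometry={"E2_c": -1.0, "adp_c": -1.0, "A_c": 1.0, "atp_c": 1.0},
                lb=-M,
                ub=M,
            )
        )
        model.add_reaction(
            Reaction(id="ATPM", stoichiometry={"atp_c": -1.0, "adp_c": 1.0},
                     lb=0.0, ub=M)
        )

    alignment = []
    gene_scores: dict[str, float] = {}
    for gene in planted_genes:
        bitscore = float(np.round(math.exp(rng.normal(math.log(100.0), 0.5)), 1))
        gene_scores[gene] = bitscore
        alignment.append(
            (f"q_{gene}", gene, 95.0, 300, 2, 0, 1, 300, 1, 300, 1e-50, bitscore)
        )

    media = {"A10": Medium({"A": 10.0}, id="A10")}
    universe = RandomUniverse(
        model=model,
        planted=planted,
        alignment=alignment,
        gene_scores=gene_scores,
        media=media,
        spec=spec,
    )
    # the planted subnetwork must sustain growth
    organism = model.copy()
    organism.remove_reactions([r for r in model.reactions if r not in planted])
    organism.remove_orphan_metabolites()
    if fba(organism, medium=media["A10"]).growth <= 0:
        raise RuntimeError(
            f"spec {spec} yields a non-growing planted network; "
            "adjust pathway parameters"
        )
    return universe


def write_alignment_tsv(rows: list[tuple], path: str | Path) -> None:
    with open(path, "w") as handle:
        for row in rows:
            handle.write("\t".join(str(x) for x in row) + "\n")
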