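"""Ensembles of alternative carved models.

Reactions without genetic evidence carry an arbitrary default penalty;
redrawing that penalty uniformly from [-1, 0) and re-solving the carve
MILP explores alternative optima. Phenotypes are then called by voting
across members with a strict ">" threshold. Positive-evidence weights
are never jittered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .carving import CarveParams, CarveSolution, HardConstraintSet, SoftConstraintSet, carve
from .core import Model
from .io import read_model, write_model
from .scoring import ReactionScoreTable

__all__ = [
    "Ensemble",
    "generate_ensemble",
    "jaccard_distance",
    "jaccard_matrix",
    "vote",
    "write_ensemble",
    "read_ensemble",
    "write_presence_tsv",
]


@dataclass
class Ensemble:
    universe_id: str
    reaction_ids: list[str]  # universe column order
    presence: np.ndarray  # members x reactions, int8
    members: list[CarveSolution] = field(default_factory=list)
    union_model: Model | None = None

    @property
    def size(self) -> int:
        return int(self.presence.shape[0])

    def member_reactions(self, index: int) -> set[str]:
        row = self.presence[index]
        return {r for r, bit in zip(self.reaction_ids, row) if bit}


def generate_ensemble(
    universe: Model,
    scores: ReactionScoreTable,
    size: int,
    seed: int,
    params: CarveParams | None = None,
    soft: SoftConstraintSet | None = None,
    hard: HardConstraintSet | None = None,
) -> Ensemble:
    """Carve ``size`` members with randomized no-evidence penalties.

    Each member redraws the weight of every default-negative reaction
    from U[-1, 0) using a stream seeded by ``seed``; the same seed gives
    a bitwise-identical presence matrix.
    """
    if size < 1:
        raise ValueError("ensemble size must be >= 1")
    params = params or CarveParams()
    rng = np.random.default_rng(seed)
    unscored = sorted(scores.unscored)
    reaction_ids = list(universe.reactions)
    presence = np.zeros((size, len(reaction_ids)), dtype=np.int8)
    members: list[CarveSolution] = []
    union: set[str] = set()
    for m in range(size):
        member_scores = dict(scores.scores)
        draws = rng.uniform(-1.0, 0.0, size=len(unscored))
        for rid, w in zip(unscored, draws):
            member_scores[rid] = float(w)
        member_table = ReactionScoreTable(
            scores=member_scores,
            raw_scores=scores.raw_scores,
            gprs=scores.gprs,
            unscored=scores.unscored,
            default_negative=scores.default_negative,
        )
        solution = carve(universe, member_table, params, soft=soft, hard=hard)
        members.append(solution)
        union |= solution.kept
        for j, rid in enumerate(reaction_ids):
            presence[m, j] = 1 if rid in solution.kept else 0

    union_model = universe.copy()
    union_model.remove_reactions([r for r in reaction_ids if r not in union])
    union_model.remove_orphan_metabolites()
    return Ensemble(universe.id, reaction_ids, presence, members, union_model)


def jaccard_distance(a: set[str], b: set[str]) -> float:
    if not a and not b:
        return 0.0
    return 1.0 - len(a & b) / len(a | b)


def jaccard_matrix(ensemble: Ensemble) -> np.ndarray:
    """Pairwise Jaccard distances between member reaction sets."""
    if ensemble.size < 2:
        raise ValueError("need at least 2 members for a distance matrix")
    sets = [ensemble.member_reactions(i) for i in range(ensemble.size)]
    out = np.zeros((ensemble.size, ensemble.size))
    for i in range(ensemble.size):
        for j in range(i + 1, ensemble.size):
            out[i, j] = out[j, i] = jaccard_distance(sets[i], sets[j])
    return out


def vote(member_calls: "np.ndarray | list", threshold: float) -> np.ndarray:
    """Consensus call: positive iff the positive fraction exceeds T (strict).

    ``member_calls`` is members x items, boolean/0-1.
    """
    calls = np.asarray(member_calls, dtype=float)
    if calls.ndim != 2:
        raise ValueError("member_calls must be a 2-D members x items array")
    fraction = calls.mean(axis=0)
    return fraction > threshold


# ---------------------------------------------------------------------------
# export: single SBML file of the union model + presence annotations
# ---------------------------------------------------------------------------


def write_ensemble(ensemble: Ensemble, path: str | Path, dialect: str = "sbml-fbc2") -> None:
    """Union model with per-reaction member-presence bit strings."""
    if ensemble.union_model is None:
        raise ValueError("ensemble has no union model")
    model = ensemble.union_model.copy()
    index = {r: j for j, r in enumerate(ensemble.reaction_ids)}
    model.annotation["ENSEMBLE_SIZE"] = str(ensemble.size)
    for rxn in model.reactions.values():
        bits = ensemble.presence[:, index[rxn.id]]
        rxn.annotation["ENSEMBLE_PRESENCE"] = "".join(str(int(b)) for b in bits)
    write_model(model, path, dialect)


def read_ensemble(path: str | Path) -> Ensemble:
    model = read_model(path)
    size = int(model.annotation.get("ENSEMBLE_SIZE", "1"))
    reaction_ids = list(model.reactions)
    presence = np.zeros((size, len(reaction_ids)), dtype=np.int8)
    for j, rxn in enumerate(model.reactions.values()):
        bits = rxn.annotation.get("ENSEMBLE_PRESENCE", "1" * size)
        for m, bit in enumerate(bits[:size]):
            presence[m, j] = int(bit)
    return Ensemble(model.id, reaction_ids, presence, members=[], union_model=model)


def write_presence_tsv(ensemble: Ensemble, path: str | Path) -> None:
    df = pd.DataFrame(
        ensemble.presence,
        columns=ensemble.reaction_ids,
        index=[f"member_{i}" for i in range(ensemble.size)],
    )
    df.to_csv(path, sep="\t")
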