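"""Gene-evidence scoring of universe reactions.

Tabular alignment evidence (BLAST outfmt-6) is reduced to per-gene scores
(best bitscore), then pushed through the GPR algebra: a protein complex
scores the minimum of its subunit gene scores and is absent if any
subunit is unscored; a reaction score sums its present complexes
(isozymes). Evidence scores are normalized to median 1; enzyme-catalyzed
reactions without evidence get a default negative score and spontaneous
reactions a neutral one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from statistics import median

from .core import GPRExpression, Model, ReactionKind

__all__ = [
    "AlignmentFormatError",
    "AlignmentHit",
    "ReactionScoreTable",
    "parse_alignment",
    "score_reactions",
    "normalize_scores",
    "score_pipeline",
    "DEFAULT_EVALUE_CUTOFF",
    "DEFAULT_NEGATIVE_SCORE",
]

DEFAULT_EVALUE_CUTOFF = 1e-6
DEFAULT_NEGATIVE_SCORE = -1.0


class AlignmentFormatError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentHit:
    """One row of 12-column BLAST-style tabular output (outfmt 6)."""

    query: str
    subject: str
    identity: float
    length: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.bitscore < 0 or self.evalue < 0:
            raise ValueError(f"invalid hit {self.query}->{self.subject}")


def iter_alignment_hits(path: str | Path) -> "list[AlignmentHit]":
    hits = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise AlignmentFormatError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                hits.append(
                    AlignmentHit(
                        query=fields[0],
                        subject=fields[1],
                        identity=float(fields[2]),
                        length=int(fields[3]),
                        evalue=float(fields[10]),
                        bitscore=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise AlignmentFormatError(
                    f"{path}:{lineno}: malformed row: {exc}"
                ) from exc
    return hits


def parse_alignment(
    path: str | Path, evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF
) -> dict[str, float]:
    """Gene-score table from an alignment file.

    For each database (subject) gene, the score is the maximum bitscore
    over retained hits; hits above the e-value cutoff are dropped.
    """
    scores: dict[str, float] = {}
    for hit in iter_alignment_hits(path):
        if hit.evalue > evalue_cutoff:
            continue
        if hit.bitscore > scores.get(hit.subject, -1.0):
            scores[hit.subject] = hit.bitscore
    return scores


# ---------------------------------------------------------------------------
# GPR algebra
# ---------------------------------------------------------------------------


def score_reactions(
    universe: Model, gene_scores: dict[str, float]
) -> tuple[dict[str, float], dict[str, GPRExpression]]:
    """Raw reaction scores and organism-specific GPRs.

    complex score  = min over subunit gene scores (undefined if any
                     subunit is unscored; the complex is then absent)
    reaction score = sum over present complexes
    organism GPR   = the DNF restricted to present complexes

    Reactions with no present complex receive no raw score and no entry.
    """
    raw: dict[str, float] = {}
    gprs: dict[str, GPRExpression] = {}
    scored_genes = set(gene_scores)
    for rxn in universe.reactions.values():
        if rxn.gpr.is_empty:
            continue
        present = [c for c in rxn.gpr.complexes if c <= scored_genes]
        if not present:
            continue
        raw[rxn.id] = sum(min(gene_scores[g] for g in cplx) for cplx in present)
        gprs[rxn.id] = GPRExpression(frozenset(present))
    return raw, gprs


@dataclass
class ReactionScoreTable:
    """Normalized per-reaction evidence scores plus organism GPRs.

    ``scores`` covers every reaction in the universe: evidence-based
    scores are normalized to median 1, unscored enzymatic/transport
    reactions carry the default negative score, and spontaneous, exchange
    and biomass reactions are neutral (0). ``unscored`` records which
    reactions received the default, which is what ensemble generation
    randomizes.
    """

    scores: dict[str, float]
    raw_scores: dict[str, float] = field(default_factory=dict)
    gprs: dict[str, GPRExpression] = field(default_factory=dict)
    unscored: frozenset[str] = frozenset()
    default_negative: float = DEFAULT_NEGATIVE_SCORE

    def __getitem__(self, rxn_id: str) -> float:
        return self.scores[rxn_id]

    def get(self, rxn_id: str, default: float = 0.0) -> float:
        return self.scores.get(rxn_id, default)

    def evidence_scores(self) -> dict[str, float]:
        return {r: self.scores[r] for r in self.raw_scores}


def normalize_scores(
    universe: Model,
    raw: dict[str, float],
    gprs: dict[str, GPRExpression] | None = None,
    default_negative: float = DEFAULT_NEGATIVE_SCORE,
) -> ReactionScoreTable:
    """Normalize raw scores to median 1 and fill in defaults."""
    if not raw:
        raise ValueError("no raw reaction scores: nothing to normalize")
    med = median(raw.values())
    if med <= 0:
        raise ValueError(f"median raw score is {med}; cannot normalize")
    scores: dict[str, float] = {}
    unscored: set[str] = set()
    for rxn in universe.reactions.values():
        if rxn.id in raw:
            scores[rxn.id] = raw[rxn.id] / med
        elif rxn.kind in (ReactionKind.ENZYMATIC, ReactionKind.TRANSPORT):
            scores[rxn.id] = default_negative
            unscored.add(rxn.id)
        else:  # spontaneous, exchange, biomass: neutral
            scores[rxn.id] = 0.0
    return ReactionScoreTable(
        scores=scores,
        raw_scores=dict(raw),
        gprs=dict(gprs or {}),
        unscored=frozenset(unscored),
        default_negative=default_negative,
    )


def score_pipeline(
    universe: Model,
    gene_scores: dict[str, float],
    default_negative: float = DEFAULT_NEGATIVE_SCORE,
) -> ReactionScoreTable:
    """Gene scores -> normalized reaction score table, in one call."""
    raw, gprs = score_reactions(universe, gene_scores)
    return normalize_scores(
        universe, raw, gprs, default_negative=default_negative
    )
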