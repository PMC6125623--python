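"""Core data model for constraint-based metabolic networks.

Defines metabolites, reactions, boolean gene-protein-reaction (GPR)
associations in disjunctive normal form, models, growth media, and the
stoichiometric matrix assembly. All flux units are mmol/gDW/h except the
biomass reaction, whose flux is the growth rate in 1/h.

Sign conventions follow COBRA: negative stoichiometric coefficients are
substrates, positive are products; exchange reactions carry the boundary
metabolite as sole substrate, so uptake is a negative flux and secretion a
positive one.
"""

from __future__ import annotations

import copy
import enum
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
from scipy import sparse

__all__ = [
    "ReactionKind",
    "GPRExpression",
    "GPRParseError",
    "Metabolite",
    "Reaction",
    "Model",
    "Medium",
    "MediumWarning",
    "ModelValidationError",
    "parse_gpr",
    "parse_formula",
    "formula_to_string",
    "build_stoichiometric_matrix",
    "apply_medium",
    "complete_medium",
]

DEFAULT_MAX_FLUX = 100.0


class ReactionKind(str, enum.Enum):
    """Functional class of a reaction."""

    ENZYMATIC = "enzymatic"
    TRANSPORT = "transport"
    EXCHANGE = "exchange"
    SPONTANEOUS = "spontaneous"
    BIOMASS = "biomass"


class GPRParseError(ValueError):
    """Raised when a GPR string cannot be parsed; carries the token position."""


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


class MediumWarning(UserWarning):
    """Raised when a medium entry cannot be matched to an exchange reaction."""


# ---------------------------------------------------------------------------
# GPR expressions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GPRExpression:
    """Boolean gene association in disjunctive normal form.

    ``complexes`` is a set of protein complexes; each complex is a non-empty
    frozenset of gene ids. The expression is satisfied iff at least one
    complex has all of its genes present. The empty expression (no
    complexes) denotes "no gene requirement" and evaluates to True for
    gap-independent reactions such as exchanges and spontaneous reactions.
    """

    complexes: frozenset[frozenset[str]] = frozenset()

    def __post_init__(self) -> None:
        for cplx in self.complexes:
            if not cplx:
                raise ValueError("empty protein complex in GPR expression")

    @property
    def is_empty(self) -> bool:
        return not self.complexes

    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for cplx in self.complexes:
            out.update(cplx)
        return frozenset(out)

    def evaluate(self, present: Iterable[str]) -> bool:
        """DNF evaluation: true iff some complex is fully present."""
        present = set(present)
        return any(cplx <= present for cplx in self.complexes)

    def restrict(self, present: Iterable[str]) -> "GPRExpression":
        """Sub-expression keeping only complexes fully covered by ``present``."""
        present = set(present)
        return GPRExpression(
            frozenset(c for c in self.complexes if c <= present)
        )

    def to_string(self) -> str:
        if self.is_empty:
            return ""
        parts = []
        for cplx in sorted(self.complexes, key=lambda c: sorted(c)):
            genes = " and ".join(sorted(cplx))
            parts.append(f"({genes})" if len(cplx) > 1 and len(self.complexes) > 1 else genes)
        return " or ".join(parts)

    @staticmethod
    def from_complexes(complexes: Iterable[Iterable[str]]) -> "GPRExpression":
        return GPRExpression(frozenset(frozenset(c) for c in complexes))


_GPR_TOKEN = re.compile(r"\s*(\(|\)|[^\s()]+)")


def _tokenize_gpr(text: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    pos = 0
    while pos < len(text):
        match = _GPR_TOKEN.match(text, pos)
        if match is None:
            break
        tokens.append((match.group(1), match.start(1)))
        pos = match.end()
    return tokens


def parse_gpr(text: str) -> GPRExpression:
    """Parse a boolean gene-association string into DNF.

    Grammar: case-insensitive ``and`` / ``or``, parentheses, any other
    token is a gene id. AND distributes over OR during parsing, so
    ``g1 and (g2 or g3)`` yields ``{{g1,g2},{g1,g3}}``.
    """
    if text is None or not text.strip():
        return GPRExpression()
    tokens = _tokenize_gpr(text)
    idx = 0

    def error(msg: str, position: int) -> GPRParseError:
        return GPRParseError(f"{msg} at position {position} in GPR {text!r}")

    def peek() -> tuple[str, int] | None:
        return tokens[idx] if idx < len(tokens) else None

    def parse_or() -> list[set[str]]:
        nonlocal idx
        result = parse_and()
        while True:
            nxt = peek()
            if nxt is None or nxt[0].lower() != "or":
                return result
            idx += 1
            result = result + parse_and()

    def parse_and() -> list[set[str]]:
        nonlocal idx
        result = parse_atom()
        while True:
            nxt = peek()
            if nxt is None or nxt[0].lower() != "and":
                return result
            idx += 1
            rhs = parse_atom()
            # distribute AND over OR: cross-product of complex unions
            result = [a | b for a in result for b in rhs]
        return result

    def parse_atom() -> list[set[str]]:
        nonlocal idx
        nxt = peek()
        if nxt is None:
            raise error("unexpected end of expression", len(text))
        token, position = nxt
        if token == "(":
            idx += 1
            inner = parse_or()
            closing = peek()
            if closing is None or closing[0] != ")":
                raise error("missing closing parenthesis", position)
            idx += 1
            return inner
        if token == ")":
            raise error("unexpected ')'", position)
        if token.lower() in ("and", "or"):
            raise error(f"unexpected operator {token!r}", position)
        idx += 1
        return [{token}]

    complexes = parse_or()
    trailing = peek()
    if trailing is not None:
        raise error(f"unexpected token {trailing[0]!r}", trailing[1])
    return GPRExpression.from_complexes(complexes)


# ---------------------------------------------------------------------------
# Formulas
# ---------------------------------------------------------------------------

_FORMULA_ELEMENT = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> dict[str, int]:
    """Parse an elemental formula string such as ``C6H12O6`` into a map."""
    if not text:
        return {}
    if not re.fullmatch(r"(?:[A-Z][a-z]?\d*)+", text):
        raise ValueError(f"malformed formula: {text!r}")
    out: dict[str, int] = {}
    for element, count in _FORMULA_ELEMENT.findall(text):
        out[element] = out.get(element, 0) + (int(count) if count else 1)
    return out


def formula_to_string(formula: Mapping[str, int] | None) -> str:
    if not formula:
        return ""
    return "".join(
        f"{el}{n if n != 1 else ''}" for el, n in sorted(formula.items())
    )


# ---------------------------------------------------------------------------
# Metabolites, reactions, models
# ---------------------------------------------------------------------------


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: dict[str, int] | None = None
    charge: int = 0
    annotation: dict[str, str] = field(default_factory=dict)


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lb: float = -DEFAULT_MAX_FLUX
    ub: float = DEFAULT_MAX_FLUX
    gpr: GPRExpression = field(default_factory=GPRExpression)
    kind: ReactionKind = ReactionKind.ENZYMATIC
    name: str = ""
    subsystem: str = ""
    annotation: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if isinstance(self.kind, str):
            self.kind = ReactionKind(self.kind)
        if self.lb > self.ub:
            raise ModelValidationError(
                f"reaction {self.id}: lb {self.lb} > ub {self.ub}"
            )

    @property
    def reversible(self) -> bool:
        return self.lb < 0 < self.ub

    def substrates(self) -> dict[str, float]:
        return {m: -c for m, c in self.stoichiometry.items() if c < 0}

    def products(self) -> dict[str, float]:
        return {m: c for m, c in self.stoichiometry.items() if c > 0}


class Model:
    """A compartmentalized stoichiometric network.

    Metabolites and reactions are stored in insertion order, which fixes
    the row/column order of the stoichiometric matrix.
    """

    def __init__(
        self,
        model_id: str,
        compartments: Mapping[str, str] | Iterable[str] | None = None,
        extracellular: str = "e",
        annotation: dict[str, str] | None = None,
    ) -> None:
        self.id = model_id
        if compartments is None:
            compartments = {}
        if not isinstance(compartments, Mapping):
            compartments = {c: c for c in compartments}
        self.compartments: dict[str, str] = dict(compartments)
        self.extracellular = extracellular
        self.metabolites: dict[str, Metabolite] = {}
        self.reactions: dict[str, Reaction] = {}
        self.objective: str | None = None
        self.annotation: dict[str, str] = dict(annotation or {})

    # -- construction -------------------------------------------------

    def add_compartment(self, comp_id: str, name: str = "") -> None:
        self.compartments.setdefault(comp_id, name or comp_id)

    def add_metabolite(self, met: Metabolite) -> Metabolite:
        if met.id in self.metabolites:
            raise ModelValidationError(f"duplicate metabolite id {met.id!r}")
        if met.compartment not in self.compartments:
            self.add_compartment(met.compartment)
        self.metabolites[met.id] = met
        return met

    def add_reaction(self, rxn: Reaction) -> Reaction:
        if rxn.id in self.reactions:
            raise ModelValidationError(f"duplicate reaction id {rxn.id!r}")
        for met_id in rxn.stoichiometry:
            if met_id not in self.metabolites:
                raise ModelValidationError(
                    f"reaction {rxn.id} references unknown metabolite {met_id!r}"
                )
        self.reactions[rxn.id] = rxn
        return rxn

    def remove_reactions(self, rxn_ids: Iterable[str]) -> None:
        for rid in rxn_ids:
            self.reactions.pop(rid, None)

    def remove_orphan_metabolites(self) -> list[str]:
        used: set[str] = set()
        for rxn in self.reactions.values():
            used.update(rxn.stoichiometry)
        orphans = [m for m in self.metabolites if m not in used]
        for mid in orphans:
            del self.metabolites[mid]
        return orphans

    def copy(self) -> "Model":
        return copy.deepcopy(self)

    # -- queries ------------------------------------------------------

    @property
    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions.values() if r.kind is ReactionKind.EXCHANGE]

    @property
    def biomass_reaction(self) -> Reaction | None:
        if self.objective and self.objective in self.reactions:
            return self.reactions[self.objective]
        for rxn in self.reactions.values():
            if rxn.kind is ReactionKind.BIOMASS:
                return rxn
        return None

    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for rxn in self.reactions.values():
            out.update(rxn.gpr.genes)
        return frozenset(out)

    def metabolite_ids(self) -> list[str]:
        return list(self.metabolites)

    def reaction_ids(self) -> list[str]:
        return list(self.reactions)

    def exchange_compound(self, rxn: Reaction) -> str:
        """Compound id exported/imported by an exchange reaction.

        The metabolite id with the extracellular compartment suffix
        stripped (a convention, not a requirement: un-suffixed ids are
        returned verbatim).
        """
        (met_id,) = rxn.stoichiometry
        suffix = f"_{self.extracellular}"
        if met_id.endswith(suffix):
            return met_id[: -len(suffix)]
        return met_id

    def exchanges_by_compound(self) -> dict[str, list[Reaction]]:
        out: dict[str, list[Reaction]] = {}
        for rxn in self.exchanges:
            out.setdefault(self.exchange_compound(rxn), []).append(rxn)
        return out

    def validate(self) -> None:
        """Check structural invariants; raises ModelValidationError."""
        for met in self.metabolites.values():
            if met.compartment not in self.compartments:
                raise ModelValidationError(
                    f"metabolite {met.id} in undeclared compartment {met.compartment!r}"
                )
        n_biomass = 0
        for rxn in self.reactions.values():
            for mid in rxn.stoichiometry:
                if mid not in self.metabolites:
                    raise ModelValidationError(
                        f"reaction {rxn.id} references unknown metabolite {mid!r}"
                    )
            if rxn.kind is ReactionKind.EXCHANGE:
                if len(rxn.stoichiometry) != 1:
                    raise ModelValidationError(
                        f"exchange {rxn.id} must touch exactly one metabolite"
                    )
                (mid,) = rxn.stoichiometry
                met = self.metabolites[mid]
                if met.compartment != self.extracellular:
                    raise ModelValidationError(
                        f"exchange {rxn.id} metabolite {mid} is not extracellular"
                    )
            if rxn.kind is ReactionKind.BIOMASS:
                n_biomass += 1
        if n_biomass > 1:
            raise ModelValidationError("more than one biomass reaction")
        if self.objective is not None and self.objective not in self.reactions:
            raise ModelValidationError(
                f"objective reaction {self.objective!r} does not exist"
            )

    def __contains__(self, rxn_id: str) -> bool:
        return rxn_id in self.reactions

    def __iter__(self) -> Iterator[Reaction]:
        return iter(self.reactions.values())

    def __repr__(self) -> str:
        return (
            f"Model({self.id!r}, {len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions)"
        )


# ---------------------------------------------------------------------------
# Media
# ---------------------------------------------------------------------------


@dataclass
class Medium:
    """Maximum uptake rates (mmol/gDW/h) per extracellular compound."""

    entries: dict[str, float] = field(default_factory=dict)
    id: str = ""

    def __post_init__(self) -> None:
        for compound, rate in self.entries.items():
            if rate < 0:
                raise ValueError(
                    f"medium {self.id or '<anonymous>'}: negative uptake "
                    f"rate for {compound}"
                )

    def __contains__(self, compound: str) -> bool:
        return compound in self.entries

    def replace_source(self, old: str, new: str, rate: float) -> "Medium":
        """Medium with ``old`` removed and ``new`` set to ``rate``."""
        entries = {c: r for c, r in self.entries.items() if c != old}
        entries[new] = rate
        return Medium(entries, id=self.id)


def apply_medium(model: Model, medium: Medium) -> Model:
    """Constrain a model's exchange bounds to a medium.

    Exchanges of compounds listed in the medium get ``lb = -rate``; all
    other exchanges get ``lb = 0``. Upper (secretion) bounds are left
    unchanged. Compounds without any exchange reaction trigger a
    :class:`MediumWarning` and are skipped. Returns a modified copy.
    """
    out = model.copy()
    by_compound = out.exchanges_by_compound()
    for rxn in out.exchanges:
        rxn.lb = 0.0
    for compound, rate in medium.entries.items():
        hits = by_compound.get(compound)
        if not hits:
            warnings.warn(
                f"medium {medium.id or '<anonymous>'}: compound {compound!r} "
                "has no exchange reaction; entry skipped",
                MediumWarning,
                stacklevel=2,
            )
            continue
        for rxn in hits:
            rxn.lb = -rate
    return out


def complete_medium(model: Model, max_uptake: float = DEFAULT_MAX_FLUX) -> Medium:
    """Medium allowing every exchange reaction to carry uptake flux."""
    return Medium(
        {c: max_uptake for c in model.exchanges_by_compound()}, id="complete"
    )


# ---------------------------------------------------------------------------
# Stoichiometric matrix
# ---------------------------------------------------------------------------


def build_stoichiometric_matrix(model: Model) -> sparse.csr_matrix:
    """Assemble S (metabolites x reactions) in model insertion order.

    Entry (i, j) is the coefficient of metabolite i in reaction j. An
    empty model yields a 0x0 matrix.
    """
    met_index = {m: i for i, m in enumerate(model.metabolites)}
    rows: list[int] = []
    cols: list[int] = []
    data: list[float] = []
    for j, rxn in enumerate(model.reactions.values()):
        for met_id, coeff in rxn.stoichiometry.items():
            if coeff == 0:
                continue
            rows.append(met_index[met_id])
            cols.append(j)
            data.append(float(coeff))
    shape = (len(model.metabolites), len(model.reactions))
    return sparse.csr_matrix(
        (np.asarray(data), (rows, cols)), shape=shape
    )
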