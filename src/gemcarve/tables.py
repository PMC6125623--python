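"""Readers/writers for the tabular side inputs.

All tables are plain TSV with a header row:

- media:               medium_id, compound_id, max_uptake
- thermodynamics:      reaction_id, dG0_kJ_mol
- concentrations:      metabolite_id, cmin_mM, cmax_mM
- biomass components:  metabolite_id, mass_fraction, mw
- curated directions:  reaction_id, direction in {fwd, rev, rev_ok}
- gene scores:         gene_id, score
- soft constraints:    reaction_id, value in {-1, 0, 1}
- hard constraints:    reaction_id, lb, ub
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .core import Medium

__all__ = [
    "read_media_tsv",
    "read_thermo_tsv",
    "read_concentration_tsv",
    "read_biomass_tsv",
    "read_direction_tsv",
    "read_gene_scores_tsv",
    "write_gene_scores_tsv",
    "read_soft_constraints_tsv",
    "read_hard_constraints_tsv",
    "write_reaction_scores_tsv",
]


def _load(path: str | Path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def read_media_tsv(path: str | Path) -> dict[str, Medium]:
    """Ordered map medium_id -> Medium (order of first appearance)."""
    df = _load(path, ["medium_id", "compound_id", "max_uptake"])
    media: dict[str, Medium] = {}
    for medium_id, group in df.groupby("medium_id", sort=False):
        media[str(medium_id)] = Medium(
            dict(zip(group["compound_id"].astype(str), group["max_uptake"].astype(float))),
            id=str(medium_id),
        )
    return media


def read_thermo_tsv(path: str | Path) -> dict[str, float]:
    df = _load(path, ["reaction_id", "dG0_kJ_mol"])
    df = df.dropna(subset=["dG0_kJ_mol"])
    return dict(zip(df["reaction_id"].astype(str), df["dG0_kJ_mol"].astype(float)))


def read_concentration_tsv(path: str | Path) -> dict[str, tuple[float, float]]:
    df = _load(path, ["metabolite_id", "cmin_mM", "cmax_mM"])
    return {
        str(row.metabolite_id): (float(row.cmin_mM), float(row.cmax_mM))
        for row in df.itertuples()
    }


def read_biomass_tsv(path: str | Path) -> list[tuple[str, float, float]]:
    df = _load(path, ["metabolite_id", "mass_fraction", "mw"])
    return [
        (str(row.metabolite_id), float(row.mass_fraction), float(row.mw))
        for row in df.itertuples()
    ]


def read_direction_tsv(path: str | Path) -> dict[str, str]:
    df = _load(path, ["reaction_id", "direction"])
    allowed = {"fwd", "rev", "rev_ok"}
    out: dict[str, str] = {}
    for row in df.itertuples():
        direction = str(row.direction)
        if direction not in allowed:
            raise ValueError(
                f"{path}: invalid direction {direction!r} for {row.reaction_id} "
                f"(expected one of {sorted(allowed)})"
            )
        out[str(row.reaction_id)] = direction
    return out


def read_gene_scores_tsv(path: str | Path) -> dict[str, float]:
    df = _load(path, ["gene_id", "score"])
    return dict(zip(df["gene_id"].astype(str), df["score"].astype(float)))


def write_gene_scores_tsv(scores: dict[str, float], path: str | Path) -> None:
    pd.DataFrame(
        {"gene_id": list(scores), "score": list(scores.values())}
    ).to_csv(path, sep="\t", index=False)


def read_soft_constraints_tsv(path: str | Path) -> dict[str, int]:
    df = _load(path, ["reaction_id", "value"])
    out: dict[str, int] = {}
    for row in df.itertuples():
        value = int(row.value)
        if value not in (-1, 0, 1):
            raise ValueError(
                f"{path}: soft-constraint value must be -1, 0 or 1 "
                f"(got {value} for {row.reaction_id})"
            )
        out[str(row.reaction_id)] = value
    return out


def read_hard_constraints_tsv(path: str | Path) -> dict[str, tuple[float, float]]:
    df = _load(path, ["reaction_id", "lb", "ub"])
    out: dict[str, tuple[float, float]] = {}
    for row in df.itertuples():
        lb, ub = float(row.lb), float(row.ub)
        if lb > ub:
            raise ValueError(f"{path}: lb > ub for {row.reaction_id}")
        out[str(row.reaction_id)] = (lb, ub)
    return out


def write_reaction_scores_tsv(
    scores: dict[str, float], path: str | Path, gprs: dict | None = None
) -> None:
    rows = {
        "reaction_id": list(scores),
        "score": list(scores.values()),
    }
    if gprs is not None:
        rows["gpr"] = [
            gprs[rid].to_string() if rid in gprs else "" for rid in scores
        ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
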