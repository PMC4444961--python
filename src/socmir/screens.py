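"""Candidate screens over the presence/absence matrix, tree and trait labels.

Two hypothesis-driven screens and a phylogeny-independence summary:

* ``trait_exclusive``   — miRNAs present only in trait-positive (eusocial)
  genomes; facultatively eusocial species carry a *neutral* label whose
  presences neither qualify nor disqualify a candidate.
* ``clade_exclusive``   — miRNAs confined to a named clade (e.g. unique to
  Hymenoptera).
* ``clade_universal``   — miRNAs present in (all − tolerance) members of a
  clade and absent outside it (the Aculeata-specificity criterion).
* ``convergence_summary`` — parsimony gain/loss counts per miRNA, with the
  number of inferred gains leading into all-positive lineages, as a
  phylogeny-independence report (no significance test is computed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .phylo import (
    BinaryCharacter,
    SpeciesTree,
    TreeError,
    count_independent_gains,
    fitch_min_changes,
)
from .profile import PresenceAbsenceMatrix

__all__ = [
    "TraitLabels",
    "CandidateReport",
    "ScreenError",
    "trait_exclusive",
    "clade_exclusive",
    "clade_universal",
    "convergence_summary",
    "POSITIVE",
    "NEGATIVE",
    "NEUTRAL",
]

POSITIVE = "positive"
NEGATIVE = "negative"
NEUTRAL = "neutral"

# external label vocabulary (labels TSV) -> internal
_LABEL_ALIASES = {
    "eusocial": POSITIVE,
    "yes": POSITIVE,
    "positive": POSITIVE,
    "solitary": NEGATIVE,
    "no": NEGATIVE,
    "negative": NEGATIVE,
    "facultative": NEUTRAL,
    "neutral": NEUTRAL,
}


class ScreenError(ValueError):
    """Raised on label/clade/matrix inconsistencies."""


@dataclass
class TraitLabels:
    """Trait label per genome: positive / negative / neutral (facultative)."""

    labels: dict[str, str]

    def __post_init__(self) -> None:
        bad = {g: l for g, l in self.labels.items()
               if l not in (POSITIVE, NEGATIVE, NEUTRAL)}
        if bad:
            raise ScreenError(f"invalid labels: {bad}")

    def __getitem__(self, genome_id: str) -> str:
        return self.labels[genome_id]

    def of(self, kind: str) -> set[str]:
        return {g for g, l in self.labels.items() if l == kind}

    def check_cover(self, matrix: PresenceAbsenceMatrix) -> None:
        missing = set(matrix.col_names) - set(self.labels)
        if missing:
            raise ScreenError(f"unlabeled genomes: {sorted(missing)}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TraitLabels":
        df = pd.read_csv(path, sep="\t", comment="#")
        labels = {}
        for _, row in df.iterrows():
            raw = str(row.iloc[1]).strip().lower()
            if raw not in _LABEL_ALIASES:
                raise ScreenError(f"unknown trait label {raw!r}")
            labels[str(row.iloc[0])] = _LABEL_ALIASES[raw]
        return cls(labels)

    def to_tsv(self, path: str | Path) -> None:
        inv = {POSITIVE: "eusocial", NEGATIVE: "solitary", NEUTRAL: "facultative"}
        with open(path, "w") as fh:
            fh.write("genome_id\tlabel\n")
            for g, l in self.labels.items():
                fh.write(f"{g}\t{inv[l]}\n")


@dataclass
class CandidateReport:
    """One screen hit, re-checkable from the raw matrix alone."""

    mirna_name: str
    category: str  # "trait_exclusive" | "clade_exclusive:<c>" | "clade_universal:<c>"
    present_in: list[str]
    absent_in_violation: list[str] = field(default_factory=list)
    parsimony_summary: tuple[int, int] | None = None  # (independent gains, losses)

    def to_dict(self) -> dict:
        return {
            "mirna_name": self.mirna_name,
            "category": self.category,
            "present_in": list(self.present_in),
            "absent_in_violation": list(self.absent_in_violation),
            "parsimony_summary": self.parsimony_summary,
        }


def _character(matrix: PresenceAbsenceMatrix, mirna: str) -> BinaryCharacter:
    row = matrix.values.loc[mirna]
    return BinaryCharacter(mirna, {g: int(row[g]) for g in matrix.col_names})


def _parsimony_pair(
    matrix: PresenceAbsenceMatrix, tree: SpeciesTree | None, mirna: str
) -> tuple[int, int] | None:
    if tree is None:
        return None
    char = _character(matrix, mirna)
    gains = count_independent_gains(tree, char)
    rec = fitch_min_changes(tree, char)
    return (gains, rec.n_losses)


def trait_exclusive(
    matrix: PresenceAbsenceMatrix,
    labels: TraitLabels,
    min_positive: int = 1,
    tree: SpeciesTree | None = None,
) -> list[CandidateReport]:
    """miRNAs with zero presences in negative genomes and >= min_positive in
    positive genomes. Neutral (facultative) columns are ignored entirely."""
    labels.check_cover(matrix)
    pos = [g for g in matrix.col_names if labels[g] == POSITIVE]
    neg = [g for g in matrix.col_names if labels[g] == NEGATIVE]
    out: list[CandidateReport] = []
    for mirna in matrix.row_names:
        row = matrix.values.loc[mirna]
        if int(row[neg].sum()) == 0 and int(row[pos].sum()) >= min_positive:
            out.append(
                CandidateReport(
                    mirna_name=mirna,
                    category="trait_exclusive",
                    present_in=matrix.present_in(mirna),
                    parsimony_summary=_parsimony_pair(matrix, tree, mirna),
                )
            )
    return out


def _clade_split(
    matrix: PresenceAbsenceMatrix, tree: SpeciesTree, clade: str
) -> tuple[list[str], list[str]]:
    """Clade membership restricted to the panel at hand.

    A panel may sample only part of a clade (the starred initial panel
    does), so membership is intersected with the matrix columns; the clade
    must still be represented by at least one column.
    """
    members = tree.clade_leaves(clade)
    inside = [g for g in matrix.col_names if g in members]
    outside = [g for g in matrix.col_names if g not in members]
    if not inside:
        raise ScreenError(f"clade {clade!r} has no genomes in this panel")
    return inside, outside


def clade_exclusive(
    matrix: PresenceAbsenceMatrix,
    tree: SpeciesTree,
    clade: str,
    min_inside: int = 1,
) -> list[CandidateReport]:
    """miRNAs absent from every genome outside the clade and present in at
    least ``min_inside`` genomes inside it."""
    inside, outside = _clade_split(matrix, tree, clade)
    out = []
    for mirna in matrix.row_names:
        row = matrix.values.loc[mirna]
        if int(row[outside].sum()) == 0 and int(row[inside].sum()) >= min_inside:
            out.append(
                CandidateReport(
                    mirna_name=mirna,
                    category=f"clade_exclusive:{clade}",
                    present_in=matrix.present_in(mirna),
                )
            )
    return out


def clade_universal(
    matrix: PresenceAbsenceMatrix,
    tree: SpeciesTree,
    clade: str,
    tolerance: int = 0,
) -> list[CandidateReport]:
    """miRNAs present in >= (|clade| − tolerance) clade genomes and absent
    from all non-clade genomes (the clade-universality criterion)."""
    inside, outside = _clade_split(matrix, tree, clade)
    if tolerance >= len(inside):
        raise ScreenError(
            f"tolerance {tolerance} >= clade size {len(inside)}"
        )
    out = []
    for mirna in matrix.row_names:
        row = matrix.values.loc[mirna]
        if int(row[outside].sum()) == 0 and int(row[inside].sum()) >= len(inside) - tolerance:
            missing = [g for g in inside if row[g] == 0]
            out.append(
                CandidateReport(
                    mirna_name=mirna,
                    category=f"clade_universal:{clade}",
                    present_in=matrix.present_in(mirna),
                    absent_in_violation=missing if tolerance == 0 else [],
                )
            )
    return out


def convergence_summary(
    matrix: PresenceAbsenceMatrix,
    tree: SpeciesTree,
    labels: TraitLabels,
) -> pd.DataFrame:
    """Per-miRNA parsimony summary of trait convergence.

    For each row: the minimum number of independent gains (root prior
    absent, unit costs), the Fitch loss count, and how many gain branches of
    the Fitch reconstruction lead into subtrees whose labeled leaves are all
    positive-or-neutral. Sorted by ``gains_in_positive_lineages`` descending.
    """
    labels.check_cover(matrix)
    rows = []
    subtree_ok: dict[str, bool] = {}
    for node in tree.postorder():
        leaves = tree.leafset(node)
        subtree_ok[node.node_id] = all(
            labels[g] in (POSITIVE, NEUTRAL) for g in leaves if g in labels.labels
        )
    for mirna in matrix.row_names:
        char = _character(matrix, mirna)
        gains = count_independent_gains(tree, char)
        rec = fitch_min_changes(tree, char)
        gp = 0
        for branch, kind in rec.events:
            if kind == "gain":
                ok = subtree_ok.get(branch)
                if ok is None:  # root stem: whole panel
                    ok = subtree_ok[tree.root.node_id]
                if ok:
                    gp += 1
        rows.append(
            {
                "mirna_name": mirna,
                "independent_gains": gains,
                "gains_in_positive_lineages": gp,
                "losses": rec.n_losses,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(
            ["gains_in_positive_lineages", "mirna_name"],
            ascending=[False, True],
        ).reset_index(drop=True)
    return df
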