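"""Mature miRNA query catalog.

Builds the query set for genome scanning from a miRBase-style mature FASTA:
RNA sequences are converted to DNA (U→T), validated against the mature-miRNA
length range, collapsed across source species when byte-identical, and
assigned to miRNA families by name.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "MatureMiRNA",
    "MiRNACatalog",
    "CatalogError",
    "load_mature_fasta",
    "dedup_catalog",
    "assign_family",
    "MIN_MATURE_LEN",
    "MAX_MATURE_LEN",
]

# Mature miRNAs are ~18-24 nt; bounds padded for edge annotations.
MIN_MATURE_LEN = 16
MAX_MATURE_LEN = 30

_VALID_CHARS = set("ACGUTacgut")
_DNA = set("ACGT")


class CatalogError(ValueError):
    """Raised for invalid catalog records or configuration."""


@dataclass
class MatureMiRNA:
    """One deduplicated mature miRNA query sequence (DNA alphabet).

    Attributes
    ----------
    name : canonical name, e.g. ``"ame-miR-279c"``.
    species_prefix : the 3-letter miRBase species code of the canonical name.
    family : family label with prefix/arm/paralog decorations stripped,
        e.g. ``"miR-279"``.
    sequence : uppercase DNA string over ``{A,C,G,T}``.
    source_ids : original FASTA record IDs merged into this entry.
    """

    name: str
    species_prefix: str
    family: str
    sequence: str
    source_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not set(self.sequence) <= _DNA:
            raise CatalogError(
                f"{self.name}: sequence contains non-ACGT characters: "
                f"{sorted(set(self.sequence) - _DNA)}"
            )
        n = len(self.sequence)
        if not (MIN_MATURE_LEN <= n <= MAX_MATURE_LEN):
            raise CatalogError(
                f"{self.name}: length {n} outside mature range "
                f"[{MIN_MATURE_LEN}, {MAX_MATURE_LEN}]"
            )


class MiRNACatalog:
    """Deduplicated mature-miRNA query set with name and family indices."""

    def __init__(self, entries: Sequence[MatureMiRNA]):
        self.entries: list[MatureMiRNA] = list(entries)
        self.by_name: dict[str, MatureMiRNA] = {}
        self.by_family: dict[str, list[MatureMiRNA]] = {}
        seqs: dict[str, str] = {}
        for e in self.entries:
            if e.name in self.by_name:
                raise CatalogError(f"duplicate catalog name: {e.name}")
            if e.sequence in seqs:
                raise CatalogError(
                    f"identical sequence for {seqs[e.sequence]} and {e.name}; "
                    "run dedup_catalog first"
                )
            seqs[e.sequence] = e.name
            self.by_name[e.name] = e
            self.by_family.setdefault(e.family, []).append(e)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __contains__(self, name: str) -> bool:
        return name in self.by_name

    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("name\tfamily\tsequence\tsource_ids\n")
            for e in self.entries:
                fh.write(
                    f"{e.name}\t{e.family}\t{e.sequence}\t"
                    f"{';'.join(e.source_ids)}\n"
                )

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for e in self.entries:
                fh.write(f">{e.name}\n{e.sequence}\n")


# --- name parsing ---------------------------------------------------------

# miRBase dialects: ame-miR-279c, dme-miR-13b-3p, ame-let-7, dme-bantam,
# nvi-miR-9a-2 (duplicate-locus numeral), cel-lin-4.
_NAME_RE = re.compile(
    r"""^(?P<prefix>[a-z]{3,4})-
        (?P<body>
            (?:miR|mir|let|lin)-\d+[a-z]*(?:-\d+)*(?:-[35]p)?
          | (?:bantam|iab)(?:-\d+[a-z]*)?(?:-[35]p)?
        )$""",
    re.VERBOSE,
)
_FAMILY_RE = re.compile(r"^(?P<head>(?:miR|mir|let|lin)-\d+|bantam|iab(?:-\d+)?)")


def assign_family(name: str) -> str:
    """Family label for a miRBase-style mature name.

    Strips the species prefix, the -5p/-3p arm suffix, trailing paralog
    letters and duplicate-locus numerals: ``ame-miR-279c`` → ``miR-279``,
    ``dme-miR-13b-3p`` → ``miR-13``, ``ame-let-7`` → ``let-7``.
    """
    m = _NAME_RE.match(name)
    if m is None:
        raise CatalogError(f"cannot parse miRNA name: {name!r}")
    body = m.group("body")
    fm = _FAMILY_RE.match(body)
    if fm is None:  # pragma: no cover - body grammar guarantees a head
        raise CatalogError(f"cannot derive family from: {name!r}")
    head = fm.group("head")
    return "miR-" + head[4:] if head.startswith("mir-") else head


def species_prefix(name: str) -> str:
    m = _NAME_RE.match(name)
    if m is None:
        raise CatalogError(f"cannot parse miRNA name: {name!r}")
    return m.group("prefix")


# --- loading & dedup ------------------------------------------------------

def load_mature_fasta(path: str | Path) -> list[MatureMiRNA]:
    """Parse a miRBase-style mature FASTA into validated DNA query records.

    The first whitespace-delimited header token is the record ID; sequences
    are uppercased with U→T. Records with characters outside the RNA/DNA
    alphabet or outside the mature length range raise :class:`CatalogError`
    naming the record.
    """
    path = Path(path)
    entries: list[MatureMiRNA] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq)
        if not raw:
            raise CatalogError(f"record {rec.id!r}: empty sequence")
        bad = set(raw) - _VALID_CHARS
        if bad:
            raise CatalogError(
                f"record {rec.id!r}: invalid characters {sorted(bad)}"
            )
        seq = raw.upper().replace("U", "T")
        name = rec.id
        entries.append(
            MatureMiRNA(
                name=name,
                species_prefix=species_prefix(name),
                family=assign_family(name),
                sequence=seq,
                source_ids=[rec.id],
            )
        )
    return entries


DEFAULT_PRECEDENCE = ("ame", "nvi", "dme")


def dedup_catalog(
    entries: Iterable[MatureMiRNA],
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
) -> MiRNACatalog:
    """Collapse byte-identical sequences into one catalog entry each.

    The canonical name of a merged entry comes from the highest-precedence
    species prefix present among the merged records; ``source_ids`` keeps
    every merged ID. Order of first appearance is preserved.
    """
    entries = list(entries)
    rank = {p: i for i, p in enumerate(precedence)}
    for e in entries:
        if e.species_prefix not in rank:
            raise CatalogError(
                f"species prefix {e.species_prefix!r} of {e.name} not in "
                f"precedence list {list(precedence)}"
            )
    merged: dict[str, MatureMiRNA] = {}
    order: list[str] = []
    for e in entries:
        prev = merged.get(e.sequence)
        if prev is None:
            merged[e.sequence] = MatureMiRNA(
                name=e.name,
                species_prefix=e.species_prefix,
                family=e.family,
                sequence=e.sequence,
                source_ids=list(e.source_ids),
            )
            order.append(e.sequence)
        else:
            for sid in e.source_ids:
                if sid not in prev.source_ids:
                    prev.source_ids.append(sid)
            if rank[e.species_prefix] < rank[prev.species_prefix]:
                prev.name = e.name
                prev.species_prefix = e.species_prefix
                prev.family = e.family
    return MiRNACatalog([merged[s] for s in order])
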