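"""Lineage-annotated reference sequences and lineage algebra.

A reference record carries a full seven-rank taxonomic lineage
(domain, phylum, class, order, family, genus, species) encoded in its
FASTA header with one bracket-numbered slot per rank::

    >R1 [0]Archaea;[1]Thaumarchaeota;[2]Nitrososphaeria;[3]Nitrososphaerales;[4]Nitrososphaeraceae;[5]Nitrososphaera;[6]sp1

Lineages form a prefix hierarchy: a rank may only be present if every
shallower rank is present, and the lowest common ancestor (LCA) of two
lineages is their longest common prefix.  An empty lineage (depth 0)
means "unclassified".
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from Bio import SeqIO

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
N_RANKS = len(RANKS)

_HEADER_SLOT = re.compile(r"\[(\d)\]([^;\[\]]+)")


class ReferenceParseError(ValueError):
    """Raised when a reference FASTA does not follow the header dialect."""


@dataclass(frozen=True)
class TaxonomicLineage:
    """Ordered rank labels from domain downward; possibly truncated."""

    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.labels) > N_RANKS:
            raise ValueError(f"lineage deeper than {N_RANKS} ranks: {self.labels}")
        for lab in self.labels:
            if not lab or not lab.strip():
                raise ValueError("lineage labels must be non-empty (prefix structure)")

    @property
    def depth(self) -> int:
        return len(self.labels)

    def label_at(self, rank: str) -> str | None:
        i = RANKS.index(rank)
        return self.labels[i] if i < self.depth else None

    def truncate(self, depth: int) -> "TaxonomicLineage":
        if depth < 0:
            raise ValueError("depth must be >= 0")
        return TaxonomicLineage(self.labels[:depth])

    def is_unclassified(self) -> bool:
        return self.depth == 0

    def __str__(self) -> str:
        return ";".join(self.labels) if self.labels else "<unclassified>"


def lca(a: TaxonomicLineage, b: TaxonomicLineage) -> TaxonomicLineage:
    """Lowest common ancestor: the longest common prefix of two lineages."""
    common: list[str] = []
    for x, y in zip(a.labels, b.labels):
        if x != y:
            break
        common.append(x)
    return TaxonomicLineage(tuple(common))


def lca_many(lineages: Iterable[TaxonomicLineage]) -> TaxonomicLineage:
    it = iter(lineages)
    try:
        acc = next(it)
    except StopIteration:
        raise ValueError("lca_many requires at least one lineage") from None
    for lin in it:
        acc = lca(acc, lin)
        if acc.depth == 0:
            break
    return acc


@dataclass(frozen=True)
class ReferenceRecord:
    id: str
    lineage: TaxonomicLineage
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("reference id must be non-empty")
        if self.lineage.depth != N_RANKS:
            raise ValueError(f"reference {self.id}: lineage must be complete (7 ranks)")
        if len(self.sequence) < 200:
            raise ValueError(f"reference {self.id}: sequence shorter than 200 nt")
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise ValueError(f"reference {self.id}: non-ACGT characters {sorted(bad)}")

    @property
    def genus(self) -> str | None:
        return self.lineage.label_at("genus")


@dataclass
class ReferenceDatabase:
    records: list[ReferenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("reference database must contain at least one record")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ReferenceParseError(f"duplicate reference ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ReferenceRecord]:
        return iter(self.records)

    def by_id(self, rid: str) -> ReferenceRecord:
        for r in self.records:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def genera(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            g = r.genus
            if g is not None:
                seen.setdefault(g, None)
        return list(seen)


def parse_lineage_header(description: str, *, where: str = "") -> tuple[str, TaxonomicLineage]:
    """Parse ``ID [0]domain;...;[6]species`` into (id, lineage)."""
    parts = description.split(None, 1)
    if len(parts) != 2:
        raise ReferenceParseError(f"malformed header{where}: {description!r} (no lineage)")
    rid, rest = parts
    slots = dict()
    for num, label in _HEADER_SLOT.findall(rest):
        slots[int(num)] = label.strip()
    missing = [i for i in range(N_RANKS) if i not in slots or not slots[i]]
    if missing:
        raise ReferenceParseError(
            f"malformed header{where}: {description!r} (missing rank slot(s) {missing})"
        )
    return rid, TaxonomicLineage(tuple(slots[i] for i in range(N_RANKS)))


def parse_reference_fasta(path) -> ReferenceDatabase:
    """Read a lineage-annotated reference FASTA.

    Sequences are upper-cased and U is mapped to T.  Malformed headers and
    duplicate ids raise :class:`ReferenceParseError` naming the offending line.
    """
    # header -> line-number map so parse errors can name the line
    header_lines: dict[int, int] = {}
    with open(path) as fh:
        n = 0
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                header_lines[n] = lineno
                n += 1

    records: list[ReferenceRecord] = []
    seen: set[str] = set()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        where = f" at line {header_lines.get(i, '?')}"
        rid, lineage = parse_lineage_header(rec.description, where=where)
        if rid in seen:
            raise ReferenceParseError(f"duplicate reference id {rid!r}{where}")
        seen.add(rid)
        seq = str(rec.seq).upper().replace("U", "T")
        records.append(ReferenceRecord(id=rid, lineage=lineage, sequence=seq))
    if not records:
        raise ReferenceParseError(f"no records in {path}")
    return ReferenceDatabase(records)


def format_lineage_header(rid: str, lineage: TaxonomicLineage) -> str:
    if lineage.depth != N_RANKS:
        raise ValueError("can only format complete lineages")
    slots = ";".join(f"[{i}]{lab}" for i, lab in enumerate(lineage.labels))
    return f"{rid} {slots}"


def write_reference_fasta(db: ReferenceDatabase, path, *, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in db:
            fh.write(">" + format_lineage_header(rec.id, rec.lineage) + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")
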