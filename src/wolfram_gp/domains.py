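"""Transmembrane-domain tables and TM classification of in-frame variants.

Wolframin is an ER membrane glycoprotein with multiple membrane-spanning
helices; in-frame variants are classified as transmembrane (TM) or not by
matching their amino-acid position against the protein's annotated TM
residue ranges.  Ranges are 1-based, inclusive at both ends (protein
convention).  A multi-residue in-frame variant counts as TM if ANY affected
residue lies in ANY TM range (closed-interval overlap — the conservative
generalization of the single-position rule used for missense variants).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .variants import BroadClass, ProteinVariant, VariantKind, broad_class

__all__ = [
    "DomainTable",
    "load_domain_table",
    "affected_interval",
    "is_transmembrane",
    "count_tm_inframe",
]


@dataclass(frozen=True)
class DomainTable:
    """Ordered, non-overlapping 1-based inclusive residue ranges for one protein."""

    protein_id: str
    ranges: tuple[tuple[int, int], ...]
    provenance: str
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.provenance.strip():
            raise ValueError("DomainTable provenance must be non-empty")
        prev_end = 0
        for i, (start, end) in enumerate(self.ranges):
            if start < 1 or end < start:
                raise ValueError(
                    f"range {i + 1} ({start}, {end}) is inverted or non-positive"
                )
            if start <= prev_end:
                raise ValueError(
                    f"range {i + 1} ({start}, {end}) overlaps or is out of order "
                    f"with the previous range ending at {prev_end}"
                )
            prev_end = end

    @property
    def n_residues(self) -> int:
        """Total number of residues covered by the ranges."""
        return sum(end - start + 1 for start, end in self.ranges)


def load_domain_table(path: str | Path) -> DomainTable:
    """Read a TM-domain table from 3-column TSV (start, end, label).

    ``#``-prefixed header lines carry metadata as ``# key: value``; the keys
    ``protein_id`` and ``provenance`` are required (a real table must record
    which database snapshot it came from).  Rows are sorted by start and
    validated: overlapping or inverted ranges raise with the offending row
    named.  An empty range list is valid (every variant is then non-TM).
    """
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[tuple[int, int, str]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if ":" in stripped:
                key, _, value = stripped.partition(":")
                meta[key.strip().lower()] = value.strip()
            continue
        fields = line.split("\t")
        if fields[0].lower() == "start":  # optional column header
            continue
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected start<TAB>end[<TAB>label]")
        try:
            start, end = int(fields[0]), int(fields[1])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer residue index") from exc
        label = fields[2] if len(fields) > 2 else f"TM{len(rows) + 1}"
        rows.append((start, end, label))

    if "protein_id" not in meta:
        raise ValueError(f"{path}: missing '# protein_id:' header")
    if not meta.get("provenance", "").strip():
        raise ValueError(f"{path}: missing '# provenance:' header")

    rows.sort(key=lambda r: r[0])
    return DomainTable(
        protein_id=meta["protein_id"],
        ranges=tuple((s, e) for s, e, _ in rows),
        provenance=meta["provenance"],
        labels=tuple(label for _, _, label in rows),
    )


def affected_interval(v: ProteinVariant) -> tuple[int, int]:
    """Residue interval (1-based, inclusive) affected by an in-frame variant.

    Missense: the substituted residue.  In-frame deletions and delins: the
    deleted block.  In-frame insertions: the two flanking residues — a pure
    insertion has no reference residue of its own.
    """
    if broad_class(v) is not BroadClass.INFRAME:
        raise ValueError(
            f"affected_interval requires an in-frame allele, got {v.kind.value} "
            f"({v.raw_text!r})"
        )
    if v.kind is VariantKind.MISSENSE:
        return (v.start_pos, v.start_pos)
    if v.kind is VariantKind.INFRAME_INSERTION:
        return (v.start_pos, v.start_pos + 1)
    return (v.start_pos, v.end_pos)


def is_transmembrane(v: ProteinVariant, table: DomainTable) -> bool:
    """True iff the variant's affected interval overlaps any TM range."""
    start, end = affected_interval(v)
    return any(start <= r_end and end >= r_start for r_start, r_end in table.ranges)


def count_tm_inframe(
    allele1: ProteinVariant, allele2: ProteinVariant, table: DomainTable
) -> int:
    """Number of in-frame alleles overlapping a TM domain (0, 1 or 2).

    NSFS alleles never contribute.  The genotype must carry at least one
    in-frame allele — TM dose is undefined for two-NSFS genotypes.
    Symmetric in the two alleles.
    """
    classes = [broad_class(a) for a in (allele1, allele2)]
    for a, c in zip((allele1, allele2), classes):
        if c is BroadClass.OTHER:
            raise ValueError(f"allele {a.raw_text!r} classifies OTHER")
    inframe = [a for a, c in zip((allele1, allele2), classes) if c is BroadClass.INFRAME]
    if not inframe:
        raise ValueError("TM dose is undefined for genotypes with no in-frame allele")
    return sum(1 for a in inframe if is_transmembrane(a, table))
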