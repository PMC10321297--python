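"""Protein-level variant descriptors and allele classification.

Wolfram syndrome genotype–phenotype analysis groups each WFS1 allele into
one of two broad classes: truncating nonsense/frameshift (NSFS) alleles, and
in-frame alleles (missense and in-frame insertions/deletions) that preserve
the reading frame.  This module parses protein-level HGVS-style descriptors
(``p.Arg558Cys``, ``p.Trp613*``, ``p.Val412Serfs*29``, ``p.Phe883del`` ...)
into :class:`ProteinVariant` objects and maps them onto that two-bin scheme.

Only protein-level (``p.``) notation is handled: the downstream analysis
operates on amino-acid residue positions.  cDNA-level (``c.``) descriptors
and variant kinds outside the two-bin scheme (start-loss, stop-loss,
synonymous, splice-style strings) classify as ``OTHER`` and are excluded
from dose analyses upstream.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum

logger = logging.getLogger(__name__)

__all__ = [
    "VariantKind",
    "BroadClass",
    "ProteinVariant",
    "parse_protein_descriptor",
    "broad_class",
    "count_nsfs_alleles",
]


class VariantKind(Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    INFRAME_DELETION = "inframe_deletion"
    INFRAME_INSERTION = "inframe_insertion"
    INFRAME_DELINS = "inframe_delins"
    OTHER = "other"


class BroadClass(Enum):
    """Two-bin allele classification: truncating vs reading-frame preserving."""

    NSFS = "nsfs"
    INFRAME = "inframe"
    OTHER = "other"


#: 3-letter -> 1-letter amino-acid codes ("Ter" and "*" both mean stop).
AA3_TO_1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "Ter": "*",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
_AA1 = set("ACDEFGHIKLMNPQRSTVWY")

# one residue token: a 3-letter code, a 1-letter code, Ter, or *
_RES = r"(?:Ala|Arg|Asn|Asp|Cys|Gln|Glu|Gly|His|Ile|Leu|Lys|Met|Phe|Pro|Ser|Thr|Trp|Tyr|Val|Ter|[ACDEFGHIKLMNPQRSTVWY]|\*)"
_RES_SEQ = rf"(?:{_RES})+"

_RE_SUB = re.compile(rf"^({_RES})(\d+)({_RES})$")
_RE_FS = re.compile(
    rf"^({_RES})(\d+)({_RES})?fs(?:(?:Ter|\*)\s*(\d+|\?)?)?$"
)
_RE_DEL = re.compile(rf"^({_RES})(\d+)(?:_({_RES})(\d+))?del$")
_RE_INS = re.compile(rf"^({_RES})(\d+)_({_RES})(\d+)ins({_RES_SEQ})$")
_RE_DELINS = re.compile(rf"^({_RES})(\d+)(?:_({_RES})(\d+))?delins({_RES_SEQ})$")
_RE_DUP = re.compile(rf"^({_RES})(\d+)(?:_({_RES})(\d+))?dup$")


def _norm_res(token: str) -> str:
    """Normalize one residue token to its 1-letter code."""
    if token in AA3_TO_1:
        return AA3_TO_1[token]
    if token == "*":
        return "*"
    if token in _AA1:
        return token
    raise ValueError(f"unknown amino-acid code {token!r}")


def _norm_seq(seq: str) -> str:
    out = []
    i = 0
    while i < len(seq):
        if seq[i] == "*":
            out.append("*")
            i += 1
        elif seq[i : i + 3] in AA3_TO_1:
            out.append(AA3_TO_1[seq[i : i + 3]])
            i += 3
        elif seq[i] in _AA1:
            out.append(seq[i])
            i += 1
        else:  # pragma: no cover - grammar guarantees tokens
            raise ValueError(f"unparseable residue sequence {seq!r}")
    return "".join(out)


def _seq_to_3(seq: str) -> str:
    return "".join(AA1_TO_3[a] for a in seq)


@dataclass(frozen=True)
class ProteinVariant:
    """One parsed protein-level allele descriptor.

    Positions are 1-based residue indices, inclusive at both ends.  Residue
    strings are stored as 1-letter codes; ``"*"`` denotes a stop.  For
    frameshifts, ``fs_term`` records the ``fs*N`` stop distance when given.
    """

    raw_text: str
    start_pos: int
    end_pos: int
    ref_residues: str
    alt_residues: str
    kind: VariantKind
    fs_term: int | None = field(default=None)

    def __post_init__(self) -> None:
        if self.kind is VariantKind.OTHER:
            return
        if self.start_pos < 1 or self.end_pos < self.start_pos:
            raise ValueError(
                f"invalid residue interval [{self.start_pos}, {self.end_pos}] "
                f"in {self.raw_text!r}"
            )

    def to_hgvs(self) -> str:
        """Serialize back to canonical 3-letter protein HGVS notation.

        Re-parsing the serialized form yields an identical variant
        (round-trip stability); ``OTHER`` variants return their raw text.
        """
        k = self.kind
        if k is VariantKind.OTHER:
            return self.raw_text
        ref3 = _seq_to_3(self.ref_residues[0])
        if k in (VariantKind.MISSENSE, VariantKind.NONSENSE):
            alt = "*" if self.alt_residues == "*" else _seq_to_3(self.alt_residues)
            return f"p.{ref3}{self.start_pos}{alt}"
        if k is VariantKind.FRAMESHIFT:
            alt = _seq_to_3(self.alt_residues) if self.alt_residues else ""
            term = f"*{self.fs_term}" if self.fs_term is not None else ""
            return f"p.{ref3}{self.start_pos}{alt}fs{term}"
        span = f"{ref3}{self.start_pos}"
        if self.end_pos > self.start_pos:
            span += f"_{_seq_to_3(self.ref_residues[-1])}{self.end_pos}"
        if k is VariantKind.INFRAME_DELETION:
            return f"p.{span}del"
        if k is VariantKind.INFRAME_INSERTION:
            return f"p.{span}ins{_seq_to_3(self.alt_residues)}"
        if k is VariantKind.INFRAME_DELINS:
            return f"p.{span}delins{_seq_to_3(self.alt_residues)}"
        raise AssertionError(k)  # pragma: no cover


def _other(text: str, reason: str) -> ProteinVariant:
    logger.warning("descriptor %r classified OTHER: %s", text, reason)
    return ProteinVariant(
        raw_text=text, start_pos=1, end_pos=1,
        ref_residues="", alt_residues="", kind=VariantKind.OTHER,
    )


def parse_protein_descriptor(text: str) -> ProteinVariant:
    """Parse a protein-level HGVS-style descriptor into a :class:`ProteinVariant`.

    Accepts 1- and 3-letter residue codes and an optional ``p.`` prefix
    (surrounding parentheses tolerated).  Descriptors outside the supported
    grammar — including cDNA-level ``c.`` strings — return ``kind=OTHER``
    with the raw text preserved and a warning logged, never an exception.

    Raises
    ------
    ValueError
        If ``text`` is empty/whitespace, or a position is zero.
    """
    if text is None or not str(text).strip():
        raise ValueError("empty variant descriptor")
    raw = str(text).strip()
    body = raw
    if body.startswith("p."):
        body = body[2:]
    body = body.strip("()")
    if re.match(r"^[cgnmr]\.", raw):
        return _other(
            raw,
            "cDNA/genomic-level descriptor; only protein-level (p.) "
            "amino-acid positions are analyzed",
        )

    def pos(tok: str) -> int:
        p = int(tok)
        if p < 1:
            raise ValueError(f"residue position must be >= 1, got {p} in {raw!r}")
        return p

    m = _RE_SUB.match(body)
    if m:
        ref, alt = _norm_res(m.group(1)), _norm_res(m.group(3))
        p = pos(m.group(2))
        if ref == "*":
            return _other(raw, "stop-loss (extension) is outside the two-bin scheme")
        if alt == "*":
            return ProteinVariant(raw, p, p, ref, "*", VariantKind.NONSENSE)
        if alt == ref:
            return _other(raw, "synonymous substitution")
        if p == 1 and ref == "M":
            return _other(raw, "start-loss is outside the two-bin scheme")
        return ProteinVariant(raw, p, p, ref, alt, VariantKind.MISSENSE)

    m = _RE_FS.match(body)
    if m:
        ref = _norm_res(m.group(1))
        p = pos(m.group(2))
        alt = _norm_res(m.group(3)) if m.group(3) else ""
        term = m.group(4)
        fs_term = int(term) if term and term != "?" else None
        return ProteinVariant(raw, p, p, ref, alt, VariantKind.FRAMESHIFT, fs_term)

    m = _RE_DEL.match(body)
    if m:
        start = pos(m.group(2))
        end = pos(m.group(4)) if m.group(4) else start
        if end < start:
            raise ValueError(f"inverted residue range in {raw!r}")
        ref = _norm_res(m.group(1)) + (_norm_res(m.group(3)) if m.group(3) else "")
        return ProteinVariant(raw, start, end, ref, "", VariantKind.INFRAME_DELETION)

    m = _RE_INS.match(body)
    if m:
        start, end = pos(m.group(2)), pos(m.group(4))
        if end != start + 1:
            return _other(raw, "insertion flanks are not adjacent residues")
        ref = _norm_res(m.group(1)) + _norm_res(m.group(3))
        return ProteinVariant(
            raw, start, end, ref, _norm_seq(m.group(5)), VariantKind.INFRAME_INSERTION
        )

    m = _RE_DELINS.match(body)
    if m:
        start = pos(m.group(2))
        end = pos(m.group(4)) if m.group(4) else start
        if end < start:
            raise ValueError(f"inverted residue range in {raw!r}")
        ref = _norm_res(m.group(1)) + (_norm_res(m.group(3)) if m.group(3) else "")
        return ProteinVariant(
            raw, start, end, ref, _norm_seq(m.group(5)), VariantKind.INFRAME_DELINS
        )

    m = _RE_DUP.match(body)
    if m:
        # a duplication inserts a copy after the duplicated block; treat as an
        # in-frame insertion attributed to the block's last residue and its
        # successor so the affected interval stays well defined
        start = pos(m.group(2))
        end = pos(m.group(4)) if m.group(4) else start
        if end < start:
            raise ValueError(f"inverted residue range in {raw!r}")
        last = _norm_res(m.group(3)) if m.group(3) else _norm_res(m.group(1))
        return ProteinVariant(
            raw, end, end + 1, last, last, VariantKind.INFRAME_INSERTION
        )

    return _other(raw, "descriptor does not match the protein-variant grammar")


def broad_class(v: ProteinVariant) -> BroadClass:
    """Map a parsed variant onto the NSFS / in-frame / other scheme.

    Nonsense and frameshift alleles are predicted truncating (NSFS);
    missense and in-frame insertions, deletions and delins preserve the
    reading frame (INFRAME); everything else is OTHER.  Total and
    deterministic over :class:`VariantKind`.
    """
    if v.kind in (VariantKind.NONSENSE, VariantKind.FRAMESHIFT):
        return BroadClass.NSFS
    if v.kind in (
        VariantKind.MISSENSE,
        VariantKind.INFRAME_DELETION,
        VariantKind.INFRAME_INSERTION,
        VariantKind.INFRAME_DELINS,
    ):
        return BroadClass.INFRAME
    return BroadClass.OTHER


def count_nsfs_alleles(allele1: ProteinVariant, allele2: ProteinVariant) -> int:
    """Number of a genotype's two alleles that are nonsense/frameshift (0, 1 or 2).

    Each allele counts independently, so a homozygous truncating genotype
    counts 2.  Alleles must classify NSFS or INFRAME; an OTHER allele here
    is a contract violation (such patients are excluded upstream).
    """
    doses = []
    for a in (allele1, allele2):
        c = broad_class(a)
        if c is BroadClass.OTHER:
            raise ValueError(
                f"allele {a.raw_text!r} classifies OTHER; "
                "exclude the patient before dose counting"
            )
        doses.append(1 if c is BroadClass.NSFS else 0)
    return sum(doses)
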