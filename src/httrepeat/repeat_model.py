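"""Domain model of the *HTT* exon-1 repeat region.

The repeat region of a disease chromosome is an ordered series of
trinucleotide runs: an uninterrupted CAG tract followed by a polymorphic
glutamine/proline-codon flank, ending at the invariant CAGCTTCCT 9-mer.
Most chromosomes carry the canonical flank (a single CAACAG after the CAG
tract); rarer chromosomes lack the CAA interruption ("CAA-loss") or carry
two tandem CAACAG units ("CAACAG-duplication").  These structural classes
matter because (a) they decouple encoded polyglutamine length from
uninterrupted CAG length, and (b) the standard PCR fragment-sizing assay,
calibrated on canonical standards, mis-estimates the uninterrupted CAG
length on non-canonical alleles.

This module provides the structure types, run-notation parsing/formatting,
the CAG / polyglutamine arithmetic, structure classification, and the
fragment-assay estimation model together with its exact inverse.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "TripletRun",
    "RepeatStructure",
    "StructureClass",
    "AlleleCall",
    "StructureParseError",
    "parse_structure",
    "format_structure",
    "uninterrupted_cag_length",
    "polyglutamine_length",
    "classify_structure",
    "fragment_assay_estimate",
    "correct_estimated_cag",
    "make_structure",
    "structures_to_fasta",
    "TERMINATOR",
]

#: Invariant 9-mer marking the 3' end of the polymorphic triplet tract.
TERMINATOR = "CAGCTTCCT"

_GLN_CODONS = frozenset({"CAG", "CAA"})
_CODON_RE = re.compile(r"^[ACGT]{3}$")
_TOKEN_RE = re.compile(r"^([ACGT]{3})_(\d+)$")


class StructureParseError(ValueError):
    """Raised when run notation or a DNA string cannot be parsed."""


class StructureClass(enum.Enum):
    """Mutually exclusive repeat-region structure classes."""

    CANONICAL = "canonical"
    CAA_LOSS = "caa_loss"
    CAACAG_DUP = "caacag_dup"
    OTHER = "other"


@dataclass(frozen=True)
class TripletRun:
    """A run of ``count`` consecutive copies of a trinucleotide ``codon``."""

    codon: str
    count: int

    def __post_init__(self) -> None:
        if not _CODON_RE.match(self.codon):
            raise StructureParseError(f"invalid codon {self.codon!r}")
        if self.count < 1:
            raise StructureParseError(f"run count must be >= 1, got {self.count}")


@dataclass(frozen=True)
class RepeatStructure:
    """Ordered trinucleotide runs describing a repeat region.

    ``terminator_found`` records whether the CAGCTTCCT terminator was
    observed at the 3' end when the structure was profiled from a read;
    structures built from notation default to complete.
    """

    runs: tuple[TripletRun, ...]
    terminator_found: bool = True

    def __post_init__(self) -> None:
        if not self.runs:
            raise StructureParseError("structure must contain at least one run")
        for a, b in zip(self.runs, self.runs[1:]):
            if a.codon == b.codon:
                raise StructureParseError(
                    f"adjacent runs share codon {a.codon}; structure not normalized"
                )

    @classmethod
    def from_runs(
        cls, runs: Iterable[tuple[str, int] | TripletRun], terminator_found: bool = True
    ) -> "RepeatStructure":
        """Build from (codon, count) pairs, merging equal adjacent codons."""
        norm: list[TripletRun] = []
        for r in runs:
            run = r if isinstance(r, TripletRun) else TripletRun(*r)
            if norm and norm[-1].codon == run.codon:
                norm[-1] = TripletRun(run.codon, norm[-1].count + run.count)
            else:
                norm.append(run)
        return cls(tuple(norm), terminator_found)

    @classmethod
    def from_dna(cls, seq: str, terminator_found: bool = True) -> "RepeatStructure":
        """Run-length encode an in-frame DNA string (length multiple of 3)."""
        seq = seq.upper()
        if not seq or len(seq) % 3:
            raise StructureParseError("DNA string length must be a positive multiple of 3")
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        return cls.from_runs(((c, 1) for c in codons), terminator_found)

    def to_dna(self) -> str:
        return "".join(r.codon * r.count for r in self.runs)

    def __str__(self) -> str:
        return format_structure(self)


@dataclass(frozen=True)
class AlleleCall:
    """One called chromosome: CAG length, structure, class and read support."""

    uninterrupted_cag: int
    structure: RepeatStructure
    cls: StructureClass
    support: int

    def __post_init__(self) -> None:
        head = self.structure.runs[0]
        if head.codon != "CAG" or head.count != self.uninterrupted_cag:
            raise ValueError(
                "uninterrupted_cag must equal the first CAG run of the structure"
            )


def parse_structure(text: str) -> RepeatStructure:
    """Parse run notation like ``"CAG_42 CAA_1 CAG_1 CCG_1 CCA_1 CCG_7 CCT_2"``.

    Tokens are CODON_COUNT pairs separated by whitespace.  Equal adjacent
    codons are merged so that ``format_structure(parse_structure(s))`` is the
    normalized form of ``s``.
    """
    tokens = text.split()
    if not tokens:
        raise StructureParseError("empty structure string")
    runs = []
    for tok in tokens:
        m = _TOKEN_RE.match(tok)
        if not m:
            raise StructureParseError(f"malformed token {tok!r}")
        codon, count = m.group(1), int(m.group(2))
        if count == 0:
            raise StructureParseError(f"zero count in token {tok!r}")
        runs.append((codon, count))
    return RepeatStructure.from_runs(runs)


def format_structure(structure: RepeatStructure) -> str:
    """Serialize to the canonical run notation."""
    return " ".join(f"{r.codon}_{r.count}" for r in structure.runs)


def uninterrupted_cag_length(structure: RepeatStructure) -> int:
    """Length of the leading pure CAG tract."""
    head = structure.runs[0]
    if head.codon != "CAG":
        raise ValueError(f"structure does not start with CAG (got {head.codon})")
    return head.count


def polyglutamine_length(structure: RepeatStructure) -> int:
    """Encoded polyglutamine length.

    CAA and CAG both encode glutamine, so this is the total length of the
    maximal contiguous stretch of glutamine codons starting at the leading
    CAG run: n for CAA-loss, n+2 for canonical, n+4 for CAACAG-duplication
    alleles with n uninterrupted CAGs.
    """
    uninterrupted_cag_length(structure)  # validates the head run
    total = 0
    for run in structure.runs:
        if run.codon not in _GLN_CODONS:
            break
        total += run.count
    return total


def _glutamine_segment(structure: RepeatStructure) -> tuple[TripletRun, ...]:
    seg = []
    for run in structure.runs:
        if run.codon not in _GLN_CODONS:
            break
        seg.append(run)
    return tuple(seg)


def classify_structure(structure: RepeatStructure) -> StructureClass:
    """Assign a structure class from the glutamine-codon segment.

    canonical:   CAG_n CAA_1 CAG_1      (one CAACAG after the tract)
    caa_loss:    CAG_n                  (no CAA interruption)
    caacag_dup:  CAG_n CAA_1 CAG_1 CAA_1 CAG_1
    other:       anything else
    """
    if structure.runs[0].codon != "CAG":
        return StructureClass.OTHER
    seg = _glutamine_segment(structure)
    pattern = tuple((r.codon, r.count) for r in seg[1:])
    if not pattern:
        return StructureClass.CAA_LOSS
    if pattern == (("CAA", 1), ("CAG", 1)):
        return StructureClass.CANONICAL
    if pattern == (("CAA", 1), ("CAG", 1), ("CAA", 1), ("CAG", 1)):
        return StructureClass.CAACAG_DUP
    return StructureClass.OTHER


def fragment_assay_estimate(
    true_cag: int, cls: StructureClass, misprime: bool = False
) -> int:
    """CAG length reported by the fragment-sizing assay for a true length.

    The assay is calibrated on canonical standards, so canonical alleles are
    sized correctly; CAA-loss alleles are underestimated by 2; duplication
    alleles are overestimated by 2, or by only 1 when the PCR primer
    mis-primes on the duplicated CAACAG.
    """
    if true_cag < 1:
        raise ValueError("true_cag must be >= 1")
    if cls is StructureClass.CANONICAL:
        return true_cag
    if cls is StructureClass.CAA_LOSS:
        return true_cag - 2
    if cls is StructureClass.CAACAG_DUP:
        return true_cag + (1 if misprime else 2)
    raise ValueError(f"no assay model for structure class {cls.value!r}")


def correct_estimated_cag(
    estimated: int, cls: StructureClass, misprime: bool = False
) -> int:
    """Exact inverse of :func:`fragment_assay_estimate`."""
    if cls is StructureClass.CANONICAL:
        return estimated
    if cls is StructureClass.CAA_LOSS:
        return estimated + 2
    if cls is StructureClass.CAACAG_DUP:
        return estimated - (1 if misprime else 2)
    raise ValueError(f"no assay model for structure class {cls.value!r}")


# Flank run patterns observed on sequenced chromosomes of each class
# (proline-rich region between the glutamine segment and the terminator).
_FLANKS: dict[StructureClass, tuple[tuple[str, int], ...]] = {
    StructureClass.CANONICAL: (
        ("CAA", 1), ("CAG", 1), ("CCG", 1), ("CCA", 1), ("CCG", 7), ("CCT", 2),
    ),
    StructureClass.CAA_LOSS: (("CCG", 12), ("CCT", 2)),
    StructureClass.CAACAG_DUP: (
        ("CAA", 1), ("CAG", 1), ("CAA", 1), ("CAG", 1),
        ("CCG", 1), ("CCA", 1), ("CCG", 7), ("CCT", 3),
    ),
    # A rare-variant style flank used for the residual "other" class.
    StructureClass.OTHER: (
        ("CAA", 1), ("CAG", 2), ("CCG", 1), ("CCA", 1), ("CCG", 7), ("CCT", 2),
    ),
}


def make_structure(cls: StructureClass, cag: int) -> RepeatStructure:
    """Construct a full repeat-region structure of a class with ``cag`` CAGs."""
    if cag < 1:
        raise ValueError("cag must be >= 1")
    return RepeatStructure.from_runs((("CAG", cag),) + _FLANKS[cls])


def structures_to_fasta(
    structures: Sequence[tuple[str, RepeatStructure]], handle_or_path
) -> None:
    """Write repeat-region sequences (runs + terminator) as FASTA records."""
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [
        SeqRecord(Seq(s.to_dna() + TERMINATOR), id=name, description=str(s))
        for name, s in structures
    ]
    SeqIO.write(records, handle_or_path, "fasta")
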