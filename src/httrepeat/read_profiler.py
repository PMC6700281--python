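"""Repeat-structure profiling from sequencing reads.

Two scanners are implemented.  The forward scanner (for 2x300 bp amplicon
paired-end reads) anchors on the first CAGCAGCAG 9-mer, consumes successive
in-frame triplets, and stops at the CAGCTTCCT terminator or the read end.
A read pair is retained only when both mates (the antisense mate after
reverse complementation) yield the identical run list.  Retained profiles
are aggregated into a histogram from which a two-allele genotype is called.

The reverse scanner (for pre-extracted whole-genome-sequencing reads)
anchors on the CAGCTTCCT terminator and walks 3'->5' in frame until three
consecutive CAG triplets are found; aggregated complete sequences with a
share of 14% or less are filtered out before genotype assignment.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .repeat_model import (
    TERMINATOR,
    AlleleCall,
    RepeatStructure,
    classify_structure,
    format_structure,
)

__all__ = [
    "ANCHOR",
    "ReadPair",
    "ProfileHistogram",
    "Genotype",
    "WgsCallStatus",
    "WgsCall",
    "profile_forward",
    "profile_pair",
    "aggregate_profiles",
    "call_genotype_miseq",
    "profile_reverse_wgs",
    "read_paired_fastq",
]

#: 9-mer anchoring the 5' end of the uninterrupted CAG tract.
ANCHOR = "CAGCAGCAG"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = frozenset("ACGT")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReadPair:
    """A read pair; ``mate`` is stored in antisense orientation."""

    id: str
    forward: str
    mate: str

    def __post_init__(self) -> None:
        if not self.forward or not self.mate:
            raise ValueError("read sequences must be nonempty")


def profile_forward(seq: str) -> Optional[RepeatStructure]:
    """Scan a sense-orientation read into a repeat structure.

    Profiling begins at the first CAGCAGCAG occurrence and consumes
    successive triplets in that frame until the next nine bases equal the
    CAGCTTCCT terminator (``terminator_found=True``) or the read ends
    (``terminator_found=False``).  Returns ``None`` when no anchor exists or
    a non-ACGT base falls inside the profiled window.
    """
    seq = seq.upper()
    start = seq.find(ANCHOR)
    if start < 0:
        return None
    codons: list[str] = []
    pos = start
    terminator_found = False
    n = len(seq)
    while True:
        if seq[pos : pos + 9] == TERMINATOR:
            terminator_found = True
            break
        if pos + 3 > n:
            break
        codon = seq[pos : pos + 3]
        if not _VALID.issuperset(codon):
            return None
        codons.append(codon)
        pos += 3
    if not codons:
        return None
    return RepeatStructure.from_runs(((c, 1) for c in codons), terminator_found)


def _profile_either_orientation(seq: str) -> Optional[RepeatStructure]:
    # Orientation auto-detection makes profiling invariant to which mate is
    # the sense read: an antisense read carries no CAGCAGCAG anchor frame of
    # the repeat, so at most one orientation yields a profile in practice.
    p = profile_forward(seq)
    if p is not None:
        return p
    return profile_forward(_revcomp(seq))


def profile_pair(pair: ReadPair) -> Optional[RepeatStructure]:
    """Profile both mates; retain only when their run lists match exactly."""
    fwd = _profile_either_orientation(pair.forward)
    rev = _profile_either_orientation(pair.mate)
    if fwd is None or rev is None:
        return None
    if fwd.runs != rev.runs:
        return None
    return RepeatStructure(
        fwd.runs, fwd.terminator_found and rev.terminator_found
    )


@dataclass
class ProfileHistogram:
    """Counts of retained structures plus discard bookkeeping."""

    counts: Counter = field(default_factory=Counter)  # RepeatStructure -> int
    total_pairs: int = 0
    discarded: int = 0

    def add(self, structure: Optional[RepeatStructure]) -> None:
        self.total_pairs += 1
        if structure is None:
            self.discarded += 1
        else:
            self.counts[structure] += 1

    def to_table(self) -> list[dict]:
        rows = [
            {
                "structure": format_structure(s),
                "terminator_found": s.terminator_found,
                "count": c,
            }
            for s, c in self.counts.most_common()
        ]
        return rows


def aggregate_profiles(pairs: Iterable[ReadPair]) -> ProfileHistogram:
    """Profile every pair and aggregate retained structures."""
    hist = ProfileHistogram()
    for pair in pairs:
        hist.add(profile_pair(pair))
    return hist


@dataclass(frozen=True)
class Genotype:
    """Two-allele call from a profile histogram."""

    alleles: tuple[AlleleCall, ...]
    homozygous: bool
    tie: bool = False
    incomplete: bool = False


def _cag_complete(s: RepeatStructure) -> bool:
    # A profile contributes a CAG length only if its leading CAG run is
    # known to have ended inside the read: either a later run follows it or
    # the terminator was reached.  An incomplete CAG run is only a lower
    # bound and would bias the length histogram toward truncations.
    return s.runs[0].codon == "CAG" and (len(s.runs) > 1 or s.terminator_found)


def call_genotype_miseq(hist: ProfileHistogram, min_support: int = 1) -> Genotype:
    """Call the two most frequent uninterrupted CAG lengths and attach, for
    each, the highest-count terminator-complete structure of that length."""
    cag_counts: Counter = Counter()
    for s, c in hist.counts.items():
        if _cag_complete(s):
            cag_counts[s.runs[0].count] += c
    cag_counts = Counter({L: c for L, c in cag_counts.items() if c >= min_support})
    if not cag_counts:
        raise ValueError("histogram contains no complete CAG profiles")

    # Deterministic tie-break: equal counts -> keep the longer CAG.
    ranked = sorted(cag_counts.items(), key=lambda kv: (-kv[1], -kv[0]))
    chosen = ranked[:2]
    tie = False
    if len(ranked) >= 2 and ranked[0][1] == ranked[1][1]:
        tie = True
    if len(ranked) >= 3 and ranked[1][1] == ranked[2][1]:
        tie = True

    alleles = []
    incomplete = False
    for length, _ in chosen:
        candidates = [
            (c, s)
            for s, c in hist.counts.items()
            if s.runs[0].codon == "CAG"
            and s.runs[0].count == length
            and s.terminator_found
        ]
        if not candidates:
            incomplete = True
            candidates = [
                (c, s)
                for s, c in hist.counts.items()
                if _cag_complete(s) and s.runs[0].count == length
            ]
        support, structure = max(
            candidates, key=lambda cs: (cs[0], format_structure(cs[1]))
        )
        alleles.append(
            AlleleCall(
                uninterrupted_cag=length,
                structure=structure,
                cls=classify_structure(structure),
                support=support,
            )
        )
    homozygous = len(alleles) == 1
    if homozygous:
        alleles = alleles * 2
    return Genotype(tuple(alleles), homozygous=homozygous, tie=tie, incomplete=incomplete)


class WgsCallStatus(enum.Enum):
    NO_CALL = "no_call"
    HOMOZYGOUS = "homozygous"
    HETEROZYGOUS = "heterozygous"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class WgsCall:
    """Adjacent-sequence genotype from the reverse (WGS) scanner."""

    status: WgsCallStatus
    sequences: tuple[str, ...]          # surviving complete sequences, count-ranked
    structures: tuple[RepeatStructure, ...]
    counts: dict
    filtered_out: dict


def _scan_reverse(seq: str) -> Optional[str]:
    """Extract the complete adjacent sequence from one read, if present."""
    seq = seq.upper()
    j = seq.find(TERMINATOR)
    if j < 0:
        seq = _revcomp(seq)
        j = seq.find(TERMINATOR)
        if j < 0:
            return None
    codons: list[str] = []
    pos = j - 3
    complete = False
    while pos >= 0:
        codon = seq[pos : pos + 3]
        if not _VALID.issuperset(codon):
            return None
        codons.insert(0, codon)
        if len(codons) >= 3 and codons[0] == codons[1] == codons[2] == "CAG":
            complete = True
            break
        pos -= 3
    if not complete:
        return None
    return "".join(codons) + TERMINATOR


def profile_reverse_wgs(
    reads: Iterable[str], completeness_filter: float = 0.14
) -> WgsCall:
    """Aggregate complete adjacent sequences from WGS reads and call a
    genotype after dropping sequences whose share is <= ``completeness_filter``
    of all aggregated complete reads."""
    counts: Counter = Counter()
    for read in reads:
        s = _scan_reverse(read)
        if s is not None:
            counts[s] += 1
    total = sum(counts.values())
    if total == 0:
        return WgsCall(WgsCallStatus.NO_CALL, (), (), {}, {})
    survivors = {s: c for s, c in counts.items() if c / total > completeness_filter}
    filtered = {s: c for s, c in counts.items() if s not in survivors}
    ranked = sorted(survivors.items(), key=lambda kv: (-kv[1], kv[0]))
    seqs = tuple(s for s, _ in ranked)
    structures = tuple(
        RepeatStructure.from_dna(s[: -len(TERMINATOR)], terminator_found=True)
        for s in seqs
    )
    if len(seqs) == 0:
        status = WgsCallStatus.NO_CALL
    elif len(seqs) == 1:
        status = WgsCallStatus.HOMOZYGOUS
    elif len(seqs) == 2:
        status = WgsCallStatus.HETEROZYGOUS
    else:
        status = WgsCallStatus.AMBIGUOUS
    return WgsCall(status, seqs, structures, dict(counts), filtered)


def read_paired_fastq(fastq1, fastq2) -> list[ReadPair]:
    """Load mate-paired FASTQ files into :class:`ReadPair` objects."""
    from Bio import SeqIO

    r1 = list(SeqIO.parse(fastq1, "fastq"))
    r2 = list(SeqIO.parse(fastq2, "fastq"))
    if len(r1) != len(r2):
        raise ValueError("paired FASTQ files have different read counts")
    return [
        ReadPair(a.id, str(a.seq), str(b.seq)) for a, b in zip(r1, r2)
    ]
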