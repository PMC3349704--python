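"""Core domain types shared across the package.

All genomic coordinates are 0-based half-open internally; conversion to and
from 1-based inclusive conventions (GFF3, report columns) happens only at
file boundaries. Sequences are stored in the DNA alphabet (U is normalized
to T on input); RNA output is produced on request at write time.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

VALID_STRANDS = ("+", "-")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA-alphabet sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


def to_rna(seq: str) -> str:
    return seq.replace("T", "U").replace("t", "u")


class SnoverifyError(Exception):
    """Base class for user-facing errors (CLI exit code 1)."""


class ParseError(SnoverifyError):
    pass


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    seq: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.seq.upper()) - set("ACGTN")
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains illegal characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    contig: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneModel:
    """A gene collapsed to a single exon chain (its longest transcript).

    Exons are stored in ascending genomic coordinates regardless of strand.
    """

    gene_id: str
    contig: str
    strand: str
    exons: list[GenomicInterval]

    def __post_init__(self):
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        prev_end = -1
        for e in self.exons:
            if e.contig != self.contig:
                raise ValueError(f"gene {self.gene_id}: exon on wrong contig")
            if e.start < prev_end:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
            prev_end = e.end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.contig, self.exons[0].start, self.exons[-1].end, self.strand
        )


@dataclass(frozen=True)
class FamilyProfile:
    """A snoRNA family anchored on the human reference gene.

    ``independent_promoter`` marks the handful of snoRNA genes transcribed
    from their own promoters (SNORD3, SNORD13, SNORD118, SCARNA2, SCARNA17)
    rather than processed from a host-gene intron.
    """

    family: str
    klass: str  # CD | HACA | scaRNA
    reference_seq: str
    target_rna_id: Optional[str] = None
    target_position: Optional[int] = None  # 1-based in the target RNA
    independent_promoter: bool = False

    def __post_init__(self):
        if self.klass not in ("CD", "HACA", "scaRNA"):
            raise ValueError(f"unknown snoRNA class {self.klass!r}")
        if self.target_position is not None and self.target_rna_id is None:
            raise ValueError(
                f"family {self.family}: target_position without target_rna_id"
            )


@dataclass
class LocationCall:
    status: str  # intronic | exonic_overlap | intergenic
    host_gene: Optional[str] = None
    intron_index: Optional[int] = None  # 0-based, in gene orientation
    same_strand: Optional[bool] = None

    def __post_init__(self):
        if self.status not in ("intronic", "exonic_overlap", "intergenic"):
            raise ValueError(f"unknown location status {self.status!r}")
        if (self.status == "intronic") != (
            self.host_gene is not None and self.intron_index is not None
        ):
            raise ValueError("host_gene/intron_index set iff status is intronic")
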