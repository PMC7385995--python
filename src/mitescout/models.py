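"""Core coordinate and sequence containers shared by every pipeline stage.

All coordinates held in memory are 0-based half-open intervals; conversion to
1-based inclusive (GFF3) or back happens only at format boundaries in
:mod:`mitescout.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["GenomeSequence", "GenomicInterval", "GeneModel"]

_VALID_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """A located span on a named sequence, 0-based half-open."""

    seqid: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.seqid:
            raise ValueError("seqid must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seqid == other.seqid
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.seqid != other.seqid:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class GenomeSequence:
    """One assembly sequence (chromosome, scaffold or contig)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be nonempty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        if any(c.isspace() for c in self.residues):
            raise ValueError(f"sequence {self.id!r} contains whitespace")
        self.residues = self.residues.upper()

    def __len__(self) -> int:
        return len(self.residues)

    def fetch(self, interval: GenomicInterval) -> str:
        if interval.seqid != self.id:
            raise ValueError(f"interval on {interval.seqid!r}, sequence is {self.id!r}")
        if interval.end > len(self.residues):
            raise ValueError("interval extends past end of sequence")
        return self.residues[interval.start : interval.end]


@dataclass
class GeneModel:
    """A gene span with its ordered exon structure.

    Exons are sorted, non-overlapping and contained in the span; a gene read
    without exon children is represented as a single exon equal to its span.
    """

    gene_id: str
    span: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.exons:
            self.exons = [self.span]
        self.exons = sorted(self.exons, key=lambda e: e.start)
        prev_end = None
        for exon in self.exons:
            if exon.seqid != self.span.seqid:
                raise ValueError(f"gene {self.gene_id}: exon on wrong seqid")
            if exon.start < self.span.start or exon.end > self.span.end:
                raise ValueError(f"gene {self.gene_id}: exon outside gene span")
            if prev_end is not None and exon.start < prev_end:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
            prev_end = exon.end

    @property
    def strand(self) -> str:
        return self.span.strand

    @property
    def tss(self) -> int:
        """Transcription start coordinate (strand-aware)."""
        return self.span.start if self.strand != "-" else self.span.end - 1

    @property
    def tts(self) -> int:
        """Transcription termination coordinate (strand-aware)."""
        return self.span.end - 1 if self.strand != "-" else self.span.start
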