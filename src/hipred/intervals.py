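"""Core genomic domain types.

All coordinates are 0-based half-open (BED convention) on named
chromosomes. GFF3 input is converted on read; nothing downstream ever sees
1-based closed intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class ValidationError(ValueError):
    """Raised when a record violates a domain invariant."""


@dataclass(frozen=True)
class GenomeInterval:
    """Half-open genomic interval [start, end) on a chromosome.

    Strand is "+", "-" or "." (unspecified); deletions are strandless,
    transcripts must carry an explicit strand.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chromosome must be non-empty")
        if self.start < 0:
            raise ValidationError(f"interval start {self.start} < 0")
        if self.end <= self.start:
            raise ValidationError(
                f"interval end {self.end} <= start {self.start}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomeInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class Transcript:
    """One transcript model: exon structure plus an optional CDS.

    ``exons`` are non-overlapping and sorted by start; every CDS segment
    lies within an exon. A transcript with an empty ``cds`` is non-coding.
    """

    id: str
    gene_id: str
    interval: GenomeInterval
    exons: list[GenomeInterval]
    cds: list[GenomeInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.interval.strand == ".":
            raise ValidationError(
                f"transcript {self.id}: explicit strand required"
            )
        if not self.exons:
            raise ValidationError(f"transcript {self.id}: no exons")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"transcript {self.id}: overlapping exons {a} and {b}"
                )
        self.cds = sorted(self.cds, key=lambda c: c.start)
        for c in self.cds:
            if not any(e.contains(c) for e in self.exons):
                raise ValidationError(
                    f"transcript {self.id}: CDS {c} outside exons"
                )
        if self.cds and self.cds_length == 0:
            raise ValidationError(f"transcript {self.id}: zero-length CDS")

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)

    @property
    def cds_length(self) -> int:
        return sum(len(c) for c in self.cds)

    @property
    def first_exon(self) -> GenomeInterval:
        """The 5'-most exon in transcription direction."""
        return self.exons[0] if self.strand == "+" else self.exons[-1]

    @property
    def tss(self) -> int:
        """Transcription start site.

        For "+" transcripts this is the interval start; for "-" the 5' end
        is the interval end (the TSS base itself is ``end - 1``).
        """
        return self.interval.start if self.strand == "+" else self.interval.end

    def introns(self) -> list[GenomeInterval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomeInterval(self.chrom, a.end, b.start, self.strand))
        return out

    def start_codon_positions(self) -> list[int]:
        """Genomic positions of the 3 5'-most CDS bases (strand-aware)."""
        bases: list[int] = []
        if self.strand == "+":
            for c in self.cds:
                for p in range(c.start, c.end):
                    bases.append(p)
                    if len(bases) == 3:
                        return bases
        else:
            for c in reversed(self.cds):
                for p in range(c.end - 1, c.start - 1, -1):
                    bases.append(p)
                    if len(bases) == 3:
                        return bases
        return bases


@dataclass
class GeneModelSet:
    """Map of gene_id -> transcripts, the substrate of LOF calling."""

    genes: dict[str, list[Transcript]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gid, txs in self.genes.items():
            if not txs:
                raise ValidationError(f"gene {gid}: no transcripts")
            for tx in txs:
                if tx.gene_id != gid:
                    raise ValidationError(
                        f"transcript {tx.id} filed under {gid} but "
                        f"claims gene {tx.gene_id}"
                    )

    def add(self, tx: Transcript) -> None:
        self.genes.setdefault(tx.gene_id, []).append(tx)

    def transcripts(self):
        for txs in self.genes.values():
            yield from txs

    def coding_transcripts(self, gene_id: str) -> list[Transcript]:
        return [t for t in self.genes[gene_id] if t.is_coding]

    def gene_interval(self, gene_id: str) -> GenomeInterval:
        txs = self.genes[gene_id]
        return GenomeInterval(
            txs[0].chrom,
            min(t.interval.start for t in txs),
            max(t.interval.end for t in txs),
            txs[0].strand,
        )

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class CNVCall:
    """One deletion call in one individual."""

    sample_id: str
    interval: GenomeInterval
    type: str = "deletion"

    def __post_init__(self) -> None:
        if self.type != "deletion":
            raise ValidationError("only deletion CNVs are modeled")
        if not self.sample_id:
            raise ValidationError("CNV sample_id must be non-empty")
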