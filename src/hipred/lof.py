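"""Loss-of-function calling for deletion CNVs.

A deletion disrupts a coding transcript if it (in this fixed order):

1. removes strictly more than half of the coding sequence,
2. removes any base of the start codon (the 3 5'-most CDS bases),
3. fully contains the 5'-most exon,
4. overlaps a splice signal (the 2 intronic bp flanking any exon), or
5. partially overlaps the CDS removing a number of bases not divisible
   by 3 (frameshift).

A gene is loss-of-function in an individual when every coding transcript
carries at least one disrupting deletion from that individual. Genes
recurrently rendered LOF in at least ``min_individuals`` apparently healthy
individuals form the haplosufficient (HS) catalog used as negative training
data for the haploinsufficiency classifier.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from .intervals import CNVCall, GenomeInterval, GeneModelSet, Transcript

CRITERIA = (
    "over_half_cds",
    "start_codon",
    "first_exon",
    "splice_signal",
    "frameshift",
)


@dataclass(frozen=True)
class LofCall:
    """Verdict for one (transcript, deletion, sample) triple."""

    transcript_id: str
    sample_id: str
    is_lof: bool
    criterion: str  # one of CRITERIA or "none"

    def __post_init__(self) -> None:
        if self.is_lof != (self.criterion != "none"):
            raise ValueError("is_lof must be true iff a criterion fired")


def transcript_lof(
    transcript: Transcript,
    deletion: GenomeInterval,
    sample_id: str = "",
) -> LofCall:
    """Evaluate the five LOF criteria for one deletion against one transcript.

    Criteria are evaluated in the fixed order above and the first satisfied
    one is reported. The transcript must be coding; a deletion on another
    chromosome is trivially not LOF.
    """
    if not transcript.is_coding:
        raise ValueError(
            f"transcript {transcript.id} is non-coding; filter before calling"
        )
    if deletion.chrom != transcript.chrom:
        return LofCall(transcript.id, sample_id, False, "none")

    cds_total = transcript.cds_length
    cds_deleted = sum(deletion.overlap_bp(c) for c in transcript.cds)

    # 1. over half of the coding sequence (strictly more than 50%)
    if cds_deleted * 2 > cds_total:
        return LofCall(transcript.id, sample_id, True, "over_half_cds")

    # 2. start codon: any of the 3 5'-most CDS bases removed
    for pos in transcript.start_codon_positions():
        if deletion.start <= pos < deletion.end:
            return LofCall(transcript.id, sample_id, True, "start_codon")

    # 3. first (5'-most) exon fully contained in the deletion
    if deletion.contains(transcript.first_exon):
        return LofCall(transcript.id, sample_id, True, "first_exon")

    # 4. splice signal: 2 intronic bp on each side of every intron
    for intron in transcript.introns():
        donor = GenomeInterval(
            intron.chrom, intron.start, min(intron.start + 2, intron.end)
        )
        acceptor = GenomeInterval(
            intron.chrom, max(intron.end - 2, intron.start), intron.end
        )
        if any(deletion.overlaps(w) for w in (donor, acceptor)):
            return LofCall(transcript.id, sample_id, True, "splice_signal")

    # 5. frameshift: partial CDS overlap with non-multiple-of-3 loss
    if 0 < cds_deleted < cds_total and cds_deleted % 3 != 0:
        return LofCall(transcript.id, sample_id, True, "frameshift")

    return LofCall(transcript.id, sample_id, False, "none")


def gene_lof_in_individual(
    gene_transcripts: list[Transcript],
    deletions: list[GenomeInterval],
) -> bool:
    """True iff every coding transcript is disrupted by >=1 of the deletions.

    The deletions are one individual's; different transcripts may be hit by
    different deletions. Non-coding transcripts of a coding gene are
    ignored.
    """
    coding = [t for t in gene_transcripts if t.is_coding]
    if not coding:
        raise ValueError("gene has no coding transcript")
    for tx in coding:
        if not any(transcript_lof(tx, d).is_lof for d in deletions):
            return False
    return True


@dataclass
class HSCatalog:
    """Recurrence-filtered haplosufficient gene catalog.

    ``genes`` maps gene_id -> number of distinct individuals in which the
    gene is LOF; only genes with count >= ``min_individuals`` are listed.
    ``putative`` is the >=1-individual set. ``criterion_tally`` counts LOF
    events (one transcript in one individual) per criterion.
    """

    genes: dict[str, int]
    putative: dict[str, int]
    min_individuals: int
    criterion_tally: dict[str, int] = field(default_factory=dict)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def __len__(self) -> int:
        return len(self.genes)


def build_hs_catalog(
    cnvs: list[CNVCall],
    gene_models: GeneModelSet,
    min_individuals: int = 2,
) -> HSCatalog:
    """Build the HS catalog from deletion calls and gene models.

    A gene enters the catalog when its gene-level LOF (all coding
    transcripts disrupted) holds in at least ``min_individuals`` distinct
    samples. Counting is over distinct individuals, not deletion events.
    """
    if min_individuals < 1:
        raise ValueError("min_individuals must be >= 1")

    dels_by_sample: dict[str, list[GenomeInterval]] = defaultdict(list)
    for c in cnvs:
        dels_by_sample[c.sample_id].append(c.interval)

    lof_individuals: dict[str, set[str]] = defaultdict(set)
    tally: dict[str, int] = {c: 0 for c in CRITERIA}
    for gid, txs in gene_models.genes.items():
        coding = [t for t in txs if t.is_coding]
        if not coding:
            continue
        # cheap bounding-interval prefilter per sample
        span = gene_models.gene_interval(gid)
        for sample, dels in dels_by_sample.items():
            near = [d for d in dels if d.overlaps(span)]
            if not near:
                continue
            all_hit = True
            calls = []
            for tx in coding:
                tx_calls = [transcript_lof(tx, d, sample) for d in near]
                hit = [c for c in tx_calls if c.is_lof]
                if not hit:
                    all_hit = False
                    break
                calls.extend(hit)
            if all_hit:
                lof_individuals[gid].add(sample)
                seen = set()
                for c in calls:
                    # one LOF event per (transcript, individual)
                    if c.transcript_id not in seen:
                        tally[c.criterion] += 1
                        seen.add(c.transcript_id)

    putative = {g: len(s) for g, s in lof_individuals.items()}
    catalog = {g: n for g, n in putative.items() if n >= min_individuals}
    return HSCatalog(
        genes=catalog,
        putative=putative,
        min_individuals=min_individuals,
        criterion_tally=tally,
    )
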