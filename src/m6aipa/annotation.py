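"""Gene/transcript/exon annotation model, derived introns, and polyA sites."""

from __future__ import annotations

from dataclasses import dataclass, field

from .intervals import GenomicInterval


@dataclass(frozen=True)
class PolyASite:
    """A single-base cleavage/polyadenylation position."""

    chrom: str
    pos: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("polyA site requires an explicit strand")


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)

    def validate(self) -> None:
        """Exons must be sorted, non-overlapping, and on one chrom/strand."""
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        self.exons.sort(key=lambda e: e.start)
        prev = None
        for exon in self.exons:
            if exon.chrom != self.chrom:
                raise ValueError(
                    f"transcript {self.transcript_id}: exon on {exon.chrom}, "
                    f"transcript on {self.chrom}"
                )
            if prev is not None and exon.start < prev.end:
                raise ValueError(
                    f"transcript {self.transcript_id} has overlapping exons "
                    f"[{prev.start},{prev.end}) and [{exon.start},{exon.end})"
                )
            prev = exon


@dataclass(frozen=True)
class Intron:
    """A derived intron, linked to its host transcript."""

    interval: GenomicInterval
    transcript_id: str
    gene_id: str
    index: int  # 0-based, in genomic coordinate order


@dataclass
class GeneAnnotation:
    """Genes -> transcripts -> ordered exons, plus a polyA feature track."""

    transcripts: dict[str, Transcript] = field(default_factory=dict)
    polya_sites: list[PolyASite] = field(default_factory=list)

    def add_transcript(self, tx: Transcript) -> None:
        self.transcripts[tx.transcript_id] = tx

    def validate(self) -> None:
        for tx in self.transcripts.values():
            tx.validate()

    def all_exons(self) -> list[tuple[str, GenomicInterval]]:
        """All exons as ``(transcript_id, interval)`` in genomic order."""
        out = [
            (tx.transcript_id, exon)
            for tx in self.transcripts.values()
            for exon in tx.exons
        ]
        out.sort(key=lambda t: (t[1].chrom, t[1].start, t[1].end))
        return out


def derive_introns(annotation: GeneAnnotation) -> list[Intron]:
    """Gaps between consecutive exons of each transcript.

    A transcript with ``k`` exons yields exactly ``k - 1`` introns; strand is
    inherited from the transcript.  Transcripts with overlapping exons are
    rejected by validation.
    """
    annotation.validate()
    introns: list[Intron] = []
    for tx in annotation.transcripts.values():
        for i in range(len(tx.exons) - 1):
            left, right = tx.exons[i], tx.exons[i + 1]
            if right.start == left.end:  # abutting exons: no gap
                continue
            introns.append(
                Intron(
                    interval=GenomicInterval(tx.chrom, left.end, right.start, tx.strand),
                    transcript_id=tx.transcript_id,
                    gene_id=tx.gene_id,
                    index=i,
                )
            )
    introns.sort(key=lambda it: (it.interval.chrom, it.interval.start, it.transcript_id))
    return introns
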