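"""Discovery of ZFC3H1-regulated intronic-polyadenylation (IPA) regions.

An intron is called as producing an IPA transcript when, in the knockdown
(shZFC3H1) coverage, read density is enriched over the 5' fifth of the
intron relative to the 3' fifth, the intron gains reads relative to
shControl, and an annotated polyA site lies in its interior.  The IPA region
then runs from the intron's 5' splice site to the most 5'-proximal contained
polyA site.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

from intervaltree import IntervalTree

from .annotation import GeneAnnotation, Intron, PolyASite, derive_introns
from .coverage import CoverageTrack
from .intervals import GenomicInterval
from .simulate import ipa_region_from_polya

logger = logging.getLogger(__name__)

MIN_INTRON_LENGTH = 10  # below this the 20% windows collapse


@dataclass
class IpaParams:
    """Selection thresholds.

    ``min_enrichment`` is the strict lower bound on the 5'/3' window ratio;
    ``pseudocount`` is added to both window sums; ``libsize_normalize``
    compares per-million-scaled instead of raw depth sums between conditions;
    ``strict_same_strand`` additionally drops introns overlapping same-strand
    exons of other isoforms.
    """

    min_enrichment: float = 1.0
    pseudocount: float = 1.0
    libsize_normalize: bool = False
    strict_same_strand: bool = False


@dataclass
class IpaRegion:
    """A selected IPA region with its selection diagnostics."""

    interval: GenomicInterval
    transcript_id: str
    gene_id: str
    intron: GenomicInterval
    polya_pos: int
    enrichment_ratio: float
    reads_shZFC: float
    reads_shCtrl: float

    @property
    def region_id(self) -> str:
        return f"{self.transcript_id}_intron{self.intron.start}"


def compile_clean_introns(
    annotation: GeneAnnotation, strict_same_strand: bool = False
) -> list[Intron]:
    """Introns with zero base overlap with any exon on the opposite strand.

    Same-strand exon overlap (other isoforms) does not exclude an intron
    unless ``strict_same_strand`` is set.  Abutting features (shared
    boundary, half-open coordinates) do not count as overlapping.
    """
    introns = derive_introns(annotation)
    trees: dict[tuple[str, str], IntervalTree] = {}
    for _tx_id, exon in annotation.all_exons():
        trees.setdefault((exon.chrom, exon.strand), IntervalTree()).addi(
            exon.start, exon.end
        )
    clean: list[Intron] = []
    for intron in introns:
        iv = intron.interval
        opposite = "-" if iv.strand == "+" else "+"
        tree = trees.get((iv.chrom, opposite))
        if tree is not None and tree.overlap(iv.start, iv.end):
            continue
        if strict_same_strand:
            same = trees.get((iv.chrom, iv.strand))
            if same is not None and same.overlap(iv.start, iv.end):
                continue
        clean.append(intron)
    return clean


def intronic_enrichment(
    intron: GenomicInterval, track: CoverageTrack, pseudocount: float = 1.0
) -> float:
    """5'-window over 3'-window depth ratio of an intron.

    Both windows span ``floor(0.2 x length)`` bases (minimum 1); "first" is
    the 5' end of the intron on its own strand.  ``pseudocount`` is added to
    both sums.
    """
    strand = intron.require_strand()
    if intron.length < MIN_INTRON_LENGTH:
        raise ValueError(
            f"intron {intron.chrom}:{intron.start}-{intron.end} shorter than "
            f"{MIN_INTRON_LENGTH} bases"
        )
    w = max(1, math.floor(0.2 * intron.length))
    left = GenomicInterval(intron.chrom, intron.start, intron.start + w, strand)
    right = GenomicInterval(intron.chrom, intron.end - w, intron.end, strand)
    five, three = (left, right) if strand == "+" else (right, left)
    return (track.depth_sum(five) + pseudocount) / (track.depth_sum(three) + pseudocount)


def select_ipa_regions(
    introns: Sequence[Intron],
    shzfc: CoverageTrack,
    shctrl: CoverageTrack,
    polya_sites: Sequence[PolyASite],
    params: IpaParams | None = None,
) -> list[IpaRegion]:
    """Apply the three selection criteria and build IPA regions.

    An intron qualifies iff (i) its 5'/3' enrichment ratio in shZFC3H1
    exceeds ``min_enrichment``, (ii) its total shZFC3H1 depth strictly
    exceeds shControl (optionally per-million normalized), and (iii) it
    contains at least one same-strand polyA site.  The region's 3' end is the
    most 5'-proximal contained polyA site.
    """
    params = params or IpaParams()
    zfc_scale = ctrl_scale = 1.0
    if params.libsize_normalize:
        zfc_scale = 1e6 / max(shzfc.library_size, 1.0)
        ctrl_scale = 1e6 / max(shctrl.library_size, 1.0)

    pa_by_key: dict[tuple[str, str], list[int]] = {}
    for site in polya_sites:
        pa_by_key.setdefault((site.chrom, site.strand), []).append(site.pos)
    for positions in pa_by_key.values():
        positions.sort()

    selected: list[IpaRegion] = []
    n_short = n_no_polya = 0
    for intron in introns:
        iv = intron.interval
        if iv.length < MIN_INTRON_LENGTH:
            n_short += 1
            continue
        enrichment = intronic_enrichment(iv, shzfc, params.pseudocount)
        if not enrichment > params.min_enrichment:
            continue
        reads_zfc = shzfc.depth_sum(iv) * zfc_scale
        reads_ctrl = shctrl.depth_sum(iv) * ctrl_scale
        if not reads_zfc > reads_ctrl:
            continue
        contained = [
            p for p in pa_by_key.get((iv.chrom, iv.strand), []) if iv.start <= p < iv.end
        ]
        if not contained:
            n_no_polya += 1
            continue
        polya_pos = min(contained) if iv.strand == "+" else max(contained)
        region = ipa_region_from_polya(iv, polya_pos)
        selected.append(
            IpaRegion(
                interval=region,
                transcript_id=intron.transcript_id,
                gene_id=intron.gene_id,
                intron=iv,
                polya_pos=polya_pos,
                enrichment_ratio=enrichment,
                reads_shZFC=reads_zfc,
                reads_shCtrl=reads_ctrl,
            )
        )
    if n_short:
        logger.info("skipped %d introns shorter than %d bases", n_short, MIN_INTRON_LENGTH)
    if n_no_polya:
        logger.info(
            "%d introns passed coverage criteria but contain no polyA site", n_no_polya
        )
    return selected
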