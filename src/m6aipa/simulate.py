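"""Synthetic genome, annotation, coverage, and miCLIP truncation tracks.

The generator emulates the statistical structure of the study system: a
two-condition knockdown RNA-seq pair (``shControl`` vs ``shZFC3H1``) in which
depletion of the PAXT scaffold stabilises intronic-polyadenylated (IPA)
transcripts — visible as 5'-biased intronic coverage that rises under the
knockdown — plus an expression-reference track and two miCLIP replicates
whose reverse-transcription truncation counts pile up at planted
DRACH-anchored m6A sites over a uniform background.

Planted m6A sites are written into the genome sequence as DRACH 5-mers, so
ground-truth coordinates are exact and downstream recovery is measurable.
All randomness flows from ``SimConfig.seed``; a fixed seed gives
byte-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import yaml

from .annotation import GeneAnnotation, PolyASite, Transcript
from .coverage import CoverageTrack
from .intervals import GenomicInterval

_BASES = np.array(["A", "C", "G", "T"])
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: DRACH alphabet: D = A/G/T, R = A/G, then A, C, H = A/C/T (T stands for U).
DRACH_D = "AGT"
DRACH_R = "AG"
DRACH_H = "ACT"


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


@dataclass
class SimConfig:
    """All knobs of the synthetic dataset.

    Lengths are in bases, rates in expected events; ``m6a_rate_*`` are planted
    sites per kilobase of feature, ``truncation_*_rate`` are expected miCLIP
    truncation counts per base at a site / elsewhere, before scaling by local
    expression relative to the midpoint of ``expression_range``.
    """

    seed: int
    chrom_name: str = "chrSim"
    chrom_length: int = 2_000_000
    n_genes: int = 200
    exons_per_gene: tuple[int, int] = (2, 5)
    exon_length: tuple[int, int] = (100, 1500)
    intron_length: tuple[int, int] = (500, 2000)
    intergenic_gap: tuple[int, int] = (200, 800)
    fraction_ipa_introns: float = 0.3
    intron_background_frac: float = 0.05
    ipa_coverage_bias: float = 20.0
    zfc_up_factor: float = 3.0
    expression_range: tuple[float, float] = (5.0, 50.0)
    m6a_rate_ipa: float = 6.0
    m6a_rate_exon: float = 2.0
    truncation_signal_rate: float = 50.0
    truncation_background_rate: float = 2.5
    n_replicates: int = 2
    noiseless: bool = False
    polya_interior: tuple[float, float] = (0.2, 0.8)
    ipa_end_bias: float = 0.0
    exon_end_depletion: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction_ipa_introns <= 1.0):
            raise ValueError("fraction_ipa_introns must be in [0, 1]")
        for name in ("m6a_rate_ipa", "m6a_rate_exon", "truncation_signal_rate",
                     "truncation_background_rate", "intron_background_frac"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.ipa_coverage_bias <= 1:
            raise ValueError("ipa_coverage_bias must be > 1")
        if self.zfc_up_factor <= 0:
            raise ValueError("zfc_up_factor must be > 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        lo, hi = self.polya_interior
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("polya_interior must satisfy 0 < lo < hi < 1")

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        for key, val in data.items():
            if isinstance(val, tuple):
                data[key] = list(val)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "seed" not in data:
            raise ValueError("config must set a seed")
        for key, val in list(data.items()):
            if isinstance(val, list):
                data[key] = tuple(val)
        return cls(**data)


def small_config(seed: int, **overrides) -> SimConfig:
    """A reduced configuration (~0.4 Mb, 40 genes) for repeated simulations."""
    cfg = SimConfig(seed=seed, chrom_length=400_000, n_genes=40)
    return replace(cfg, **overrides) if overrides else cfg


@dataclass(frozen=True)
class TrueIpa:
    """A planted IPA intron: the intron, its polyA site, and the IPA region
    (intron 5' boundary to the polyA base, inclusive of that base)."""

    transcript_id: str
    gene_id: str
    intron: GenomicInterval
    polya_pos: int
    region: GenomicInterval


@dataclass(frozen=True)
class TrueSite:
    """A planted m6A site: genomic coordinate of the methylated A."""

    chrom: str
    pos: int
    strand: str
    feature_kind: str  # "ipa" or "exon"
    feature_id: str


@dataclass
class GroundTruth:
    """Oracle for recovery tests: planted IPA regions, m6A sites, and the
    per-gene expression levels shared by all simulated tracks."""

    ipa_regions: list[TrueIpa] = field(default_factory=list)
    sites: list[TrueSite] = field(default_factory=list)
    gene_levels: dict[str, float] = field(default_factory=dict)

    def ipa_intron_keys(self) -> set[tuple[str, int, int]]:
        return {(t.intron.chrom, t.intron.start, t.intron.end) for t in self.ipa_regions}


def ipa_region_from_polya(intron: GenomicInterval, polya_pos: int) -> GenomicInterval:
    """IPA region: from the intron's 5' boundary to the polyA base inclusive."""
    strand = intron.require_strand()
    if not intron.contains(intron.chrom, polya_pos):
        raise ValueError("polyA position lies outside the intron")
    if strand == "+":
        return GenomicInterval(intron.chrom, intron.start, polya_pos + 1, "+")
    return GenomicInterval(intron.chrom, polya_pos, intron.end, "-")


def _plant_in_feature(
    rng: np.random.Generator,
    feature: GenomicInterval,
    rate_per_kb: float,
    blocked: set[int],
    end_bias: float = 0.0,
    end_depletion: float = 0.0,
    margin: int = 2,
    min_spacing: int = 5,
) -> list[int]:
    """Sample planted-site positions inside one feature.

    ``end_bias`` routes that fraction of sites into the outer 10% of the
    feature; ``end_depletion`` excludes that fraction at each end.  Positions
    keep ``min_spacing`` bases apart so the written 5-mers never overlap.
    """
    length = feature.length
    lo = feature.start + margin
    hi = feature.end - margin - 1  # inclusive
    if end_depletion > 0:
        lo = max(lo, feature.start + int(np.ceil(end_depletion * length)))
        hi = min(hi, feature.start + int(np.floor((1 - end_depletion) * length)) - 1)
    if hi < lo:
        return []
    n = rng.poisson(rate_per_kb * length / 1000.0)
    out: list[int] = []
    edge = max(1, int(0.1 * length))
    for _ in range(n):
        for _attempt in range(60):
            if end_bias > 0 and rng.random() < end_bias:
                if rng.random() < 0.5:
                    pos = int(rng.integers(lo, min(hi, feature.start + edge) + 1))
                else:
                    pos = int(rng.integers(max(lo, feature.end - edge), hi + 1))
            else:
                pos = int(rng.integers(lo, hi + 1))
            if pos not in blocked:
                out.append(pos)
                blocked.update(range(pos - min_spacing + 1, pos + min_spacing))
                break
    return out


def _random_drach(rng: np.random.Generator) -> str:
    d = DRACH_D[rng.integers(len(DRACH_D))]
    r = DRACH_R[rng.integers(len(DRACH_R))]
    h = DRACH_H[rng.integers(len(DRACH_H))]
    return f"{d}{r}AC{h}"


def simulate_genome(config: SimConfig) -> tuple[dict[str, str], GeneAnnotation, GroundTruth]:
    """Lay out genes on one chromosome and plant IPA polyA sites and m6A sites.

    Returns the genome (``{chrom: sequence}``), the annotation (exons plus the
    polyA feature track), and the :class:`GroundTruth` oracle.
    """
    rng = np.random.default_rng([config.seed, 0])
    seq = _BASES[rng.integers(0, 4, config.chrom_length)]
    chrom = config.chrom_name

    annotation = GeneAnnotation()
    truth = GroundTruth()
    blocked: set[int] = set()

    cursor = int(rng.integers(*config.intergenic_gap))
    for gi in range(config.n_genes):
        gene_id = f"gene{gi:04d}"
        tx_id = f"tx{gi:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exon_lens = rng.integers(config.exon_length[0], config.exon_length[1] + 1, n_exons)
        intron_lens = rng.integers(config.intron_length[0], config.intron_length[1] + 1,
                                   max(0, n_exons - 1))
        gene_span = int(exon_lens.sum() + intron_lens.sum())
        if cursor + gene_span > config.chrom_length:
            raise ValueError(
                f"gene {gene_id} does not fit: need {cursor + gene_span} bases, "
                f"chromosome has {config.chrom_length}; shrink gene sizes or count"
            )
        exons: list[GenomicInterval] = []
        introns: list[GenomicInterval] = []
        pos = cursor
        for ei in range(n_exons):
            exons.append(GenomicInterval(chrom, pos, pos + int(exon_lens[ei]), strand))
            pos += int(exon_lens[ei])
            if ei < n_exons - 1:
                introns.append(GenomicInterval(chrom, pos, pos + int(intron_lens[ei]), strand))
                pos += int(intron_lens[ei])
        annotation.add_transcript(Transcript(tx_id, gene_id, chrom, strand, exons))
        truth.gene_levels[gene_id] = float(rng.uniform(*config.expression_range))

        # plant intronic polyA sites (IPA introns) in the interior window
        for intron in introns:
            if rng.random() >= config.fraction_ipa_introns:
                continue
            u = rng.uniform(*config.polya_interior)
            polya_pos = intron.start + int(u * intron.length)
            polya_pos = min(max(polya_pos, intron.start + 1), intron.end - 2)
            region = ipa_region_from_polya(intron, polya_pos)
            annotation.polya_sites.append(PolyASite(chrom, polya_pos, strand))
            truth.ipa_regions.append(TrueIpa(tx_id, gene_id, intron, polya_pos, region))

        # plant m6A sites: exons at the exon rate, IPA regions at the IPA rate
        for ei, exon in enumerate(exons):
            for p in _plant_in_feature(rng, exon, config.m6a_rate_exon, blocked,
                                       end_depletion=config.exon_end_depletion):
                truth.sites.append(TrueSite(chrom, p, strand, "exon", f"{tx_id}_exon{ei}"))

        cursor = pos + int(rng.integers(*config.intergenic_gap))

    for k, tipa in enumerate(truth.ipa_regions):
        for p in _plant_in_feature(rng, tipa.region, config.m6a_rate_ipa, blocked,
                                   end_bias=config.ipa_end_bias):
            truth.sites.append(TrueSite(chrom, p, tipa.region.strand, "ipa", f"ipa{k:04d}"))

    # write each planted site's DRACH 5-mer into the sequence, A at the site
    for site in truth.sites:
        motif = _random_drach(rng)
        written = motif if site.strand == "+" else revcomp(motif)
        seq[site.pos - 2 : site.pos + 3] = list(written)

    annotation.validate()
    genome = {chrom: "".join(seq)}
    return genome, annotation, truth


def _expected_expression(
    annotation: GeneAnnotation, truth: GroundTruth, config: SimConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Expected per-base depth under shControl, and the shZFC3H1 multiplier."""
    base = np.zeros(config.chrom_length)
    zfc_mult = np.ones(config.chrom_length)
    ipa_by_intron = {(t.intron.start, t.intron.end): t for t in truth.ipa_regions}
    for tx in annotation.transcripts.values():
        level = truth.gene_levels[tx.gene_id]
        for exon in tx.exons:
            base[exon.start : exon.end] = level
        bg = level * config.intron_background_frac
        for i in range(len(tx.exons) - 1):
            s, e = tx.exons[i].end, tx.exons[i + 1].start
            base[s:e] = bg
            tipa = ipa_by_intron.get((s, e))
            if tipa is not None:
                r = tipa.region
                base[r.start : r.end] = bg * config.ipa_coverage_bias
                zfc_mult[r.start : r.end] = config.zfc_up_factor
    return base, zfc_mult


def simulate_coverage(
    annotation: GeneAnnotation, truth: GroundTruth, config: SimConfig
) -> dict[str, CoverageTrack]:
    """Two-condition and expression-reference coverage tracks.

    Exons sit at the gene's expression level; non-IPA intron bases at a small
    background fraction of it; the 5' segment of an IPA intron (up to the
    polyA site) at background x ``ipa_coverage_bias``, further multiplied by
    ``zfc_up_factor`` in the shZFC3H1 condition.  Per-base Poisson noise
    unless ``noiseless``.
    """
    base, zfc_mult = _expected_expression(annotation, truth, config)
    chrom = config.chrom_name
    expectations = {
        "shControl": base,
        "shZFC3H1": base * zfc_mult,
        "expression_ref": base,
    }
    tracks: dict[str, CoverageTrack] = {}
    for i, (sample, exp) in enumerate(expectations.items()):
        track = CoverageTrack(sample)
        if config.noiseless:
            track.add_chrom(chrom, exp.copy())
        else:
            rng = np.random.default_rng([config.seed, 1, i])
            track.add_chrom(chrom, rng.poisson(exp).astype(float))
        tracks[sample] = track
    return tracks


def simulate_miclip(
    annotation: GeneAnnotation, truth: GroundTruth, config: SimConfig
) -> list[CoverageTrack]:
    """Per-replicate miCLIP truncation-count tracks.

    Counts are Poisson with expectation ``truncation_signal_rate`` at planted
    site positions and ``truncation_background_rate`` elsewhere, both scaled
    by expected local expression relative to the midpoint of
    ``expression_range`` (truncations can only come from transcribed RNA).
    """
    if config.truncation_signal_rate <= config.truncation_background_rate:
        warnings.warn(
            "truncation signal rate <= background rate: site recovery will degrade",
            stacklevel=2,
        )
    base, _ = _expected_expression(annotation, truth, config)
    ref = 0.5 * (config.expression_range[0] + config.expression_range[1])
    scale = base / ref
    rate = config.truncation_background_rate * scale
    for site in truth.sites:
        rate[site.pos] = config.truncation_signal_rate * scale[site.pos]
    chrom = config.chrom_name
    tracks = []
    for rep in range(config.n_replicates):
        track = CoverageTrack(f"miclip_rep{rep + 1}")
        if config.noiseless:
            track.add_chrom(chrom, rate.copy())
        else:
            rng = np.random.default_rng([config.seed, 2, rep])
            track.add_chrom(chrom, rng.poisson(rate).astype(float))
        tracks.append(track)
    return tracks
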