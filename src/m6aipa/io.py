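"""Readers and writers for FASTA, GTF, BED6, bedGraph, and TSV.

Coordinate conventions are converted exactly once, here: GTF is 1-based
inclusive on disk and 0-based half-open in memory; BED and bedGraph are
already 0-based half-open.  Every writer emits ``#`` header lines carrying
the tool version and the parameters used, and every reader skips ``#``,
``track`` and ``browser`` lines, so write -> read round-trips are lossless.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._version import __version__
from .annotation import GeneAnnotation, PolyASite, Transcript
from .coverage import CoverageTrack
from .intervals import GenomicInterval


class FileFormatError(ValueError):
    """Malformed line in a genomic text format."""

    def __init__(self, path: str | Path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


def _header_lines(params: Mapping[str, object] | None) -> list[str]:
    lines = [f"# m6aipa v{__version__}"]
    for key, val in (params or {}).items():
        lines.append(f"# {key}={val}")
    return lines


def _is_meta(line: str) -> bool:
    s = line.strip()
    return not s or s.startswith("#") or s.startswith("track") or s.startswith("browser")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Genome as a ``{chrom: sequence}`` dict of uppercase strings."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, genome: Mapping[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GTF

_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def write_gtf(
    path: str | Path,
    annotation: GeneAnnotation,
    params: Mapping[str, object] | None = None,
    source: str = "m6aipa",
) -> None:
    """Write transcripts and exons as GTF (1-based inclusive on disk)."""
    lines = _header_lines(params)
    txs = sorted(
        annotation.transcripts.values(),
        key=lambda t: (t.chrom, t.exons[0].start if t.exons else 0, t.transcript_id),
    )
    for tx in txs:
        attrs = f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
        tx_start = min(e.start for e in tx.exons)
        tx_end = max(e.end for e in tx.exons)
        lines.append(
            "\t".join(
                [tx.chrom, source, "transcript", str(tx_start + 1), str(tx_end),
                 ".", tx.strand, ".", attrs]
            )
        )
        for exon in tx.exons:
            lines.append(
                "\t".join(
                    [tx.chrom, source, "exon", str(exon.start + 1), str(exon.end),
                     ".", tx.strand, ".", attrs]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gtf(path: str | Path) -> GeneAnnotation:
    """Parse exon features from a GTF file into a :class:`GeneAnnotation`."""
    ann = GeneAnnotation()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _is_meta(line):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise FileFormatError(path, lineno, f"expected 9 GTF fields, got {len(fields)}")
            chrom, _source, feature, start, end, _score, strand, _frame, attr_str = fields
            if feature != "exon":
                continue
            attrs = dict(_GTF_ATTR.findall(attr_str))
            try:
                gene_id = attrs["gene_id"]
                tx_id = attrs["transcript_id"]
            except KeyError as exc:
                raise FileFormatError(path, lineno, f"missing attribute {exc}") from exc
            try:
                iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)
            except ValueError as exc:
                raise FileFormatError(path, lineno, str(exc)) from exc
            if tx_id not in ann.transcripts:
                ann.add_transcript(Transcript(tx_id, gene_id, chrom, strand))
            ann.transcripts[tx_id].exons.append(iv)
    ann.validate()
    return ann


# ---------------------------------------------------------------------------
# BED6

@dataclass(frozen=True)
class Bed6Record:
    chrom: str
    start: int
    end: int
    name: str = "."
    score: str = "."
    strand: str = "."

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)


def write_bed6(
    path: str | Path,
    records: Iterable[Bed6Record],
    params: Mapping[str, object] | None = None,
) -> None:
    lines = _header_lines(params)
    for rec in records:
        lines.append(
            f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.name}\t{rec.score}\t{rec.strand}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_bed6(path: str | Path) -> list[Bed6Record]:
    out: list[Bed6Record] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _is_meta(line):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FileFormatError(path, lineno, "expected >= 3 BED fields")
            fields = fields + ["."] * (6 - len(fields))
            try:
                out.append(
                    Bed6Record(
                        fields[0], int(fields[1]), int(fields[2]),
                        fields[3], fields[4], fields[5],
                    )
                )
            except ValueError as exc:
                raise FileFormatError(path, lineno, str(exc)) from exc
    return out


def polya_to_bed(sites: Sequence[PolyASite]) -> list[Bed6Record]:
    return [
        Bed6Record(s.chrom, s.pos, s.pos + 1, f"polyA_{i}", ".", s.strand)
        for i, s in enumerate(sites)
    ]


def bed_to_polya(records: Iterable[Bed6Record]) -> list[PolyASite]:
    sites = []
    for rec in records:
        if rec.end != rec.start + 1:
            raise ValueError(f"polyA BED record {rec.name} is not single-base")
        sites.append(PolyASite(rec.chrom, rec.start, rec.strand))
    return sites


# ---------------------------------------------------------------------------
# bedGraph

def write_bedgraph(
    path: str | Path,
    track: CoverageTrack,
    params: Mapping[str, object] | None = None,
) -> None:
    """Run-length encode a dense track; zero-depth runs are omitted."""
    lines = _header_lines(params)
    lines.append(f'track type=bedGraph name="{track.sample}"')
    for chrom in sorted(track.depth):
        arr = track.depth[chrom]
        if arr.size == 0:
            continue
        # boundaries of constant-value runs
        change = np.flatnonzero(np.diff(arr)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [arr.size]])
        for s, e in zip(starts, ends):
            val = arr[s]
            if val == 0:
                continue
            sval = format(val, ".6g")
            lines.append(f"{chrom}\t{s}\t{e}\t{sval}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_bedgraph(
    path: str | Path,
    sample: str | None = None,
    chrom_sizes: Mapping[str, int] | None = None,
) -> CoverageTrack:
    """Expand a bedGraph into dense per-chromosome depth arrays.

    Without ``chrom_sizes`` each chromosome array extends to the last covered
    base; pass sizes (or call :func:`pad_track`) when downstream features can
    lie beyond that.
    """
    spans: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _is_meta(line):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 4:
                raise FileFormatError(path, lineno, f"expected 4 bedGraph fields, got {len(fields)}")
            try:
                chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise FileFormatError(path, lineno, str(exc)) from exc
            if value < 0:
                raise FileFormatError(path, lineno, f"negative depth {value}")
            spans.setdefault(chrom, []).append((start, end, value))
    track = CoverageTrack(sample or Path(path).stem)
    sizes = dict(chrom_sizes or {})
    chroms = set(spans) | set(sizes)
    for chrom in chroms:
        chrom_spans = spans.get(chrom, [])
        size = sizes.get(chrom, max((e for _, e, _ in chrom_spans), default=0))
        arr = np.zeros(size)
        for s, e, v in chrom_spans:
            arr[s:e] = v
        track.add_chrom(chrom, arr)
    return track


def pad_track(track: CoverageTrack, chrom_sizes: Mapping[str, int]) -> CoverageTrack:
    """Zero-extend depth arrays so each chromosome reaches the given size."""
    for chrom, size in chrom_sizes.items():
        arr = track.depth.get(chrom, np.zeros(0))
        if arr.size < size:
            track.depth[chrom] = np.concatenate([arr, np.zeros(size - arr.size)])
    return track


# ---------------------------------------------------------------------------
# TSV

def write_tsv(
    path: str | Path,
    table: pd.DataFrame,
    params: Mapping[str, object] | None = None,
) -> None:
    header = "\n".join(_header_lines(params)) + "\n"
    with open(path, "w") as fh:
        fh.write(header)
        table.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
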