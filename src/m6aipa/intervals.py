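"""Strand-aware genomic intervals and interval arithmetic.

All coordinates in this package are 0-based, half-open ``[start, end)``.
Conversion to and from 1-based formats (GTF) happens only in :mod:`m6aipa.io`.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

STRANDS = ("+", "-")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic span ``[start, end)`` on one strand.

    ``strand`` may be ``"."`` (unknown) for features that do not need
    orientation; operations that depend on 5'/3' polarity reject it.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def require_strand(self) -> str:
        """Return the strand, rejecting strand-unaware features."""
        if self.strand not in STRANDS:
            raise ValueError(
                f"feature {self.chrom}:{self.start}-{self.end} has no strand; "
                "a stranded feature is required here"
            )
        return self.strand

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two spans share at least one base (strand ignored)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        """Half-open membership test for a single base."""
        return chrom == self.chrom and self.start <= pos < self.end


def merge_positions(
    positions: Mapping[tuple[str, str], Iterable[int]] | Sequence[tuple[str, int, str]],
    max_gap: int = 1,
) -> list[GenomicInterval]:
    """Cluster single-base positions into intervals.

    Two positions ``p < q`` on the same chromosome and strand belong to the
    same cluster iff they are linked by a chain of neighbours with at most
    ``max_gap`` unoccupied bases between consecutive members; the gap between
    ``p`` and ``q`` is ``q - p - 1``.  Each output interval spans
    ``[min, max + 1)`` of its members.

    Parameters
    ----------
    positions
        Either a mapping ``(chrom, strand) -> iterable of positions`` or a
        flat sequence of ``(chrom, pos, strand)`` tuples.
    max_gap
        Maximum number of unoccupied bases bridged within one cluster.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    grouped: dict[tuple[str, str], list[int]] = defaultdict(list)
    if isinstance(positions, Mapping):
        for key, vals in positions.items():
            grouped[key].extend(int(v) for v in vals)
    else:
        for chrom, pos, strand in positions:
            grouped[(chrom, strand)].append(int(pos))

    out: list[GenomicInterval] = []
    for (chrom, strand), vals in sorted(grouped.items()):
        if not vals:
            continue
        vals = sorted(set(vals))
        run_start = prev = vals[0]
        for p in vals[1:]:
            if p - prev - 1 > max_gap:
                out.append(GenomicInterval(chrom, run_start, prev + 1, strand))
                run_start = p
            prev = p
        out.append(GenomicInterval(chrom, run_start, prev + 1, strand))
    out.sort(key=lambda iv: (iv.chrom, iv.start, iv.end, iv.strand))
    return out
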