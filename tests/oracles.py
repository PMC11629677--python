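"""Independent brute-force oracles used by the test suite.

Everything here recomputes quantities by definition (per-base boolean
arrays, explicit enumeration, the step-up formula), deliberately sharing no
code with the implementation under test.
"""

from __future__ import annotations

import re

import numpy as np

DRACH_RE = re.compile(r"(?=([AGT][AG]AC[ACT]))")
_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def regex_drach(seq: str, strand: str = "+") -> list[tuple[int, str]]:
    """DRACH A-offsets on the forward axis, via regex with overlap lookahead."""
    scanned = seq.upper() if strand == "+" else rc(seq.upper())
    n = len(scanned)
    hits = []
    for m in DRACH_RE.finditer(scanned):
        a = m.start() + 2
        motif = m.group(1)
        if strand == "-":
            a = n - 1 - a
        hits.append((a, motif))
    if strand == "-":
        hits.reverse()
    return hits


def brute_bh(p: np.ndarray) -> np.ndarray:
    """Adjusted q-values straight from the step-up definition:
    for sorted p(1)<=...<=p(m), q(k) = min_{j>=k} m*p(j)/j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    for k in range(m):
        q_sorted[k] = min(
            min(m * p[order[j]] / (j + 1) for j in range(k, m)), 1.0
        )
    q = np.empty(m)
    q[order] = q_sorted
    return q


def brute_merge(positions: list[int], max_gap: int) -> list[tuple[int, int]]:
    """Cluster single-base positions by scanning a per-base occupancy array."""
    if not positions:
        return []
    positions = sorted(set(positions))
    lo, hi = positions[0], positions[-1]
    occupied = np.zeros(hi - lo + 1, dtype=bool)
    for p in positions:
        occupied[p - lo] = True
    clusters = []
    start = prev = positions[0]
    for p in positions[1:]:
        n_unoccupied = int((~occupied[prev - lo + 1 : p - lo]).sum())
        if n_unoccupied > max_gap:
            clusters.append((start, prev + 1))
            start = p
        prev = p
    clusters.append((start, prev + 1))
    return clusters


def brute_introns(exons: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Intron spans from a per-base exon membership array."""
    if len(exons) < 2:
        return []
    lo = min(s for s, _ in exons)
    hi = max(e for _, e in exons)
    member = np.zeros(hi - lo, dtype=bool)
    for s, e in exons:
        member[s - lo : e - lo] = True
    introns = []
    in_gap = False
    for i in range(member.size):
        if not member[i] and not in_gap:
            in_gap, gap_start = True, i + lo
        elif member[i] and in_gap:
            in_gap = False
            introns.append((gap_start, i + lo))
    return introns


def brute_overlaps_opposite(
    intron: tuple[int, int], opposite_exons: list[tuple[int, int]]
) -> bool:
    """Per-base check: does the intron share any base with an antisense exon?"""
    for base in range(intron[0], intron[1]):
        for s, e in opposite_exons:
            if s <= base < e:
                return True
    return False


def brute_count_sites(
    feature: tuple[str, int, int, str], sites: list[tuple[str, int, str]]
) -> int:
    chrom, start, end, strand = feature
    return sum(
        1
        for (sc, sp, ss) in sites
        if sc == chrom and ss == strand and start <= sp < end
    )


def random_toy_annotation(rng: np.random.Generator, span: int = 10_000):
    """A handful of random multi-exon transcripts on both strands, for
    oracle comparisons; returns a list of (tx_id, strand, [(s, e), ...])."""
    txs = []
    for t in range(rng.integers(2, 6)):
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(1, 5))
        cursor = int(rng.integers(0, span // 2))
        exons = []
        for _ in range(n_exons):
            length = int(rng.integers(20, 200))
            if cursor + length >= span:
                break
            exons.append((cursor, cursor + length))
            cursor += length + int(rng.integers(10, 300))
        if exons:
            txs.append((f"t{t}", strand, exons))
    return txs
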