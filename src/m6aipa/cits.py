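"""Single-nucleotide m6A sites from miCLIP truncation pileups.

Reverse transcription stops at the antibody crosslink, so truncation-count
pileups mark candidate modification sites (CITS).  The pipeline is:
per-replicate significance against a local Poisson background with
Benjamini-Hochberg FDR control, cross-replicate merging at a 1-bp maximum
gap, extension of each peak by 2 bp on both sides, and DRACH-motif
filtering, with the motif's A designated as the m6A coordinate.

The truncation tracks carry no strand, so strand is resolved at the DRACH
step: both strands of the extended window are scanned and the site inherits
the strand of the chosen motif.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .coverage import CoverageTrack
from .simulate import revcomp

_D = np.frombuffer(b"AGT", dtype=np.uint8)
_R = np.frombuffer(b"AG", dtype=np.uint8)
_H = np.frombuffer(b"ACT", dtype=np.uint8)
_A = ord("A")
_C = ord("C")


def scan_drach(sequence: str, strand: str = "+") -> list[tuple[int, str]]:
    """All DRACH matches on one strand of a sequence.

    Returns ``(a_offset, motif)`` pairs where ``a_offset`` is the position of
    the methylatable A on the *forward* axis of ``sequence`` and ``motif`` is
    the 5-mer as read on the scanned strand.  D = A/G/T, R = A/G, H = A/C/T;
    N never matches.  Overlapping matches are all reported.
    """
    if strand not in ("+", "-"):
        raise ValueError(f"invalid strand {strand!r}")
    seq = sequence.upper()
    scanned = seq if strand == "+" else revcomp(seq)
    arr = np.frombuffer(scanned.encode("ascii"), dtype=np.uint8)
    n = arr.size
    if n < 5:
        return []
    match = (
        np.isin(arr[: n - 4], _D)
        & np.isin(arr[1 : n - 3], _R)
        & (arr[2 : n - 2] == _A)
        & (arr[3 : n - 1] == _C)
        & np.isin(arr[4:], _H)
    )
    out = []
    for start in np.flatnonzero(match):
        a_off = int(start) + 2
        motif = scanned[start : start + 5]
        if strand == "-":
            a_off = n - 1 - a_off
        out.append((a_off, motif))
    if strand == "-":
        out.reverse()
    return out


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up FDR-adjusted q-values, order-preserving with the input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_truncation_sites(
    track: CoverageTrack,
    expression: CoverageTrack | None = None,
    fdr_threshold: float = 0.01,
    window: int = 50,
) -> pd.DataFrame:
    """Significant single-base truncation sites for one replicate.

    Every position with a nonzero count is tested with a one-sided Poisson
    tail p-value against a local background rate: the median of nonzero
    counts in a +/-``window`` neighbourhood, optionally scaled by the
    position's expression relative to the neighbourhood mean.  Q-values are
    Benjamini-Hochberg over all tested positions; rows with
    ``q <= fdr_threshold`` are returned.
    """
    if not (0.0 < fdr_threshold < 1.0):
        raise ValueError("fdr_threshold must be in (0, 1)")
    frames = []
    for chrom in sorted(track.depth):
        counts = track.depth[chrom]
        tested = np.flatnonzero(counts > 0)
        if tested.size == 0:
            continue
        masked = pd.Series(np.where(counts > 0, counts, np.nan))
        lam = (
            masked.rolling(2 * window + 1, center=True, min_periods=1)
            .median()
            .to_numpy()
        )
        if expression is not None and chrom in expression.depth:
            expr = expression.depth[chrom]
            if expr.size < counts.size:
                expr = np.concatenate([expr, np.zeros(counts.size - expr.size)])
            local_mean = (
                pd.Series(expr[: counts.size])
                .rolling(2 * window + 1, center=True, min_periods=1)
                .mean()
                .to_numpy()
            )
            with np.errstate(divide="ignore", invalid="ignore"):
                factor = np.where(
                    (local_mean > 0) & (expr[: counts.size] > 0),
                    expr[: counts.size] / local_mean,
                    1.0,
                )
            lam = lam * factor
        lam = np.maximum(lam, 1e-6)
        p = stats.poisson.sf(counts[tested] - 1, lam[tested])
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": tested,
                    "count": counts[tested].astype(int),
                    "p_value": p,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "count", "p_value", "q_value"])
    table = pd.concat(frames, ignore_index=True)
    table["q_value"] = benjamini_hochberg(table["p_value"].to_numpy())
    sig = table[table["q_value"] <= fdr_threshold].reset_index(drop=True)
    return sig


@dataclass(frozen=True)
class CitsPeak:
    """A merged cross-replicate truncation peak (strandless at this stage)."""

    chrom: str
    start: int
    end: int
    rep_support: frozenset
    min_q: float

    @property
    def center(self) -> float:
        return (self.start + self.end - 1) / 2.0


def merge_replicate_cits(
    replicate_sites: list[pd.DataFrame],
    max_gap: int = 1,
    mode: str = "union",
) -> list[CitsPeak]:
    """Merge per-replicate significant sites into peaks.

    Positions from all replicates are pooled and clustered: consecutive
    positions stay in one cluster while at most ``max_gap`` unoccupied bases
    separate them.  In ``union`` mode every cluster becomes a peak; in
    ``intersection`` mode only clusters supported by every replicate survive.
    """
    if mode not in ("union", "intersection"):
        raise ValueError(f"unknown merge mode {mode!r}")
    rows = []
    for rep_idx, table in enumerate(replicate_sites):
        for rec in table.itertuples(index=False):
            rows.append((rec.chrom, int(rec.pos), rep_idx, float(rec.q_value)))
    rows.sort()
    peaks: list[CitsPeak] = []

    def flush(chrom, start, prev, support, min_q):
        peaks.append(CitsPeak(chrom, start, prev + 1, frozenset(support), min_q))

    cur = None  # (chrom, run_start, prev_pos, support set, min_q)
    for chrom, pos, rep_idx, q in rows:
        if cur is None or chrom != cur[0] or pos - cur[2] - 1 > max_gap:
            if cur is not None:
                flush(*cur)
            cur = (chrom, pos, pos, {rep_idx}, q)
        else:
            cur = (chrom, cur[1], pos, cur[3] | {rep_idx}, min(cur[4], q))
    if cur is not None:
        flush(*cur)
    if mode == "intersection":
        n_reps = len(replicate_sites)
        peaks = [p for p in peaks if len(p.rep_support) == n_reps]
    return peaks


@dataclass(frozen=True)
class M6aSite:
    """A single-nucleotide m6A call: the A of a DRACH motif near a peak."""

    chrom: str
    pos: int
    strand: str
    motif: str
    peak_id: str
    q_value: float = float("nan")


def extend_and_designate(
    peaks: list[CitsPeak],
    genome: dict[str, str],
    flank: int = 2,
) -> tuple[list[M6aSite], int]:
    """Extend peaks by ``flank`` bp, DRACH-filter, and designate the A.

    Both strands of the widened window are scanned; among DRACH matches whose
    A lies inside the window, the one nearest the original peak center is
    chosen (ties break toward the smaller genomic coordinate).  Peaks with no
    match are dropped; their number is returned alongside the sites.
    """
    sites: list[M6aSite] = []
    n_dropped = 0
    for i, peak in enumerate(peaks):
        seq = genome[peak.chrom]
        w_start = max(0, peak.start - flank)
        w_end = min(len(seq), peak.end + flank)
        # scan with 2 bp of extra context so motifs straddling the window
        # edge are still found when their A is inside the window
        ctx_start = max(0, w_start - 2)
        ctx_end = min(len(seq), w_end + 2)
        subseq = seq[ctx_start:ctx_end]
        candidates = []
        for strand in ("+", "-"):
            for a_off, motif in scan_drach(subseq, strand):
                a_pos = ctx_start + a_off
                if w_start <= a_pos < w_end:
                    candidates.append((abs(a_pos - peak.center), a_pos, strand, motif))
        if not candidates:
            n_dropped += 1
            continue
        _, a_pos, strand, motif = min(candidates)
        sites.append(
            M6aSite(peak.chrom, a_pos, strand, motif, f"peak{i:06d}", peak.min_q)
        )
    return sites, n_dropped


def call_m6a_sites(
    miclip_tracks: list[CoverageTrack],
    genome: dict[str, str],
    expression: CoverageTrack | None = None,
    fdr_threshold: float = 0.01,
    window: int = 50,
    max_gap: int = 1,
    flank: int = 2,
    merge_mode: str = "union",
) -> tuple[list[M6aSite], dict]:
    """Full replicate-to-sites pipeline; returns sites and stage counts."""
    per_rep = [
        call_truncation_sites(track, expression, fdr_threshold, window)
        for track in miclip_tracks
    ]
    peaks = merge_replicate_cits(per_rep, max_gap=max_gap, mode=merge_mode)
    sites, n_dropped = extend_and_designate(peaks, genome, flank=flank)
    info = {
        "sites_per_replicate": [len(t) for t in per_rep],
        "n_peaks": len(peaks),
        "n_peaks_without_drach": n_dropped,
        "n_sites": len(sites),
    }
    return sites, info
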