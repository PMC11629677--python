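"""Dense per-base coverage tracks and depth statistics."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .intervals import GenomicInterval


@dataclass
class CoverageTrack:
    """Per-chromosome per-base read depth for one sample.

    Depth arrays are dense float arrays (one entry per base).  Synthetic
    genomes are small, so density costs little and keeps slicing trivial.
    """

    sample: str
    depth: dict[str, np.ndarray] = field(default_factory=dict)

    def add_chrom(self, chrom: str, values: np.ndarray) -> None:
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 1:
            raise ValueError("depth must be a 1-D array")
        if np.any(arr < 0):
            raise ValueError(f"negative depth in {self.sample}/{chrom}")
        self.depth[chrom] = arr

    @property
    def library_size(self) -> float:
        """Total depth mass across all chromosomes."""
        return float(sum(arr.sum() for arr in self.depth.values()))

    def _slice(self, feature: GenomicInterval) -> np.ndarray:
        if feature.chrom not in self.depth:
            # a chromosome absent from the track has zero coverage everywhere
            return np.zeros(feature.length)
        arr = self.depth[feature.chrom]
        if feature.end > arr.size:
            raise ValueError(
                f"feature {feature.chrom}:{feature.start}-{feature.end} extends "
                f"beyond chromosome end ({arr.size})"
            )
        return arr[feature.start : feature.end]

    def depth_sum(self, feature: GenomicInterval) -> float:
        """Total depth over the feature's bases (strand-independent)."""
        return float(self._slice(feature).sum())

    def mean_depth(self, feature: GenomicInterval) -> float:
        """Mean per-base depth over the feature, as samtools-coverage reports."""
        return self.depth_sum(feature) / feature.length


def mean_depth(feature: GenomicInterval, track: CoverageTrack) -> float:
    """Functional alias for :meth:`CoverageTrack.mean_depth`."""
    return track.mean_depth(feature)
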