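"""Recovery metrics of pipeline output against planted ground truth."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .ipa import IpaRegion
from .simulate import GroundTruth


def ipa_recovery(selected: Sequence[IpaRegion], truth: GroundTruth) -> dict:
    """Intron-level sensitivity and precision of IPA discovery."""
    true_keys = truth.ipa_intron_keys()
    called_keys = {(r.intron.chrom, r.intron.start, r.intron.end) for r in selected}
    tp = len(true_keys & called_keys)
    sensitivity = tp / len(true_keys) if true_keys else float("nan")
    precision = tp / len(called_keys) if called_keys else float("nan")
    return {
        "n_true": len(true_keys),
        "n_called": len(called_keys),
        "n_recovered": tp,
        "sensitivity": sensitivity,
        "precision": precision,
    }


def site_recovery(called: Sequence, truth_sites: Sequence, tol: int = 2) -> dict:
    """Site-level recovery: a planted site counts as recovered when a call
    lies within ``tol`` bases of it; a call with no planted site within
    ``tol`` is a false discovery."""
    true_by_chrom: dict[str, np.ndarray] = {}
    for s in truth_sites:
        true_by_chrom.setdefault(s.chrom, []).append(s.pos)  # type: ignore[arg-type]
    true_by_chrom = {k: np.sort(np.asarray(v)) for k, v in true_by_chrom.items()}
    called_by_chrom: dict[str, np.ndarray] = {}
    for s in called:
        called_by_chrom.setdefault(s.chrom, []).append(s.pos)  # type: ignore[arg-type]
    called_by_chrom = {k: np.sort(np.asarray(v)) for k, v in called_by_chrom.items()}

    def near(query: np.ndarray, ref: np.ndarray) -> np.ndarray:
        if ref.size == 0:
            return np.zeros(query.size, dtype=bool)
        idx = np.searchsorted(ref, query)
        left = np.abs(query - ref[np.clip(idx - 1, 0, ref.size - 1)])
        right = np.abs(query - ref[np.clip(idx, 0, ref.size - 1)])
        return np.minimum(left, right) <= tol

    n_true = sum(v.size for v in true_by_chrom.values())
    n_called = sum(v.size for v in called_by_chrom.values())
    n_recovered = sum(
        int(near(v, called_by_chrom.get(chrom, np.array([]))).sum())
        for chrom, v in true_by_chrom.items()
    )
    n_false = sum(
        int((~near(v, true_by_chrom.get(chrom, np.array([])))).sum())
        for chrom, v in called_by_chrom.items()
    )
    return {
        "n_true": n_true,
        "n_called": n_called,
        "n_recovered": n_recovered,
        "sensitivity": n_recovered / n_true if n_true else float("nan"),
        "fdp": n_false / n_called if n_called else float("nan"),
    }
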