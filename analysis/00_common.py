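"""Shared helpers for the analysis drivers: the study dataset and paths.

Every driver regenerates the synthetic study dataset deterministically from
the seed (generation takes seconds), so the scripts can run independently
and in any order.  Large browsable files live under scratch/, small result
tables under results/.
"""

from pathlib import Path

import m6aipa as M

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"
SEED = 1


def study_dataset(seed: int = SEED):
    """The default-configuration synthetic dataset used throughout."""
    cfg = M.SimConfig(seed=seed)
    genome, annotation, truth = M.simulate_genome(cfg)
    tracks = M.simulate_coverage(annotation, truth, cfg)
    miclip = M.simulate_miclip(annotation, truth, cfg)
    return cfg, genome, annotation, truth, tracks, miclip


def feature_tables(annotation, truth, expr, sites):
    ipa_ids = [f"ipa{k:04d}" for k in range(len(truth.ipa_regions))]
    ipa_ivs = [t.region for t in truth.ipa_regions]
    exon_ids, exon_ivs = [], []
    for tx in annotation.transcripts.values():
        for i, exon in enumerate(tx.exons):
            exon_ids.append(f"{tx.transcript_id}_e{i}")
            exon_ivs.append(exon)
    return (
        M.FeatureTable.build(ipa_ids, ipa_ivs, expr, sites),
        M.FeatureTable.build(exon_ids, exon_ivs, expr, sites),
    )
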