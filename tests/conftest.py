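import numpy as np
import pytest

import m6aipa as M


@pytest.fixture(scope="session")
def default_dataset():
    """One full synthetic dataset at default configuration (seed 1)."""
    cfg = M.SimConfig(seed=1)
    genome, annotation, truth = M.simulate_genome(cfg)
    tracks = M.simulate_coverage(annotation, truth, cfg)
    miclip = M.simulate_miclip(annotation, truth, cfg)
    return {
        "config": cfg,
        "genome": genome,
        "annotation": annotation,
        "truth": truth,
        "tracks": tracks,
        "miclip": miclip,
    }


@pytest.fixture(scope="session")
def called_sites(default_dataset):
    """End-to-end m6A calls on the default dataset."""
    sites, info = M.call_m6a_sites(
        default_dataset["miclip"],
        default_dataset["genome"],
        default_dataset["tracks"]["expression_ref"],
    )
    return sites, info


@pytest.fixture()
def rng():
    return np.random.default_rng(20231)


def build_feature_tables(annotation, truth, expr, sites):
    """IPA-region and exon FeatureTables straight from ground truth."""
    ipa_ids = [f"ipa{k:04d}" for k in range(len(truth.ipa_regions))]
    ipa_ivs = [t.region for t in truth.ipa_regions]
    exon_ids, exon_ivs = [], []
    for tx in annotation.transcripts.values():
        for i, exon in enumerate(tx.exons):
            exon_ids.append(f"{tx.transcript_id}_e{i}")
            exon_ivs.append(exon)
    ipas = M.FeatureTable.build(ipa_ids, ipa_ivs, expr, sites)
    exons = M.FeatureTable.build(exon_ids, exon_ivs, expr, sites)
    return ipas, exons
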