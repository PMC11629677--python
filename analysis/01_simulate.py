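"""Generate the synthetic study dataset and write it out for inspection.

Emulates the study's data layout: a genome with ~200 genes, planted IPA
introns whose 5' segments gain coverage under shZFC3H1, planted
DRACH-anchored m6A sites, and two miCLIP truncation replicates.  Files go
to scratch/data/ (they are large); a small composition table goes to
results/.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from importlib import import_module

common = import_module("00_common")

import m6aipa.io as mio
from m6aipa.io import write_tsv


def main() -> None:
    cfg, genome, annotation, truth, tracks, miclip = common.study_dataset()
    outdir = common.SCRATCH / "data"
    outdir.mkdir(parents=True, exist_ok=True)

    params = {"seed": cfg.seed}
    mio.write_fasta(outdir / "genome.fa", genome)
    mio.write_gtf(outdir / "annotation.gtf", annotation, params)
    mio.write_bed6(outdir / "polya.bed", mio.polya_to_bed(annotation.polya_sites), params)
    mio.write_bedgraph(outdir / "shControl.bedgraph", tracks["shControl"], params)
    mio.write_bedgraph(outdir / "shZFC3H1.bedgraph", tracks["shZFC3H1"], params)
    mio.write_bedgraph(outdir / "expr.bedgraph", tracks["expression_ref"], params)
    for i, track in enumerate(miclip):
        mio.write_bedgraph(outdir / f"miclip_rep{i + 1}.bedgraph", track, params)

    import m6aipa as M

    n_introns = len(M.derive_introns(annotation))
    n_exons = sum(len(tx.exons) for tx in annotation.transcripts.values())
    summary = pd.DataFrame(
        [
            {"quantity": "genes", "value": len(annotation.transcripts)},
            {"quantity": "exons", "value": n_exons},
            {"quantity": "introns", "value": n_introns},
            {"quantity": "ipa_introns_planted", "value": len(truth.ipa_regions)},
            {"quantity": "m6a_sites_planted_ipa",
             "value": sum(1 for s in truth.sites if s.feature_kind == "ipa")},
            {"quantity": "m6a_sites_planted_exon",
             "value": sum(1 for s in truth.sites if s.feature_kind == "exon")},
        ]
    )
    common.RESULTS.mkdir(exist_ok=True)
    write_tsv(common.RESULTS / "simulation_summary.tsv", summary, params)
    print(summary.to_string(index=False))
    print(f"\ndataset written to {outdir}")


if __name__ == "__main__":
    main()
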