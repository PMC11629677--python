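# m6aipa

Misprocessed mRNAs that retain an intact 5′ splice-site motif — in
particular intronic-polyadenylated (IPA) transcripts, produced when a
cryptic intronic cleavage/polyadenylation site terminates transcription
inside an intron — are retained and degraded in the nucleus by the PAXT
complex (scaffolded by ZFC3H1). `m6aipa` implements the computational
analysis chain used to ask whether N6-methyladenosine (m6A) marks
accumulate on these transcripts:

1. **IPA-region discovery.** From gene annotation plus two-condition
   coverage (shControl vs shZFC3H1 knockdown, which stabilizes IPA
   transcripts), introns that do not overlap antisense exons are screened
   for 5′-biased read density — the depth sum over the first 20% of the
   intron versus the last 20%, ratio > 1 — a read gain under shZFC3H1, and
   a contained intronic poly(A) site. The IPA region runs from the intron's
   5′ splice site to the most 5′-proximal poly(A) site.
2. **m6A site calling from miCLIP.** Reverse transcription truncates at the
   antibody crosslink, so per-base truncation counts mark candidate sites.
   Each nonzero position is tested against a local Poisson background
   (median nonzero count in a ±50 bp window, expression-scaled), with
   Benjamini–Hochberg control at FDR ≤ 0.01, per replicate. Significant
   positions from both replicates are merged at a maximum gap of 1 bp,
   peaks are extended ±2 bp, and only peaks containing a DRACH motif
   (D=[A/G/U], R=[A/G], A, C, H=[A/C/U]) survive; the motif's A becomes the
   single-nucleotide m6A coordinate.
3. **Matched resampling null.** Each IPA region is paired with a randomly
   chosen exon matched in length (±10%) and mean read depth (±10%); five
   repetitions give six feature sets (IPA, exon reps 1–5) whose per-feature
   m6A counts are summarized, stratified (0, 1–6, 7–12, >12 sites), and
   compared (paired t-test by default).
4. **Metagene profiles.** Sites are mapped to relative coordinates in
   [0, 1] along each feature (0 = 5′SS, 1 = poly(A) site for IPA regions)
   and summarized as a KDE or histogram density.

A synthetic-data generator replaces the study's raw sequencing data: it
plants IPA introns and DRACH-anchored m6A sites with known coordinates, so
every stage is testable against ground truth with no downloads.

## Worked example

The numbered drivers under `analysis/` run the whole chain on the default
synthetic dataset (seed 1: 200 genes, 160 planted IPA introns, 1,708
planted m6A sites at 6/kb in IPA regions vs 2/kb in exons):

```bash
python analysis/01_simulate.py
python analysis/02_discover_ipa.py
python analysis/03_call_m6a.py
python analysis/04_matched_null.py
python analysis/05_metagene.py
```

Stage 2 prints

```
clean introns screened: 518
IPA regions selected:   160
recovery vs planted truth: sensitivity 1.000, precision 1.000
```

— all 160 planted IPA introns are found with no false calls. Stage 3
prints

```
m6A sites called: 1726
recovery vs planted truth: 0.999 at false-discovery proportion 0.012
```

and stage 4 summarizes the matched comparison:

```
paired comparison of mean m6A per feature: t = 12.15, df = 152, p = 3.72e-24
IPA regions lacking m6A: 0.044 vs matched exons 0.316 (p = 8.76e-17)
```

With three-fold denser planting in IPA regions, their mean m6A count
(3.33 per region) clearly exceeds the length/expression-matched exons
(1.31), far fewer IPA regions carry no m6A at all, and more fall in the low
(1–6 site) stratum — the qualitative pattern of m6A accumulation on IPA
transcripts. Result tables land in `results/`; the full file bundle
(FASTA/GTF/BED/bedGraph) in `scratch/data/`.

Each stage is also exposed as a CLI over the same functions
(`m6aipa simulate | discover-ipa | call-m6a | match | metagene`), reading
and writing standard formats; reruns with the same seed are byte-identical.

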