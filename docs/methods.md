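# Methods

## Coordinates and formats

All internal coordinates are 0-based half-open `[start, end)`; conversion
to 1-based GTF happens only in the readers/writers (`m6aipa.io`). The "gap"
between single-base positions p < q is defined as q − p − 1 unoccupied
bases, which makes "merge at a maximum gap of 1 bp" exact: {100, 101, 103}
cluster together, {100, 104} do not. Coverage is held as dense per-base
float arrays per chromosome — synthetic genomes are ~2 Mb, so density costs
a few MB and keeps window sums trivial. Features that need 5′/3′ polarity
(introns, metagene features) reject strand ".". Writers emit `#` headers
with the package version and parameters, never timestamps, so identical
inputs give byte-identical files.

## Synthetic data generator

The generator emulates the statistical structure of the study system, not
its sequence content. One chromosome (default 2 Mb) carries ~200
single-isoform genes with 2–5 exons (100–1,500 bp) separated by introns
(500–2,000 bp). Per intron, with probability `fraction_ipa_introns`
(default 0.3) an intronic poly(A) site is planted uniformly in the interior
20–80% of the intron, defining the true IPA region (intron 5′ boundary to
the poly(A) base).

**Coverage.** Each gene draws an expression level g ~ U(5, 50) (mean
depth units), shared by all tracks. Expected depth is g over exons,
g × `intron_background_frac` (0.05) over intron bases, and background ×
`ipa_coverage_bias` (20) over the 5′ segment of IPA introns — i.e. the IPA
segment sits at 1.0 × g, inside the exon expression range, which is what
makes ±10% expression matching of IPA regions to exons feasible at all;
expressing the bias relative to the intronic background rather than to the
host level is deliberate for that reason. In shZFC3H1 the IPA segment is
further multiplied by `zfc_up_factor` (3). Noise is per-base Poisson; a
`noiseless` flag freezes expectations so window ratios have closed forms
used in tests.

**m6A sites.** Sites are planted at `m6a_rate_ipa` = 6/kb in IPA regions
and `m6a_rate_exon` = 2/kb in exons (counts Poisson in feature length),
≥5 bp apart, ≥2 bp from feature edges. The generator *writes* a random
DRACH 5-mer into the genome with its A at the site (reverse-complemented
for − strand genes), so truth coordinates are exact and the DRACH
invariant of every call can be checked against the FASTA. Optional knobs
route a fraction of IPA sites into the outer 10% of the region
(`ipa_end_bias`) or exclude exon ends (`exon_end_depletion`) to emulate
the end-enrichment/depletion geometry of real metagene profiles.

**miCLIP.** Truncation counts are Poisson with expectation
`truncation_signal_rate` (50) at planted sites and
`truncation_background_rate` (2.5, i.e. signal/background = 20) elsewhere,
both scaled by expected local expression relative to the midpoint of the
expression range — truncations can only come from transcribed RNA.
Replicates draw independently.

**What the generator does not model:** splicing-aware coverage (depth is
genomic-span), read-level artifacts (duplicates, mapping bias, soft
clipping), overlapping genes/isoforms, truncation offsets relative to the
methylated A (real miCLIP truncates at +1/+2 with protocol-dependent
frequencies), and overdispersion beyond Poisson. Passing recovery tests
therefore demonstrates correctness of the pipeline's logic under its own
stated model, not performance on real libraries.

## IPA discovery

Clean introns are those with zero base overlap with any exon annotated on
the opposite strand; same-strand overlap from other isoforms does not
exclude (a strict flag does). Enrichment is
(Σ depth over 5′-most 20% + 1) / (Σ depth over 3′-most 20% + 1), windows of
floor(0.2 L) bases, minimum 1; the pseudocount of 1 read prevents division
by zero and, at the default threshold of 1, leaves the strict comparison
"5′ sum > 3′ sum" unchanged under any joint rescaling of the tracks.
Introns shorter than 10 bp are skipped (logged). Condition comparison uses
raw depth sums by default — matching the literal "more overall reads"
criterion — with an optional per-million normalization flag. Introns
passing both coverage criteria but containing no same-strand poly(A) site
are excluded and counted. When several poly(A) sites fall in one intron
the most 5′-proximal is used, giving one deterministic region per intron.

## m6A site calling

The truncation-significance test is this package's own transparent
stand-in for black-box CLIP peak callers: for every position with count
c > 0, a one-sided Poisson tail P(X ≥ c | λ) with λ the median of nonzero
counts in a ±50 bp window (a robust local background that a handful of true
sites cannot inflate), multiplied by the position's expression relative to
the window mean when an expression track is supplied, floored at 10⁻⁶.
Benjamini–Hochberg runs over all tested positions (statsmodels step-up);
q ≤ 0.01 is significant, mirroring the declared FDR ≤ 0.01 contract. Under
background-only tracks the λ estimate is conservative (the median nonzero
count of a sub-unit-rate Poisson is 1 ≥ λ), so the observed false-call
fraction sits well under the nominal level.

Replicate merging defaults to union-with-clustering at max gap 1 (an
`intersection` mode requiring support from every replicate is available;
the union is the literal reading of "merged"). Peaks extend ±2 bp; the
extended window is scanned on *both* strands — the truncation bedGraphs
carry no strand, so strand is resolved by the motif itself, which is
unambiguous for planted sites — with 2 bp of extra sequence context so
motifs straddling the window edge are still found when their A lies
inside. Among candidate DRACH As the one nearest the original peak center
wins; ties break toward the smaller genomic coordinate. One site is
emitted per peak; motif-less peaks are dropped and counted.

## Matched null and comparison

Matching is greedy in a shuffled IPA order, without replacement within a
repetition and independent across the R = 5 repetitions; eligibility is
|Δlength| ≤ 10% and |Δmean depth| ≤ 10% relative to the IPA region. IPAs
with an empty eligible set are dropped from that repetition (warned above
20%) rather than matched at relaxed tolerance, preserving the ±10%
contract. Strata are 0, 1–6, 7–12 and >12 sites; the middle bin completes
the partition between the printed low and high bins.

The default comparison is a **paired t-test** on per-IPA differences
(IPA count minus the mean of its matched exon counts across repetitions).
The six-set layout invites a one-sample t of the IPA mean against the five
exon-repetition means, and that comparison is provided as
`method="six_sets"` for descriptive use — but as a test it is strongly
anti-conservative: the between-repetition spread reflects only the exon
resampling variance and omits the IPA mean's own sampling variance
entirely, and the repetitions are positively correlated through shared
eligible pools. Analytically the t statistic is inflated by roughly √6;
empirically the six-set test rejects a true null ~25–55% of the time at
α = 0.05, while the paired test sits at the nominal 5% (verified over 200
simulated null datasets in the acceptance suite). Welch's two-sample t on
per-feature counts is available via `method="welch"`. Degenerate
(zero-variance) comparisons return p = 1 when the values agree and a
machine-floor p with a `degenerate` flag otherwise.

Calibration and power simulations use a reduced configuration (40 genes,
0.4 Mb, ~25–35 IPA introns) — the calibration property concerns the test,
not the genome size, and 200 repetitions at this size complete in well
under a minute each batch.

## Metagene profiles

A site at base p in feature [s, e) maps to (p − s + 0.5)/(e − s) on +
strand and (e − p − 0.5)/(e − s) on −, the half-base keeping single-base
sites strictly inside (0, 1). The KDE is Gaussian with Silverman bandwidth
on a 512-point grid, renormalized to unit integral over [0, 1] —
renormalization rather than boundary reflection, because it is the
simplest well-defined analog of an unbounded-support density restricted to
the unit interval, and the 50-bin histogram mode provides an
estimator-independent check. The cost is a structural dip within ~2
bandwidths of the boundaries (kernel mass leaking outside [0, 1] is
redistributed multiplicatively), so flatness checks on uniform input apply
to the interior; edge-enrichment comparisons (edge vs center mean density)
are biased *against* detecting enrichment and therefore conservative.
Profiles are normalized per feature set. Empty input returns an empty
profile; KDE needs ≥2 distinct positions (use the histogram otherwise).

## Known limitations

- Coverage and feature depths are genomic-span based; spliced
  (transcript-level) depth is not modeled, matching the per-span reading
  of mean-depth computation.
- The Poisson local-background CITS test is a stand-in; it reproduces the
  FDR-gating contract, not the internals of published CLIP toolkits.
- Strand assignment of called sites relies on DRACH presence, which can in
  principle pick the antisense motif of a genuine site; with planted
  motifs this is not observed, and on real data stranded truncation tracks
  would remove the ambiguity.
- Matching supports one expression track per invocation; concordance
  across independent expression experiments is obtained by rerunning, and
  no cross-run statistic is defined.
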