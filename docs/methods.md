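# Methods

This note documents the models implemented in `texrip`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions that matter when comparing results.

## Coordinates and formats

All internal coordinates are 0-based, half-open and strand-explicit. The
only module that converts to and from on-disk conventions is `texrip.io`:
GFF3 is written/read as 1-based inclusive, bedgraph and BED as 0-based
half-open. Bedgraph files carry raw integer counts; normalization always
happens downstream of parsing so files stay auditable. BED6 scores are
`round(-10·log10(p))` capped at 1000, a conventional monotone transform of
significance.

## 5′-end site detection (`texrip.sites`)

**Model.** Read starts at a position in two libraries are treated as Poisson
counts with rates proportional to the library sizes under the null. The
decision statistic is the exact conditional binomial rate-ratio test:
conditioned on the total n = k_a + k_b, the enriched-library count is
Binomial(n, s_a/(s_a+s_b)) under the null, and the one-sided p-value is
P(X ≥ k_a). This test is exact at any depth, parameter-free, and one-sided —
enrichment of the "wrong" library can never produce a call, which is what
makes TPS detection by input inversion safe. The Skellam-background
approach used by TSSAR-style callers is a noted alternative; the binomial
conditioning avoids fitting any background distribution.

**Defaults** (all exposed as arguments / CLI flags):

| parameter | default | meaning |
|---|---|---|
| `min_reads` | 10 | minimum read starts in the enriched library |
| `alpha` | 1e-9 | candidate threshold on the one-sided p |
| `group_gap` | 5 nt | candidates this close merge into one site |
| `min_score` | 600 | filter: normalized enriched count (per 10⁷ library counts) |
| `min_delta` | 10 | filter: difference of normalized counts |
| `max_p` | 0.05 | filter: p-value ceiling (inclusive, like the other two) |

"Score" and "delta" are defined here as library-size-normalized read-start
counts scaled to starts per 10⁷ library counts; upstream tools print both
without defining them, so they are plain recalibratable thresholds rather
than derived statistics. Replicates are summed per library before testing —
this matches the one-p-per-position structure the filter cascade assumes and
is more powerful than per-replicate testing at these depths.

**Grouping.** Candidates within `group_gap` nt on the same strand merge
transitively; the representative is the position with the maximal enriched
count, ties resolved to the most 5′ position on the strand (the biologically
upstream start). The grouper is oracle-tested against an O(n²)
transitive-closure implementation.

**TSS classes.** pTSS (closest call within 300 nt upstream of a same-strand
gene start), UTR (in the window but not closest), iTSS (inside a same-strand
gene), aTSS (inside or within 100 nt of an opposite-strand gene), oTSS
(elsewhere), applied in that precedence order. The five-class scheme names
four classes explicitly in the source literature; internal starts (iTSS) are
the natural fifth. The 300/100 nt windows are package defaults, not
literature constants, and are exposed as arguments.

## Transcript annotation (`texrip.transcripts`)

An oTSS/aTSS call becomes a transcript when a same-strand TTS lies within
(TSS, TSS+400] measured 5′→3′; the **nearest** downstream TTS wins when
several fall in the window — the shortest transcript consistent with both
termini (the alternative, strongest Term-seq signal, would need signal
values the TTS lists do not always carry). The emitted interval spans both
termini inclusively, so lengths are ≤ 401 nt by construction.

ORF calling scans the transcript sequence for start codons (ATG/GTG/TTG)
with an in-frame stop fully inside the transcript and keeps the longest.
`aa_length` counts codons strictly between start and stop; candidates with
10–49 aa are upgraded to smORFs (small proteins are defined as < 50 aa).
Expression validation requires TPM ≥ 1 in ≥ 1 condition — an
operationalization of "validated expression in at least one condition";
both numbers are arguments.

Motif scanning is exact degenerate-letter (IUPAC) matching, U ≡ T,
overlapping hits allowed, optionally on both strands via the
reverse-complemented consensus (degenerate letters complement class-wise:
R↔Y, K↔M, B↔V, D↔H). The four processing-site consensus motifs reported for
*S. acidocaldarius* ship as `PROCESSING_MOTIFS`. De-novo motif discovery is
out of scope; scanning reported consensi replaces it.

When merging novel candidates with a curated annotation, features with
≥ 90% reciprocal same-strand overlap collapse onto the curated entry, and no
two emitted features share (start, end, strand).

## RIP-seq interaction sites (`texrip.ripseq`)

Each replicate track is scaled to the mean library size across both arms and
averaged within arm; the coordinate-wise statistic is
log2((coIP + 1)/(mock + 1)) on the normalized averages. The pseudocount of 1
(exposed) keeps zero-coverage positions at exactly 0. Candidate peaks are
maximal runs of ≥ 10 consecutive positions ≥ 1; a single below-threshold
position splits runs.

Peak significance uses a Welch two-sample test on log2 of library-size-
normalized per-peak replicate sums, one-sided (greater), BH-adjusted across
all peaks of one experiment; the emitted set requires padj < 0.01 and mean
log2FC ≥ 1. The one-sided alternative reflects that the emitted set is
already constrained to enrichment; a negative-binomial GLM (DESeq2) is the
heavyweight alternative and externally produced DESeq2 tables are accepted
as a drop-in wherever a fold-change table is an input. With fewer than two
replicates per arm no p-value is computed and the peak is left unflagged
rather than silently passed.

Positional classes use the peak midpoint mapped to the transcript's 5′→3′
axis: [0, 0.25) five_prime, [0.25, 0.75) internal, [0.75, 1] three_prime.
Half-open boundaries make the assignment single-valued; midpoints exactly at
0.25 or 0.75 fall into the downstream class.

The GC background is the GC fraction of 50 nt windows every 25 nt starting
at 0, trailing partial window dropped — exactly
floor((L − 50)/25) + 1 windows — compared against peak GC values with a
two-sided Mann–Whitney U test at p < 0.05. All windows enter the background,
including peak-overlapping ones (`exclude` would bias small genomes;
the effect is negligible at realistic peak densities).

## Expression integration (`texrip.expression`)

TPM is the usual length-then-depth normalization (sums to 10⁶ exactly). The
DE stand-in uses median-of-ratios size factors, log2FC of mean normalized
counts with a 0.5 pseudocount, a Welch test on log2 normalized counts, and
BH adjustment; significance is |log2FC| ≥ 1 and p < 0.05. Its type-I error
is calibration-tested at 0.05 ± 0.02 on null simulations.

Pair correlation is the standard Pearson formula over contrasts finite in
both vectors; fewer than 3 shared contrasts or a zero-variance vector yields
a *missing* PCC (class "uncorrelated"), never 0 — a zero would silently
inflate the uncorrelated mass with false confidence. Class thresholds are
inclusive at ±0.5.

Direction agreement counts sign products of per-timepoint log2FCs among
pairs with |PCC| ≥ 0.5; zero log2FCs are excluded from the denominator (sign
undefined). The larger percentage is computed directly and the smaller as
its complement, so the two sum to exactly 100 in floating point.

Protein integration classifies each of asRNA/mRNA/protein as
up/down/unchanged with the RNA thresholds (|log2FC| ≥ 1, p < 0.05) — the
proteomics literature the pipeline targets prints no separate cutoffs, so
the RNA thresholds are reused and exposed. Pairs without protein data are
excluded and counted.

Trajectory summaries build the groups protein-only (per protein), both, and
unbound by set algebra over the target sets and the transcript universe;
each bound group is compared to unbound with a two-sided Mann–Whitney U
test, BH-adjusted within each timepoint (no procedure is prescribed by the
figure conventions the tiers mimic: * p < 0.05, *** p < 0.005).

## Synthetic data (`texrip.synthetic`)

The generator is first-class, tested code that defines the study conditions:

* **Genome**: i.i.d. bases, default 100 kb at GC 0.37 with 60 non-overlapping
  genes on both strands — a desk-scale stand-in for a ~2.2 Mb low-GC
  archaeal chromosome, sized so the full pipeline runs in seconds.
  Coordinates are linear; circular topology is not emulated because no
  analysis step in scope depends on wraparound.
* **dRNA-seq**: Poisson read starts; background 0.5 starts/nt, planted sites
  add `depth` (default −TEX mean 10 for the generic demo; recovery studies
  use 50) in the base library and `ratio × depth` (default ratio 5) in the
  enriched library; TSS and TPS are exact mirror images. 2 replicates per
  library by default (typical dRNA-seq designs; the source protocols do not
  fix a count).
* **RIP-seq**: mock Poisson(depth = 50); inside planted 30 nt peaks the coIP
  mean is multiplied by 2^log2FC (default log2FC 2); 3 replicates per arm.
* **Expression**: per pair, bivariate-normal log2FCs across contrasts
  (marginal sd 1) at the planted correlation, cycled through
  {−0.9, −0.5, 0, 0.5, 0.9}; protein log2FC = 0.5 × mRNA + N(0, 0.3),
  emulating damped propagation to protein level; p-values are two-sided
  normal tails of lfc/0.3, consistent with the effect sizes.

Everything is deterministic under the seed, byte-identically so for emitted
files; the truth manifest round-trips through TSV.

**What the generator does not emulate — and therefore what passing tests do
not show:** read-level errors, alignment artifacts, overdispersion beyond
Poisson (a gamma multiplier hook exists but is off by default), positional
spreading of 5′ ends around a true site, correlated background between
libraries, and transcript-abundance heterogeneity. Recovery rates of 1.0 on
synthetic data are statements about the implementation under the stated
model, not expected field performance on real libraries, where score/delta
thresholds in particular will need recalibration.

## Problem sizes used in the shipped checks

The automated checks run the recovery studies at 100 kb with 200 planted
TSSs (or 40 peaks / 40 antisense units) and 500 pairs × 5 correlation
levels, chosen as the smallest sizes at which the binomial/rank statistics
are in their asymptotic regime; the whole suite completes in well under a
minute on one CPU.

## Known limitations

* The site test conditions on totals and so has discrete p-values; at very
  low totals the test is conservative (p = 1 when n = 0 by definition).
* The Welch stand-in for peak/DE significance assumes approximate normality
  of log counts — good at depth ≥ ~20, questionable below.
* aTSS classification uses a fixed 100 nt antisense flank; antisense calls
  to distant 3′ UTR overlaps beyond the flank become oTSS.
* `annotate_transcripts` assigns one record per aTSS with a list of cognate
  genes; it does not split a multi-gene antisense overlap into one record
  per gene (the pairing step in `expression.build_pairs` does that instead).
* Mann–Whitney on GC fractions has ties by construction (discrete values);
  scipy's tie-corrected normal approximation makes the null calibration
  slightly conservative (~2.5–4% empirical rejection at nominal 5%).
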