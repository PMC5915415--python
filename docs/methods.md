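# Methods

This note documents the models, rules and numerical choices behind
`apsflow`, and what the synthetic-data generator does and does not
emulate.

## Coordinates and strand bookkeeping

All internal coordinates are 0-based half-open; GFF3 I/O converts to and
from 1-based inclusive. WTTS-seq reads start at the poly(A) tail, so a
read is the reverse complement of its transcript's 3′ terminus: under
the default `antisense` orientation, an alignment on the genomic minus
strand implies a plus-strand transcript whose terminus-adjacent base is
the alignment's end-most coordinate, and vice versa. Because library
preparations differ in how this bookkeeping lands in the aligner's
output, the convention is a flag (`read_orientation: antisense|sense`)
rather than a constant.

## Read processing

A read is dropped when strictly more than 50% of its bases are below
Q10 (a read at exactly 50% is kept), then the longest leading poly(T)
prefix is removed, then reads shorter than 16 bp are dropped — in that
order. The order is a choice; when both rules would fire the outcome is
the same, only the ledger attribution differs. Reads are not
deduplicated, and only primary alignments at or above a configurable
MAPQ (default 0) are used. Every run asserts the conservation identity
`n_raw = n_dropped_quality + n_dropped_short + n_unmapped + n_termini`.

## Site calling

"Clustered within a window of 24 nucleotides" is read as single-linkage
chaining: sort terminus positions per (chromosome, strand) and break
wherever the gap to the previous position exceeds 24 bp. Chaining is
order-invariant and equals the transitive closure of |a − b| ≤ 24 (the
test suite pins this against an O(n²) union-find oracle). A fixed,
non-sliding window would be an alternative reading; chaining matches
common 3′-seq practice. The cluster's representative position is its
highest-count member, ties broken toward the 3′-most position with
respect to the strand — the coordinate choice is ours, since single
positions and modal peaks coincide on clean data. The ≥ 16-read cutoff
is applied to the total across the libraries of the analysis set; a
per-comparison subset (e.g. the four libraries of one KO/WT pair) can
therefore retain fewer sites than the full catalogue, and both
behaviours are exposed via the `libraries` argument.

## Class codes

Class codes are re-implemented from their definitions, using the
cluster span (not the representative point): c when the span is inside
an exon; e when it overlaps an exon and runs ≥ 10 bp into an adjacent
intron; i when inside an intron; o for any other exon overlap
(junction-spanning with < 10 bp of intron, or running past the terminal
exon); p when the span lies within 2,000 bp downstream of a transcript
3′ end and outside the gene; x when it overlaps an exon of an
opposite-strand gene and nothing same-strand claims it; u otherwise.
Precedence — same-strand (c > e > i > o across transcripts) over
downstream (p) over antisense (x) — is this package's decision; the
one-line definitions do not specify one, and this ordering makes every
site receive exactly one code. Overlapping same-strand genes are
resolved by greatest exonic overlap, ties to the nearer 3′ end, with
the decision logged. Downstream distance is measured from the
transcript 3′ end to the span's proximal edge, 1-based (the first base
after the transcript is at distance 1), so 1,999/2,000 bp are p and
2,001 is u. The *distal* view (class ∈ {c, o, p}) is a derived
approximation of TTS-centred annotation categories, not a
re-implementation of any external annotator.

## A-rich stretches and signal scanning

The ARS rule — ≥ 7 consecutive A, or ≥ 8 A within any 10-bp window, in
the 30 bp downstream — is evaluated on the transcript strand, because
the adenines that mislead oligo(dT) priming are those of the continuing
sense sequence. At chromosome ends the rule is applied to whatever
sequence is available. The polyA-signal scan reports every occurrence
of the supplied hexamers whose 3′-most base lies 1–100 bp upstream of
the site (transcript strand), overlapping matches included, offsets
negative and measured to that 3′-most base. The default list contains
only the canonical AATAAA/ATTAAA pair: the larger published signal sets
come from external compilations that users should supply explicitly
(`load_signal_list`) rather than have silently hard-coded.

## Differential model

Counts are normalized by median-of-ratios size factors (geometric-mean
reference; when no feature is observed in every library, the reference
falls back to features observed in at least half of them, logged). The
test is a negative-binomial Wald test on the KO − WT log fold change:

* per-feature dispersion is estimated by method of moments on the
  within-condition variance of normalized counts, regressed on an
  `a0 + a1/μ` mean-dispersion trend (one outlier-trimming pass), and
  shrunk toward the trend on the log scale with weight `d/(d + d0)`
  where `d` is the residual degrees of freedom and `d0 = 6` the prior
  strength — low-replicate designs need strong shrinkage; estimates are
  floored at 1e-4 and capped at 10;
* the Wald variance of each condition's log mean is
  `(Σ_j 1/(q s_j) + n α)/n²`, the delta-method variance of the mean of
  normalized NB counts; a half-read floor on the normalized mean keeps
  the statistic finite for features observed in only one condition;
* p-values are two-sided normal, adjusted by an in-package
  Benjamini–Hochberg step-up (checked against the textbook procedure).

Significant features (adjusted p < 0.1 by default) are categorized:
*gained* when every WT raw count is zero (and some KO count positive),
*lost* symmetrically, otherwise *up*/*down* by fold-change sign. Both
the significance threshold and the all-zero rule are required for
gained/lost — "not expressed" alone, without significance, stays *ns*.
This is a documented re-implementation of the standard NB workflow;
matching any external package's numbers exactly is a non-goal, and the
tests assert statistical properties (type-I error, FDR, sensitivity,
fold-change recovery) instead. Under the 2-vs-2 design at depth 100 and
dispersion 0.05 the observed operating point is an empirical FDR of
about 0.07 at the 0.1 threshold with near-complete sensitivity for
|log2FC| = 2, and a null type-I rate of about 0.05 at raw p < 0.05
(recomputed by `scripts/acceptance.py`).

Gene-level analysis sums the counts of a gene's sites with class codes
{c, e, i, o, p}; antisense (x) sites are not added to the opposite-
strand host gene (configurable — the biology is genuinely ambiguous),
and genes below 16 total reads are dropped.

## Genomic statistics

Differential-site regions are built greedily per chromosome: grow from
the left-most unassigned site while the span stays ≤ 5 Mb, emit when ≥ 3
members, resume at the next unassigned site. Window placement (greedy
anchored vs sliding) is underdetermined; greedy spans are deterministic
and every emitted region provably satisfies both constraints. The χ²
test applies the Yates continuity correction exactly for 2×2 tables and
no correction otherwise, matching the convention of common statistical
environments — the reconstructable published 2×2 statistic is
reproduced only under this convention (26.589 corrected vs 28.906
uncorrected). Direction groups merge gained with up and lost with down.

## The synthetic generator

`SimConfig` defaults encode the emulated study conditions: 2 KO vs 2 WT
libraries, ~100 reads per site per library, NB dispersion 0.05, 10% of
sites differential at |log2FC| = 2 (half of them exclusive to one
condition, i.e. gained/lost-type), signal hexamers planted 15–30 bp
upstream, and an internal-priming artifact read fraction of 5%. The
genome is uniform random ACGT; genes (protein-coding, lncRNA,
pseudogene, miRNA, small RNA in proportions chosen to exercise every
biotype at toy scale) are laid out in non-overlapping slots except for
one deliberately antisense-overlapping pair, with one planted
antisense-exonic (x) site. Up/down effects are applied symmetrically
(±log2FC/2 per condition) so the KO/WT mean ratio is exactly 2^log2FC.
Poly(T) tail lengths are geometric (support ≥ 1, p = 0.35) — real tail
length distributions are not published for this chemistry, so this is a
modelling choice, as is the fixed 40-bp genomic read length.

Generator simplifications to know about when interpreting green tests:

* the terminus-adjacent base of every planted site is fixed to a non-A
  (a C on the transcript strand, echoing the common cleavage context),
  because a genomic A at the cleavage site is genuinely
  indistinguishable from the tail after poly(T) trimming — real data
  loses those bases, the simulation sidesteps the ambiguity;
* downstream 30-mers of genuine sites are scrubbed of accidental A-rich
  stretches so truth ARS labels are exact;
* truth alignments are emitted directly as BED (no aligner, no mapping
  error); sequencing error, rRNA contamination and transcript secondary
  structure are not modelled;
* jitter blurs positions but not the truth class labels, so exact-
  recovery checks run at `jitter_sd = 0`.

Passing tests therefore demonstrate correctness of the pipeline's
logic and calibration of its statistics under the stated generative
model — not robustness to alignment artifacts or chemistry-specific
noise in real libraries.

## Problem sizes

The default demo uses 60 genes on 2 × 300-kb chromosomes (~110 sites,
~90k reads); distributional checks in the tests use up to 560 genes
(~1,000 sites) and 5,000-feature count matrices over 10 seeds. These
sizes are chosen to make every property measurable with comfortable
Monte-Carlo margins while keeping the whole suite fast on a laptop.

## Known limitations

Single-factor two-condition designs only; no shrunken fold-change
estimator or independent filtering; no sub-cluster peak splitting; the
p-class search considers transcript 3′ ends only (not polyA databases);
ASS (5′) mode reuses the identical clustering and so inherits the
3′-centric defaults for annotation windows.
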