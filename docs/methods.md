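# Methods

`spaceraq` analyses population-level spacer acquisition in a bacterium that
carries two CRISPR-Cas loci acquiring spacers from the same phage: a
DNA-targeting subtype II-C style locus whose array is transcribed from within
the array toward the variable end (`array_to_leader`), and an RNA-targeting
subtype VI-B style locus transcribed conventionally from the leader
(`leader_to_array`). This note records the models, conventions, parameter
choices, and numerical decisions the package embodies.

## Coordinate and orientation contracts

All internal coordinates are 0-based half-open on the forward genome strand;
conversion from 1-based inclusive GFF3/feature-table coordinates happens only
at the I/O boundary. Three orientation contracts drive everything downstream:

1. **Spacers are stored in crRNA orientation**: the spacer string equals the
   sequence of the genome strand that matches the crRNA (the nontarget
   strand), read 5'→3'.
2. **A protospacer hit's `strand` is the crRNA-matching strand.** This single
   definition fixes both motif orientation and mRNA classification.
3. **Flanks are guide-oriented**: the 15-nt upstream/downstream contexts are
   read 5'→3' on the crRNA-matching strand, so a given genomic motif looks
   identical regardless of which strand the spacer came from.

The locus's transcription direction alone decides which flank carries the
shared acquisition motif (SAM): downstream `NNNNNTAAA` for array-to-leader
loci; the same genomic motif read upstream as `TTTANNNNN` for leader-to-array
loci. The two detection rules are exact reverse-complement images of each
other — the package tests this equivalence exhaustively on toy genomes.

Whether a pipeline's stored spacer orientation is crRNA or array-genomic is a
convention; ours is crRNA throughout, which anyone comparing raw intermediate
files against other tools should keep in mind.

## Read processing

Trimming mirrors Trimmomatic semantics with the fixed order TRAILING(23) →
SLIDINGWINDOW(3, 21) → MINLEN(100): 3'-terminal bases below Q23 are removed,
then the read is cut at the start of the first full 3-base window whose mean
quality drops below 21, and reads shorter than 100 nt are dropped. Only full
windows are evaluated; the order and the window rule are fixed so results are
bit-reproducible.

Extraction finds the first intact full-length repeat (exact by default;
`max_repeat_mismatches` is an escape hatch for noisy data), then scans anchor
offsets 27..32 nt downstream in ascending order for the first 4-nt prefix of
the next repeat. The intervening bases are the new spacer; at most one spacer
is taken per read (the amplicons target the variable end, which carries one
new unit). Ascending offset order means the leader-proximal valid spacer wins
deterministically. When a locus is sequenced from the strand opposite its
crRNA, the read is reverse-complemented first, so output is always
crRNA-oriented.

## Clustering and identity

Sequence identity is the effective CD-HIT-EST definition for near-equal-length
fragments: the best ungapped alignment over all relative offsets, matches
divided by the length of the shorter sequence. Gapped alignment is omitted —
spacers differ by at most 5 nt in length and acquisition copies sequence
verbatim — which makes the definition brute-force checkable. Greedy clustering
(threshold 0.8, word size 5) processes distinct sequences in a deterministic
content-based order (count desc, length desc, lexicographic) instead of file
order, so clustering is invariant to input order. Membership requires at least
one shared exact word of 5 nt, as in CD-HIT's word filter; at 0.8 identity a
shared 5-mer is not mathematically guaranteed (only 4-mers are), so the filter
can occasionally split a borderline pair exactly as the original tool would.
Cross-pool sharing at 0.9 identity counts the fraction of query
representatives with at least one reference representative at or above
threshold. Reverse complements are deliberately not compared: spacers are
already orientation-canonicalized, and collapsing strands would conflate sense
and antisense acquisition events.

## Mapping

Spacers map by ungapped local alignment: +2 per match, −6 per mismatch,
soft-clipping free, acceptance threshold `10 + 8·ln(L)` for spacer length L
(≈37.2 at L=30, so ≥19 clean matched bases are needed). Both strands are
scanned; the best hit is kept with ties broken by fewer mismatches, then
smaller start, then `+` before `-`. Mapping is hierarchical — phage first,
then host for the phage-unmapped remainder, then discard — and the three-way
partition always sums to the input count.

Two search strategies must agree (tested): an exhaustive vectorized scan for
genomes ≤100 kb and exact 9-mer seed-and-extend above that. Nine was chosen
because a 9-mer window is pigeonhole-guaranteed to survive two substitutions
in a 27-mer, preserving ≥99% recall for realistically mutated spacers; longer
seeds would miss a few percent of 2-mismatch spacers. Because the aligner
soft-clips, edge substitutions may be trimmed from the reported interval;
consumers needing the full protospacer extent should treat `start`/`end` as
the aligned span, not the insertion-size estimate.

The discard rates of the original short-read aligner configuration this
scoring mimics depend on that aligner's heuristics; this reimplementation is
not expected to reproduce historical discard percentages exactly.

## Motif analysis

The canonical SAM test is fixed-offset: TAAA at positions 6–9 (1-based) of
the downstream flank, equivalently TTTA at positions 7–10 of the upstream
flank for leader-to-array loci. Variants with longer or shorter N-regions are
not counted as canonical SAM; instead a position-resolved offset histogram of
the TAAA core is reported, since such offset-shifted motifs behave as
deprecated in interference. Position-frequency matrices are built from
untruncated flanks only; per-column information content is `2 − H` bits with
`0·log 0 = 0`.

Motif counting supports IUPAC motifs on both strands, counting every
(possibly overlapping) occurrence. Whole-genome scope labels forward=coding /
reverse=template as a pure reporting convention; CDS scope restricts to
occurrences fully inside each feature and labels strands by the feature's own
orientation, which is the biologically grounded labeling. Both scopes are
exposed because genome-wide and CDS-restricted site lists legitimately differ
and either can be the right denominator depending on the question; features
are counted independently, so overlapping CDS double-count by design.

## mRNA-targeting statistics

A hit targets mRNA iff (i) its crRNA-matching strand is opposite the ORF
strand (the crRNA can anneal to the transcript) and (ii) the interval lies
fully inside the ORF. Boundary-straddling and intergenic hits are excluded
from both numerator and denominator. Antisense and intergenic transcription
are ignored, so mRNA-targeting counts are lower bounds. Each pool
(locus × target genome × unique/absolute view, pooled or per replicate) is
tested one-tailed against Binomial(n, 1/2); the tail is computed by exact
log-space summation of the pmf (cross-checked against an independent library
implementation in the tests), and the 95% expected band comes from the exact
binomial quantiles scaled by n. The tail direction follows the observed side
(above when the proportion exceeds 1/2) and is recorded explicitly in every
output row; no multiple-testing correction is applied across pools.

Binned target maps use bins spanning 3% of each genome (34 bins, the last
absorbing the remainder), assignment by interval midpoint, per-replicate
normalization over all (bin, strand) cells, and a centered 5-bin moving
average of the across-replicate mean as the smoothed curve — a moving average
rather than a fitted smoother so the curve is reproducible without a plotting
dependency.

## Overlap nulls

To ask whether two loci share more spacers than independent acquisition
predicts, pools of simulated 30-mers (the modal spacer length; configurable)
are drawn from the phage genome with replacement, either uniformly over
positions and strands or uniformly over SAM-adjacent placements, and each
pool's 0.9-identity match fraction against the reference pool is recorded.
A normal distribution is fitted by maximum likelihood (sample mean,
population SD) and an observed overlap is scored by the upper tail; the
rank-based empirical p-value `(1 + #{fractions ≥ obs}) / (1 + iterations)` is
co-reported because the normal fit is an approximation and degenerates when
the SD is zero (flagged explicitly). The PAM-adjacent null is the sharper
comparison: conditioning on the motif alone raises the expected overlap with
a SAM-enriched reference well above the uniform null, so only overlap beyond
the PAM-adjacent mean is evidence of a genuinely shared prespacer pool.

## The synthetic-data generator

The generator emulates the structure of a dual-locus acquisition experiment
with full ground truth; its defaults are the package's study conditions:

| parameter | default | meaning |
|---|---|---|
| phage / host length | 47 kb / 300 kb | phage kept at realistic size; host scaled down from Mb scale so runs stay fast |
| GC fraction | 0.32 | AT-rich, matching the flavobacterial setting and giving abundant TAAA sites |
| ORF density | 0.9 | typical dense microbial coding fraction |
| `pam_preference` π | 0.63 | fraction of events drawn from SAM-adjacent placements |
| `spacer_length_dist` | mode 30 on 27–32 | acquired-spacer length spectrum |
| `strand_bias` β | 0.5 | probability a free ORF-contained event takes the mRNA-targeting strand |
| `self_fraction` σ | 0.05 | probability an event targets the host |
| hotspot mixture | one Gaussian at 0.8 of the genome (width 0.04–0.05), weight 0.5, plus uniform 0.5 | positional acquisition hotspot near one genome end |
| `shared_pool_fraction` ρ | 0.58 | probability a later-locus event reuses a donor-locus prespacer |
| read errors | sub 0.005, ins 0.003, del 0.005, ×4 in homopolymers | semiconductor-sequencing-like, indel-tilted noise |

Design details worth knowing:

* **SAM planting** chooses a placement whose guide-strand flank matches
  `NNNNNTAAA` at the detection offset, weighted by the hotspot density, so
  motif preference and positional preference compose. Events not planted can
  still be SAM-adjacent by chance; the recorded flag is always the realized
  adjacency, so recovery comparisons are estimate-vs-realized, not
  estimate-vs-nominal.
* **Shared-pool reuse copies the donor event wholesale** (genome, interval,
  strand, spacer string) and inherits the donor's SAM flag. A real shared
  dsDNA prespacer read out per-locus would yield reverse-complement crRNAs
  between loci; the simulator instead keeps the string identical so that
  sharing is recoverable under the package's strand-strict 0.9-identity
  comparison. This is a deliberate simplification of insertion-orientation
  biology, stated here so nobody mistakes it for a claim about mechanism.
* **Anchor-collision resampling**: a candidate spacer that contains the
  repeat's 4-nt anchor prefix at offset ≥27 would be truncated by the
  first-valid extraction rule, so such candidates (~1–2% of draws) are
  rejected and resampled. This keeps error-free extraction exactly lossless
  at the cost of a negligible sampling bias against anchor-containing
  spacers.
* Reads are emitted primer-trimmed, one amplicon structure per event
  (repeat – new spacer – repeat – 20 nt of old array), with per-base
  qualities drawn i.i.d. normal and clipped to [2, 41].

What the generator does **not** emulate: PCR chimeras and duplicates, barcode
demultiplexing, quality-correlated error profiles, phage population evolution,
interference/selection during the experiment, antisense transcription, and
per-locus insertion-orientation effects. Passing the recovery tests therefore
shows the analysis chain is correct and calibrated on data satisfying the
model's assumptions — not that real sequencing artifacts cannot bias the
estimates.

## Test scaling and numerical choices

The suite runs parameter recovery at 300 events per locus with error-free,
high-quality reads (noise robustness is exercised separately at the stated
error rates) and checks estimates against exact Clopper–Pearson 99% intervals.
Null calibration uses one 300-iteration null and 200 fresh query draws ranked
against it; because the overlap fraction is discrete, uniformity is assessed
on the randomized PIT, which is exactly U(0,1) under the null. Power and
ordering checks use 150–300 iterations; the acceptance script uses the full
1000. Identity thresholds are compared with a 1e-12 tolerance so that exact
boundary cases (24/30, 27/30) are inclusive. Degenerate situations are
explicit statuses, not crashes: empty pools yield NA rows, zero-SD null fits
warn and report p ∈ {0, 1}, truncated flanks are excluded from rates and
matrices.

## Known limitations

* Ungapped alignment cannot place spacers whose reads acquired indels inside
  the protospacer span; they are discarded by the score threshold, which
  slightly deflates absolute counts under heavy indel noise.
* The cross-pool identity is strand-strict; pools canonicalized under
  opposite conventions would need explicit reverse-complementation before
  comparison.
* Binomial tests treat spacers as independent draws; priming-style clustering
  of acquisition events violates this mildly in the absolute view.
* The host genome default (300 kb) is a scaled stand-in for a multi-Mb
  chromosome; per-bin host statistics are correspondingly coarser than a
  full-size genome would give.
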