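# spaceraq

Analysis toolkit for population-level CRISPR **spacer acquisition** in
systems with two CRISPR-Cas loci sampling the same phage — a DNA-targeting
II-C-style locus and an RNA-targeting VI-B-style locus. Starting from
CRISPR-array amplicon reads, the package:

* quality-trims reads and extracts newly acquired 27–32 nt spacers between an
  intact repeat and the first 4 nt of the next repeat, emitting them in
  canonical crRNA orientation;
* collapses them into unique/absolute pools by greedy CD-HIT-style identity
  clustering (0.8, word size 5);
* maps unique spacers to the phage genome, then the host, by ungapped local
  alignment (+2 match / −6 mismatch, threshold `10 + 8·ln L`);
* infers the guide-oriented spacer acquisition motif (SAM, `5'-NNNNNTAAA-3'`
  downstream for array-to-leader loci, upstream `TTTANNNNN` for
  leader-to-array loci) via fixed-offset detection and position-frequency
  matrices;
* quantifies inter-locus spacer sharing against two Monte-Carlo nulls
  (uniform-random and PAM-adjacent genome sampling, normal fit + upper-tail
  p, empirical p co-reported);
* tests mRNA-targeting bias per pool with exact one-tailed binomial tests
  against a fair-strand null, and produces binned per-strand target maps;
* ships a synthetic-data generator (genomes, acquisition events with tunable
  SAM preference π, strand bias β, self-targeting fraction σ, hotspots and a
  shared prespacer pool ρ, plus error-bearing amplicon reads) with full
  ground truth, so every stage is testable end to end.

The core quantities: a spacer pool's **overlap fraction** with another pool is
the share of its unique spacers with a ≥0.9-identity match in the reference
pool (ungapped, shorter-sequence denominator); its significance is the upper
tail of a normal fitted to 1000 simulated null overlaps. A spacer is
**mRNA-targeting** iff its crRNA is complementary to the coding strand and the
protospacer lies fully within an ORF; each pool's proportion is scored by
`P(X ≥ k)` or `P(X ≤ k)` with `X ~ Binomial(n, 1/2)`.

## Worked example

`examples/03_overlap_null.py` simulates a study in which 58% of the second
locus's acquisition events reuse prespacers already sampled by the first
locus, then scores the observed sharing against both nulls:

```
observed: 47.9% of 240 unique second-locus spacers match the 250-spacer first-locus pool at 90% identity
       random null: mean 1.9% (SD 0.91%), normal-tail p = 0, empirical p = 0.00332
 pam_adjacent null: mean 12.5% (SD 2.23%), normal-tail p = 4.17e-57, empirical p = 0.00332
```

Reading it: independent uniform sampling would share ~2% of spacers and
conditioning on the shared motif alone ~12%, so the observed ~48% overlap is
evidence for a common prespacer pool far beyond either null (the empirical p
is floored at 1/(iterations+1)). The other examples cover extraction
(`01`, lossless on clean reads), motif inference (`02`, SAM detected next to
62% of phage protospacers at π = 0.63, flank consensus `...TAAA...` with the
information concentrated in the four motif columns), and mRNA bias (`04`,
proportion 0.488 with p = 0.39 for an unbiased locus vs 0.881 with
p = 1.5e-30 for a biased one).

Each module is importable on its own (`spaceraq.read_processing`,
`.clustering`, `.mapping`, `.motifs`, `.target_stats`, `.overlap_null`,
`.synthetic_data`), and a thin CLI wraps the common steps:

```bash
spaceraq simulate --out sim/ --seed 1
spaceraq run --config sim/run_config.yaml --out results/
spaceraq extract|cluster|crossmatch|overlap-null|study --help
```

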