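import re

import numpy as np
import pytest

from spaceraq import (CANONICAL_SAM, GenomeRecord, OrfFeature, ParameterError,
                      build_pfm, count_motif, detect_sam, extract_flanks,
                      motif_offset_histogram)
from spaceraq._dna import IUPAC, revcomp
from spaceraq.mapping import ProtospacerHit


def hit(start, end, strand, genome_id="toy"):
    return ProtospacerHit(spacer="N", genome_id=genome_id, start=start, end=end,
                          strand=strand, score=60, mismatches=0)


def naive_motif_count(seq, motif):
    """Per-position IUPAC set check, both strands (independent oracle)."""
    def count_one(s, m):
        total = 0
        for i in range(len(s) - len(m) + 1):
            if all(s[i + j] in IUPAC[sym] for j, sym in enumerate(m)):
                total += 1
        return total
    return count_one(seq, motif) + count_one(revcomp(seq), motif)


class TestExtractFlanks:
    def test_plus_strand_flanks(self, toy_genome):
        ctx = extract_flanks(hit(100, 130, "+"), toy_genome)
        assert ctx.upstream == toy_genome.sequence[85:100]
        assert ctx.downstream == toy_genome.sequence[130:145]
        assert not ctx.upstream_truncated and not ctx.downstream_truncated

    def test_minus_strand_flanks_are_reverse_complements(self, toy_genome):
        ctx = extract_flanks(hit(100, 130, "-"), toy_genome)
        assert ctx.upstream == revcomp(toy_genome.sequence[130:145])
        assert ctx.downstream == revcomp(toy_genome.sequence[85:100])

    def test_linear_genome_truncates_at_edge(self, toy_genome):
        ctx = extract_flanks(hit(3, 33, "+"), toy_genome)
        assert ctx.upstream_truncated and len(ctx.upstream) == 3
        assert not ctx.downstream_truncated

    def test_circular_genome_wraps(self, toy_genome):
        circ = GenomeRecord(id="c", sequence=toy_genome.sequence,
                            topology="circular")
        ctx = extract_flanks(hit(3, 33, "+"), circ)
        assert not ctx.upstream_truncated
        assert ctx.upstream == circ.sequence[-12:] + circ.sequence[:3]

    def test_strand_flip_involution(self, toy_genome, rng):
        """Reverse-complementing the genome and flipping hit strands leaves
        the guide-oriented flank strings unchanged."""
        G = len(toy_genome)
        flipped = GenomeRecord(id="f", sequence=revcomp(toy_genome.sequence))
        for _ in range(20):
            s = int(rng.integers(20, G - 60))
            e = s + 30
            for strand in "+-":
                ctx = extract_flanks(hit(s, e, strand), toy_genome)
                other = "-" if strand == "+" else "+"
                ctx2 = extract_flanks(hit(G - e, G - s, other), flipped)
                assert ctx.upstream == ctx2.upstream
                assert ctx.downstream == ctx2.downstream


def ctx_with(downstream=None, upstream=None):
    from spaceraq.motifs import FlankContext
    return FlankContext(hit=None, upstream=upstream or "G" * 15,
                        downstream=downstream or "G" * 15,
                        upstream_truncated=False, downstream_truncated=False)


class TestDetectSam:
    def test_downstream_motif_at_offset_six(self, iic):
        assert detect_sam(ctx_with(downstream="GCGCG" + "TAAA" + "ACGTAC"), iic)

    def test_offset_matters(self, iic):
        assert not detect_sam(ctx_with(downstream="GCGC" + "TAAA" + "ACGTACG"), iic)

    def test_upstream_reverse_complement_for_leader_first_locus(self, vib):
        # TTTA at 1-based positions 7-10 of the upstream flank
        assert detect_sam(ctx_with(upstream="GCGCGC" + "TTTA" + "CGCGC"), vib)
        assert not detect_sam(ctx_with(upstream="GCGCG" + "TTTA" + "CGCGCC"), vib)

    def test_truncated_flank_is_indeterminate(self, iic):
        c = ctx_with(downstream="GCGCG" + "TAAA" + "ACGTAC")
        c.downstream_truncated = True
        assert detect_sam(c, iic) is None

    def test_shared_sam_equivalence_on_toy_genome(self, toy_genome, iic, vib):
        """The downstream-TAAA (array-to-leader) and upstream-TTTA
        (leader-to-array) conventions flag the same genomic protospacers on
        opposite crRNA strands — exhaustively over the toy genome."""
        G = len(toy_genome)
        for start in range(15, G - 45):
            end = start + 30
            for strand in "+-":
                other = "-" if strand == "+" else "+"
                a = detect_sam(extract_flanks(hit(start, end, strand), toy_genome), iic)
                b = detect_sam(extract_flanks(hit(start, end, other), toy_genome), vib)
                assert a == b


class TestPfm:
    def test_identical_flanks_have_full_information(self):
        contexts = [ctx_with(downstream="GCGCGTAAAACGTAC") for _ in range(10)]
        pfm = build_pfm(contexts, "downstream")
        assert pfm.n_sequences == 10
        assert np.allclose(pfm.information_content, 2.0)
        assert pfm.consensus() == "GCGCGTAAAACGTAC"

    def test_uniform_columns_have_zero_information(self):
        contexts = [ctx_with(downstream=b * 15) for b in "ACGT"]
        pfm = build_pfm(contexts, "downstream")
        assert np.allclose(pfm.information_content, 0.0)

    def test_no_usable_contexts_is_an_error(self):
        c = ctx_with()
        c.downstream_truncated = True
        with pytest.raises(ParameterError):
            build_pfm([c], "downstream")

    def test_column_sums_equal_n(self):
        contexts = [ctx_with(downstream="ACGTACGTACGTACG"),
                    ctx_with(downstream="TTTTTTTTTTTTTTT")]
        pfm = build_pfm(contexts, "downstream")
        assert (pfm.counts.sum(axis=0) == 2).all()


class TestCountMotif:
    def test_hand_enumerated_palindromic_pair(self):
        g = GenomeRecord(id="t", sequence="TAAATTTA")
        res = count_motif(g, "TAAA", scope="whole_genome")
        # forward TAAA at 0; reverse occurrence via TTTA at 4
        assert res.count_total == 2
        assert res.count_coding_strand == 1 and res.count_template_strand == 1

    def test_no_adenine_means_no_motif(self):
        g = GenomeRecord(id="t", sequence="GCGCGCGCGC")
        assert count_motif(g, "TAAA").count_total == 0

    def test_full_length_cds_equals_whole_genome(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=2000, p=[.34, .16, .16, .34]))
        g = GenomeRecord(id="t", sequence=seq,
                         features=[OrfFeature(id="o", start=0, end=2000, strand="+")])
        whole = count_motif(g, "TAAA", "whole_genome")
        cds = count_motif(g, "TAAA", "cds_only")
        assert (whole.count_total, whole.count_coding_strand) == \
               (cds.count_total, cds.count_coding_strand)

    def test_minus_strand_cds_swaps_labels(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=1000, p=[.34, .16, .16, .34]))
        plus = GenomeRecord(id="t", sequence=seq,
                            features=[OrfFeature(id="o", start=0, end=1000, strand="+")])
        minus = GenomeRecord(id="t", sequence=seq,
                             features=[OrfFeature(id="o", start=0, end=1000, strand="-")])
        a = count_motif(plus, "TAAA", "cds_only")
        b = count_motif(minus, "TAAA", "cds_only")
        assert a.count_coding_strand == b.count_template_strand
        assert a.count_template_strand == b.count_coding_strand

    def test_overlapping_occurrences_counted(self):
        g = GenomeRecord(id="t", sequence="TAAAAA")
        # TAAA at 0 only on +; TTTA absent; degenerate WAAA hits 0,1,2
        assert count_motif(g, "TAAA").count_coding_strand == 1
        assert count_motif(g, "WAAA").count_coding_strand == 3

    def test_unknown_symbol_rejected(self):
        g = GenomeRecord(id="t", sequence="ACGT")
        with pytest.raises((ParameterError, ValueError)):
            count_motif(g, "TAXA")

    @pytest.mark.parametrize("motif", ["TAAA", CANONICAL_SAM, "RYSW"])
    def test_matches_naive_oracle_on_random_genome(self, rng, motif):
        seq = "".join(rng.choice(list("ACGT"), size=5000, p=[.3, .2, .2, .3]))
        g = GenomeRecord(id="t", sequence=seq)
        assert count_motif(g, motif).count_total == naive_motif_count(seq, motif)


class TestOffsetHistogram:
    def test_offsets_resolved(self):
        contexts = [ctx_with(downstream="GCGCGTAAAGCGCGC"),
                    ctx_with(downstream="GCGTAAAGCGCGCGC")]
        hist = motif_offset_histogram(contexts, "TAAA", "downstream")
        assert hist == {5: 1, 3: 1}
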