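import io

import numpy as np
import pytest

from spaceraq import (AcquisitionParams, GenomeRecord, ParameterError,
                      ReadErrorModel, emit_amplicon_reads, generate_genome,
                      simulate_acquisition, write_fastq)
from spaceraq.read_processing import ExtractionConfig, extract_all


def _fastq_bytes(reads_by_key):
    buf = io.StringIO()
    for key in sorted(reads_by_key):
        for r in reads_by_key[key]:
            qual = "".join(chr(q + 33) for q in r.qualities)
            buf.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")
    return buf.getvalue()


class TestGenerateGenome:
    def test_deterministic_for_fixed_seed(self):
        a = generate_genome(50_000, 0.32, 0.9, seed=7)
        b = generate_genome(50_000, 0.32, 0.9, seed=7)
        assert a.sequence == b.sequence
        assert [(f.start, f.end, f.strand) for f in a.features] == \
               [(f.start, f.end, f.strand) for f in b.features]

    def test_zero_density_means_no_features(self):
        assert generate_genome(5000, 0.5, 0.0, seed=1).features == []

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_density_is_respected(self, seed):
        g = generate_genome(10_000, 0.32, 0.5, seed=seed)
        span = sum(f.length for f in g.features)
        assert 0.4 <= span / len(g) <= 0.6

    def test_overfull_density_rejected(self):
        with pytest.raises(ParameterError):
            generate_genome(5000, 0.5, 0.96, seed=1)

    def test_orfs_do_not_overlap(self):
        g = generate_genome(30_000, 0.32, 0.9, seed=3)
        feats = sorted(g.features, key=lambda f: f.start)
        for a, b in zip(feats, feats[1:]):
            assert a.end <= b.start


@pytest.fixture
def small_world(loci):
    phage = generate_genome(12_000, 0.32, 0.8, seed=11, genome_id="P")
    host = generate_genome(15_000, 0.32, 0.8, seed=12, genome_id="H",
                           topology="circular")
    return phage, host


class TestSimulateAcquisition:
    def test_full_pam_preference_flags_every_event(self, small_world, loci):
        phage, host = small_world
        p = AcquisitionParams(n_events=50, pam_preference=1.0, self_fraction=0.0)
        truth = simulate_acquisition(phage, host, loci, p, seed=1)
        assert all(e.sam_flag for e in truth.events)

    def test_zero_self_fraction_targets_only_phage(self, small_world, loci):
        phage, host = small_world
        p = AcquisitionParams(n_events=40, self_fraction=0.0)
        truth = simulate_acquisition(phage, host, loci, p, seed=2)
        assert {e.target_class for e in truth.events} == {"phage"}

    def test_full_sharing_makes_second_pool_subset_of_first(self, small_world, loci):
        phage, host = small_world
        p = AcquisitionParams(n_events=60, shared_pool_fraction=1.0,
                              self_fraction=0.0)
        truth = simulate_acquisition(phage, host, loci, p, seed=3)
        first = {(e.genome_id, e.start, e.end, e.strand)
                 for e in truth.for_locus(loci[0].locus_id)}
        second = {(e.genome_id, e.start, e.end, e.strand)
                  for e in truth.for_locus(loci[1].locus_id)}
        assert second <= first

    def test_pam_preference_without_motif_is_an_error(self, loci):
        # alternating GC genome: contains neither TAAA nor TTTA
        phage = GenomeRecord(id="noP", sequence="GC" * 2000)
        host = GenomeRecord(id="noH", sequence="CG" * 2000, topology="circular")
        p = AcquisitionParams(n_events=5, pam_preference=1.0, self_fraction=0.0)
        with pytest.raises(ParameterError):
            simulate_acquisition(phage, host, loci, p, seed=1)

    def test_spacer_is_crRNA_oriented_genome_slice(self, small_world, loci):
        from spaceraq._dna import revcomp
        phage, host = small_world
        p = AcquisitionParams(n_events=40, self_fraction=0.0)
        truth = simulate_acquisition(phage, host, loci, p, seed=5)
        for e in truth.events:
            sub = phage.sequence[e.start:e.end]
            assert e.spacer == (sub if e.strand == "+" else revcomp(sub))


class TestEmitReads:
    def test_depth_gives_exact_read_count(self, small_world, loci):
        phage, host = small_world
        p = AcquisitionParams(n_events=20, self_fraction=0.0)
        truth = simulate_acquisition(phage, host, loci, p, seed=4)
        reads = emit_amplicon_reads(truth, loci, depth_per_event=3,
                                    error_model=ReadErrorModel(0, 0, 0), seed=9)
        assert sum(len(v) for v in reads.values()) == 3 * len(truth.events)

    def test_error_free_reads_recover_truth_exactly(self, small_world, loci):
        phage, host = small_world
        p = AcquisitionParams(n_events=60, self_fraction=0.1)
        truth = simulate_acquisition(phage, host, loci, p, seed=6)
        em = ReadErrorModel(0, 0, 0, quality_mean=38, quality_sd=1)
        reads = emit_amplicon_reads(truth, loci, depth_per_event=1, error_model=em,
                                    seed=10)
        cfg = ExtractionConfig()
        for locus in loci:
            got = []
            for (lid, rep), rr in reads.items():
                if lid == locus.locus_id:
                    obs, summary = extract_all(rr, locus, cfg, replicate_id=rep)
                    got.extend(o.sequence for o in obs)
                    assert summary.n_extracted == summary.n_input
            from collections import Counter
            assert Counter(got) == truth.spacer_multiset(locus.locus_id)

    def test_substitution_rate_is_realized(self, small_world, loci):
        phage, host = small_world
        p = AcquisitionParams(n_events=50, self_fraction=0.0)
        truth = simulate_acquisition(phage, host, loci, p, seed=7)
        em = ReadErrorModel(substitution_rate=0.01, insertion_rate=0.0,
                            deletion_rate=0.0, quality_mean=38, quality_sd=1)
        reads = emit_amplicon_reads(truth, loci, depth_per_event=10,
                                    error_model=em, seed=11)
        by_id = {e.event_id: e for e in truth.events}
        locus_by_id = {l.locus_id: l for l in loci}
        mism = total = 0
        for (lid, rep), rr in reads.items():
            locus = locus_by_id[lid]
            for r in rr:
                ev = by_id[r.id.split("|")[0]]
                pad = (locus.preexisting_spacers[0] if locus.preexisting_spacers
                       else locus.leader * 4)
                template = locus.repeat + ev.spacer + locus.repeat + pad[:20]
                assert len(r.sequence) == len(template)  # no indels configured
                mism += sum(a != b for a, b in zip(r.sequence, template))
                total += len(template)
        assert 0.005 <= mism / total <= 0.02

    def test_identical_seed_gives_byte_identical_fastq(self, small_world, loci):
        phage, host = small_world
        p = AcquisitionParams(n_events=25)
        truth = simulate_acquisition(phage, host, loci, p, seed=8)
        em = ReadErrorModel()
        a = emit_amplicon_reads(truth, loci, 2, em, seed=13)
        b = emit_amplicon_reads(truth, loci, 2, em, seed=13)
        assert _fastq_bytes(a) == _fastq_bytes(b)

    def test_depth_zero_rejected(self, small_world, loci):
        phage, host = small_world
        truth = simulate_acquisition(phage, host, loci,
                                     AcquisitionParams(n_events=2), seed=1)
        with pytest.raises(ParameterError):
            emit_amplicon_reads(truth, loci, 0, ReadErrorModel(), seed=1)
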