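import numpy as np
import pytest
from hypothesis import given, strategies as st

from spaceraq import ClusterConfig, ParameterError, SpacerObservation, cluster_pool, cross_pool_fraction, sequence_identity
from spaceraq.clustering import bulk_best_identity

CFG = ClusterConfig()

dna = st.text(alphabet="ACGT", min_size=5, max_size=40)


def obs(seqs, locus="L", rep="r1"):
    return [SpacerObservation(sequence=s, locus_id=locus, replicate_id=rep,
                              source_read_id=f"read{i}") for i, s in enumerate(seqs)]


def naive_identity(a, b):
    """Independent re-implementation: pure-python offset scan."""
    best = 0
    for k in range(-(len(a) - 1), len(b)):
        m = sum(1 for i in range(len(a))
                if 0 <= k + i < len(b) and a[i] == b[k + i])
        best = max(best, m)
    return best / min(len(a), len(b))


def brute_force_clusters(seqs_with_counts, cfg):
    """All-pairs oracle with the same content-based ordering rule."""
    order = sorted(seqs_with_counts, key=lambda t: (-t[1], -len(t[0]), t[0]))
    reps, assign = [], {}
    for seq, _ in order:
        for rep in reps:
            shared_word = any(seq[i:i + cfg.word_size] in rep
                              for i in range(len(seq) - cfg.word_size + 1))
            if shared_word and naive_identity(seq, rep) >= cfg.within_pool_identity - 1e-12:
                assign[seq] = rep
                break
        else:
            reps.append(seq)
            assign[seq] = seq
    return assign


def mutate(rng, seq, k):
    s = list(seq)
    for pos in rng.choice(len(s), size=k, replace=False):
        s[pos] = rng.choice([b for b in "ACGT" if b != s[pos]])
    return "".join(s)


class TestSequenceIdentity:
    def test_identical_sequences(self, rng):
        s = "".join(rng.choice(list("ACGT"), size=30))
        assert sequence_identity(s, s) == 1.0

    def test_six_mismatches_in_frame(self, rng):
        a = "".join(rng.choice(list("ACGT"), size=30))
        b = mutate(rng, a, 6)
        # guard against an alternative offset scoring higher by chance
        assert naive_identity(a, b) == 24 / 30
        assert sequence_identity(a, b) == pytest.approx(24 / 30)

    def test_exact_substring_scores_one(self, rng):
        b = "".join(rng.choice(list("ACGT"), size=30))
        a = b[1:29]
        assert sequence_identity(a, b) == 1.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ParameterError):
            sequence_identity("", "ACGT")

    @given(dna, dna)
    def test_symmetric_and_bounded(self, a, b):
        ab = sequence_identity(a, b)
        assert ab == pytest.approx(sequence_identity(b, a))
        assert 0.0 <= ab <= 1.0

    @given(dna, dna)
    def test_matches_naive_reimplementation(self, a, b):
        assert sequence_identity(a, b) == pytest.approx(naive_identity(a, b))


class TestClusterPool:
    def test_distant_sequences_stay_apart(self, rng):
        s = "A" * 15 + "C" * 15
        t = "G" * 15 + "T" * 15
        pool = cluster_pool(obs([s, s, s, t]), CFG)
        sizes = sorted(c.size for c in pool.clusters)
        assert len(pool) == 2 and sizes == [1, 3]

    def test_threshold_boundary_inclusive(self, rng):
        a = "".join(rng.choice(list("ACGT"), size=30))
        b = mutate(rng, a, 6)
        assert naive_identity(a, b) == 0.8  # same-frame is the best offset
        assert len(cluster_pool(obs([a, b]), CFG)) == 1

    def test_below_threshold_splits(self, rng):
        rng2 = np.random.default_rng(77)
        a = "".join(rng2.choice(list("ACGT"), size=30))
        b = mutate(rng2, a, 7)
        assert naive_identity(a, b) == 23 / 30
        assert len(cluster_pool(obs([a, b]), CFG)) == 2

    def test_input_order_does_not_matter(self, rng):
        base = ["".join(rng.choice(list("ACGT"), size=30)) for _ in range(8)]
        seqs = base + [mutate(rng, b, 3) for b in base]
        p1 = cluster_pool(obs(seqs), CFG)
        p2 = cluster_pool(obs(list(reversed(seqs))), CFG)
        assert sorted(p1.representatives) == sorted(p2.representatives)

    def test_absolute_counts_conserved(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=28)) for _ in range(20)]
        seqs = seqs + seqs[:5]
        pool = cluster_pool(obs(seqs), CFG, view="absolute")
        assert sum(pool.counts()) == len(seqs)
        assert len(pool) <= len(set(seqs))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_greedy_equals_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        base = ["".join(rng.choice(list("ACGT"), size=int(rng.integers(27, 33))))
                for _ in range(12)]
        seqs = base + [mutate(rng, rng.choice(base), int(rng.integers(1, 8)))
                       for _ in range(28)]
        counts = {}
        for s in seqs:
            counts[s] = counts.get(s, 0) + 1
        pool = cluster_pool(obs(seqs), CFG)
        oracle = brute_force_clusters(list(counts.items()), CFG)
        got = {m: c.representative for c in pool.clusters for m, _ in c.members}
        assert got == oracle


class TestCrossPool:
    def test_self_comparison_is_one(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=30)) for _ in range(10)]
        pool = cluster_pool(obs(seqs), CFG)
        frac, _ = cross_pool_fraction(pool, pool, CFG)
        assert frac == 1.0

    def test_disjoint_random_pools_share_nothing(self, rng):
        a = ["".join(rng.choice(list("ACGT"), size=30)) for _ in range(50)]
        b = ["".join(rng.choice(list("ACGT"), size=30)) for _ in range(50)]
        # brute-force guard: no cross pair reaches 0.9
        assert all(naive_identity(x, y) < 0.9 for x in a for y in b)
        frac, _ = cross_pool_fraction(cluster_pool(obs(a), CFG),
                                      cluster_pool(obs(b), CFG), CFG)
        assert frac == 0.0

    def test_three_mismatches_count_at_boundary(self, rng):
        a = "".join(rng.choice(list("ACGT"), size=30))
        b = mutate(rng, a, 3)
        assert naive_identity(a, b) == 27 / 30  # exactly the 0.9 threshold
        frac, matched = cross_pool_fraction(cluster_pool(obs([b]), CFG),
                                            cluster_pool(obs([a]), CFG), CFG)
        assert frac == 1.0 and matched == [True]

    def test_monotone_in_reference(self, rng):
        q = ["".join(rng.choice(list("ACGT"), size=30)) for _ in range(20)]
        refs = q[:5] + ["".join(rng.choice(list("ACGT"), size=30)) for _ in range(10)]
        qp = cluster_pool(obs(q), CFG)
        prev = 0.0
        for n in (5, 10, 15):
            rp = cluster_pool(obs(refs[:n]), CFG)
            frac, _ = cross_pool_fraction(qp, rp, CFG)
            assert frac >= prev
            prev = frac

    def test_empty_query_rejected(self, rng):
        empty = cluster_pool(obs([]), CFG)
        ref = cluster_pool(obs(["ACGT" * 8]), CFG)
        with pytest.raises(ParameterError):
            cross_pool_fraction(empty, ref, CFG)


class TestBulkIdentity:
    @pytest.mark.parametrize("seed", [5, 6])
    def test_bulk_agrees_with_pairwise(self, seed):
        rng = np.random.default_rng(seed)
        refs = ["".join(rng.choice(list("ACGT"), size=int(rng.integers(27, 33))))
                for _ in range(15)]
        queries = [mutate(rng, rng.choice(refs), int(rng.integers(0, 6)))
                   for _ in range(20)]
        queries += ["".join(rng.choice(list("ACGT"), size=30)) for _ in range(10)]
        got = bulk_best_identity(queries, refs, 0.9)
        expected = [any(sequence_identity(q, r) >= 0.9 - 1e-12 for r in refs)
                    for q in queries]
        assert got.tolist() == expected
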